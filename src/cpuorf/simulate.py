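"""Synthetic genomes, transcript databases and lineage tables with planted
truth labels.

The generator emulates the study conditions the pipeline is built for: gene
families whose uORF peptides evolve under purifying selection (conserved
CPuORFs), under neutrality (controls), families whose curated transcripts
are predominantly uORF-mORF fusion isoforms ('spurious' uORFs), and
cross-order contaminant EST entries.  Sequences evolve along a star
phylogeny: per branch, substitutions are proposed at a fixed per-nucleotide
rate and accepted with probability 1 when synonymous and omega when
nonsynonymous (proposals creating stop codons are rejected), so the planted
dN/dS is directly controlled.  The focal species' families are additionally
written as a genome FASTA + GFF3 with two-exon gene models on alternating
strands, so the extraction stage is exercised end to end.

Everything is deterministic under the seed; ``emit_dataset`` writes
byte-identical files across runs with an equal configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._seq import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, revcomp
from .orfs import TranscriptRecord
from .search import SequenceDbEntry, write_fasta_db
from .taxonomy import Lineage, write_lineage_table

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedDataset",
    "ORDER_DEFS",
    "simulate_taxonomy",
    "evolve_gene_family",
    "simulate_dataset",
    "emit_dataset",
]

# order -> (category key, clade names below Viridiplantae, in root->tip order)
_STREPTO = ("Streptophyta",)
_EMBRYO = _STREPTO + ("Embryophyta",)
_EUPHYLLO = _EMBRYO + ("Tracheophyta", "Euphyllophyta")
_SPERM = _EUPHYLLO + ("Spermatophyta",)
_ANGIO = _SPERM + ("Magnoliophyta",)
_MESANGIO = _ANGIO + ("Mesangiospermae",)
_EUDICOT = _MESANGIO + ("eudicotyledons", "Gunneridae", "Pentapetalae")
_ROSID = _EUDICOT + ("rosids",)
_ASTERID = _EUDICOT + ("asterids",)
_MONOCOT = _MESANGIO + ("Liliopsida", "Petrosaviidae")

ORDER_DEFS: dict[str, tuple[str, tuple[str, ...]]] = {
    "Brassicales": ("malvids", _ROSID + ("malvids",)),
    "Malvales": ("malvids", _ROSID + ("malvids",)),
    "Malpighiales": ("fabids", _ROSID + ("fabids",)),
    "Fabales": ("fabids", _ROSID + ("fabids",)),
    "Solanales": ("lamiids", _ASTERID + ("lamiids",)),
    "Gentianales": ("lamiids", _ASTERID + ("lamiids",)),
    "Asterales": ("asterids_other", _ASTERID + ("campanulids",)),
    "Vitales": ("eudicots_other", _ROSID),  # rosids but neither fabids nor malvids
    "Caryophyllales": ("eudicots_other", _EUDICOT + ("Caryophyllales",)),
    "Poales": ("commelinids", _MONOCOT + ("commelinids",)),
    "Zingiberales": ("commelinids", _MONOCOT + ("commelinids",)),
    "Asparagales": ("monocots_other", _MONOCOT + ("Asparagales",)),
    "Amborellales": ("angiosperms_other", _ANGIO + ("Amborellales",)),
    "Pinales": ("gymnosperms", _SPERM + ("Acrogymnospermae", "Pinidae")),
    "Polypodiales": ("polypodiopsida", _EUPHYLLO + ("Polypodiopsida",)),
    "Funariales": ("embryophyta_other", _EMBRYO + ("Bryophyta",)),
    "Charales": ("streptophyta_other", _STREPTO + ("Charophyceae",)),
    "Chlamydomonadales": ("viridiplantae_other", ("Chlorophyta", "Chlorophyceae")),
}

ANGIOSPERM_ORDERS: tuple[str, ...] = tuple(
    o for o, (_, clades) in ORDER_DEFS.items() if "Magnoliophyta" in clades
)

FOCAL_SPECIES = "brassicales_ref"
FOCAL_ORDER = "Brassicales"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Family-class counts mirror the benchmark design: conserved families
    (uORF under strong purifying selection), neutral families (control),
    spurious-fusion families (conserved peptide, but the curated isoforms
    are predominantly uORF-mORF fusions) and contaminant sources (a
    cross-order mislabelled near-copy of one family member).
    """

    n_conserved: int = 20
    n_neutral: int = 20
    n_fusion: int = 10
    n_contaminants: int = 5
    omega_conserved: float = 0.05
    omega_neutral: float = 1.0
    omega_morf: float = 0.1
    fusion_isoform_fraction: float = 0.6
    orders_per_family: int = 7  # sampled from the non-focal angiosperm pool
    species_per_order: int = 2
    branch_proposals_per_nt: float = 0.25
    uorf_aa_len: int = 24  # residues after the initiator Met
    morf_aa_len: int = 60
    default_species_total: int = 20000  # declared per-species sequence counts
    contaminant_species_total: int = 6000
    gymnosperm_every: int = 3  # every k-th family gains a gymnosperm homolog
    contaminant_noise: float = 0.005
    seed: int = 1

    def __post_init__(self):
        for w in (self.omega_conserved, self.omega_neutral, self.omega_morf):
            if w <= 0:
                raise ValueError("omega values must be positive")
        if not 0.0 <= self.fusion_isoform_fraction <= 1.0:
            raise ValueError("fusion_isoform_fraction must be in [0,1]")


@dataclass
class TruthRecord:
    uorf_id: str
    label: str  # conserved | neutral | spurious_fusion
    planted_orders: list[str]
    true_fusion_ratio: float


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    lineages: dict[str, Lineage]
    species_totals: dict[str, int]
    transcripts: list[TranscriptRecord]  # focal-species truth transcripts
    db_entries: list[SequenceDbEntry]
    truth: list[TruthRecord]
    contaminant_entries: list[str]
    genome: dict[str, str]
    gff3: str


# ---------------------------------------------------------------------------
# taxonomy


def simulate_taxonomy(
    cfg: SimulationConfig, orders: dict[str, tuple[str, tuple[str, ...]]] | None = None
) -> tuple[dict[str, Lineage], dict[str, int]]:
    """Deterministic lineage table covering all 13 taxonomic categories."""
    orders = orders or ORDER_DEFS
    lineages: dict[str, Lineage] = {}
    totals: dict[str, int] = {}
    for order in orders:
        _, clades = orders[order]
        for i in range(cfg.species_per_order):
            sp = f"{order.lower()}_sp{i + 1}"
            lineages[sp] = Lineage(
                species_id=sp,
                clade_names=("Viridiplantae",) + clades + (order, sp),
                order_name=order,
            )
            totals[sp] = cfg.default_species_total
    _, focal_clades = orders[FOCAL_ORDER]
    lineages[FOCAL_SPECIES] = Lineage(
        species_id=FOCAL_SPECIES,
        clade_names=("Viridiplantae",) + focal_clades + (FOCAL_ORDER, FOCAL_SPECIES),
        order_name=FOCAL_ORDER,
    )
    totals[FOCAL_SPECIES] = cfg.default_species_total
    return lineages, totals


# ---------------------------------------------------------------------------
# sequence evolution


def _random_orf_codons(n_aa: int, rng: np.random.Generator) -> list[str]:
    """ATG + n_aa random sense codons + stop."""
    interior = [SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), n_aa)]
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    return ["ATG"] + interior + [stop]


def _mutate_codons(
    codons: list[str], omega: float, rate: float, rng: np.random.Generator
) -> list[str]:
    """One star-phylogeny branch: propose, then select on the peptide.

    Proposals land uniformly on interior codon positions (the initiator ATG
    and the stop codon are kept intact); synonymous proposals are always
    accepted, nonsynonymous ones with probability ``omega``, and proposals
    creating a stop codon are rejected.
    """
    out = list(codons)
    n_interior_nt = 3 * (len(out) - 2)
    if n_interior_nt <= 0:
        return out
    n_prop = int(rng.poisson(rate * n_interior_nt))
    for _ in range(n_prop):
        pos = int(rng.integers(n_interior_nt))
        ci, off = 1 + pos // 3, pos % 3
        old = out[ci]
        alts = [b for b in "ACGT" if b != old[off]]
        new = old[:off] + alts[int(rng.integers(3))] + old[off + 1 :]
        if new in STOP_CODONS:
            continue
        if GENETIC_CODE[new] == GENETIC_CODE[old] or rng.random() < omega:
            out[ci] = new
    return out


def _pad(n: int, rng: np.random.Generator) -> str:
    """Random nucleotide pad free of ATG triggers (any register)."""
    s = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, n))
    while "ATG" in s:
        s = s.replace("ATG", "ACG", 1)
    return s


def evolve_gene_family(
    ancestor_uorf: list[str],
    ancestor_morf: list[str],
    species: list[str],
    omega_uorf: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    """Evolve (uORF, mORF) codon sequences for each species on a star tree.

    Returns ``{species_id: (uorf_nt, morf_nt)}`` with stop codons included.
    """
    out = {}
    for sp in species:
        u = _mutate_codons(ancestor_uorf, omega_uorf, cfg.branch_proposals_per_nt, rng)
        m = _mutate_codons(ancestor_morf, cfg.omega_morf, cfg.branch_proposals_per_nt, rng)
        out[sp] = ("".join(u), "".join(m))
    return out


def _transcript_layout(
    uorf_nt: str, morf_nt: str, rng: np.random.Generator, fused: bool = False
) -> tuple[str, int, int]:
    """Assemble a transcript; returns (seq, morf_start, morf_end).

    Normal layout: [pad][uORF][spacer][mORF][pad] with the uORF wholly
    inside the 5'-UTR; the spacer carries a stop codon in the mORF's reading
    frame, as real transcripts almost always do just upstream of the main
    start codon.  Fused layout joins the uORF (stop removed) in frame to the
    mORF, producing a single long ORF, as minor fusion isoforms do.
    """
    p5 = _pad(8, rng)
    # TAA at spacer offset 4 is codon-aligned with the downstream mORF
    mid = _pad(4, rng) + "TAA" + _pad(3, rng)
    p3 = _pad(15, rng)
    if fused:
        seq = p5 + uorf_nt[:-3] + morf_nt + p3
        morf_start = len(p5) + len(uorf_nt) - 3
    else:
        seq = p5 + uorf_nt + mid + morf_nt + p3
        morf_start = len(p5) + len(uorf_nt) + len(mid)
    return seq, morf_start, morf_start + len(morf_nt)


def _noisy_copy(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Uniform substitution noise, sparing ``protected`` positions (the
    ORF-defining start/stop codons, so a copy stays a recognizable homolog)."""
    lst = list(seq)
    n = int(rng.poisson(rate * len(seq)))
    for _ in range(n):
        pos = int(rng.integers(len(lst)))
        if pos in protected:
            continue
        alts = [b for b in "ACGT" if b != lst[pos]]
        lst[pos] = alts[int(rng.integers(3))]
    return "".join(lst)


# ---------------------------------------------------------------------------
# dataset assembly


def _gff_feature(seqid, ftype, start, end, strand, attrs, phase="."):
    return f"{seqid}\tsim\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attrs}"


def _focal_gene(
    fam: str,
    transcript: TranscriptRecord,
    strand: str,
    rng: np.random.Generator,
) -> tuple[str, list[str]]:
    """Write one focal gene as a two-exon contig + GFF3 rows."""
    t = transcript.seq
    split = transcript.morf_start + 91  # intron inside the mORF, off codon boundary
    intron = "GT" + _pad(56, rng) + "AG"
    pad_l, pad_r = _pad(50, rng), _pad(50, rng)
    contig_plus = pad_l + t[:split] + intron + t[split:] + pad_r
    glen = len(contig_plus)

    def g(p: int) -> int:  # transcript offset -> 1-based genomic (plus layout)
        return 51 + p if p < split else 51 + p + len(intron)

    # 1-based inclusive plus-layout features
    exon1 = (g(0), g(split - 1))
    exon2 = (g(split), g(len(t) - 1))
    cds1 = (g(transcript.morf_start), g(split - 1))
    cds2 = (g(split), g(transcript.morf_end - 1))
    phase2 = str((3 - (cds1[1] - cds1[0] + 1) % 3) % 3)
    if strand == "-":
        contig = revcomp(contig_plus)
        flip = lambda se: (glen - se[1] + 1, glen - se[0] + 1)
        exon1, exon2 = flip(exon1), flip(exon2)
        cds1, cds2 = flip(cds1), flip(cds2)
        exon1, exon2 = sorted([exon1, exon2])
        cds1, cds2 = sorted([cds1, cds2])
        # phase of the 5'-most CDS piece (genomically last on minus strand)
        phase_by_start = {cds2: "0", cds1: phase2}
    else:
        contig = contig_plus
        phase_by_start = {cds1: "0", cds2: phase2}
    seqid = f"chr_{fam}"
    gid, tid = transcript.gene_id, transcript.transcript_id
    gene_span = (min(exon1[0], exon2[0]), max(exon1[1], exon2[1]))
    rows = [
        _gff_feature(seqid, "gene", *gene_span, strand, f"ID={gid}"),
        _gff_feature(seqid, "mRNA", *gene_span, strand, f"ID={tid};Parent={gid}"),
        _gff_feature(seqid, "exon", *exon1, strand, f"ID={tid}.e1;Parent={tid}"),
        _gff_feature(seqid, "exon", *exon2, strand, f"ID={tid}.e2;Parent={tid}"),
        _gff_feature(seqid, "CDS", *cds1, strand, f"ID={tid}.c1;Parent={tid}", phase_by_start[cds1]),
        _gff_feature(seqid, "CDS", *cds2, strand, f"ID={tid}.c2;Parent={tid}", phase_by_start[cds2]),
    ]
    return contig, rows


def simulate_dataset(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the full synthetic benchmark in memory."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    lineages, totals = simulate_taxonomy(cfg)

    labels = (
        ["conserved"] * cfg.n_conserved
        + ["neutral"] * cfg.n_neutral
        + ["spurious_fusion"] * cfg.n_fusion
    )
    contaminant_families = set(range(min(cfg.n_contaminants, cfg.n_conserved)))
    pool = [o for o in ANGIOSPERM_ORDERS if o != FOCAL_ORDER]

    transcripts: list[TranscriptRecord] = []
    db_entries: list[SequenceDbEntry] = []
    truth: list[TruthRecord] = []
    contaminant_entries: list[str] = []
    genome: dict[str, str] = {}
    gff_rows: list[str] = ["##gff-version 3"]

    for fam_idx, label in enumerate(labels):
        fam = f"fam{fam_idx + 1:03d}"
        omega_u = (
            cfg.omega_neutral if label == "neutral" else cfg.omega_conserved
        )
        anc_u = _random_orf_codons(cfg.uorf_aa_len, rng)
        anc_m = _random_orf_codons(cfg.morf_aa_len, rng)
        k = min(cfg.orders_per_family, len(pool))
        orders = [pool[int(i)] for i in rng.choice(len(pool), size=k, replace=False)]
        est_orders = set(orders[:1])  # one order's entries are EST-sourced
        species = [
            f"{o.lower()}_sp{i + 1}"
            for o in orders
            for i in range(cfg.species_per_order)
        ]
        evolved = evolve_gene_family(anc_u, anc_m, [FOCAL_SPECIES] + species, omega_u, cfg, rng)

        # focal gene -> genome + annotation
        u_nt, m_nt = evolved[FOCAL_SPECIES]
        seq, ms, me = _transcript_layout(u_nt, m_nt, rng)
        focal_t = TranscriptRecord(
            transcript_id=f"{fam}t1",
            gene_id=f"{fam}g",
            species_id=FOCAL_SPECIES,
            seq=seq,
            morf_start=ms,
            morf_end=me,
        )
        transcripts.append(focal_t)
        strand = "+" if fam_idx % 2 == 0 else "-"
        contig, rows = _focal_gene(fam, focal_t, strand, rng)
        genome[f"chr_{fam}"] = contig
        gff_rows.extend(rows)

        # companion transcripts
        curated = [sp for sp in species if _order_of(sp) not in est_orders]
        est = [sp for sp in species if _order_of(sp) in est_orders]
        n_fused = (
            int(round(cfg.fusion_isoform_fraction * len(curated)))
            if label == "spurious_fusion"
            else 0
        )
        fused_set = {
            curated[int(i)]
            for i in rng.choice(len(curated), size=n_fused, replace=False)
        }
        for sp in species:
            su, sm = evolved[sp]
            c_seq, _, _ = _transcript_layout(su, sm, rng, fused=sp in fused_set)
            source = "est" if sp in est else "curated_rna"
            out_seq = c_seq
            if source == "est" and fam_idx % 2 == 1:
                out_seq = revcomp(c_seq)  # ESTs deposited in either orientation
            db_entries.append(
                SequenceDbEntry(f"{fam}_{sp}", out_seq, sp, source)
            )
        # occasional gymnosperm homolog (excluded from Ka/Ks, kept for taxonomy)
        if fam_idx % cfg.gymnosperm_every == 0:
            sp = "pinales_sp1"
            gu = _mutate_codons(anc_u, omega_u, cfg.branch_proposals_per_nt, rng)
            gm = _mutate_codons(anc_m, cfg.omega_morf, cfg.branch_proposals_per_nt, rng)
            g_seq, _, _ = _transcript_layout("".join(gu), "".join(gm), rng)
            db_entries.append(SequenceDbEntry(f"{fam}_{sp}", g_seq, sp, "est"))

        # planted contaminant: a near-copy of one companion, mislabelled with
        # a species from an order outside this family
        if label == "conserved" and fam_idx in contaminant_families:
            source_sp = curated[0]
            host_order = next(
                o
                for o in pool
                if o != _order_of_name(source_sp) and o not in orders
            )
            host_sp = f"{host_order.lower()}_cx{fam_idx + 1}"
            lineages[host_sp] = Lineage(
                species_id=host_sp,
                clade_names=("Viridiplantae",)
                + ORDER_DEFS[host_order][1]
                + (host_order, host_sp),
                order_name=host_order,
            )
            totals[host_sp] = cfg.default_species_total
            src_entry = next(
                e for e in db_entries if e.entry_id == f"{fam}_{source_sp}"
            )
            u_len = len(evolved[source_sp][0])
            ms = 8 + u_len + 10  # layout: pad8 + uORF + spacer10 + mORF
            me = ms + len(evolved[source_sp][1])
            protected = frozenset(
                list(range(8, 11))  # uORF ATG
                + list(range(8 + u_len - 3, 8 + u_len))  # uORF stop
                + list(range(8 + u_len + 4, 8 + u_len + 7))  # spacer stop
                + list(range(ms, ms + 3))  # mORF ATG
                + list(range(me - 3, me))  # mORF stop
            )
            contam = _noisy_copy(
                src_entry.seq, cfg.contaminant_noise, rng, protected
            )
            eid = f"{fam}_contam"
            db_entries.append(SequenceDbEntry(eid, contam, host_sp, "est"))
            contaminant_entries.append(eid)
            totals[source_sp] = cfg.contaminant_species_total

        ratio = (len(fused_set) / len(curated)) if curated else 0.0
        truth.append(
            TruthRecord(
                uorf_id=f"{fam}t1.u1",
                label=label,
                planted_orders=sorted(set(orders)),
                true_fusion_ratio=ratio,
            )
        )

    return SimulatedDataset(
        config=cfg,
        lineages=lineages,
        species_totals=totals,
        transcripts=transcripts,
        db_entries=db_entries,
        truth=truth,
        contaminant_entries=contaminant_entries,
        genome=genome,
        gff3="\n".join(gff_rows) + "\n",
    )


def _order_of(sp: str) -> str:
    return sp.rsplit("_sp", 1)[0].capitalize()


def _order_of_name(sp: str) -> str:
    base = sp.rsplit("_sp", 1)[0]
    for o in ORDER_DEFS:
        if o.lower() == base:
            return o
    raise KeyError(sp)


def emit_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, GFF3, transcript DB FASTA, lineage TSV and truth
    JSON; byte-identical across runs with an equal seed/config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gff3": out / "annotation.gff3",
        "transcript_db": out / "transcripts.fa",
        "lineages": out / "lineages.tsv",
        "truth": out / "truth.json",
    }
    with open(paths["genome"], "w") as fh:
        for contig in sorted(ds.genome):
            fh.write(f">{contig}\n")
            seq = ds.genome[contig]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write(ds.gff3)
    write_fasta_db(ds.db_entries, paths["transcript_db"])
    lineages = {
        sp: Lineage(l.species_id, l.clade_names, l.order_name, ds.species_totals[sp])
        for sp, l in ds.lineages.items()
    }
    write_lineage_table(lineages, paths["lineages"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": asdict(ds.config),
                "focal_species": FOCAL_SPECIES,
                "families": [asdict(t) for t in ds.truth],
                "contaminant_entries": ds.contaminant_entries,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
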