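"""Ka/Ks conservation testing of candidate CPuORFs.

For each candidate, one representative homolog is chosen per order (smallest
geometric mean of the uORF and mORF search E-values, preferring subjects
whose mORF E-value is below 1e-20).  Angiosperm representatives' putative
uORF peptides are aligned, back-translated into a codon-delimited alignment,
and pairwise Ka and Ks (original vs each homolog) are estimated with the
Nei-Gojobori (1986) pathway-counting method under a Jukes-Cantor correction.
The null model replaces each homolog by artificial mutants of the original
uORF carrying the same number of nucleotide substitutions at random
positions, which preserves the mutation load while destroying any
amino-acid-level constraint; a one-sided Mann-Whitney U test asks whether
the observed Ka/Ks ratios are stochastically smaller than the null ratios,
with Benjamini-Hochberg FDR control across candidates.  A candidate is
accepted when its median Ka/Ks is below 0.5 and q < 0.05.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as sps

from ._seq import BASES, GENETIC_CODE, STOP_CODONS, is_stop, translate
from .homology import CandidateCpuorf, HomologHit
from .taxonomy import Lineage

__all__ = [
    "RepresentativeSet",
    "CodonAlignment",
    "KaksResult",
    "ConservationTest",
    "ConservationConfig",
    "select_representatives",
    "restrict_to_angiosperms",
    "align_proteins",
    "codon_delimited_alignment",
    "kaks_pair",
    "median_kaks",
    "generate_null_mutants",
    "null_kaks_ratios",
    "test_candidate",
    "adjust_fdr",
    "final_selection",
]

E_FLOOR = 1e-180  # floor applied before geometric means (external engines emit 0)

_ANGIOSPERM_NAMES = frozenset({"magnoliophyta", "angiospermae"})


@dataclass(frozen=True)
class ConservationConfig:
    rep_morf_e_max: float = 1e-20
    kaks_max_ratio: float = 0.5  # strict: median must be < this
    q_max: float = 0.05  # strict: q must be < this
    n_null_reps: int = 100  # mutant replicates per homolog
    all_pairs: bool = False  # median over all-vs-all instead of original-vs-each


@dataclass
class RepresentativeSet:
    candidate_id: str
    per_order: dict[str, HomologHit]  # exactly one representative per order


@dataclass
class CodonAlignment:
    """Codon-delimited alignment rows: (seq_id, aligned_nt, aligned_aa)."""

    rows: list[tuple[str, str, str]]
    n_codon_columns: int


@dataclass
class KaksResult:
    pairs: list[tuple[str, float, float, float | None]]  # (id, ka, ks, ratio)
    median_ratio: float | None
    n_excluded: int  # pairs with ks = 0 or saturated distances


@dataclass
class ConservationTest:
    candidate_id: str
    observed_ratios: list[float]
    null_ratios: list[float]
    u_statistic: float
    p_value: float
    q_value: float | None = None
    median_ratio: float | None = None
    accepted: bool | None = None


# ---------------------------------------------------------------------------
# representative selection


def _geometric_mean_e(h: HomologHit) -> float:
    eu = max(h.uorf_hit.evalue, E_FLOOR)
    em = max(h.morf_hit.evalue, E_FLOOR)
    return math.sqrt(eu * em)


def select_representatives(
    candidate: CandidateCpuorf, cfg: ConservationConfig | None = None
) -> RepresentativeSet:
    """One representative per order: smallest geometric mean of E-values
    among subjects with mORF E < 1e-20, falling back to all the order's
    hits when none passes that restriction."""
    cfg = cfg or ConservationConfig()
    per: dict[str, HomologHit] = {}
    for order in sorted(candidate.hits_by_order):
        hits = candidate.hits_by_order[order]
        pool = [h for h in hits if h.morf_hit.evalue < cfg.rep_morf_e_max] or list(hits)
        per[order] = min(
            pool, key=lambda h: (_geometric_mean_e(h), h.uorf_hit.subject_id)
        )
    return RepresentativeSet(candidate.uorf.uorf_id, per)


def restrict_to_angiosperms(
    reps: RepresentativeSet, lineages: dict[str, Lineage]
) -> RepresentativeSet:
    """Drop representative orders outside the flowering plants."""
    per = {
        order: h
        for order, h in reps.per_order.items()
        if _ANGIOSPERM_NAMES
        & {n.casefold() for n in lineages[h.species_id].clade_names}
    }
    return RepresentativeSet(reps.candidate_id, per)


# ---------------------------------------------------------------------------
# alignment

_MSA_ALIGNER: Align.PairwiseAligner | None = None


def _msa_aligner() -> Align.PairwiseAligner:
    global _MSA_ALIGNER
    if _MSA_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        _MSA_ALIGNER = a
    return _MSA_ALIGNER


def _merge_into_star(
    master_center: str, rows: list[str], c_gapped: str, s_gapped: str
) -> tuple[str, list[str], str]:
    """Merge one pairwise (center, seq) alignment into the growing MSA
    ('once a gap, always a gap')."""
    i = j = 0
    new_center: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_seq: list[str] = []
    while i < len(master_center) or j < len(c_gapped):
        mc = master_center[i] if i < len(master_center) else None
        cc = c_gapped[j] if j < len(c_gapped) else None
        if mc == "-" and cc != "-":
            new_center.append("-")
            for out, row in zip(new_rows, rows):
                out.append(row[i])
            new_seq.append("-")
            i += 1
        elif cc == "-" and mc != "-":
            new_center.append("-")
            for out in new_rows:
                out.append("-")
            new_seq.append(s_gapped[j])
            j += 1
        else:  # both residues (equal center char) or both gaps
            new_center.append(mc)
            for out, row in zip(new_rows, rows):
                out.append(row[i])
            new_seq.append(s_gapped[j])
            i += 1
            j += 1
    return "".join(new_center), ["".join(r) for r in new_rows], "".join(new_seq)


def align_proteins(aa_seqs: list[str]) -> list[str]:
    """Multiple protein alignment (progressive center-star, BLOSUM62).

    Rows are returned in input order and degap back to the inputs exactly.
    Any multiple-alignment provider honouring that contract may replace this
    built-in default.
    """
    if len(aa_seqs) < 2:
        raise ValueError("multiple alignment needs at least 2 sequences")
    if any(not s for s in aa_seqs):
        raise ValueError("empty sequence in multiple-alignment input")
    a = _msa_aligner()
    n = len(aa_seqs)
    # center = sequence with the greatest summed pairwise score
    totals = [0.0] * n
    for i, j in itertools.combinations(range(n), 2):
        s = float(a.score(aa_seqs[i], aa_seqs[j]))
        totals[i] += s
        totals[j] += s
    center = max(range(n), key=lambda i: (totals[i], -i))
    master = aa_seqs[center]
    rows: list[str] = []
    order: list[int] = []
    for i in range(n):
        if i == center:
            continue
        aln = next(iter(a.align(master.replace("-", ""), aa_seqs[i])))
        c_gapped, s_gapped = str(aln[0]), str(aln[1])
        # re-expand the pairwise center row to the current master gap pattern
        master, rows, new_row = _merge_into_star(master, rows, c_gapped, s_gapped)
        rows.append(new_row)
        order.append(i)
    out = [""] * n
    out[center] = master
    for i, row in zip(order, rows):
        out[i] = row
    return out


def codon_delimited_alignment(
    protein_msa: list[tuple[str, str]], nt_seqs: list[str]
) -> CodonAlignment:
    """Back-translate a protein MSA into a codon-delimited alignment.

    Each residue is replaced by its source codon and each gap by ``---``;
    terminal stop codons are excluded.  A nucleotide sequence that does not
    translate to its row's ungapped peptide is an error naming the row.
    """
    if len(protein_msa) != len(nt_seqs):
        raise ValueError("protein MSA and nucleotide list differ in length")
    widths = {len(aa) for _, aa in protein_msa}
    if len(widths) != 1:
        raise ValueError("protein MSA rows have unequal lengths")
    rows = []
    for (seq_id, aa_row), nt in zip(protein_msa, nt_seqs):
        core = nt
        if len(nt) % 3 == 0 and len(nt) >= 3 and is_stop(nt[-3:]):
            core = nt[:-3]
        if translate(core) != aa_row.replace("-", ""):
            raise ValueError(
                f"row {seq_id!r}: nucleotide sequence does not translate to its "
                "aligned peptide"
            )
        codons = [core[i : i + 3] for i in range(0, len(core), 3)]
        it = iter(codons)
        aligned_nt = "".join("---" if c == "-" else next(it) for c in aa_row)
        rows.append((seq_id, aligned_nt, aa_row))
    return CodonAlignment(rows=rows, n_codon_columns=widths.pop())


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pathway counting


@lru_cache(maxsize=None)
def _site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three alternative bases
    that are synonymous; changes producing a stop codon count as
    nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    All minimal substitution pathways are weighted equally; pathways passing
    through a stop codon are excluded unless every pathway does.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _valid_codon(c: str) -> bool:
    return "-" not in c and c in GENETIC_CODE


def kaks_pair(row_a: str, row_b: str) -> tuple[float, float]:
    """Nei-Gojobori Ka and Ks between two aligned codon rows.

    Codon columns containing a gap or an ambiguous base in either row are
    skipped (the spirit of seqinR's ``rmgap = FALSE``: no whole-column
    removal, only pairwise skipping).  Saturated proportions (p >= 3/4)
    yield NaN for that distance.
    """
    if len(row_a) != len(row_b) or len(row_a) % 3:
        raise ValueError("codon rows must be equal length multiples of 3")
    S = N = sd = nd = 0.0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if not (_valid_codon(ca) and _valid_codon(cb)):
            continue
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    if S <= 0.0:
        ks = 0.0 if sd == 0.0 else math.nan
    else:
        ks = _jukes_cantor(sd / S)
    if N <= 0.0:
        ka = 0.0 if nd == 0.0 else math.nan
    else:
        ka = _jukes_cantor(nd / N)
    return ka, ks


def _ratio(ka: float, ks: float) -> float | None:
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        return None
    return ka / ks


def median_kaks(
    original_row: tuple[str, str],
    homolog_rows: list[tuple[str, str]],
    all_pairs: bool = False,
) -> KaksResult:
    """Median Ka/Ks over pairwise combinations.

    Default pairing is original-vs-each-homolog (matching the null model's
    construction); ``all_pairs=True`` spans every pair among original and
    homologs.  Pairs with ks = 0 or saturated distances are excluded from
    the median and reported via ``n_excluded``.
    """
    rows = [original_row] + list(homolog_rows)
    if all_pairs:
        combos = list(itertools.combinations(range(len(rows)), 2))
    else:
        combos = [(0, j) for j in range(1, len(rows))]
    pairs = []
    for i, j in combos:
        ka, ks = kaks_pair(rows[i][1], rows[j][1])
        label = rows[j][0] if i == 0 else f"{rows[i][0]}|{rows[j][0]}"
        pairs.append((label, ka, ks, _ratio(ka, ks)))
    defined = [r for _, _, _, r in pairs if r is not None]
    return KaksResult(
        pairs=pairs,
        median_ratio=statistics.median(defined) if defined else None,
        n_excluded=len(pairs) - len(defined),
    )


# ---------------------------------------------------------------------------
# artificial-mutant null


def _pair_nt_differences(row_a: str, row_b: str) -> int:
    d = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if not (_valid_codon(ca) and _valid_codon(cb)):
            continue
        d += sum(1 for x, y in zip(ca, cb) if x != y)
    return d


def generate_null_mutants(
    original_row: str,
    homolog_rows: list[tuple[str, str]],
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Artificial mutants of the original uORF matching observed mutation loads.

    For each homolog, ``n_reps`` mutants of the (ungapped) original sequence
    are generated, each carrying exactly the homolog's observed nucleotide
    difference count at uniformly sampled distinct positions, each
    substituted base drawn uniformly from the three alternatives.  No indels
    are introduced; the result is reproducible under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orig = original_row.replace("-", "")
    out: list[tuple[str, str]] = []
    for hid, row in homolog_rows:
        d = _pair_nt_differences(original_row, row)
        if d > len(orig):
            raise ValueError(
                f"{hid}: difference count {d} exceeds sequence length {len(orig)}"
            )
        for r in range(n_reps):
            lst = list(orig)
            positions = rng.choice(len(orig), size=d, replace=False)
            for pos in sorted(int(p) for p in positions):
                alts = [b for b in BASES if b != lst[pos]]
                lst[pos] = alts[int(rng.integers(3))]
            out.append((f"{hid}.null{r + 1}", "".join(lst)))
    return out


def null_kaks_ratios(
    original_row: str,
    homolog_rows: list[tuple[str, str]],
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[float]:
    """Ka/Ks ratios of original-vs-mutant pairs (undefined pairs excluded)."""
    orig = original_row.replace("-", "")
    ratios = []
    for _, mut in generate_null_mutants(original_row, homolog_rows, n_reps, seed):
        ka, ks = kaks_pair(orig, mut)
        r = _ratio(ka, ks)
        if r is not None:
            ratios.append(r)
    return ratios


# ---------------------------------------------------------------------------
# testing


def _u_statistic(obs: list[float], null: list[float]) -> float:
    return sum(
        (1.0 if o > v else 0.5 if o == v else 0.0) for o in obs for v in null
    )


def test_candidate(
    observed_ratios: list[float], null_ratios: list[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test (observed stochastically smaller).

    Exact enumeration of all arrangements when both samples have at most 8
    observations; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    obs = [float(x) for x in observed_ratios]
    null = [float(x) for x in null_ratios]
    if not obs or not null:
        return math.nan, math.nan
    u_obs = _u_statistic(obs, null)
    if len(obs) <= 8 and len(null) <= 8:
        pooled = obs + null
        n = len(obs)
        total = le = 0
        idx_all = frozenset(range(len(pooled)))
        for idx in itertools.combinations(range(len(pooled)), n):
            x = [pooled[i] for i in idx]
            y = [pooled[i] for i in idx_all.difference(idx)]
            total += 1
            if _u_statistic(x, y) <= u_obs + 1e-9:
                le += 1
        return u_obs, le / total
    res = sps.mannwhitneyu(obs, null, alternative="less", method="asymptotic")
    return u_obs, float(res.pvalue)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, order-preserving; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = sps.false_discovery_control(p[mask], method="bh")
    return q


def final_selection(
    median_ratio: float | None,
    q_value: float,
    cfg: ConservationConfig | None = None,
) -> bool:
    """Accept iff median Ka/Ks < 0.5 and q < 0.05 (both strict)."""
    cfg = cfg or ConservationConfig()
    if median_ratio is None or math.isnan(q_value):
        return False
    return median_ratio < cfg.kaks_max_ratio and q_value < cfg.q_max
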