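"""Six-stage CPuORF discovery pipeline with resumable staged artifacts.

Stages (in order): ``extract`` (genome + GFF3 -> transcripts + uORF
catalogue), ``fusion`` (uORF-mORF fusion-ratio filter), ``search``
(cross-species homology, putative-ORF reconstruction, contaminant and
fusion-type removal, candidate selection), ``kaks`` (representative
selection, codon alignment, Ka/Ks, mutant null, Mann-Whitney + BH-FDR),
``taxonomy`` (13-category conservation profiles) and ``report``.

Every stage writes a TSV/JSON artifact into the working directory and is
skipped on rerun when its inputs (file checksums + configuration + seed)
are unchanged; stage outputs are the only interface between stages, so an
external search engine can replace stage 3 by supplying the same artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Align import MultipleSeqAlignment
from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import conservation as cons
from .fusion import FusionConfig, assess_fusion
from .homology import (
    CandidateCpuorf,
    ContaminantConfig,
    HomologyConfig,
    HomologHit,
    PutativeUorf,
    assemble_candidates,
)
from .orfs import (
    OrfSpan,
    TranscriptRecord,
    UorfRecord,
    build_transcripts,
    extract_uorfs,
    read_uorf_catalog,
    write_uorf_catalog,
)
from .search import AlignmentHit, TranslatedDb, read_fasta_db
from .taxonomy import TaxCategory, conservation_profile, read_lineage_table

logger = logging.getLogger(__name__)

STAGES = ("extract", "fusion", "search", "kaks", "taxonomy", "report")

__all__ = ["PipelineConfig", "PipelineResult", "run", "STAGES"]


@dataclass
class PipelineConfig:
    genome: str
    gff3: str
    transcript_db: str
    lineages: str
    workdir: str
    focal_species: str = "focal"
    fusion_max_ratio: float = 0.3
    fusion_min_support: int = 10
    fusion_uorf_e_max: float = 2000.0
    fusion_morf_e_max: float = 0.1
    homology_uorf_e_max: float = 2000.0
    homology_morf_e_max: float = 0.1
    contaminant_e_max: float = 1e-100
    contaminant_min_identity: float = 0.95
    contaminant_min_species_total: int = 5000
    representative_morf_e_max: float = 1e-20
    kaks_max_ratio: float = 0.5
    fdr_q_max: float = 0.05
    candidate_min_other_orders: int = 2
    n_null_reps: int = 100
    kaks_all_pairs: bool = False
    engine: str = "builtin"
    seed: int = 1
    # manual-curation hook: database entries to ignore entirely
    exclude_entries: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def fusion_cfg(self) -> FusionConfig:
        return FusionConfig(
            uorf_e_max=self.fusion_uorf_e_max,
            morf_e_max=self.fusion_morf_e_max,
            max_ratio=self.fusion_max_ratio,
            min_support=self.fusion_min_support,
        )

    def homology_cfg(self) -> HomologyConfig:
        return HomologyConfig(
            uorf_e_max=self.homology_uorf_e_max,
            morf_e_max=self.homology_morf_e_max,
            min_other_orders=self.candidate_min_other_orders,
        )

    def contaminant_cfg(self) -> ContaminantConfig:
        return ContaminantConfig(
            e_max=self.contaminant_e_max,
            min_identity=self.contaminant_min_identity,
            min_species_total=self.contaminant_min_species_total,
        )

    def conservation_cfg(self) -> cons.ConservationConfig:
        return cons.ConservationConfig(
            rep_morf_e_max=self.representative_morf_e_max,
            kaks_max_ratio=self.kaks_max_ratio,
            q_max=self.fdr_q_max,
            n_null_reps=self.n_null_reps,
            all_pairs=self.kaks_all_pairs,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    artifacts: dict[str, Path]
    report: pd.DataFrame
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# checksum-gated staging


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, workdir: Path, config: PipelineConfig):
        self.path = workdir / "manifest.json"
        self.config_digest = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def stage_key(self, stage: str, inputs: list[Path]) -> str:
        h = hashlib.sha256(self.config_digest.encode())
        for p in inputs:
            h.update(_file_digest(p).encode())
        return h.hexdigest()

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return self.data.get(stage) == key and all(p.exists() for p in outputs)

    def record(self, stage: str, key: str) -> None:
        self.data[stage] = key
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# artifact (de)serialization helpers

_TRANSCRIPT_COLS = ["transcript_id", "gene_id", "species_id", "seq", "morf_start", "morf_end"]


def _write_transcripts(ts: list[TranscriptRecord], path: Path) -> None:
    pd.DataFrame([asdict(t) for t in ts], columns=_TRANSCRIPT_COLS).to_csv(
        path, sep="\t", index=False
    )


def _read_transcripts(path: Path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"seq": str})
    return [
        TranscriptRecord(
            r.transcript_id, r.gene_id, r.species_id, r.seq, int(r.morf_start), int(r.morf_end)
        )
        for r in df.itertuples(index=False)
    ]


_HIT_COLS = [
    "uorf_id", "subject_id", "species_id", "order_name",
    "u_frame", "u_qs", "u_qe", "u_ss", "u_se", "u_score", "u_evalue", "u_identity",
    "m_frame", "m_qs", "m_qe", "m_ss", "m_se", "m_score", "m_evalue", "m_identity",
    "pu_start", "pu_end", "pu_nt", "pu_aa", "putative_morf_start",
]


def _hit_row(uorf_id: str, h: HomologHit) -> dict:
    u, m, pu = h.uorf_hit, h.morf_hit, h.putative_uorf
    return {
        "uorf_id": uorf_id, "subject_id": u.subject_id,
        "species_id": h.species_id, "order_name": h.order_name,
        "u_frame": u.frame, "u_qs": u.q_start, "u_qe": u.q_end,
        "u_ss": u.s_start, "u_se": u.s_end, "u_score": u.raw_score,
        "u_evalue": u.evalue, "u_identity": u.identity,
        "m_frame": m.frame, "m_qs": m.q_start, "m_qe": m.q_end,
        "m_ss": m.s_start, "m_se": m.s_end, "m_score": m.raw_score,
        "m_evalue": m.evalue, "m_identity": m.identity,
        "pu_start": pu.span.start, "pu_end": pu.span.end,
        "pu_nt": pu.nt_seq, "pu_aa": pu.aa_seq,
        "putative_morf_start": h.putative_morf_start,
    }


def _row_hit(r) -> HomologHit:
    uhit = AlignmentHit(
        r.uorf_id, r.subject_id, int(r.u_frame), int(r.u_qs), int(r.u_qe),
        int(r.u_ss), int(r.u_se), float(r.u_score), float(r.u_evalue),
        float(r.u_identity), "+" if int(r.u_frame) >= 0 else "-",
    )
    mhit = AlignmentHit(
        f"{r.uorf_id}.morf", r.subject_id, int(r.m_frame), int(r.m_qs), int(r.m_qe),
        int(r.m_ss), int(r.m_se), float(r.m_score), float(r.m_evalue),
        float(r.m_identity), "+" if int(r.m_frame) >= 0 else "-",
    )
    pu = PutativeUorf(
        r.subject_id,
        OrfSpan(int(r.pu_start), int(r.pu_end), int(r.pu_start) % 3),
        r.pu_nt,
        r.pu_aa,
    )
    return HomologHit(
        uorf_hit=uhit, morf_hit=mhit, putative_uorf=pu,
        putative_morf_start=int(r.putative_morf_start),
        species_id=r.species_id, order_name=r.order_name,
    )


def _candidate_seed(base_seed: int, uorf_id: str) -> np.random.Generator:
    return np.random.default_rng([base_seed % (2**31), zlib.crc32(uorf_id.encode()) % (2**31)])


# ---------------------------------------------------------------------------
# the pipeline


def run(config: PipelineConfig, upto: str = "report") -> PipelineResult:
    """Execute pipeline stages 1..``upto``, skipping fresh stages."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    if config.engine != "builtin":
        raise NotImplementedError(
            "only the builtin search engine is wired into the pipeline; adapt "
            "external tabular hits via cpuorf.search.load_external_hits"
        )
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(wd, config)
    art = {
        "transcripts": wd / "transcripts.tsv",
        "uorfs": wd / "uorfs.tsv",
        "fusion": wd / "fusion.tsv",
        "hits": wd / "hits.tsv",
        "attrition": wd / "attrition.tsv",
        "contaminants": wd / "contaminants.txt",
        "kaks": wd / "kaks.tsv",
        "alignments": wd / "alignments",
        "taxonomy": wd / "taxonomy.tsv",
        "report": wd / "report.tsv",
    }
    result = PipelineResult(config=config, artifacts=art, report=pd.DataFrame())
    n_upto = STAGES.index(upto)
    lineages = read_lineage_table(config.lineages)
    species_totals = {
        sp: l.seq_total for sp, l in lineages.items() if l.seq_total is not None
    }

    def _stage(name, inputs, outputs, fn):
        key = manifest.stage_key(name, [Path(p) for p in inputs])
        if manifest.fresh(name, key, outputs):
            logger.info("stage %s: up to date, skipped", name)
            result.stages_skipped.append(name)
            return
        fn()
        manifest.record(name, key)
        result.stages_run.append(name)

    # stage 1: extract -------------------------------------------------
    def do_extract():
        ts = build_transcripts(config.genome, config.gff3, config.focal_species)
        uorfs = []
        for t in ts:
            uorfs.extend(extract_uorfs(t))
        _write_transcripts(ts, art["transcripts"])
        write_uorf_catalog(uorfs, {t.transcript_id: t for t in ts}, art["uorfs"])
        logger.info("extract: %d transcripts, %d uORFs", len(ts), len(uorfs))

    _stage("extract", [config.genome, config.gff3], [art["transcripts"], art["uorfs"]], do_extract)
    if n_upto < 1:
        return result

    transcripts = {t.transcript_id: t for t in _read_transcripts(art["transcripts"])}
    uorfs = read_uorf_catalog(art["uorfs"])
    excluded = set(config.exclude_entries)
    db = TranslatedDb(
        [e for e in read_fasta_db(config.transcript_db) if e.entry_id not in excluded]
    )

    # stage 2: fusion ---------------------------------------------------
    def do_fusion():
        cfg = config.fusion_cfg()
        cache: dict[str, OrfSpan | None] = {}
        rows = []
        for u in uorfs:
            t = transcripts[u.transcript_id]
            a = assess_fusion(u, t.morf_nt, db, cfg, _largest_orf_cache=cache)
            rows.append(
                {
                    "uorf_id": a.uorf_id,
                    "n_fusion": a.n_fusion,
                    "n_separate": a.n_separate,
                    "ratio": "" if a.ratio is None else f"{a.ratio:.6f}",
                    "decision": a.decision,
                }
            )
            if a.decision != "retain":
                logger.info("uorf=%s discarded at fusion stage: %s", a.uorf_id, a.decision)
        pd.DataFrame(rows, columns=["uorf_id", "n_fusion", "n_separate", "ratio", "decision"]).to_csv(
            art["fusion"], sep="\t", index=False
        )

    _stage(
        "fusion",
        [art["uorfs"], art["transcripts"], config.transcript_db],
        [art["fusion"]],
        do_fusion,
    )
    if n_upto < 2:
        return result

    fusion_df = pd.read_csv(art["fusion"], sep="\t")
    retained_ids = set(fusion_df.loc[fusion_df.decision == "retain", "uorf_id"])

    # stage 3: search ---------------------------------------------------
    def do_search():
        hcfg = config.homology_cfg()
        ccfg = config.contaminant_cfg()
        hit_rows, attr_rows, contaminants = [], [], set()
        for u in uorfs:
            if u.uorf_id not in retained_ids:
                continue
            t = transcripts[u.transcript_id]
            res = assemble_candidates(
                u,
                t.morf_aa,
                db,
                lineages,
                species_totals,
                original_species=t.species_id,
                cfg=hcfg,
                contaminant_cfg=ccfg,
            )
            for h in res.hits:
                hit_rows.append(_hit_row(u.uorf_id, h))
            contaminants.update(res.contaminant_subjects)
            attr_rows.append(
                {
                    "uorf_id": u.uorf_id,
                    "n_clean_hits": len(res.hits),
                    "n_no_putative_uorf": res.n_no_putative_uorf,
                    "n_no_morf_hit": res.n_no_morf_hit,
                    "n_strand_conflict": res.n_strand_conflict,
                    "n_no_putative_morf": res.n_no_putative_morf,
                    "n_fusion_dropped": len(res.fusion_subjects),
                    "n_contaminant_dropped": len(res.contaminant_subjects),
                    "n_other_orders": res.candidate.n_other_orders if res.candidate else 0,
                    "is_candidate": bool(res.candidate),
                }
            )
        pd.DataFrame(hit_rows, columns=_HIT_COLS).to_csv(art["hits"], sep="\t", index=False)
        pd.DataFrame(attr_rows).to_csv(art["attrition"], sep="\t", index=False)
        art["contaminants"].write_text("".join(s + "\n" for s in sorted(contaminants)))

    _stage(
        "search",
        [art["fusion"], art["uorfs"], art["transcripts"], config.transcript_db, config.lineages],
        [art["hits"], art["attrition"], art["contaminants"]],
        do_search,
    )
    if n_upto < 3:
        return result

    def _load_candidates() -> list[CandidateCpuorf]:
        hits_df = pd.read_csv(art["hits"], sep="\t", dtype={"pu_nt": str, "pu_aa": str})
        attr = pd.read_csv(art["attrition"], sep="\t")
        cand_ids = list(attr.loc[attr.is_candidate, "uorf_id"])
        by_uorf: dict[str, dict[str, list[HomologHit]]] = {}
        for r in hits_df.itertuples(index=False):
            h = _row_hit(r)
            by_uorf.setdefault(r.uorf_id, {}).setdefault(h.order_name, []).append(h)
        umap = {u.uorf_id: u for u in uorfs}
        out = []
        for cid in cand_ids:
            orders = by_uorf.get(cid, {})
            own = lineages[transcripts[umap[cid].transcript_id].species_id].order_name
            out.append(
                CandidateCpuorf(
                    uorf=umap[cid],
                    hits_by_order=orders,
                    n_other_orders=sum(1 for o in orders if o != own),
                )
            )
        return out

    # stage 4: kaks -----------------------------------------------------
    def do_kaks():
        ccfg = config.conservation_cfg()
        art["alignments"].mkdir(exist_ok=True)
        rows = []
        for cand in _load_candidates():
            reps = cons.select_representatives(cand, ccfg)
            angio = cons.restrict_to_angiosperms(reps, lineages)
            row = {
                "uorf_id": cand.uorf.uorf_id,
                "n_orders": len(reps.per_order),
                "n_angiosperm_orders": len(angio.per_order),
                "median_kaks": np.nan,
                "n_pairs_excluded": 0,
                "u_statistic": np.nan,
                "p_value": np.nan,
            }

            def _rows(rep_set):
                names = [cand.uorf.uorf_id]
                aa = [cand.uorf.aa_seq]
                nt = [cand.uorf.nt_seq]
                for o in sorted(rep_set.per_order):
                    h = rep_set.per_order[o]
                    names.append(f"{o}|{h.uorf_hit.subject_id}")
                    aa.append(h.putative_uorf.aa_seq)
                    nt.append(h.putative_uorf.nt_seq)
                return names, aa, nt

            # exported alignments keep every representative order; only the
            # Ka/Ks analysis is restricted to angiosperms
            names_all, aa_all, nt_all = _rows(reps)
            if len(aa_all) >= 2:
                msa_all = cons.align_proteins(aa_all)
                calign_all = cons.codon_delimited_alignment(
                    list(zip(names_all, msa_all)), nt_all
                )
                _write_alignments(
                    cand.uorf.uorf_id, names_all, msa_all, calign_all, art["alignments"]
                )
            names, aa, nt = _rows(angio)
            if len(aa) >= 2:
                msa = cons.align_proteins(aa)
                calign = cons.codon_delimited_alignment(list(zip(names, msa)), nt)
                original_row = calign.rows[0][1]
                homolog_rows = [(sid, ntrow) for sid, ntrow, _ in calign.rows[1:]]
                kk = cons.median_kaks(
                    (names[0], original_row), homolog_rows, all_pairs=ccfg.all_pairs
                )
                observed = [r for _, _, _, r in kk.pairs if r is not None]
                null = cons.null_kaks_ratios(
                    original_row,
                    homolog_rows,
                    ccfg.n_null_reps,
                    _candidate_seed(config.seed, cand.uorf.uorf_id),
                )
                u_stat, p = cons.test_candidate(observed, null)
                row.update(
                    median_kaks=np.nan if kk.median_ratio is None else kk.median_ratio,
                    n_pairs_excluded=kk.n_excluded,
                    u_statistic=u_stat,
                    p_value=p,
                )
            else:
                logger.warning(
                    "uorf=%s: no angiosperm representatives; Ka/Ks skipped",
                    cand.uorf.uorf_id,
                )
            rows.append(row)
        df = pd.DataFrame(
            rows,
            columns=[
                "uorf_id", "n_orders", "n_angiosperm_orders", "median_kaks",
                "n_pairs_excluded", "u_statistic", "p_value",
            ],
        )
        df["q_value"] = cons.adjust_fdr(df["p_value"]) if len(df) else []
        df["accepted"] = [
            cons.final_selection(
                None if pd.isna(m) else float(m), float(q) if not pd.isna(q) else float("nan"), ccfg
            )
            for m, q in zip(df["median_kaks"], df["q_value"])
        ]
        df.to_csv(art["kaks"], sep="\t", index=False, float_format="%.6g")

    _stage(
        "kaks",
        [art["hits"], art["attrition"], art["uorfs"], config.lineages],
        [art["kaks"]],
        do_kaks,
    )
    if n_upto < 4:
        return result

    # stage 5: taxonomy -------------------------------------------------
    def do_taxonomy():
        ccfg = config.conservation_cfg()
        rows = []
        cats = [c.value for c in TaxCategory]
        for cand in _load_candidates():
            reps = cons.select_representatives(cand, ccfg)
            prof = conservation_profile(
                cand.uorf.uorf_id,
                reps,
                lineages,
                original_species=transcripts[cand.uorf.transcript_id].species_id,
            )
            row = {"uorf_id": cand.uorf.uorf_id, "original_category": prof.original_category.value}
            for c in TaxCategory:
                row[c.value] = prof.per_category.get(c, 0)
            rows.append(row)
        pd.DataFrame(rows, columns=["uorf_id", "original_category"] + cats).to_csv(
            art["taxonomy"], sep="\t", index=False
        )

    _stage(
        "taxonomy",
        [art["hits"], art["attrition"], art["uorfs"], config.lineages],
        [art["taxonomy"]],
        do_taxonomy,
    )
    if n_upto < 5:
        return result

    # stage 6: report ---------------------------------------------------
    def do_report():
        kaks_df = pd.read_csv(art["kaks"], sep="\t")
        tax_df = pd.read_csv(art["taxonomy"], sep="\t")
        ucat = pd.read_csv(art["uorfs"], sep="\t")
        fus = pd.read_csv(art["fusion"], sep="\t")
        rep = (
            kaks_df.loc[kaks_df.accepted]
            .merge(ucat[["uorf_id", "transcript_id", "gene_id", "aa_seq"]], on="uorf_id")
            .merge(fus[["uorf_id", "ratio"]], on="uorf_id")
            .merge(tax_df, on="uorf_id")
            .rename(columns={"ratio": "fusion_ratio"})
            .sort_values("uorf_id")
        )
        lead = [
            "uorf_id", "transcript_id", "gene_id", "aa_seq", "fusion_ratio",
            "n_orders", "n_angiosperm_orders", "median_kaks", "u_statistic",
            "p_value", "q_value", "accepted", "original_category",
        ]
        rep = rep[lead + [c.value for c in TaxCategory]]
        rep.to_csv(art["report"], sep="\t", index=False, float_format="%.6g")
        logger.info("report: %d accepted CPuORFs", len(rep))

    _stage(
        "report",
        [art["kaks"], art["taxonomy"], art["uorfs"], art["fusion"]],
        [art["report"]],
        do_report,
    )
    result.report = pd.read_csv(art["report"], sep="\t")
    return result


def _write_alignments(uorf_id, names, msa, calign, outdir: Path):
    safe = uorf_id.replace("/", "_")
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=name.replace(" ", "_"), description="") for name, row in zip(names, msa)]
    )
    with open(outdir / f"{safe}.protein.fa", "w") as fh:
        for name, row in zip(names, msa):
            fh.write(f">{name}\n{row}\n")
    with open(outdir / f"{safe}.protein.aln", "w") as fh:
        AlignIO.write(aln, fh, "clustal")
    with open(outdir / f"{safe}.codon.fa", "w") as fh:
        for name, ntrow, _ in calign.rows:
            fh.write(f">{name}\n{ntrow}\n")
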