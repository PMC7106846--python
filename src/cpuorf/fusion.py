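"""uORF-mORF fusion-ratio filter.

A uORF whose sequence is really the N-terminal part of the main protein will
show up, in curated transcripts of related species, *inside* the largest ORF
rather than upstream of it.  For each uORF, companion curated RNAs matching
both the uORF and its downstream mORF are classified as fusion type (uORF
match contained in the largest ORF, reading frame ignored) or separate type,
and the fusion ratio X/(X+Y) decides the uORF's fate: ratios >= 0.3 discard
it as 'spurious', and fewer than 10 informative companions discard it for
lack of support.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orfs import OrfSpan, UorfRecord, find_largest_orf
from .search import (
    AlignmentHit,
    ScoringParams,
    SequenceDbEntry,
    TranslatedDb,
    best_hit_per_subject,
    search_translated_query,
)

__all__ = ["FusionConfig", "FusionAssessment", "classify_companion_rna", "assess_fusion", "decide_fusion"]

_UNSET = object()


@dataclass(frozen=True)
class FusionConfig:
    uorf_e_max: float = 2000.0
    morf_e_max: float = 0.1
    max_ratio: float = 0.3  # inclusive: ratio >= max_ratio discards
    min_support: int = 10


@dataclass
class FusionAssessment:
    uorf_id: str
    n_fusion: int  # X
    n_separate: int  # Y
    ratio: float | None  # X/(X+Y); None when X+Y == 0
    decision: str  # retain | discard_high_ratio | discard_low_support


def classify_companion_rna(
    rna: SequenceDbEntry,
    uorf_hit: AlignmentHit | None,
    morf_hit: AlignmentHit | None,
    largest_orf: OrfSpan | None | object = _UNSET,
) -> str:
    """Classify one companion RNA as fusion / separate / uninformative.

    Uninformative when either hit is missing, the RNA has no complete
    forward-frame ORF, or the mORF match is not in the largest ORF's reading
    frame.  Fusion requires the uORF-matching nucleotide interval to be fully
    contained in the largest ORF (frame ignored); partial overlap counts as
    separate.
    """
    if uorf_hit is None or morf_hit is None:
        return "uninformative"
    orf = find_largest_orf(rna.seq) if largest_orf is _UNSET else largest_orf
    if orf is None:
        return "uninformative"
    if morf_hit.frame <= 0 or (morf_hit.frame - 1) != orf.start % 3:
        return "uninformative"
    if orf.start <= uorf_hit.s_start and uorf_hit.s_end <= orf.end:
        return "fusion"
    return "separate"


def decide_fusion(n_fusion: int, n_separate: int, cfg: FusionConfig) -> tuple[float | None, str]:
    """Apply the ratio/support thresholds to companion counts."""
    total = n_fusion + n_separate
    ratio = n_fusion / total if total else None
    if total < cfg.min_support:
        return ratio, "discard_low_support"
    if ratio >= cfg.max_ratio:
        return ratio, "discard_high_ratio"
    return ratio, "retain"


def assess_fusion(
    u: UorfRecord,
    morf_nt: str,
    curated_db,
    cfg: FusionConfig | None = None,
    params: ScoringParams | None = None,
    _largest_orf_cache: dict[str, OrfSpan | None] | None = None,
) -> FusionAssessment:
    """Compute the fusion ratio for one uORF against curated companion RNAs.

    Two-step translated search: the uORF nucleotide sequence against the
    curated database (permissive E-value), then the mORF sequence against the
    uORF-hit entries only (stringent E-value).  Entries with both hits are
    classified using their lowest-E-value hit per query.
    """
    cfg = cfg or FusionConfig()
    tdb = TranslatedDb.ensure(curated_db)
    curated = [e for e in tdb.entries if e.source == "curated_rna"]
    tdb = tdb.subset([e.entry_id for e in curated]) if len(curated) != len(tdb.entries) else tdb

    uorf_hits = search_translated_query(
        u.nt_seq, tdb, cfg.uorf_e_max, params=params, query_id=u.uorf_id
    )
    ubest = best_hit_per_subject(uorf_hits)
    if not ubest:
        ratio, decision = decide_fusion(0, 0, cfg)
        return FusionAssessment(u.uorf_id, 0, 0, ratio, decision)

    subset = tdb.subset(sorted(ubest))
    morf_hits = search_translated_query(
        morf_nt, subset, cfg.morf_e_max, params=params, query_id=f"{u.uorf_id}.morf"
    )
    mbest = best_hit_per_subject(morf_hits)

    cache = _largest_orf_cache if _largest_orf_cache is not None else {}
    n_fusion = n_separate = 0
    for sid in sorted(mbest):
        entry = tdb.by_id[sid]
        if sid not in cache:
            cache[sid] = find_largest_orf(entry.seq)
        cls = classify_companion_rna(entry, ubest[sid], mbest[sid], cache[sid])
        if cls == "fusion":
            n_fusion += 1
        elif cls == "separate":
            n_separate += 1
    ratio, decision = decide_fusion(n_fusion, n_separate, cfg)
    return FusionAssessment(u.uorf_id, n_fusion, n_separate, ratio, decision)
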