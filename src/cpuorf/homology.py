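"""Cross-species homology: putative-uORF reconstruction, gene-homology
verification through the mORF, contaminant screening, and candidate selection.

Hits from translated searches land anywhere inside a subject transcript, so
the actual homologous ORF has to be reconstructed around the matching region:
walk downstream in the hit's frame to the nearest stop codon, then take the
5'-most in-frame ATG upstream of that stop with no intervening stop.  The
same geometry, mirrored, locates the subject's putative mORF start; if that
start falls inside the putative uORF the subject is itself a uORF-mORF fusion
transcript and is discarded.  EST/TSA subjects additionally pass a
cross-order near-identity screen that flags probable contaminant sequences
(e.g. parasite or insect RNA deposited under a plant species name).

Candidates must retain clean hits in at least two orders other than the
query's own order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import is_stop, revcomp, translate
from .orfs import OrfSpan, UorfRecord
from .search import (
    AlignmentHit,
    ScoringParams,
    SequenceDbEntry,
    TranslatedDb,
    best_hit_per_subject,
    search_nucleotide_query,
    search_protein_query,
)
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

__all__ = [
    "PutativeUorf",
    "HomologHit",
    "CandidateCpuorf",
    "HomologyConfig",
    "ContaminantConfig",
    "extract_putative_uorf",
    "locate_putative_morf",
    "detect_contaminant",
    "assemble_candidates",
    "HomologySearchResult",
]


@dataclass(frozen=True)
class HomologyConfig:
    uorf_e_max: float = 2000.0
    morf_e_max: float = 0.1
    min_other_orders: int = 2


@dataclass(frozen=True)
class ContaminantConfig:
    e_max: float = 1e-100
    min_identity: float = 0.95
    min_species_total: int = 5000
    word_size: int = 11


@dataclass
class PutativeUorf:
    """A reconstructed ORF on the sense-normalized subject."""

    subject_id: str
    span: OrfSpan  # coordinates on the sense-normalized subject
    nt_seq: str
    aa_seq: str


@dataclass
class HomologHit:
    uorf_hit: AlignmentHit
    morf_hit: AlignmentHit
    putative_uorf: PutativeUorf
    putative_morf_start: int
    species_id: str
    order_name: str
    contaminant: bool = False
    fusion_type: bool = False


@dataclass
class CandidateCpuorf:
    uorf: UorfRecord
    hits_by_order: dict[str, list[HomologHit]]
    n_other_orders: int


@dataclass
class HomologySearchResult:
    """Per-uORF outcome of the homology stage, with attrition accounting."""

    candidate: CandidateCpuorf | None
    hits: list[HomologHit] = field(default_factory=list)  # clean hits only
    contaminant_subjects: list[str] = field(default_factory=list)
    fusion_subjects: list[str] = field(default_factory=list)
    n_no_putative_uorf: int = 0
    n_no_morf_hit: int = 0
    n_strand_conflict: int = 0
    n_no_putative_morf: int = 0


def _normalized(hit: AlignmentHit, subject_seq: str) -> tuple[str, int, int]:
    """Sense-normalize a translated hit: (seq, match_start, match_end).

    Negative-frame hits reverse-complement the subject and remap the
    matching region; the returned match start is codon-aligned in the hit's
    reading frame on the normalized strand.
    """
    if hit.frame >= 0:
        return subject_seq, hit.s_start, hit.s_end
    L = len(subject_seq)
    return revcomp(subject_seq), L - hit.s_end, L - hit.s_start


def extract_putative_uorf(
    hit: AlignmentHit, subject: SequenceDbEntry
) -> PutativeUorf | None:
    """Reconstruct the putative uORF around a uORF-matching region.

    (i) select the downstream in-frame stop codon closest to the 5' end of
    the matching region; (ii) select the 5'-most in-frame ATG upstream of
    that stop with no intervening in-frame stop.  Returns None (hit
    discarded) when either codon cannot be found.
    """
    seq, a, _ = _normalized(hit, subject.seq)
    stop_at = None
    p = a
    while p + 3 <= len(seq):
        if is_stop(seq[p : p + 3]):
            stop_at = p
            break
        p += 3
    if stop_at is None:
        return None
    atg = None
    q = stop_at - 3
    while q >= 0:
        codon = seq[q : q + 3]
        if is_stop(codon):
            break
        if codon == "ATG":
            atg = q
        q -= 3
    if atg is None:
        return None
    nt = seq[atg : stop_at + 3]
    return PutativeUorf(
        subject_id=subject.entry_id,
        span=OrfSpan(atg, stop_at + 3, atg % 3),
        nt_seq=nt,
        aa_seq=translate(nt)[:-1],
    )


def locate_putative_morf(
    morf_hit: AlignmentHit, subject: SequenceDbEntry, pu: PutativeUorf
) -> tuple[int | None, bool | None]:
    """Locate the putative mORF start; flag overlap with the putative uORF.

    (iii) the upstream in-frame stop codon closest to the 5' end of the
    mORF-matching region bounds the scan (sequence start if absent);
    (iv) the 5'-most in-frame ATG downstream of that boundary is the
    putative mORF initiation codon.  Returns ``(None, None)`` when no ATG
    exists (hit discarded), else ``(start, fusion_type)`` where fusion_type
    means the mORF initiates before the putative uORF terminates.
    """
    seq, a, _ = _normalized(morf_hit, subject.seq)
    boundary = a % 3
    q = a - 3
    while q >= 0:
        if is_stop(seq[q : q + 3]):
            boundary = q + 3
            break
        q -= 3
    p = boundary
    while p + 3 <= len(seq):
        if seq[p : p + 3] == "ATG":
            return p, p < pu.span.end
        p += 3
    return None, None


def detect_contaminant(
    hit_seq: SequenceDbEntry,
    global_db,
    lineages: dict[str, Lineage],
    species_totals: dict[str, int],
    cfg: ContaminantConfig | None = None,
    params: ScoringParams | None = None,
) -> bool:
    """Cross-order near-identity screen for contaminant EST/TSA sequences.

    A nucleotide search of the hit sequence against the full database
    (both strands, E < 1e-100, identity >= 95%) triggers contaminant
    candidacy only when matches come from a *different order*.  The ratio of
    matching entries to the species' declared total sequence count is then
    compared: the hit is a contaminant iff its own species' ratio is lower
    than that of at least one cross-order matching species, considering only
    species with declared totals >= 5000 as comparators.
    """
    cfg = cfg or ContaminantConfig()
    if hit_seq.species_id not in lineages:
        raise ValueError(f"species {hit_seq.species_id!r} missing from lineage table")
    matches = search_nucleotide_query(
        hit_seq.seq,
        global_db,
        cfg.e_max,
        cfg.min_identity,
        params=params,
        query_id=hit_seq.entry_id,
        word_size=cfg.word_size,
    )
    tdb = TranslatedDb.ensure(global_db)
    counts: dict[str, set[str]] = {}
    for h in matches:
        sp = tdb.by_id[h.subject_id].species_id
        counts.setdefault(sp, set()).add(h.subject_id)
    self_sp = hit_seq.species_id
    self_order = lineages[self_sp].order_name
    cross = []
    for sp in sorted(counts):
        if sp == self_sp:
            continue
        if sp not in lineages:
            raise ValueError(f"species {sp!r} missing from lineage table")
        if lineages[sp].order_name != self_order:
            cross.append(sp)
    if not cross:
        return False
    qualifying = [
        sp for sp in cross if species_totals.get(sp, 0) >= cfg.min_species_total
    ]
    if not qualifying:
        return False
    self_total = species_totals.get(self_sp)
    if not self_total:
        raise ValueError(f"no declared sequence total for species {self_sp!r}")
    r_self = len(counts.get(self_sp, ())) / self_total
    return any(
        r_self < len(counts[sp]) / species_totals[sp] for sp in qualifying
    )


def assemble_candidates(
    u: UorfRecord,
    morf_aa: str,
    db,
    lineages: dict[str, Lineage],
    species_totals: dict[str, int],
    original_species: str,
    cfg: HomologyConfig | None = None,
    contaminant_cfg: ContaminantConfig | None = None,
    params: ScoringParams | None = None,
) -> HomologySearchResult:
    """Run the full homolog search for one uORF and select it as a candidate.

    uORF-tBLASTn (excluding the query's own species) seeds putative-uORF
    reconstruction from the lowest-E hit per subject; mORF-tBLASTn on those
    subjects verifies gene homology; fusion-type subjects and EST/TSA
    contaminants are dropped; surviving hits are grouped by taxonomic order
    and a candidate is emitted iff clean hits remain in at least
    ``min_other_orders`` orders besides the query species' own.
    """
    cfg = cfg or HomologyConfig()
    tdb = TranslatedDb.ensure(db)
    res = HomologySearchResult(candidate=None)
    if original_species not in lineages:
        raise ValueError(f"species {original_species!r} missing from lineage table")
    original_order = lineages[original_species].order_name

    uorf_hits = search_protein_query(
        u.aa_seq,
        tdb,
        cfg.uorf_e_max,
        exclude_species={original_species},
        params=params,
        query_id=u.uorf_id,
    )
    ubest = best_hit_per_subject(uorf_hits)
    if not ubest:
        return res

    putative: dict[str, PutativeUorf] = {}
    for sid in sorted(ubest):
        pu = extract_putative_uorf(ubest[sid], tdb.by_id[sid])
        if pu is None:
            res.n_no_putative_uorf += 1
            logger.info("uorf=%s subject=%s dropped: no putative uORF", u.uorf_id, sid)
        else:
            putative[sid] = pu
    if not putative:
        return res

    subset = tdb.subset(sorted(putative))
    morf_hits = search_protein_query(
        morf_aa, subset, cfg.morf_e_max, params=params, query_id=f"{u.uorf_id}.morf"
    )
    mbest = best_hit_per_subject(morf_hits)

    clean: list[HomologHit] = []
    for sid in sorted(putative):
        subject = tdb.by_id[sid]
        uhit = ubest[sid]
        pu = putative[sid]
        mhit = mbest.get(sid)
        if mhit is None:
            res.n_no_morf_hit += 1
            logger.info("uorf=%s subject=%s dropped: no mORF hit", u.uorf_id, sid)
            continue
        if (uhit.frame < 0) != (mhit.frame < 0):
            res.n_strand_conflict += 1
            logger.info("uorf=%s subject=%s dropped: strand conflict", u.uorf_id, sid)
            continue
        morf_start, fusion = locate_putative_morf(mhit, subject, pu)
        if morf_start is None:
            res.n_no_putative_morf += 1
            logger.info("uorf=%s subject=%s dropped: no putative mORF", u.uorf_id, sid)
            continue
        if fusion:
            res.fusion_subjects.append(sid)
            logger.info("uorf=%s subject=%s dropped: uORF-mORF fusion type", u.uorf_id, sid)
            continue
        if subject.source in ("est", "tsa") and detect_contaminant(
            subject, tdb, lineages, species_totals, contaminant_cfg, params=None
        ):
            res.contaminant_subjects.append(sid)
            logger.info("uorf=%s subject=%s dropped: contaminant", u.uorf_id, sid)
            continue
        if subject.species_id not in lineages:
            raise ValueError(f"species {subject.species_id!r} missing from lineage table")
        clean.append(
            HomologHit(
                uorf_hit=uhit,
                morf_hit=mhit,
                putative_uorf=pu,
                putative_morf_start=morf_start,
                species_id=subject.species_id,
                order_name=lineages[subject.species_id].order_name,
            )
        )
    res.hits = clean
    by_order: dict[str, list[HomologHit]] = {}
    for h in clean:
        by_order.setdefault(h.order_name, []).append(h)
    n_other = sum(1 for o in by_order if o != original_order)
    if n_other >= cfg.min_other_orders:
        res.candidate = CandidateCpuorf(
            uorf=u, hits_by_order=by_order, n_other_orders=n_other
        )
    return res
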