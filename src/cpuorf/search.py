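"""Desk-scale translated/nucleotide homology search.

This module emulates the tBLASTn / tBLASTx / BLASTn searches the pipeline
needs: six-frame translation, optimal Smith-Waterman local alignment with
affine gaps (via Biopython's PairwiseAligner), and Karlin-Altschul E-values
``E = K * m * n * exp(-lambda * S)``.  It is an exact local aligner rather
than a seeded heuristic, so scores are optimal; E-values use ungapped
Karlin-Altschul constants and therefore only approximate what a production
engine such as NCBI BLAST+ would report.  All E-value thresholds downstream
are configuration, and :func:`load_external_hits` adapts the standard
12-column tabular format so an external engine can be swapped in.

Conventions: subject spans are reported in nucleotides on the subject's
sense strand, 0-based half-open.  Translated frames are +1..+3 (sense
offsets 0..2) and -1..-3 (reverse complement offsets 0..2); stop codons
translate to '*' and score through the matrix's '*' column, which prevents
local alignments from spanning stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp, translate

__all__ = [
    "SequenceDbEntry",
    "ScoringParams",
    "AlignmentHit",
    "FrameTranslation",
    "TranslatedDb",
    "translate_frames",
    "align_local",
    "align_score",
    "evalue_from_score",
    "search_protein_query",
    "search_translated_query",
    "search_nucleotide_query",
    "load_external_hits",
    "best_hit_per_subject",
    "read_fasta_db",
    "write_fasta_db",
]

SOURCES = ("curated_rna", "est", "tsa", "contig")


@dataclass
class SequenceDbEntry:
    entry_id: str
    seq: str
    species_id: str
    source: str = "curated_rna"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r} for {self.entry_id}")


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring plus Karlin-Altschul statistics.

    ``db_size`` is the total number of nucleotide residues in the searched
    database (search functions fill it in automatically when left at 0).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.3176  # nats per raw-score unit (BLOSUM62 ungapped)
    kappa: float = 0.134
    db_size: int = 1
    match: float = 2.0  # used only when matrix_name == "DNA"
    mismatch: float = -3.0

    def __post_init__(self):
        if self.lambda_ <= 0 or self.kappa <= 0 or self.db_size < 0:
            raise ValueError("lambda and kappa must be positive, db_size >= 0")

    @classmethod
    def protein_default(cls, db_size: int = 1) -> "ScoringParams":
        return cls(db_size=max(int(db_size), 1))

    @classmethod
    def nucleotide_default(cls, db_size: int = 1) -> "ScoringParams":
        # match/mismatch +2/-3, gap 5/2; approximate ungapped constants
        return cls(
            matrix_name="DNA",
            gap_open=5.0,
            gap_extend=2.0,
            lambda_=0.625,
            kappa=0.41,
            db_size=max(int(db_size), 1),
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment match.

    ``frame`` is +1..+3 / -1..-3 for translated subjects and 0 for
    protein-protein or nucleotide-nucleotide alignments (``strand`` then
    carries the orientation).  Subject spans are nucleotides on the sense
    strand; query spans are residues of whatever the query was (nucleotides
    for nucleotide/translated queries, amino acids for protein queries).
    """

    query_id: str
    subject_id: str
    frame: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: float
    evalue: float
    identity: float
    strand: str = "+"

    def __post_init__(self):
        if not (self.s_start < self.s_end):
            raise ValueError("subject span must be non-empty")
        if self.evalue < 0 or not (0.0 <= self.identity <= 1.0):
            raise ValueError("invalid evalue/identity")


# ---------------------------------------------------------------------------
# aligner plumbing


def _dna_matrix(match: float, mismatch: float):
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    # N is scored as neutral
    for a in "ACGTN":
        m[a, "N"] = 0.0
        m["N", a] = 0.0
    return m

_ALIGNERS: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(p: ScoringParams) -> Align.PairwiseAligner:
    key = (p.matrix_name, p.gap_open, p.gap_extend, p.match, p.mismatch)
    a = _ALIGNERS.get(key)
    if a is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        if p.matrix_name == "DNA":
            a.substitution_matrix = _dna_matrix(p.match, p.mismatch)
        else:
            a.substitution_matrix = substitution_matrices.load(p.matrix_name)
        # gap of length k costs gap_open + k * gap_extend
        a.open_gap_score = -(p.gap_open + p.gap_extend)
        a.extend_gap_score = -p.gap_extend
        _ALIGNERS[key] = a
    return a


def _sanitize(seq: str, alphabet: str, fallback: str) -> str:
    if all(c in alphabet for c in seq):
        return seq
    return "".join(c if c in alphabet else fallback for c in seq)


def _prepare(q: str, s: str, p: ScoringParams) -> tuple[Align.PairwiseAligner, str, str]:
    a = _aligner(p)
    alphabet = str(a.substitution_matrix.alphabet)
    fallback = "N" if p.matrix_name == "DNA" else "X"
    return a, _sanitize(q, alphabet, fallback), _sanitize(s, alphabet, fallback)


def align_score(q: str, s: str, p: ScoringParams) -> float:
    """Optimal local-alignment score only (fast path, no traceback)."""
    if not q or not s:
        return 0.0
    a, q, s = _prepare(q, s, p)
    return float(a.score(q, s))


def align_local(
    q: str, s: str, p: ScoringParams
) -> tuple[float, tuple[int, int], tuple[int, int], float] | None:
    """Optimal Smith-Waterman local alignment under affine gaps.

    Returns ``(raw_score, (q_start, q_end), (s_start, s_end), identity)`` or
    None when the best score is <= 0.  Identity is exact matches divided by
    the alignment length (gap columns included), as BLAST reports it.
    """
    if not q or not s:
        return None
    a, qs_, ss_ = _prepare(q, s, p)
    score = float(a.score(qs_, ss_))
    if score <= 0:
        return None
    aln = next(iter(a.align(qs_, ss_)))
    qb, sb = aln.aligned
    matches = 0
    cols = 0
    prev = None
    for (q0, q1), (s0, s1) in zip(qb, sb):
        if prev is not None:
            cols += (q0 - prev[0]) + (s0 - prev[1])
        matches += sum(1 for i in range(q1 - q0) if q[q0 + i] == s[s0 + i])
        cols += q1 - q0
        prev = (q1, s1)
    q_span = (int(qb[0][0]), int(qb[-1][1]))
    s_span = (int(sb[0][0]), int(sb[-1][1]))
    return score, q_span, s_span, matches / cols


def evalue_from_score(raw_score: float, m: int, p: ScoringParams) -> float:
    """Karlin-Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    exponent = -p.lambda_ * raw_score
    if exponent > 700.0:
        return math.inf
    return p.kappa * m * p.db_size * math.exp(exponent)


# ---------------------------------------------------------------------------
# six-frame translation


@dataclass(frozen=True)
class FrameTranslation:
    """One translation frame with its sense-strand coordinate map."""

    frame: int  # +1..+3 or -1..-3
    offset: int  # 0..2 within the translated strand
    peptide: str
    seq_len: int

    def nt_span(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Sense-strand nucleotide span of peptide slice [p_start, p_end)."""
        lo = self.offset + 3 * p_start
        hi = self.offset + 3 * p_end
        if self.frame > 0:
            return lo, hi
        return self.seq_len - hi, self.seq_len - lo


def translate_frames(nt: str) -> list[FrameTranslation]:
    """All six reading-frame translations (empty list when len < 3)."""
    if len(nt) < 3:
        return []
    out = []
    rc = revcomp(nt)
    for off in range(3):
        if len(nt) - off >= 3:
            out.append(FrameTranslation(off + 1, off, translate(nt, off), len(nt)))
    for off in range(3):
        if len(nt) - off >= 3:
            out.append(FrameTranslation(-(off + 1), off, translate(rc, off), len(nt)))
    return out


class TranslatedDb:
    """A subject database with cached six-frame translations and k-mer index."""

    def __init__(self, entries: list[SequenceDbEntry]):
        ids = [e.entry_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entry_id in database")
        self.entries = list(entries)
        self.by_id = {e.entry_id: e for e in self.entries}
        self._frames: dict[str, list[FrameTranslation]] = {}
        self._kmers: dict[str, frozenset[str]] = {}

    @classmethod
    def ensure(cls, db) -> "TranslatedDb":
        return db if isinstance(db, TranslatedDb) else cls(list(db))

    @property
    def total_nt(self) -> int:
        return sum(len(e.seq) for e in self.entries)

    def frames(self, entry: SequenceDbEntry) -> list[FrameTranslation]:
        fr = self._frames.get(entry.entry_id)
        if fr is None:
            fr = translate_frames(entry.seq)
            self._frames[entry.entry_id] = fr
        return fr

    def kmers(self, entry: SequenceDbEntry, k: int) -> frozenset[str]:
        key = entry.entry_id
        cached = self._kmers.get(key)
        if cached is None:
            s = entry.seq
            cached = frozenset(s[i : i + k] for i in range(len(s) - k + 1))
            self._kmers[key] = cached
        return cached

    def subset(self, entry_ids) -> "TranslatedDb":
        sub = TranslatedDb([self.by_id[i] for i in entry_ids])
        sub._frames = self._frames  # share translation cache
        sub._kmers = self._kmers
        return sub


# ---------------------------------------------------------------------------
# searches


def search_protein_query(
    query_aa: str,
    db,
    e_max: float,
    exclude_species: set[str] | frozenset[str] = frozenset(),
    params: ScoringParams | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """tBLASTn-like search of a peptide against all six frames of each subject.

    Keeps the single best local alignment per (subject, frame) with
    ``evalue < e_max``; subjects from ``exclude_species`` are skipped.
    """
    tdb = TranslatedDb.ensure(db)
    p = params or ScoringParams.protein_default(tdb.total_nt)
    if params is not None and params.db_size <= 1:
        p = replace(params, db_size=max(tdb.total_nt, 1))
    m = len(query_aa)
    hits: list[AlignmentHit] = []
    for entry in tdb.entries:
        if entry.species_id in exclude_species:
            continue
        for fr in tdb.frames(entry):
            score = align_score(query_aa, fr.peptide, p)
            if score <= 0:
                continue
            ev = evalue_from_score(score, m, p)
            if not ev < e_max:
                continue
            res = align_local(query_aa, fr.peptide, p)
            if res is None:
                continue
            raw, q_span, p_span, ident = res
            s_start, s_end = fr.nt_span(*p_span)
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=entry.entry_id,
                    frame=fr.frame,
                    q_start=q_span[0],
                    q_end=q_span[1],
                    s_start=s_start,
                    s_end=s_end,
                    raw_score=raw,
                    evalue=ev,
                    identity=ident,
                    strand="+" if fr.frame > 0 else "-",
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.frame))
    return hits


def search_translated_query(
    query_nt: str,
    db,
    e_max: float,
    exclude_species: set[str] | frozenset[str] = frozenset(),
    params: ScoringParams | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """tBLASTx-like search: query translated in its three forward frames.

    Queries are defined ORFs on the mRNA sense strand, so reverse query
    frames are not searched.  Query coordinates in the returned hits are
    nucleotides on the query.  One best hit per (subject, query-frame,
    subject-frame) is kept.
    """
    hits: list[AlignmentHit] = []
    tdb = TranslatedDb.ensure(db)
    for qoff in range(3):
        if len(query_nt) - qoff < 3:
            continue
        pep = translate(query_nt, qoff)
        for h in search_protein_query(
            pep, tdb, e_max, exclude_species, params, query_id
        ):
            hits.append(
                replace(h, q_start=qoff + 3 * h.q_start, q_end=qoff + 3 * h.q_end)
            )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.frame))
    return hits


def search_nucleotide_query(
    query_nt: str,
    db,
    e_max: float,
    min_identity: float = 0.0,
    params: ScoringParams | None = None,
    query_id: str = "query",
    word_size: int | None = 11,
) -> list[AlignmentHit]:
    """BLASTn-like nucleotide search of both strands of the query.

    ``word_size`` enables a shared-exact-word prefilter (as BLAST's word
    seeding does); pass None to force alignment of every pair.  Hits must
    satisfy ``evalue < e_max`` and ``identity >= min_identity``.
    """
    tdb = TranslatedDb.ensure(db)
    p = params or ScoringParams.nucleotide_default(tdb.total_nt)
    if params is not None and params.db_size <= 1:
        p = replace(params, db_size=max(tdb.total_nt, 1))
    rc = revcomp(query_nt)
    qwords = rcwords = None
    if word_size and len(query_nt) >= word_size:
        qwords = frozenset(
            query_nt[i : i + word_size] for i in range(len(query_nt) - word_size + 1)
        )
        rcwords = frozenset(
            rc[i : i + word_size] for i in range(len(rc) - word_size + 1)
        )
    m = len(query_nt)
    hits: list[AlignmentHit] = []
    for entry in tdb.entries:
        for strand, q in (("+", query_nt), ("-", rc)):
            if qwords is not None:
                words = qwords if strand == "+" else rcwords
                if not (words & tdb.kmers(entry, word_size)):
                    continue
            res = align_local(q, entry.seq, p)
            if res is None:
                continue
            raw, q_span, s_span, ident = res
            ev = evalue_from_score(raw, m, p)
            if not ev < e_max or ident < min_identity:
                continue
            if strand == "-":
                q_span = (m - q_span[1], m - q_span[0])
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=entry.entry_id,
                    frame=0,
                    q_start=q_span[0],
                    q_end=q_span[1],
                    s_start=s_span[0],
                    s_end=s_span[1],
                    raw_score=raw,
                    evalue=ev,
                    identity=ident,
                    strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.strand))
    return hits


def best_hit_per_subject(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Lowest-E-value hit for each subject (deterministic tie-breaking)."""
    best: dict[str, AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.frame)):
        best.setdefault(h.subject_id, h)
    return best


# ---------------------------------------------------------------------------
# I/O


def load_external_hits(tsv: str | Path) -> list[AlignmentHit]:
    """Adapt a 12-column tabular hit file (BLAST outfmt-6 conventions).

    Columns: query id, subject id, %identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, evalue, bitscore — 1-based
    inclusive coordinates, ``s.start > s.end`` signalling the minus strand.
    Coordinates are normalized to 0-based half-open sense-strand spans.
    """
    hits: list[AlignmentHit] = []
    with open(tsv) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{tsv}: line {ln}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                qs, qe = int(parts[6]), int(parts[7])
                ss, se = int(parts[8]), int(parts[9])
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{tsv}: line {ln}: malformed field ({exc})") from None
            if ss <= se:
                s_start, s_end, strand = ss - 1, se, "+"
            else:
                s_start, s_end, strand = se - 1, ss, "-"
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    frame=0,
                    q_start=qs - 1,
                    q_end=qe,
                    s_start=s_start,
                    s_end=s_end,
                    raw_score=bits,
                    evalue=ev,
                    identity=pident / 100.0,
                    strand=strand,
                )
            )
    return hits


def read_fasta_db(path: str | Path) -> list[SequenceDbEntry]:
    """Read a transcript database FASTA with ``entry_id|species_id|source`` headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 3:
            raise ValueError(
                f"{path}: header {rec.id!r} is not 'entry_id|species_id|source'"
            )
        entries.append(
            SequenceDbEntry(fields[0], str(rec.seq).upper(), fields[1], fields[2])
        )
    return entries


def write_fasta_db(entries: list[SequenceDbEntry], path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(e.seq), id=f"{e.entry_id}|{e.species_id}|{e.source}", description=""
        )
        for e in entries
    ]
    SeqIO.write(recs, str(path), "fasta")
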