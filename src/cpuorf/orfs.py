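"""Transcript models, uORF extraction and largest-ORF scanning.

A transcript is stored as its spliced, sense-strand mRNA sequence together
with the main-ORF (mORF) extent in transcript coordinates, so the 5'-UTR is
simply ``seq[:morf_start]``.  A uORF is an ATG -> nearest in-frame stop ORF
whose start *and* stop codons both lie inside the 5'-UTR; uORFs that overlap
the mORF are deliberately out of scope because their conservation could
reflect constraints on the mORF-encoded protein rather than on the uORF
peptide itself.

Coordinates are 0-based half-open internally; GFF3 input is read as 1-based
inclusive and emitted reports use 1-based inclusive transcript coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from pyfaidx import Fasta

from ._seq import is_stop, translate

logger = logging.getLogger(__name__)

__all__ = [
    "OrfSpan",
    "TranscriptRecord",
    "UorfRecord",
    "build_transcripts",
    "extract_uorfs",
    "find_largest_orf",
    "write_uorf_catalog",
    "read_uorf_catalog",
]


@dataclass(frozen=True)
class OrfSpan:
    """A complete ORF located on some sequence (0-based half-open)."""

    start: int
    end: int
    frame: int  # start mod 3 within the owning sequence
    has_stop: bool = True

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.has_stop and self.end - self.start < 6:
            raise ValueError("complete ORF needs at least ATG + stop")


@dataclass
class TranscriptRecord:
    """Spliced sense-strand mRNA with its mORF extent."""

    transcript_id: str
    gene_id: str
    species_id: str
    seq: str
    morf_start: int  # 0-based; equals the 5'-UTR length
    morf_end: int  # 0-based exclusive

    def __post_init__(self):
        if not (0 <= self.morf_start < self.morf_end <= len(self.seq)):
            raise ValueError(
                f"{self.transcript_id}: invalid mORF extent "
                f"[{self.morf_start},{self.morf_end}) on {len(self.seq)} nt"
            )

    @property
    def utr5(self) -> str:
        return self.seq[: self.morf_start]

    @property
    def morf_nt(self) -> str:
        return self.seq[self.morf_start : self.morf_end]

    @property
    def morf_aa(self) -> str:
        aa = translate(self.morf_nt)
        return aa[:-1] if aa.endswith("*") else aa


@dataclass
class UorfRecord:
    """An ATG->stop ORF contained entirely within a transcript's 5'-UTR."""

    uorf_id: str
    transcript_id: str
    span: OrfSpan
    nt_seq: str  # includes the stop codon
    aa_seq: str  # excludes the stop


def build_transcripts(
    genome_fasta: str | Path,
    annotation_gff3: str | Path,
    species_id: str = "focal",
) -> list[TranscriptRecord]:
    """Assemble spliced transcripts from a genome FASTA and GFF3 annotation.

    One record is returned per mRNA/transcript feature (splice variants are
    kept separately).  Exons are concatenated in genomic order and
    reverse-complemented for minus-strand transcripts; the mORF extent is the
    CDS span mapped into transcript coordinates.  Transcripts lacking a CDS
    child are skipped with a warning; an exon outside its contig is a hard
    error naming the feature.
    """
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(annotation_gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[TranscriptRecord] = []
    n_skipped = 0
    feature_types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    for mrna in db.features_of_type(tuple(feature_types), order_by=("seqid", "start")):
        exons = sorted(
            db.children(mrna, featuretype="exon"), key=lambda f: f.start
        )
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            logger.warning("transcript %s has no CDS; skipped", mrna.id)
            n_skipped += 1
            continue
        if not exons:  # tolerate exon-less annotations: CDS-only transcripts
            exons = cds
        contig_len = len(genome[mrna.seqid])
        for ex in exons:
            if ex.start < 1 or ex.end > contig_len:
                raise ValueError(
                    f"exon {ex.id or ex.attributes.get('Parent', ['?'])[0]} "
                    f"({mrna.seqid}:{ex.start}-{ex.end}) outside contig bounds "
                    f"(length {contig_len})"
                )
        # plus-strand concatenation and genomic->transcript offsets
        parts = []
        offsets = []  # cumulative transcript offset of each exon (plus sense)
        total = 0
        for ex in exons:
            parts.append(str(genome[mrna.seqid][ex.start - 1 : ex.end]))
            offsets.append(total)
            total += ex.end - ex.start + 1

        def plus_index(g0: int) -> int:
            """Transcript offset (plus-strand sense) of 0-based genomic g0."""
            for ex, off in zip(exons, offsets):
                if ex.start - 1 <= g0 < ex.end:
                    return off + (g0 - (ex.start - 1))
            raise ValueError(
                f"position {g0 + 1} of {mrna.id} not covered by its exons"
            )

        cds_min = min(c.start for c in cds) - 1
        cds_max = max(c.end for c in cds)  # 0-based exclusive
        seq = "".join(parts)
        if mrna.strand == "-":
            from ._seq import revcomp

            seq = revcomp(seq)
            morf_start = total - 1 - plus_index(cds_max - 1)
            morf_end = total - plus_index(cds_min)
        else:
            morf_start = plus_index(cds_min)
            morf_end = plus_index(cds_max - 1) + 1
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        records.append(
            TranscriptRecord(
                transcript_id=mrna.id,
                gene_id=gene_id,
                species_id=species_id,
                seq=seq,
                morf_start=morf_start,
                morf_end=morf_end,
            )
        )
    if n_skipped:
        logger.warning("%d transcripts lacked CDS features and were skipped", n_skipped)
    return records


def extract_uorfs(t: TranscriptRecord) -> list[UorfRecord]:
    """Extract uORFs from a transcript's 5'-UTR.

    Every ATG in the UTR is paired with its nearest downstream in-frame stop;
    both codons must fit entirely within the UTR.  When several uORFs share a
    stop codon only the longest (5'-most start) is kept.  Results are ordered
    by start position and numbered ``<transcript_id>.u<k>``.
    """
    utr = t.utr5
    by_stop: dict[int, int] = {}  # stop_end -> smallest start
    for i in range(len(utr) - 5):
        if utr[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(utr):
            if is_stop(utr[j : j + 3]):
                end = j + 3
                if end not in by_stop or i < by_stop[end]:
                    by_stop[end] = i
                break
            j += 3
    out = []
    for k, (end, start) in enumerate(sorted(by_stop.items(), key=lambda kv: kv[1]), 1):
        nt = utr[start:end]
        out.append(
            UorfRecord(
                uorf_id=f"{t.transcript_id}.u{k}",
                transcript_id=t.transcript_id,
                span=OrfSpan(start, end, start % 3),
                nt_seq=nt,
                aa_seq=translate(nt)[:-1],
            )
        )
    return out


def find_largest_orf(rna: str) -> OrfSpan | None:
    """Longest complete ATG->stop ORF over the three forward frames.

    Length is compared in nucleotides; ties break toward the smaller start.
    ORFs running off the 3' end (no stop codon) are ignored.
    """
    best: OrfSpan | None = None
    for off in range(3):
        open_start: int | None = None
        for p in range(off, len(rna) - 2, 3):
            codon = rna[p : p + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = p
            elif is_stop(codon):
                length = p + 3 - open_start
                if (
                    best is None
                    or length > best.end - best.start
                    or (length == best.end - best.start and open_start < best.start)
                ):
                    best = OrfSpan(open_start, p + 3, open_start % 3)
                open_start = None
    return best


def write_uorf_catalog(
    uorfs: list[UorfRecord],
    transcripts: dict[str, TranscriptRecord],
    path: str | Path,
) -> None:
    """Emit the uORF catalogue as TSV (1-based inclusive coordinates).

    uORFs sharing an identical peptide (typically splice variants of one
    gene) are all kept and annotated with a shared ``aa_group`` id plus an
    ``aa_group_longest`` flag, so a curator can pick the variant with the
    longest conserved region instead of the pipeline choosing silently.
    """
    groups: dict[str, str] = {}
    longest: dict[str, UorfRecord] = {}
    for u in uorfs:
        groups.setdefault(u.aa_seq, f"ag{len(groups) + 1:04d}")
        best = longest.get(u.aa_seq)
        if best is None or len(u.nt_seq) > len(best.nt_seq):
            longest[u.aa_seq] = u
    rows = [
        {
            "uorf_id": u.uorf_id,
            "transcript_id": u.transcript_id,
            "gene_id": transcripts[u.transcript_id].gene_id,
            "start": u.span.start + 1,
            "end": u.span.end,
            "nt_seq": u.nt_seq,
            "aa_seq": u.aa_seq,
            "aa_group": groups[u.aa_seq],
            "aa_group_longest": longest[u.aa_seq].uorf_id == u.uorf_id,
        }
        for u in uorfs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "uorf_id", "transcript_id", "gene_id", "start", "end",
            "nt_seq", "aa_seq", "aa_group", "aa_group_longest",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_uorf_catalog(path: str | Path) -> list[UorfRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples(index=False):
        start, end = int(r.start) - 1, int(r.end)
        out.append(
            UorfRecord(
                uorf_id=r.uorf_id,
                transcript_id=r.transcript_id,
                span=OrfSpan(start, end, start % 3),
                nt_seq=r.nt_seq,
                aa_seq=r.aa_seq,
            )
        )
    return out
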