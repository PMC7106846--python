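import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cpuorf.orfs import TranscriptRecord
from cpuorf.search import SequenceDbEntry


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_transcript(utr: str, tid: str = "t1", species: str = "sp1") -> TranscriptRecord:
    """A transcript whose 5'-UTR is exactly ``utr`` (mORF appended)."""
    morf = "ATGGAAGAAGAATAA"
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=f"{tid}.g",
        species_id=species,
        seq=utr + morf,
        morf_start=len(utr),
        morf_end=len(utr) + len(morf),
    )


def layout_rna(
    uorf_nt: str,
    morf_nt: str,
    fused: bool = False,
    entry_id: str = "rna1",
    species: str = "spX",
    source: str = "curated_rna",
) -> SequenceDbEntry:
    """Companion-RNA layout: C-pads (no spurious ATG), an in-frame stop in
    the spacer upstream of the mORF, uORF wholly inside the 5'-UTR."""
    p5 = "C" * 8
    p3 = "C" * 15
    if fused:
        seq = p5 + uorf_nt[:-3] + morf_nt + p3
    else:
        mid = "CCCC" + "TAA" + "CCC"
        seq = p5 + uorf_nt + mid + morf_nt + p3
    return SequenceDbEntry(entry_id, seq, species, source)
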