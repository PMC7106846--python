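"""Shared nucleotide/codon primitives.

The standard genetic code is taken from Biopython's codon tables; codons
containing N or any non-ACGT base translate to 'X' and never match ATG or a
stop codon (conservative treatment of ambiguous bases).
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({c: "*" for c in STOP_CODONS})

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def codon_aa(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stops, 'X' if ambiguous."""
    return GENETIC_CODE.get(codon, "X")


def translate(nt: str, offset: int = 0) -> str:
    """Translate full codons of ``nt`` starting at ``offset`` (sense strand)."""
    return "".join(
        GENETIC_CODE.get(nt[i : i + 3], "X")
        for i in range(offset, len(nt) - 2, 3)
    )


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_start(codon: str) -> bool:
    return codon == "ATG"
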