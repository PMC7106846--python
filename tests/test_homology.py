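"""Putative-ORF reconstruction, contaminant screening, candidate assembly."""

import pytest

from conftest import layout_rna

from cpuorf._seq import revcomp, translate
from cpuorf.homology import (
    ContaminantConfig,
    HomologyConfig,
    assemble_candidates,
    detect_contaminant,
    extract_putative_uorf,
    locate_putative_morf,
)
from cpuorf.orfs import OrfSpan, UorfRecord
from cpuorf.search import AlignmentHit, SequenceDbEntry
from cpuorf.taxonomy import Lineage

UORF_NT = "ATGAAAGTTCTTTGGGCTGCTCTTGTTACTTTTCTTGCTGGTTGTCAAGCTTAA"
MORF_NT = (
    "ATGGATCCTGAAACTACTGTTGAAAAGCTTAAAGAACTTGGTGAAAAACTTGGTCTTTCT"
    "GATGAAGAAATTGAAAAACTTAAAGCTGAACTTGCTAAATAA"
)


def _hit(sid, frame, s_start, s_end, evalue=1e-6):
    return AlignmentHit("q", sid, frame, 0, 10, s_start, s_end, 60.0, evalue, 0.9,
                        "+" if frame >= 0 else "-")


def _lineage(sp, order, extra=("Magnoliophyta",)):
    return Lineage(sp, ("Viridiplantae", "Streptophyta", "Embryophyta") + tuple(extra) + (order, sp), order)


class TestExtractPutativeUorf:
    def test_rules_i_and_ii(self):
        subject = SequenceDbEntry("s", "AAATGGCCTGGTAGGCC", "sp", "est")
        # match region nt 5..11 in the frame of offset 2
        pu = extract_putative_uorf(_hit("s", 3, 5, 11), subject)
        assert pu.nt_seq == "ATGGCCTGGTAG" and pu.aa_seq == "MAW"
        assert (pu.span.start, pu.span.end) == (2, 14)

    def test_intervening_stop_blocks_upstream_atg(self):
        #        ATG  TGA  ATG  GCC  TGG  TAG : first ATG separated by a stop
        subject = SequenceDbEntry("s", "ATGTGAATGGCCTGGTAGGC", "sp", "est")
        pu = extract_putative_uorf(_hit("s", 1, 9, 15), subject)
        assert pu.nt_seq == "ATGGCCTGGTAG"
        assert pu.span.start == 6

    def test_no_upstream_atg_discards(self):
        subject = SequenceDbEntry("s", "CCCCCCGCCTGGTAGGCC", "sp", "est")
        assert extract_putative_uorf(_hit("s", 1, 6, 12), subject) is None

    def test_no_downstream_stop_discards(self):
        subject = SequenceDbEntry("s", "ATGGCCGGTGCCGGT", "sp", "est")
        assert extract_putative_uorf(_hit("s", 1, 3, 9), subject) is None

    def test_negative_frame_normalizes_to_sense(self):
        plus = SequenceDbEntry("s", "AAATGGCCTGGTAGGCC", "sp", "est")
        pu_plus = extract_putative_uorf(_hit("s", 3, 5, 11), plus)
        L = len(plus.seq)
        minus = SequenceDbEntry("s", revcomp(plus.seq), "sp", "est")
        pu_minus = extract_putative_uorf(_hit("s", -3, L - 11, L - 5), minus)
        assert pu_minus.nt_seq == pu_plus.nt_seq
        assert (pu_minus.span.start, pu_minus.span.end) == (
            pu_plus.span.start,
            pu_plus.span.end,
        )


class TestLocatePutativeMorf:
    def test_separate_layout_is_not_fusion(self):
        rna = layout_rna(UORF_NT, MORF_NT)
        pu = extract_putative_uorf(_hit(rna.entry_id, 1 + 8 % 3, 8, 8 + 30), rna)
        morf_at = rna.seq.index(MORF_NT)
        ms, fusion = locate_putative_morf(
            _hit(rna.entry_id, 1 + morf_at % 3, morf_at, morf_at + 30), rna, pu
        )
        assert ms == morf_at and fusion is False

    def test_fused_layout_is_fusion(self):
        rna = layout_rna(UORF_NT, MORF_NT, fused=True)
        pu = extract_putative_uorf(_hit(rna.entry_id, 1 + 8 % 3, 8, 8 + 30), rna)
        # the mORF match region lies inside the single fused ORF
        m_at = rna.seq.index(MORF_NT[3:33])
        ms, fusion = locate_putative_morf(
            _hit(rna.entry_id, 1 + m_at % 3, m_at, m_at + 30), rna, pu
        )
        assert fusion is True and ms < pu.span.end

    def test_missing_upstream_stop_uses_sequence_start(self):
        from cpuorf.homology import PutativeUorf

        seq = "CCCCCCATGGATCCTGAAACTACTGTTGAA"  # no stop upstream of the match
        rna = SequenceDbEntry("r", seq, "sp", "est")
        pu_dummy = PutativeUorf("r", OrfSpan(0, 6, 0), "ATGTAA", "M")
        ms, fusion = locate_putative_morf(_hit("r", 1 + 12 % 3, 12, 24), rna, pu_dummy)
        assert ms == 6  # first in-frame ATG downstream of position 0
        assert fusion is False


class TestDetectContaminant:
    def _db(self, seq):
        # qhit: species A (order O1); near-identical copies in species B (order O2)
        return [
            SequenceDbEntry("q", seq, "spA", "est"),
            SequenceDbEntry("b1", seq, "spB", "curated_rna"),
            SequenceDbEntry("b2", seq[:-1] + "A", "spB", "est"),
        ]

    def _lineages(self):
        return {
            "spA": _lineage("spA", "Brassicales"),
            "spB": _lineage("spB", "Solanales"),
        }

    def test_ratio_rule_flags_contaminant(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        db = self._db(seq)
        totals = {"spA": 20000, "spB": 6000}
        assert detect_contaminant(db[0], db, self._lineages(), totals) is True
        # and the true source species is not flagged (its ratio is higher)
        assert detect_contaminant(db[1], db, self._lineages(), totals) is False

    def test_small_comparator_species_are_excluded(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        db = self._db(seq)
        totals = {"spA": 20000, "spB": 4999}
        assert detect_contaminant(db[0], db, self._lineages(), totals) is False

    def test_no_cross_order_match_is_clean(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        db = self._db(seq)
        lineages = {
            "spA": _lineage("spA", "Brassicales"),
            "spB": _lineage("spB", "Brassicales"),  # same order
        }
        totals = {"spA": 20000, "spB": 6000}
        assert detect_contaminant(db[0], db, lineages, totals) is False

    def test_unknown_species_is_an_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        db = self._db(seq)
        with pytest.raises(ValueError, match="lineage"):
            detect_contaminant(db[0], db, {"spB": _lineage("spB", "Solanales")}, {})


class TestAssembleCandidates:
    ORDERS = ["Solanales", "Vitales", "Poales"]

    def _setup(self, n_orders):
        uorf = UorfRecord("u1", "t1", OrfSpan(0, len(UORF_NT), 0), UORF_NT,
                          translate(UORF_NT)[:-1])
        morf_aa = translate(MORF_NT)[:-1]
        db = []
        lineages = {"origin": _lineage("origin", "Brassicales")}
        totals = {"origin": 20000}
        for i, order in enumerate(self.ORDERS[:n_orders]):
            sp = f"sp_{order.lower()}"
            db.append(layout_rna(UORF_NT, MORF_NT, entry_id=f"r{i}", species=sp))
            lineages[sp] = _lineage(sp, order)
            totals[sp] = 20000
        return uorf, morf_aa, db, lineages, totals

    @pytest.mark.parametrize("n_orders,expect", [(3, 3), (2, 2), (1, None)])
    def test_min_other_orders_threshold(self, n_orders, expect):
        uorf, morf_aa, db, lineages, totals = self._setup(n_orders)
        res = assemble_candidates(uorf, morf_aa, db, lineages, totals, "origin")
        if expect is None:
            assert res.candidate is None
        else:
            assert res.candidate.n_other_orders == expect
            for hits in res.candidate.hits_by_order.values():
                for h in hits:
                    assert h.putative_uorf.aa_seq == translate(UORF_NT)[:-1]

    def test_own_order_does_not_count(self):
        uorf, morf_aa, db, lineages, totals = self._setup(2)
        # add a hit in the origin's own order: still only 2 other orders
        db.append(layout_rna(UORF_NT, MORF_NT, entry_id="own", species="cousin"))
        lineages["cousin"] = _lineage("cousin", "Brassicales")
        totals["cousin"] = 20000
        res = assemble_candidates(uorf, morf_aa, db, lineages, totals, "origin")
        assert res.candidate.n_other_orders == 2
        assert "Brassicales" in res.candidate.hits_by_order

    def test_fused_subjects_are_dropped(self):
        uorf, morf_aa, db, lineages, totals = self._setup(3)
        db = [
            layout_rna(UORF_NT, MORF_NT, fused=True, entry_id=e.entry_id,
                       species=e.species_id)
            for e in db
        ]
        res = assemble_candidates(uorf, morf_aa, db, lineages, totals, "origin")
        assert res.candidate is None
        assert len(res.fusion_subjects) == 3
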