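"""Ka/Ks machinery: alignment, NG86 estimation, null model, testing."""

import itertools
import math

import numpy as np
import pytest

from _oracles import bh_direct, exact_mannwhitney_less, ng86_pair

from cpuorf._seq import SENSE_CODONS, translate
from cpuorf.conservation import (
    ConservationConfig,
    adjust_fdr,
    align_proteins,
    codon_delimited_alignment,
    final_selection,
    generate_null_mutants,
    kaks_pair,
    median_kaks,
    restrict_to_angiosperms,
    select_representatives,
)
from cpuorf.conservation import test_candidate as mw_test
from cpuorf.homology import CandidateCpuorf, HomologHit, PutativeUorf
from cpuorf.orfs import OrfSpan, UorfRecord
from cpuorf.search import AlignmentHit
from cpuorf.taxonomy import Lineage


def _hom(sid, e_u, e_m, species="sp1", order="Solanales"):
    u = AlignmentHit("q", sid, 1, 0, 5, 0, 15, 30.0, e_u, 0.9)
    m = AlignmentHit("q.m", sid, 1, 0, 5, 30, 60, 60.0, e_m, 0.9)
    pu = PutativeUorf(sid, OrfSpan(0, 12, 0), "ATGGCCTGGTAG", "MAW")
    return HomologHit(u, m, pu, 30, species, order)


def _candidate(hits_by_order):
    u = UorfRecord("u1", "t1", OrfSpan(0, 9, 0), "ATGAAATAA", "MK")
    n = len(hits_by_order)
    return CandidateCpuorf(u, hits_by_order, n)


class TestRepresentatives:
    def test_smallest_geometric_mean_wins(self):
        a = _hom("A", 1e-4, 1e-30)  # gm 1e-17
        b = _hom("B", 1e-10, 1e-26)  # gm 1e-18
        reps = select_representatives(_candidate({"Solanales": [a, b]}))
        assert reps.per_order["Solanales"].uorf_hit.subject_id == "B"

    def test_fallback_when_no_morf_evalue_passes(self):
        a = _hom("A", 1e-4, 1e-10)
        b = _hom("B", 1e-2, 1e-15)
        reps = select_representatives(_candidate({"Solanales": [a, b]}))
        assert reps.per_order["Solanales"].uorf_hit.subject_id == "B"

    def test_zero_evalues_are_floored(self):
        a = _hom("A", 0.0, 0.0)
        reps = select_representatives(_candidate({"Solanales": [a]}))
        assert reps.per_order["Solanales"].uorf_hit.subject_id == "A"

    def test_angiosperm_restriction_drops_gymnosperms(self):
        sol = _hom("A", 1e-4, 1e-30, species="tomato", order="Solanales")
        pin = _hom("B", 1e-4, 1e-30, species="pine", order="Pinales")
        reps = select_representatives(
            _candidate({"Solanales": [sol], "Pinales": [pin]})
        )
        lineages = {
            "tomato": Lineage("tomato", ("Viridiplantae", "Magnoliophyta", "Solanales"), "Solanales"),
            "pine": Lineage("pine", ("Viridiplantae", "Acrogymnospermae", "Pinales"), "Pinales"),
        }
        out = restrict_to_angiosperms(reps, lineages)
        assert set(out.per_order) == {"Solanales"}


class TestProteinMsa:
    def test_identical_sequences_align_gaplessly(self):
        assert align_proteins(["MKVL", "MKVL", "MKVL"]) == ["MKVL"] * 3

    def test_single_gap_example(self):
        rows = align_proteins(["MKV", "MV"])
        assert len(rows[0]) == 3 and rows[1].count("-") == 1
        assert rows[0] == "MKV" and rows[1].replace("-", "") == "MV"

    def test_too_few_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            align_proteins(["MKV"])

    def test_rows_degap_to_inputs(self, rng):
        AA = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(30):
            seqs = [
                "".join(rng.choice(AA, size=int(rng.integers(3, 15))))
                for _ in range(int(rng.integers(2, 6)))
            ]
            rows = align_proteins(seqs)
            assert len({len(r) for r in rows}) == 1
            assert [r.replace("-", "") for r in rows] == seqs


class TestCodonAlignment:
    def test_gap_becomes_triple_dash(self):
        ca = codon_delimited_alignment([("a", "M-K"), ("b", "MGK")],
                                       ["ATGAAA", "ATGGGTAAA"])
        assert ca.rows[0][1] == "ATG---AAA"
        assert ca.rows[1][1] == "ATGGGTAAA"
        assert ca.n_codon_columns == 3

    def test_terminal_stop_is_excluded(self):
        ca = codon_delimited_alignment([("a", "MK")], ["ATGAAATGA"])
        assert ca.rows[0][1] == "ATGAAA"

    def test_translation_mismatch_names_row(self):
        with pytest.raises(ValueError, match="rowX"):
            codon_delimited_alignment([("rowX", "MK")], ["ATGCCC"])

    def test_roundtrip_degap_reproduces_input(self, rng):
        for _ in range(50):
            n_codons = int(rng.integers(2, 12))
            nts = []
            aas = []
            for _ in range(3):
                nt = "".join(
                    SENSE_CODONS[int(i)]
                    for i in rng.integers(0, len(SENSE_CODONS), n_codons)
                )
                nts.append(nt)
                aas.append(translate(nt))
            msa = align_proteins(aas)
            ca = codon_delimited_alignment(
                [(f"r{i}", row) for i, row in enumerate(msa)], nts
            )
            for (_, ntrow, _), nt in zip(ca.rows, nts):
                assert ntrow.replace("-", "") == nt


class TestKaksPair:
    def test_identical_sequences_are_zero(self):
        assert kaks_pair("ATGGCCAAA", "ATGGCCAAA") == (0.0, 0.0)

    def test_nonsynonymous_single_change(self):
        ka, ks = kaks_pair("TTTGGG", "TTAGGG")
        oka, oks = ng86_pair(["TTT", "GGG"], ["TTA", "GGG"])
        assert ks == pytest.approx(oks) and ka == pytest.approx(oka)
        assert ks == 0.0 and ka > 0.0

    def test_synonymous_third_position_change(self):
        # a lone GGT->GGC codon saturates the synonymous proportion under
        # Jukes-Cantor (1 difference / 1 site); with a context codon the
        # change is purely synonymous with finite ks
        ka, ks = kaks_pair("GGT", "GGC")
        oka, oks = ng86_pair(["GGT"], ["GGC"])
        assert ka == oka == 0.0 and math.isnan(ks) and math.isnan(oks)
        ka, ks = kaks_pair("TTAGGT", "TTAGGC")
        oka, oks = ng86_pair(["TTA", "GGT"], ["TTA", "GGC"])
        assert ka == pytest.approx(oka) == 0.0
        assert ks == pytest.approx(oks) and ks > 0.0

    def test_exhaustive_against_oracle_on_all_codon_pairs(self):
        for c1, c2 in itertools.product(SENSE_CODONS, SENSE_CODONS):
            ka, ks = kaks_pair(c1, c2)
            oka, oks = ng86_pair([c1], [c2])
            for got, want in ((ka, oka), (ks, oks)):
                if math.isnan(want):
                    assert math.isnan(got), (c1, c2)
                else:
                    assert got == pytest.approx(want), (c1, c2)

    def test_symmetry(self, rng):
        for _ in range(100):
            a = "".join(SENSE_CODONS[int(i)] for i in rng.integers(0, 61, 8))
            b = "".join(SENSE_CODONS[int(i)] for i in rng.integers(0, 61, 8))
            assert kaks_pair(a, b) == kaks_pair(b, a)

    def test_gap_and_ambiguous_codons_are_skipped(self):
        ka, ks = kaks_pair("ATG---GGT", "ATGCCCGGC")
        ka2, ks2 = kaks_pair("ATGGGT", "ATGGGC")
        assert (ka, ks) == (ka2, ks2)
        assert kaks_pair("ATGANA", "ATGAAA") == (0.0, 0.0)


class TestMedianAndNull:
    def test_median_over_defined_ratios(self):
        rows = [("h1", "TTTGGGAAA"), ("h2", "TTTGGGAAA"), ("h3", "TTTGGGAAA")]
        # engineered rows: compute medians via direct ratios instead
        res = median_kaks(("o", "TTTGGGAAA"), rows)
        assert res.median_ratio is None  # identical -> ks = 0 everywhere
        assert res.n_excluded == 3

    def test_single_homolog_median_is_its_ratio(self):
        res = median_kaks(("o", "TTTGGTACT"), [("h", "TTAGGCACG")])
        (label, ka, ks, ratio) = res.pairs[0]
        assert res.median_ratio == pytest.approx(ratio)

    def test_null_mutants_respect_difference_counts(self, rng):
        orig = "ATGGCCAAAGGTTTTACT"
        hom = "ATGGACAAAGCTTTTACG"
        d = sum(1 for a, b in zip(orig, hom) if a != b)
        muts = generate_null_mutants(orig, [("h", hom)], n_reps=20, seed=3)
        assert len(muts) == 20
        for _, m in muts:
            assert sum(1 for a, b in zip(orig, m) if a != b) == d

    def test_null_is_reproducible_under_seed(self):
        orig = "ATGGCCAAAGGTTTTACT"
        rows = [("h", "ATGGACAAAGCTTTTACG")]
        assert generate_null_mutants(orig, rows, 10, seed=7) == generate_null_mutants(
            orig, rows, 10, seed=7
        )

    def test_zero_differences_give_identical_mutants(self):
        orig = "ATGGCCAAA"
        muts = generate_null_mutants(orig, [("h", orig)], 5, seed=1)
        assert all(m == orig for _, m in muts)

    def test_every_position_may_differ(self):
        muts = generate_null_mutants("ATG", [("h", "CCC")], 5, seed=1)
        for _, m in muts:
            assert all(a != b for a, b in zip("ATG", m))


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        u, p = mw_test([0.1, 0.2], [0.8, 0.9])
        assert u == 0.0 and p == pytest.approx(1 / 6)

    def test_identical_samples_are_not_significant(self):
        _, p = mw_test([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert p >= 0.5

    def test_observed_all_larger_gives_p_one(self):
        _, p = mw_test([0.8, 0.9], [0.1, 0.2])
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n, m = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            x = list(np.round(rng.random(n), 1))  # coarse values force ties
            y = list(np.round(rng.random(m), 1))
            u, p = mw_test(x, y)
            ou, op = exact_mannwhitney_less(x, y)
            assert u == ou and p == pytest.approx(op)

    def test_asymptotic_branch_is_sane(self, rng):
        x = list(rng.random(5) * 0.1)
        y = list(0.5 + rng.random(100))
        _, p = mw_test(x, y)
        assert p < 0.01


class TestFdrAndSelection:
    def test_bh_worked_example(self):
        q = adjust_fdr([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])
        assert adjust_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(adjust_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_bh_matches_direct_formula(self, rng):
        for _ in range(100):
            p = list(rng.random(int(rng.integers(1, 30))))
            assert np.allclose(adjust_fdr(p), bh_direct(p))

    def test_bh_is_permutation_equivariant(self, rng):
        p = list(rng.random(20))
        perm = rng.permutation(20)
        q = adjust_fdr(p)
        qp = adjust_fdr([p[i] for i in perm])
        assert np.allclose(qp, [q[i] for i in perm])

    def test_nan_passthrough(self):
        q = adjust_fdr([0.01, float("nan"), 0.04])
        assert math.isnan(q[1]) and not math.isnan(q[0])

    @pytest.mark.parametrize(
        "median,q,accepted",
        [
            (0.49, 0.049, True),
            (0.5, 0.01, False),
            (0.2, 0.05, False),
            (None, 0.01, False),
        ],
    )
    def test_final_selection_boundaries(self, median, q, accepted):
        assert final_selection(median, q, ConservationConfig()) is accepted
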