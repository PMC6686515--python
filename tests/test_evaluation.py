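import math

import pytest
from hypothesis import given, strategies as st

from seedext.evaluation import (
    enrich_complexes,
    enrichment_pvalue,
    evaluate,
    jaccard_measures,
    match_and_score,
    overlap_score,
)
from seedext.ppin_io import AnnotationTable, ComplexSet

from .oracles import exact_tail


def cs(*sets):
    return ComplexSet([frozenset(s) for s in sets])


class TestOverlapScore:
    def test_identical_eleven_member_complexes(self):
        members = frozenset(f"G{i}" for i in range(11))
        assert overlap_score(members, members) == 1.0

    def test_disjoint(self):
        assert overlap_score(frozenset("ab"), frozenset("cd")) == 0.0

    def test_partial(self):
        p = frozenset(range(6))
        g = frozenset(range(11))
        assert overlap_score(p, g) == pytest.approx(36 / 66)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(frozenset(), frozenset("a"))

    @given(
        st.sets(st.integers(0, 15), min_size=1),
        st.sets(st.integers(0, 15), min_size=1),
    )
    def test_symmetric_and_bounded(self, a, b):
        assert overlap_score(a, b) == overlap_score(b, a)
        assert 0.0 <= overlap_score(a, b) <= 1.0
        assert overlap_score(a, a) == 1.0


class TestMatchAndScore:
    def test_perfect_prediction(self):
        pred = cs("abc")
        m = match_and_score(pred, pred)
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    def test_half_matched(self):
        pred = cs("abc", "xyz")
        ref = cs("abd", "qrs")
        m = match_and_score(pred, ref, omega=0.4)
        assert m.ncp == 1 and m.ncg == 1
        assert m.precision == 0.5 and m.recall == 0.5
        assert m.f_measure == pytest.approx(0.5)

    def test_boundary_match_is_inclusive(self):
        pred = cs("abc")
        ref = cs("abcdefghijklmno")  # OS = 9/45 = 0.2 exactly
        m = match_and_score(pred, ref, omega=0.2)
        assert m.ncp == 1 and m.ncg == 1

    def test_empty_sets_give_zero_metrics(self):
        m = match_and_score(ComplexSet([]), cs("abc"))
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    def test_order_invariance(self):
        pred = cs("abc", "def", "adg")
        ref = cs("abd", "defg")
        shuffled = ComplexSet(list(reversed(pred.complexes)))
        a = match_and_score(pred, ref)
        b = match_and_score(shuffled, ref)
        assert (a.precision, a.recall, a.f_measure) == (b.precision, b.recall, b.f_measure)


class TestJaccard:
    def test_identity(self):
        pred = cs("abc", "def")
        assert jaccard_measures(pred, pred) == (1.0, 1.0, 1.0)

    def test_subset_pair(self):
        assert jaccard_measures(cs("abc"), cs("abcd")) == pytest.approx(
            (0.75, 0.75, 0.75)
        )

    def test_size_weighting(self):
        pred = cs("abc", "wxyz")
        ref = cs("abcd", "wxqrstuv")  # best Jac = 0.75 and 2/10
        ji, js, jac = jaccard_measures(pred, ref)
        assert ji == pytest.approx((3 * 0.75 + 4 * 0.2) / 7)
        assert min(ji, js) <= jac <= max(ji, js)

    def test_harmonic_mean_identity(self):
        pred = cs("abc", "defg")
        ref = cs("abcd", "xyz")
        ji, js, jac = jaccard_measures(pred, ref)
        assert jac == pytest.approx(2 * ji * js / (ji + js))


class TestEnrichmentPvalue:
    def test_zero_hits_is_certain(self):
        assert enrichment_pvalue(0, 10, 5, 5) == 1.0

    def test_full_overlap_small_urn(self):
        assert enrichment_pvalue(5, 10, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_infeasible_arguments_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(6, 10, 5, 5)
        with pytest.raises(ValueError):
            enrichment_pvalue(1, 5, 6, 2)

    def test_monotone_decreasing_in_k(self):
        values = [enrichment_pvalue(k, 30, 10, 8) for k in range(9)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("n", [5, 8, 11])
    def test_agrees_with_closed_form(self, n):
        for f in range(n + 1):
            for c in range(1, n + 1):
                for k in range(min(f, c) + 1):
                    assert enrichment_pvalue(k, n, f, c) == pytest.approx(
                        exact_tail(k, n, f, c), abs=1e-12
                    )


class TestEnrichComplexes:
    def test_private_term_in_sparse_background(self):
        annot = AnnotationTable({"a": frozenset("T"), "b": frozenset("T"),
                                 "c": frozenset("T")})
        network = set("abcdefghij")
        result = enrich_complexes(cs("abc"), annot, network)
        # only one testable term, so Bonferroni factor is 1
        assert result.rows[0][6] == pytest.approx(exact_tail(3, 10, 3, 3), abs=1e-12)
        assert result.min_corrected[0] == pytest.approx(1 / math.comb(10, 3), rel=1e-9)
        assert result.significant == [True]

    def test_unannotated_complex_has_no_tests(self):
        result = enrich_complexes(cs("abc"), AnnotationTable({}), {"a", "b", "c", "d"})
        assert result.rows == []
        assert result.min_corrected == [None]
        assert result.significant == [False]

    def test_identical_complexes_get_identical_rows(self):
        annot = AnnotationTable({"a": frozenset("T"), "b": frozenset("T")})
        network = {"a", "b", "c", "d", "e"}
        result = enrich_complexes(cs("abc", "abc"), annot, network)
        first = [r[1:] for r in result.rows if r[0] == 0]
        second = [r[1:] for r in result.rows if r[0] == 1]
        assert first == second

    def test_bonferroni_scales_with_term_count(self):
        annot = AnnotationTable({
            "a": frozenset({"T1", "T2"}), "b": frozenset({"T1", "T2"}),
            "c": frozenset({"T1"}),
        })
        network = {"a", "b", "c", "d", "e", "f"}
        result = enrich_complexes(cs("abc"), annot, network)
        for row in result.rows:
            assert row[7] == pytest.approx(min(1.0, row[6] * 2))

    def test_bins_and_mean(self):
        annot = AnnotationTable({p: frozenset("T") for p in "abc"})
        result = enrich_complexes(cs("abc", "xyz"), annot,
                                  set("abcdefgh") | set("xyz"))
        assert result.bins["significant"] == result.significant.count(True)
        assert result.mean_min_pvalue == pytest.approx(result.min_corrected[0])


class TestEvaluateWrapper:
    def test_report_consistency(self):
        pred = cs("abc", "defg")
        ref = cs("abcd", "defg", "qrs")
        report = evaluate(pred, ref)
        assert report.n_predicted == 2 and report.n_reference == 3
        if report.precision + report.recall > 0:
            assert report.f_measure == pytest.approx(
                2 * report.precision * report.recall
                / (report.precision + report.recall)
            )
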