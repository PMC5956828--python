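"""Chi-square machinery and the graded slide verdict."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import embedclass as ec
from embedclass import OUTLIER, DecisionStatus


class TestChi2Uniform:
    def test_perfectly_uniform(self):
        assert ec.chi2_uniform([50, 50]) == (0.0, 1, 1.0)

    def test_heavily_skewed(self):
        stat, df, p = ec.chi2_uniform([90, 5, 5])
        assert stat == pytest.approx(144.5)
        assert df == 2
        assert p < 1e-30

    def test_df2_closed_form(self):
        # at df=2 the survival function is exp(-x/2) exactly
        stat, df, p = ec.chi2_uniform([40, 35, 25])
        assert stat == pytest.approx(3.50)
        assert df == 2
        assert p == pytest.approx(math.exp(-1.75), rel=1e-12)

    def test_single_category_convention(self):
        assert ec.chi2_uniform([17]) == (0.0, 0, 1.0)

    @pytest.mark.parametrize("bad", [[-1, 5], [2.5, 3], [], [0, 0]])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            ec.chi2_uniform(bad)


class TestDecide:
    def test_dominant_class_becomes_diagnosis_with_full_trail(self):
        d = ec.decide({"glioma": 90, "meningioma": 5, "lymphoma": 5}, alpha=0.01)
        assert d.status is DecisionStatus.DIAGNOSIS
        assert d.classes == ["glioma"]
        assert [it.removed for it in d.trail] == ["lymphoma", "meningioma", None]
        assert d.trail[0].p_value < 1e-30
        assert d.trail[1].statistic == pytest.approx(76.05, abs=0.01)
        assert d.trail[1].p_value == pytest.approx(2.2e-18, rel=0.1)
        assert d.trail[-1].p_value == 1.0

    def test_flat_distribution_is_a_differential(self):
        d = ec.decide({"A": 40, "B": 35, "C": 25}, alpha=0.01)
        assert d.status is DecisionStatus.DIFFERENTIAL
        assert d.classes == ["A", "B", "C"]  # sorted by count desc
        assert d.trail[-1].p_value == pytest.approx(math.exp(-1.75), rel=1e-9)

    def test_outlier_dominated_slide_is_undefined(self):
        d = ec.decide({OUTLIER: 60, "glioma": 20, "meningioma": 20}, alpha=0.01)
        assert d.status is DecisionStatus.UNDEFINED
        assert d.classes == []
        assert d.trail[0].statistic == pytest.approx(32.0)
        assert d.trail[0].df == 2
        assert d.trail[0].p_value == pytest.approx(1.1e-7, rel=0.1)

    def test_singleton_table_is_an_immediate_diagnosis(self):
        d = ec.decide({"glioma": 100})
        assert d.status is DecisionStatus.DIAGNOSIS
        assert d.classes == ["glioma"]

    def test_all_outlier_table_is_undefined_without_significance(self):
        d = ec.decide({OUTLIER: 40})
        assert d.status is DecisionStatus.UNDEFINED

    def test_nonmodal_outliers_are_set_aside(self):
        # significant table, but outliers are not the modal category
        d = ec.decide({"glioma": 80, OUTLIER: 10, "dura": 10})
        assert d.status is DecisionStatus.DIAGNOSIS
        assert d.classes == ["glioma"]
        assert OUTLIER not in d.classes

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ec.decide({})

    @given(st.dictionaries(st.sampled_from(["a", "b", "c", "d", "e", OUTLIER]),
                           st.integers(1, 40), min_size=1, max_size=6))
    def test_termination_and_verdict_consistency(self, table):
        d = ec.decide(table, alpha=0.01)
        n_classes = len([c for c in table if c != OUTLIER])
        elim = [it for it in d.trail if it.removed not in (None, OUTLIER)]
        assert len(elim) <= max(n_classes, 1)
        if d.status is DecisionStatus.DIAGNOSIS:
            assert len(d.classes) == 1
        elif d.status is DecisionStatus.DIFFERENTIAL:
            assert len(d.classes) >= 2
            assert d.trail[-1].p_value >= 0.01
        assert OUTLIER not in d.classes

    @given(st.dictionaries(st.sampled_from(["a", "b", "c", "d", "e"]),
                           st.integers(1, 40), min_size=1, max_size=5))
    def test_alpha_monotonicity(self, table):
        """A stricter alpha (smaller) stops elimination earlier: the retained
        class set at smaller alpha contains the set at larger alpha."""
        strict = ec.decide(table, alpha=0.001)
        loose = ec.decide(table, alpha=0.05)
        assert set(loose.classes) <= set(strict.classes)


class TestScores:
    def test_probability_diagnosis_mean_and_top(self):
        mean, top = ec.probability_diagnosis(np.array([[0.7, 0.3], [0.9, 0.1]]), ["a", "b"])
        np.testing.assert_allclose(mean, [0.8, 0.2])
        assert top == "a"

    def test_identical_tiles_mean_is_that_vector(self):
        probs = np.tile([0.2, 0.5, 0.3], (7, 1))
        mean, top = ec.probability_diagnosis(probs, ["a", "b", "c"])
        np.testing.assert_allclose(mean, [0.2, 0.5, 0.3])
        assert top == "b"

    def test_exact_tie_takes_first_label(self):
        _, top = ec.probability_diagnosis(np.array([[0.5, 0.5]]), ["x", "y"])
        assert top == "x"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ec.probability_diagnosis(np.zeros((0, 3)), ["a", "b", "c"])

    def test_combined_decision_requires_concordance(self):
        diag = ec.SlideDecision(DecisionStatus.DIAGNOSIS, ["glioma"], [], 0.01)
        diff = ec.SlideDecision(DecisionStatus.DIFFERENTIAL, ["glioma", "dura"], [], 0.01)
        assert ec.combined_decision(diag, "glioma") == "glioma"
        assert ec.combined_decision(diag, "meningioma") == "UNDEFINED"
        assert ec.combined_decision(diff, "glioma") == "UNDEFINED"

    def test_hybrid_blend(self):
        frac = np.array([0.8, 0.2, 0.0])
        prob = np.array([0.6, 0.3, 0.1])
        np.testing.assert_allclose(ec.hybrid_scores(frac, prob, 0.5), [0.7, 0.25, 0.05])
        np.testing.assert_allclose(ec.hybrid_scores(frac, prob, 1.0), frac)
        np.testing.assert_allclose(ec.hybrid_scores(frac, prob, 0.0), prob)
        with pytest.raises(ValueError, match="shape"):
            ec.hybrid_scores(frac, prob[:2])

    def test_tile_fractions_exclude_outliers(self):
        frac = ec.tile_fractions({"a": 30, OUTLIER: 10, "b": 10}, ["a", "b", "c"])
        np.testing.assert_allclose(frac, [0.75, 0.25, 0.0])
        np.testing.assert_allclose(ec.tile_fractions({OUTLIER: 10}, ["a", "b"]), [0.0, 0.0])
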