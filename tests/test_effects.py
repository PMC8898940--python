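"""Paired effect-size statistics and the seasonal summary table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swimnet.effects import (
    ci95,
    ci95_from_summary,
    classify_effect,
    hedges_g,
    paired_t_test,
    shapiro_wilk_gate,
    summarize_cohort,
)
from swimnet.errors import (
    DegenerateInputError,
    InsufficientSampleError,
)
from swimnet.simulate import CohortSimConfig, simulate_cohort


class TestShapiroGate:
    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk_gate([3.0] * 10)

    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).standard_normal(20)
        _, p = shapiro_wilk_gate(x)
        assert p > 0.05

    def test_skewed_sample_fails(self):
        x = np.random.default_rng(0).lognormal(0.0, 1.5, 20)
        _, p = shapiro_wilk_gate(x)
        assert p < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            shapiro_wilk_gate([1.0, 2.0])


class TestPairedT:
    def test_hand_computed_example(self):
        t, df, p = paired_t_test([1, 2, 3], [2, 4, 3])
        assert t == pytest.approx(1.7321, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.2254, abs=1e-4)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1, 2, 3], [1, 2, 3])

    def test_swap_negates_t_same_p(self):
        t1, _, p1 = paired_t_test([1, 2, 3], [2, 4, 3])
        t2, _, p2 = paired_t_test([2, 4, 3], [1, 2, 3])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)


class TestHedgesG:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (32.0, 7.5, 24.5, 3.8, 1.26),  # 25-m breaststroke time
            (10.2, 1.2, 11.1, 1.2, 0.75),  # decimal age
        ],
    )
    def test_published_rows(self, m1, s1, m2, s2, expected):
        assert round(hedges_g(m1, s1, m2, s2), 2) == expected

    def test_equal_means_give_zero(self):
        assert hedges_g(5.0, 1.0, 5.0, 2.0) == 0.0

    def test_both_sds_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hedges_g(1.0, 0.0, 2.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        m1=st.floats(-100, 100), s1=st.floats(0.1, 50),
        m2=st.floats(-100, 100), s2=st.floats(0.1, 50),
        shift=st.floats(-50, 50),
    )
    def test_symmetry_and_shift_invariance(self, m1, s1, m2, s2, shift):
        g = hedges_g(m1, s1, m2, s2)
        assert hedges_g(m2, s2, m1, s1) == pytest.approx(g, rel=1e-12)
        assert hedges_g(m1 + shift, s1, m2 + shift, s2) == pytest.approx(g, rel=1e-9, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "g,label",
        [
            (1.26, "large"),
            (0.16, "trivial"),
            (0.2, "small"),
            (0.6, "moderate"),
            (1.2, "large"),
            (2.0, "very large"),
            (4.0, "nearly perfect"),
            (0.0, "trivial"),
        ],
    )
    def test_bands(self, g, label):
        assert classify_effect(g) == label

    def test_negative_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_effect(-0.1)


class TestCI95:
    def test_published_age_row(self):
        lo, hi = ci95_from_summary(10.2, 1.2, 20)
        assert (round(lo, 2), round(hi, 2)) == (9.64, 10.76)

    def test_constant_sample(self):
        assert ci95([4.0, 4.0, 4.0]) == (4.0, 4.0)

    def test_n2_hand_computation(self):
        lo, hi = ci95([0.0, 2.0])
        assert lo == pytest.approx(-11.71, abs=5e-3)
        assert hi == pytest.approx(13.71, abs=5e-3)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientSampleError):
            ci95([1.0])


class TestSummarizeCohort:
    def test_single_swimmer_rejected(self, default_cohort):
        with pytest.raises(InsufficientSampleError):
            summarize_cohort([(default_cohort.before[0], default_cohort.after[0])])

    def test_identical_before_after_all_trivial(self, default_cohort):
        pairs = [(b, b) for b in default_cohort.before]
        rows = summarize_cohort(pairs)
        assert all(r.g == 0.0 for r in rows)
        assert all(r.magnitude_label == "trivial" for r in rows)

    def test_age_effect_size_near_published_value(self):
        """At the default targets, the age row's standardized change is
        close to the published 0.75 (stochastic tolerance at n=200)."""
        cohort = simulate_cohort(CohortSimConfig(n_girls=110, n_boys=90, seed=11))
        rows = summarize_cohort(list(zip(cohort.before, cohort.after)))
        age = next(r for r in rows if r.variable == "age")
        assert age.g == pytest.approx(0.75, abs=0.15)
        assert age.delta_mean == pytest.approx(8.9, abs=1e-9)

    def test_row_layout(self, default_cohort):
        rows = summarize_cohort(list(zip(default_cohort.before, default_cohort.after)))
        anthro = [r for r in rows if r.technique is None]
        assert [r.variable for r in anthro] == ["age", "height", "arm_span", "body_mass", "MO"]
        for tech in ("BREAST", "FLY"):
            kin = [r.variable for r in rows if r.technique == tech]
            assert kin == ["T25", "v", "SR", "SL", "SI"]
        for r in rows:
            assert r.ci95_before[0] < r.ci95_before[1]
            assert r.g >= 0
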