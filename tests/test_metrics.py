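"""Kinematics, maturity offset and change-score computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swimnet.errors import (
    InvalidAnthropometricsError,
    InvalidMeasurementError,
    PairingError,
    UndefinedChangeError,
)
from swimnet.metrics import (
    TrialTiming,
    build_change_vector,
    compute_kinematics,
    compute_speed,
    compute_stroke_rate,
    maturity_offset,
    percent_change,
)

from .conftest import make_session
from .oracles import maturity_offset_termwise


class TestSpeedAndStrokeRate:
    @pytest.mark.parametrize("distance,time,expected", [(10, 12.5, 0.8), (10, 10.0, 1.0)])
    def test_speed(self, distance, time, expected):
        assert compute_speed(distance, time) == pytest.approx(expected)

    @pytest.mark.parametrize("distance,time", [(10, 0), (0, 5), (10, -1)])
    def test_speed_guards(self, distance, time):
        with pytest.raises(InvalidMeasurementError):
            compute_speed(distance, time)

    @pytest.mark.parametrize(
        "n,time,cps,cpm",
        [(3, 4.0, 0.75, 45.0), (3, 3.0, 1.0, 60.0), (3, 6.0, 0.5, 30.0)],
    )
    def test_stroke_rate(self, n, time, cps, cpm):
        assert compute_stroke_rate(n, time) == pytest.approx((cps, cpm))

    def test_stroke_rate_guards(self):
        with pytest.raises(InvalidMeasurementError):
            compute_stroke_rate(3, 0)
        with pytest.raises(InvalidMeasurementError):
            compute_stroke_rate(0, 4.0)


class TestKinematicChain:
    @pytest.mark.parametrize(
        "t10,t3,v,cpm,sl,si",
        [
            (12.5, 4.0, 0.8, 45.0, 1.0667, 0.8533),
            (10.0, 3.0, 1.0, 60.0, 1.0, 1.0),
            (20.0, 5.0, 0.5, 36.0, 0.8333, 0.4167),
        ],
    )
    def test_examples(self, t10, t3, v, cpm, sl, si):
        k = compute_kinematics(TrialTiming(t25=3 * t10, t10=t10, t3cycles=t3))
        assert k.v == pytest.approx(v)
        assert k.sr_cpm == pytest.approx(cpm)
        assert k.sl == pytest.approx(sl, abs=1e-4)
        assert k.si == pytest.approx(si, abs=1e-4)

    @settings(derandomize=True, max_examples=200)
    @given(
        t10=st.floats(5.0, 60.0),
        t3=st.floats(1.0, 20.0),
    )
    def test_round_trip_identities(self, t10, t3):
        """v = SL * SR and SI = v * SL hold to 1e-9 for any valid trial."""
        k = compute_kinematics(TrialTiming(t25=t10 * 2.5, t10=t10, t3cycles=t3))
        assert abs(k.sl * k.sr_cps - k.v) < 1e-9
        assert abs(k.si - k.v * k.sl) < 1e-9
        assert k.sr_cpm == pytest.approx(60 * k.sr_cps)

    def test_t10_must_precede_t25(self):
        with pytest.raises(InvalidMeasurementError):
            TrialTiming(t25=10.0, t10=12.0, t3cycles=4.0)


class TestMaturityOffset:
    def test_boy_worked_example(self):
        res = maturity_offset("M", 10.5, 145.0, 76.0, 38.0)
        assert res.leg_length == pytest.approx(69.0)
        assert res.offset == pytest.approx(-2.6617, abs=1e-3)

    def test_girl_worked_example(self):
        res = maturity_offset("F", 10.0, 140.0, 74.0, 34.0)
        assert res.leg_length == pytest.approx(66.0)
        assert res.offset == pytest.approx(-1.7135, abs=1e-3)

    def test_offset_increases_with_age(self):
        young = maturity_offset("M", 10.5, 145.0, 76.0, 38.0)
        old = maturity_offset("M", 14.5, 145.0, 76.0, 38.0)
        assert old.offset > young.offset

    def test_termwise_rederivation_agreement(self, rng):
        """Both sexes' regressions agree with an independent bracket-by-
        bracket evaluation to 1e-12 over the plausible domain."""
        for _ in range(500):
            sex = "M" if rng.random() < 0.5 else "F"
            age = rng.uniform(8, 14)
            height = rng.uniform(125, 170)
            sh = rng.uniform(65, min(90, height - 1))
            bm = rng.uniform(25, 60)
            got = maturity_offset(sex, age, height, sh, bm).offset
            want = maturity_offset_termwise(sex, age, height, sh, bm)
            assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_anthropometrics(self):
        with pytest.raises(InvalidAnthropometricsError):
            maturity_offset("M", 10.0, 140.0, 141.0, 35.0)
        with pytest.raises(InvalidAnthropometricsError):
            maturity_offset("M", 10.0, 140.0, -5.0, 35.0)
        with pytest.raises(InvalidAnthropometricsError):
            maturity_offset("X", 10.0, 140.0, 74.0, 35.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(100, 110, 10.0), (32.0, 24.5, -23.4375), (7.3, 7.3, 0.0)],
    )
    def test_examples(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(0.1, 1e6),
        b=st.floats(-1e6, 1e6),
    )
    def test_algebraic_identity(self, a, b):
        assert percent_change(a, b) == pytest.approx(-100.0 * (1.0 - b / a), rel=1e-12)
        assert percent_change(a, a) == 0.0

    def test_zero_baseline(self):
        with pytest.raises(UndefinedChangeError):
            percent_change(0.0, 5.0)


class TestChangeVector:
    def test_identical_sessions_give_zero_deltas(self):
        before = make_session()
        after = make_session()
        cv = build_change_vector(before, after, "BREAST")
        assert all(v == pytest.approx(0.0) for v in cv.delta.values())
        assert cv.gender_code == 1

    def test_mo_change_composes_with_offset_oracle(self):
        """The maturity-offset delta equals percent_change of the two
        session offsets computed directly."""
        before = make_session(sex="M", age=10.5, height=145.0, sitting_height=76.0,
                              arm_span=147.0, body_mass=38.0)
        after = make_session(sex="M", age=14.5, height=165.0, sitting_height=86.0,
                             arm_span=168.0, body_mass=52.0)
        cv = build_change_vector(before, after, "BREAST")
        mo_b = maturity_offset("M", 10.5, 145.0, 76.0, 38.0).offset
        mo_a = maturity_offset("M", 14.5, 165.0, 86.0, 52.0).offset
        assert cv.delta["MO"] == pytest.approx(percent_change(mo_b, mo_a))

    def test_missing_trial_is_a_pairing_error(self):
        before = make_session(trials={"BREAST": TrialTiming(32.0, 12.5, 4.0)})
        after = make_session()
        with pytest.raises(PairingError):
            build_change_vector(before, after, "FLY")

    def test_id_mismatch_is_a_pairing_error(self):
        with pytest.raises(PairingError):
            build_change_vector(make_session("S01"), make_session("S02"), "BREAST")


def test_maturity_offset_monotonic_in_age_over_domain(rng):
    """Offset strictly increases with age over the plausible pediatric
    domain (randomized sampling, fixed seed)."""
    for _ in range(2000):
        height = rng.uniform(125, 170)
        sh = rng.uniform(65, min(90, height - 1))
        bm = rng.uniform(25, 60)
        sex = "M" if rng.random() < 0.5 else "F"
        a1, a2 = sorted(rng.uniform(8, 14, size=2))
        if a2 - a1 < 1e-6:
            continue
        o1 = maturity_offset(sex, a1, height, sh, bm).offset
        o2 = maturity_offset(sex, a2, height, sh, bm).offset
        assert o2 > o1
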