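"""Synthetic cohort and Gaussian-graphical-model generators."""

import numpy as np
import pytest

from swimnet.errors import ConfigError
from swimnet.metrics import build_change_vector, session_maturity
from swimnet.simulate import (
    CohortSimConfig,
    sample_ggm,
    simulate_cohort,
)


class TestSampleGgm:
    def test_zero_density_near_independent(self):
        truth, X = sample_ggm(5, 0.0, (0.3, 0.4), 5000, seed=1)
        assert truth.edges == set()
        R = np.corrcoef(X, rowvar=False) - np.eye(5)
        assert np.abs(R).max() < 0.06

    def test_p2_partial_correlation_is_correlation(self):
        truth, X = sample_ggm(2, 0.5, (0.5, 0.5), 100_000, seed=3, edges={(0, 1)})
        r = np.corrcoef(X, rowvar=False)[0, 1]
        assert r == pytest.approx(truth.partial_correlations[0, 1], abs=0.01)

    def test_same_seed_identical(self):
        t1, X1 = sample_ggm(6, 0.3, (0.3, 0.4), 100, seed=42)
        t2, X2 = sample_ggm(6, 0.3, (0.3, 0.4), 100, seed=42)
        assert np.array_equal(X1, X2)
        assert t1.edges == t2.edges

    def test_truth_magnitudes_in_range(self):
        truth, _ = sample_ggm(10, 0.2, (0.3, 0.4), 10, seed=0)
        mags = [abs(truth.partial_correlations[i, j]) for i, j in truth.edges]
        assert all(0.3 <= m <= 0.4 for m in mags)
        assert np.linalg.eigvalsh(truth.precision)[0] > 0

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            sample_ggm(1, 0.2, (0.3, 0.4), 10, seed=0)
        with pytest.raises(ConfigError):
            sample_ggm(5, 0.2, (0.0, 0.4), 10, seed=0)


class TestSimulateCohort:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(CohortSimConfig(n_girls=0, n_boys=0))

    def test_single_swimmer_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(CohortSimConfig(n_girls=1, n_boys=0))

    def test_determinism(self):
        a = simulate_cohort(CohortSimConfig(seed=5))
        b = simulate_cohort(CohortSimConfig(seed=5))
        for s1, s2 in zip(a.before + a.after, b.before + b.after):
            assert s1 == s2

    def test_sessions_satisfy_all_invariants(self, large_cohort):
        for s in large_cohort.before + large_cohort.after:
            # dataclass validation already enforces positivity/ordering;
            # re-check the load-bearing ones explicitly
            assert s.sitting_height < s.height
            for t in s.trials.values():
                assert 0 < t.t10 < t.t25
                assert t.t3cycles > 0
            assert session_maturity(s).leg_length > 0

    def test_calibration_hits_targets(self, large_cohort):
        """Realized cohort Delta% mean/SD equal the configured targets for
        every drawn variable (within-sample calibration)."""
        cfg = CohortSimConfig()
        pairs = list(zip(large_cohort.before, large_cohort.after))
        for tech in ("BREAST", "FLY"):
            changes = [build_change_vector(b, a, tech) for b, a in pairs]
            for var in ("age", "height", "arm_span", "body_mass"):
                d = np.array([c.delta[var] for c in changes])
                mu, sd = cfg.delta[var]
                assert d.mean() == pytest.approx(mu, abs=1e-9)
                assert d.std(ddof=1) == pytest.approx(sd, abs=1e-9)
            d = np.array([c.delta["v"] for c in changes])
            mu, sd = cfg.delta_kinematics[tech]["v"]
            assert d.mean() == pytest.approx(mu, abs=1e-9)
            assert d.std(ddof=1) == pytest.approx(sd, abs=1e-9)
            # SR's huge change SD can hit the -95% physical floor, which
            # perturbs the calibrated moments slightly
            d = np.array([c.delta["SR"] for c in changes])
            mu, sd = cfg.delta_kinematics[tech]["SR"]
            assert d.mean() == pytest.approx(mu, abs=0.5)
            assert d.std(ddof=1) == pytest.approx(sd, rel=0.05)

    def test_zero_loadings_give_uncorrelated_changes(self):
        cfg = CohortSimConfig(
            n_girls=100,
            n_boys=100,
            seed=13,
            loadings={k: 0.0 for k in CohortSimConfig().loadings},
        )
        cohort = simulate_cohort(cfg)
        changes = [
            build_change_vector(b, a, "BREAST")
            for b, a in zip(cohort.before, cohort.after)
        ]
        for u, v in [("height", "v"), ("body_mass", "SR"), ("arm_span", "T25")]:
            x = np.array([c.delta[u] for c in changes])
            y = np.array([c.delta[v] for c in changes])
            assert abs(np.corrcoef(x, y)[0, 1]) < 0.15

    def test_gender_split_and_codes(self, default_cohort):
        codes = [s.gender_code for s in default_cohort.before]
        assert codes.count(1) == 11 and codes.count(2) == 9

    def test_invalid_loading_rejected(self):
        cfg = CohortSimConfig()
        cfg.loadings["v"] = 1.5
        with pytest.raises(ConfigError):
            simulate_cohort(cfg)


def test_pipeline_recovers_kinematic_coupling():
    """With strong latent coupling of the kinematic changes, the highest-
    strength node of the selected network is a kinematic variable in a
    majority of seeds."""
    from swimnet.centrality import strength
    from swimnet.network import CohortChangeMatrix, select_network

    kinematic = {"T25", "v", "SR", "SL", "SI"}
    hits = 0
    seeds = range(10)
    for seed in seeds:
        cfg = CohortSimConfig(n_girls=30, n_boys=30, seed=seed)
        cfg.loadings.update({"v": 0.95, "SR": 0.9, "T25": 0.95})
        cohort = simulate_cohort(cfg)
        changes = [
            build_change_vector(b, a, "BREAST")
            for b, a in zip(cohort.before, cohort.after)
        ]
        net, _ = select_network(CohortChangeMatrix.from_change_vectors(changes))
        s = strength(net.weights)
        order = [net.nodes[i] for i in np.argsort(-s)]
        top_non_gender = next(n for n in order if n != "gender")
        if top_non_gender in kinematic:
            hits += 1
    assert hits >= 6
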