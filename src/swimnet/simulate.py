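"""Synthetic data with known ground truth.

Two generators:

``simulate_cohort`` emulates a paired before/after cohort of age-group
swimmers over one 47-week season. Before-values are drawn from the
published group summaries (heights, arm spans and body masses share a
latent body-size factor so the anthropometry is realistically correlated);
trial timings are solved back from the drawn mid-pool speed and stroke rate
so every kinematic invariant holds by construction. Seasonal change is
driven by a per-swimmer latent maturation-tempo factor: each variable's
percent change is a loading on that factor plus independent noise, then
standardized within-sample and mapped to the configured Delta% mean/SD, so
the realized cohort moments equal the targets exactly. The 25-m time loads
negatively on the tempo factor (faster development shortens the race).

``sample_ggm`` draws multivariate-normal data from a random sparse
partial-correlation structure, providing exact ground truth for network
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import reference
from .errors import ConfigError, ConstructionError
from .metrics import SwimmerSession, TrialTiming

_SQ = math.sqrt


def _default_before():
    return {
        "height": reference.summary_row("height").before,
        "arm_span": reference.summary_row("arm_span").before,
        "body_mass": reference.summary_row("body_mass").before,
    }


def _default_before_kinematics():
    return {
        tech: {
            "v": reference.summary_row("v", tech).before,
            "SR": reference.summary_row("SR", tech).before,
        }
        for tech in ("BREAST", "FLY")
    }


def _default_delta():
    return {
        var: reference.summary_row(var).delta
        for var in ("age", "height", "arm_span", "body_mass")
    }


def _default_delta_kinematics():
    return {
        tech: {
            var: reference.summary_row(var, tech).delta
            for var in ("T25", "v", "SR")
        }
        for tech in ("BREAST", "FLY")
    }


def _default_loadings():
    # share of each Delta% composite carried by the latent maturation-tempo
    # factor; age change is essentially mechanical (same elapsed season) and
    # is left unloaded
    return {
        "age": 0.0,
        "height": 0.7,
        "arm_span": 0.7,
        "body_mass": 0.6,
        "T25": 0.7,
        "v": 0.7,
        "SR": 0.4,
    }


@dataclass
class CohortSimConfig:
    """Targets and couplings of the simulated cohort.

    ``before`` / ``delta`` hold (mean, SD) pairs per variable; kinematic
    entries are nested per technique. ``loadings`` in [0, 1] set how strongly
    each variable's change follows the shared maturation-tempo factor.
    """

    n_girls: int = reference.N_GIRLS
    n_boys: int = reference.N_BOYS
    seed: int = 2022
    age_before: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(reference.AGE_BEFORE)
    )
    before: Dict[str, Tuple[float, float]] = field(default_factory=_default_before)
    before_kinematics: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=_default_before_kinematics
    )
    delta: Dict[str, Tuple[float, float]] = field(default_factory=_default_delta)
    delta_kinematics: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=_default_delta_kinematics
    )
    loadings: Dict[str, float] = field(default_factory=_default_loadings)
    sitting_height_ratio: float = 0.52  # sitting height as fraction of stature
    sitting_height_ratio_sd: float = 0.015
    t25_factor: float = 2.5  # t25 = t10 * factor * (1 + noise)
    t25_noise_sd: float = 0.05

    def validate(self) -> None:
        if self.n_girls < 0 or self.n_boys < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.n_girls + self.n_boys == 0:
            raise ConfigError("empty cohort: n_girls + n_boys must be > 0")
        if self.n_girls + self.n_boys < 2:
            raise ConfigError(
                "cohort must have at least 2 swimmers (within-sample "
                "calibration is undefined for a single swimmer)"
            )
        for name, (m, s) in {**self.before, **self.delta}.items():
            if s < 0:
                raise ConfigError(f"negative SD for {name}")
        for var, l in self.loadings.items():
            if not 0.0 <= l <= 1.0:
                raise ConfigError(f"loading for {var} must be in [0, 1], got {l}")
        if not 0 < self.sitting_height_ratio < 1:
            raise ConfigError("sitting_height_ratio must be in (0, 1)")


@dataclass
class SimulatedCohort:
    """Paired sessions plus the generating ground truth."""

    before: List[SwimmerSession]
    after: List[SwimmerSession]
    truth: Dict


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw one paired cohort; bit-identical for identical seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_girls + config.n_boys
    sexes = ["F"] * config.n_girls + ["M"] * config.n_boys
    ids = [f"S{i + 1:02d}" for i in range(n)]

    # latent factors
    size = rng.standard_normal(n)  # body-size factor (before-values)
    tempo = rng.standard_normal(n)  # maturation-tempo factor (changes)

    def blended(loading: float) -> np.ndarray:
        return loading * size + _SQ(1.0 - loading**2) * rng.standard_normal(n)

    age = np.array(
        [
            config.age_before[s][0] + config.age_before[s][1] * z
            for s, z in zip(sexes, rng.standard_normal(n))
        ]
    )
    age = np.maximum(age, 5.0)
    hm, hs = config.before["height"]
    height = hm + hs * blended(0.85)
    am, asd = config.before["arm_span"]
    arm_span = am + asd * blended(0.85)
    bm, bs = config.before["body_mass"]
    body_mass = np.maximum(bm + bs * blended(0.7), 15.0)
    ratio = np.clip(
        rng.normal(config.sitting_height_ratio, config.sitting_height_ratio_sd, n),
        0.40,
        0.62,
    )
    sitting_height = ratio * height

    kin_before: Dict[str, Dict[str, np.ndarray]] = {}
    for tech, dists in config.before_kinematics.items():
        vm, vs = dists["v"]
        v = np.maximum(vm + vs * blended(0.3), 0.2)
        srm, srs = dists["SR"]
        sr = np.maximum(srm + srs * rng.standard_normal(n), 10.0)
        t10 = 10.0 / v
        t3 = 180.0 / sr
        t25 = t10 * config.t25_factor * (1.0 + rng.normal(0.0, config.t25_noise_sd, n))
        t25 = np.maximum(t25, 1.05 * t10)
        kin_before[tech] = {"v": v, "SR": sr, "t10": t10, "t3": t3, "t25": t25}

    def draw_delta(target: Tuple[float, float], var: str) -> np.ndarray:
        """Percent changes with exact within-sample mean/SD calibration."""
        mu, sigma = target
        loading = config.loadings.get(var, 0.0)
        sign = -1.0 if var == "T25" else 1.0
        comp = sign * loading * tempo + _SQ(1.0 - loading**2) * rng.standard_normal(n)
        sd = comp.std(ddof=1)
        if sd == 0:
            raise ConstructionError(f"degenerate change composite for {var}")
        z = (comp - comp.mean()) / sd
        # physical floor: a measured quantity cannot lose 100%; the floor
        # only binds for variables with very large relative change SDs
        return np.maximum(mu + sigma * z, -95.0)

    d_anthro = {var: draw_delta(config.delta[var], var) for var in config.delta}
    d_kin = {
        tech: {var: draw_delta(tgt, var) for var, tgt in targets.items()}
        for tech, targets in config.delta_kinematics.items()
    }

    def grown(x: np.ndarray, d: np.ndarray, what: str) -> np.ndarray:
        out = x * (1.0 + d / 100.0)
        if np.any(out <= 0):
            raise ConstructionError(f"non-positive after-value generated for {what}")
        return out

    age_a = grown(age, d_anthro["age"], "age")
    height_a = grown(height, d_anthro["height"], "height")
    arm_span_a = grown(arm_span, d_anthro["arm_span"], "arm_span")
    body_mass_a = grown(body_mass, d_anthro["body_mass"], "body_mass")
    ratio_a = np.clip(ratio + rng.normal(0.0, 0.003, n), 0.40, 0.62)
    sitting_height_a = ratio_a * height_a

    kin_after: Dict[str, Dict[str, np.ndarray]] = {}
    for tech, kb in kin_before.items():
        v_a = grown(kb["v"], d_kin[tech]["v"], f"{tech} v")
        sr_a = grown(kb["SR"], d_kin[tech]["SR"], f"{tech} SR")
        t25_a = grown(kb["t25"], d_kin[tech]["T25"], f"{tech} T25")
        t10_a = 10.0 / v_a
        t25_a = np.maximum(t25_a, 1.05 * t10_a)
        kin_after[tech] = {"t10": t10_a, "t3": 180.0 / sr_a, "t25": t25_a}

    def session(i: int, when: str) -> SwimmerSession:
        if when == "before":
            trials = {
                tech: TrialTiming(
                    t25=float(k["t25"][i]), t10=float(k["t10"][i]), t3cycles=float(k["t3"][i])
                )
                for tech, k in kin_before.items()
            }
            return SwimmerSession(
                swimmer_id=ids[i], sex=sexes[i], age=float(age[i]),
                height=float(height[i]), sitting_height=float(sitting_height[i]),
                arm_span=float(arm_span[i]), body_mass=float(body_mass[i]),
                trials=trials,
            )
        trials = {
            tech: TrialTiming(
                t25=float(k["t25"][i]), t10=float(k["t10"][i]), t3cycles=float(k["t3"][i])
            )
            for tech, k in kin_after.items()
        }
        return SwimmerSession(
            swimmer_id=ids[i], sex=sexes[i], age=float(age_a[i]),
            height=float(height_a[i]), sitting_height=float(sitting_height_a[i]),
            arm_span=float(arm_span_a[i]), body_mass=float(body_mass_a[i]),
            trials=trials,
        )

    before = [session(i, "before") for i in range(n)]
    after = [session(i, "after") for i in range(n)]
    truth = {
        "seed": config.seed,
        "tempo_factor": tempo.tolist(),
        "size_factor": size.tolist(),
        "loadings": dict(config.loadings),
        "delta_targets": {
            **{k: list(v) for k, v in config.delta.items()},
            **{
                tech: {k: list(v) for k, v in targets.items()}
                for tech, targets in config.delta_kinematics.items()
            },
        },
    }
    return SimulatedCohort(before=before, after=after, truth=truth)


# ---------------------------------------------------------------------------
# Gaussian graphical model sampler


@dataclass
class GgmTruth:
    """Ground truth of one sampled Gaussian graphical model."""

    precision: np.ndarray  # standardized (unit diagonal) precision matrix
    partial_correlations: np.ndarray  # -theta_ij scaled; zero diagonal
    edges: Set[Tuple[int, int]]  # upper-triangle index pairs


#: maximum absolute off-diagonal row sum of the standardized precision;
#: strict diagonal dominance with this margin bounds the condition number of
#: the implied covariance so recovery tests exercise sane marginals
_DOMINANCE_BOUND = 0.9


def _degree_capped_edges(rng, p: int, k: int, cap: int, tries: int = 200):
    """Random k-edge structure with node degrees <= cap, or None."""
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    for _ in range(tries):
        order = rng.permutation(len(pairs))
        deg = [0] * p
        edges: Set[Tuple[int, int]] = set()
        for c in order:
            i, j = pairs[c]
            if deg[i] < cap and deg[j] < cap:
                edges.add(pairs[c])
                deg[i] += 1
                deg[j] += 1
                if len(edges) == k:
                    return edges
    return None


def sample_ggm(
    p: int,
    edge_density: float,
    partial_corr_range: Tuple[float, float],
    n: int,
    seed: int,
    max_tries: int = 500,
    edges: Optional[Set[Tuple[int, int]]] = None,
) -> Tuple[GgmTruth, np.ndarray]:
    """Random sparse partial-correlation structure plus an n x p Gaussian
    sample from it.

    The standardized precision is built as I - C with C holding the target
    partial correlations (random signs) on a random edge set — or on
    ``edges`` if given, e.g. a chain. The construction keeps the matrix
    strictly diagonally dominant (row sums of |C| <= 0.9): structures are
    drawn with a node-degree cap when that cap leaves enough room for k
    edges, otherwise by rejection; as a last resort the diagonal is
    inflated and the matrix restandardized, in which case the recorded
    partial correlations are the (shrunken) realized ones.
    """
    if p < 2:
        raise ConfigError(f"p must be >= 2, got {p}")
    if not 0 <= edge_density < 1:
        raise ConfigError(f"edge_density must be in [0, 1), got {edge_density}")
    lo, hi = partial_corr_range
    if not (0 < lo <= hi < 1):
        raise ConfigError(f"partial_corr_range must be within (0, 1), got {partial_corr_range}")
    if n < 2:
        raise ConfigError(f"n must be >= 2, got {n}")

    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    k = len(edges) if edges is not None else int(round(edge_density * len(pairs)))

    def magnitudes(edge_set):
        cand = np.eye(p)
        for (i, j) in sorted(edge_set):
            r = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            cand[i, j] = cand[j, i] = -r
        return cand

    def dominant(cand):
        off = np.abs(cand) - np.eye(p)
        return off.sum(axis=1).max() <= _DOMINANCE_BOUND

    theta = None
    if edges is not None:
        cand = magnitudes(edges)
        if dominant(cand):
            theta = cand
    elif k == 0:
        edges = set()
        theta = np.eye(p)
    else:
        cap = int(_DOMINANCE_BOUND / hi)
        if cap >= 1 and k <= (p * cap) // 2:
            found = _degree_capped_edges(rng, p, k, cap)
            if found is not None:
                edges = found
                theta = magnitudes(edges)
        if theta is None:
            for _ in range(max_tries):
                chosen = rng.choice(len(pairs), size=k, replace=False)
                edge_set = {pairs[c] for c in chosen}
                cand = magnitudes(edge_set)
                if dominant(cand):
                    edges = edge_set
                    theta = cand
                    break
    if theta is None:
        # fallback: inflate the diagonal into strict dominance, then
        # restandardize; realized partial correlations shrink accordingly
        if edges is None:
            chosen = rng.choice(len(pairs), size=k, replace=False)
            edges = {pairs[c] for c in chosen}
        cand = magnitudes(edges)
        rowsum = (np.abs(cand) - np.eye(p)).sum(axis=1).max()
        cand = cand + (rowsum / _DOMINANCE_BOUND - 1.0) * np.eye(p)
        d = np.sqrt(np.diag(cand))
        theta = cand / np.outer(d, d)
        if np.linalg.eigvalsh(theta)[0] <= 0:
            raise ConstructionError("could not construct an SPD precision matrix")

    pcor = -theta.copy()
    np.fill_diagonal(pcor, 0.0)
    sigma = np.linalg.inv(theta)
    L = np.linalg.cholesky(sigma)
    X = rng.standard_normal((n, p)) @ L.T
    return GgmTruth(precision=theta, partial_correlations=pcor, edges=edges), X
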