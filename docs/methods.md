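# Methods

This note records the models, conventions and design choices behind
`swimnet`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Measurement model and derived kinematics

A swimmer-session carries decimal age (consumed as given; no birthdate
arithmetic), stature, sitting height, arm span and body mass, plus per
technique the stopwatch timings of one 25-m all-out trial: total time t₂₅,
intermediate 10-m time t₁₀, and the time of three consecutive stroke
cycles t₃. Derived quantities:

- mid-pool speed v = 10/t₁₀ (m·s⁻¹),
- stroke rate SR = 3/t₃ (cycles·s⁻¹), reported ×60 (cycles·min⁻¹),
- stroke length SL = v/SR using SR in cycles·s⁻¹ (m),
- stroke index SI = v·SL (m²·s⁻¹).

SL·SR = v and SI = v·SL therefore hold to machine precision by
construction, and the tests assert them to 1e-9. Validity gates: all
measurements positive, t₁₀ < t₂₅, sitting height < stature.

## Maturity offset

Somatic maturation is summarized by the sex-specific Mirwald regressions
predicting years from peak height velocity from age A, sitting height SH,
leg length LL = stature − SH, and the mass/stature ratio (BM/HE)·100 (kg
per cm, scaled). Boys:

    MO = −9.236 + 0.0002708·LL·SH − 0.001663·A·LL + 0.007216·A·SH
         + 0.02292·(BM/HE·100)

girls:

    MO = −9.376 + 0.0001882·LL·SH + 0.0022·A·LL + 0.005847·A·SH
         − 0.002658·A·BM + 0.07693·(BM/HE·100)

Negative values mean the swimmer has not reached PHV. The source rendering
of the final term is typographically damaged in the literature this
follows; the standard ratio reading (mass over stature, ×100) is adopted
for both sexes. Within the pediatric domain the tests sample (age 8–14,
stature 125–170 cm, SH 65–90 cm, mass 25–60 kg) the offset is strictly
increasing in age; the suite verifies this on 10⁴ random inputs and checks
both regressions against an independent bracket-by-bracket re-derivation
to 1e-12.

## Change scores

Seasonal change is the relative percent change Δ% = 100·(after −
before)/before for all ten variables (age, stature, arm span, body mass,
MO, and per technique T25, v, SR, SL, SI). Two deliberate consequences:

- The maturity-offset Δ% is the percent change of a quantity that crosses
  zero near PHV, so it can be extreme or sign-flipped. No winsorization is
  applied; this matches the field's reporting practice (published cohorts
  show Δ_MO SDs in the hundreds of percent).
- A zero baseline raises an error rather than returning an infinity.

## Effect-size statistics

Per variable: before/after mean ± SD, t-based 95% CIs
(mean ± t₀.₉₇₅,ₙ₋₁·SD/√n), a two-sided paired t-test, and Hedges' g in the
two-group form with the root-mean of the two variances as pooled SD,

    g = |m₂ − m₁| / √((SD₁² + SD₂²)/2),

with **no** small-sample correction. This variant — not the n-weighted
pooled-SD form with the J correction used by generic effect-size
libraries — is the one that reproduces the published seasonal table this
package's acceptance checks target (e.g. 7.5/√((7.5²+3.8²)/2) = 1.26), so
it is authored in-package rather than delegated. Magnitudes use the
Hopkins bands with lower-edge inclusion (g = 0.2 → small). Normality is
screened per variable with Shapiro–Wilk but only logged: the t-tests run
regardless, matching the analysis convention the package mirrors. p-values
are reported raw (no multiplicity adjustment). Reports round g to 2 dp;
full-precision values are always written alongside.

## Network estimation

The change matrix is n × 11: gender coded 1 (girls) / 2 (boys) and treated
numerically as a dichotomous node, plus the ten Δ% variables. Nodes are
grouped 1 = gender + anthropometrics, 2 = performance/kinematics, 3 =
maturation. The association input is the Pearson correlation matrix
(polychoric/polyserial handling for the gender node is out of scope and
flagged); using correlations makes the selected network invariant to
rescaling any input column, which the suite asserts to 1e-8.

The estimator is the graphical lasso: maximize
log det Θ − tr(SΘ) − λ·Σ_{i≠j}|θ_ij| over SPD precision matrices, penalty
on off-diagonals only. The solver is Friedman-style block coordinate
descent (lasso inner loop via coordinate descent); convergence when the
mean absolute change of the working covariance per sweep falls below
1e-4 × mean|off-diag S| (exposed as `tol_scale`), capped at 10,000 sweeps
with a convergence error carrying the trace. Tests verify the solver
against an independent convex solve of the same objective on random
instances to 1e-4, the analytic endpoints (diagonal precision at
λ ≥ max|S_ij|; Θ = S⁻¹ at λ = 0), and exact symmetry.

Model selection: a log-spaced path of 100 penalties from
λ_max = max|S_ij| down to λ_max/100, each fit warm-started from its
predecessor, scored by

    EBIC(λ) = −2ℓ(Θ̂_λ) + E log n + 4·E·γ·log p,
    ℓ = (n/2)(log det Θ − tr(SΘ)),

with E the number of nonzero upper-triangle partial correlations
(|w| > 1e-8) and γ = 0.25 by default (exploratory convention; γ = 0 is
BIC, larger γ is more parsimonious — the suite asserts the monotonicity).
The additive −(np/2)log 2π constant is omitted (cancels on a common path).
Ties are broken toward the larger (sparser) penalty. The selected
penalized weight matrix is reported as-is; no refit of the selected
support is performed, matching the convention of the network-psychometrics
software stack this mirrors. A consequence worth knowing: because the
likelihood is evaluated at the *penalized* estimate, the EBIC minimum at
large n retains a few near-zero false edges (the suite demonstrates on
chain-structured data that all true edges are recovered while every false
edge is at most half the weakest true edge). n < p is permitted but logged
as a stability warning.

## Centrality

Edges with |w| > 1e-8 get length 1/|w| (stronger association = shorter).
Betweenness is the standard weighted-graph count over unordered pairs with
fractional credit among tied shortest paths; closeness is 1/Σ_j d(i,j)
with zero for nodes that cannot reach the whole graph (no component-size
normalization); strength is Σ_j |w_ij| — the standard edge-based
definition, adopted although the field's prose sometimes describes
strength loosely in terms of "paths". All three are invariant to flipping
every weight's sign (asserted). z-scores standardize each measure over all
nodes with the sample SD (ddof = 1, the R `scale()` convention); constant
columns map to zeros with a warning. The gender node is included in the
standardization (the field's tables print its z-scores) but flagged
"excluded from interpretation" in reports, since a fixed dichotomy has no
seasonal change to interpret.

## Synthetic cohort generator

The generator emulates the published 47-week cohort: 11 girls (age
10.0 ± 1.3 y) and 9 boys (10.5 ± 0.9 y), with pooled before-distributions
for stature (142.3 ± 9.7 cm), arm span (143.6 ± 10.4 cm), body mass
(36.7 ± 8.2 kg) and per-technique mid-pool speed and stroke rate, and
per-variable Δ% targets taken from the same table.

Structure:

- **Before-values.** Stature, arm span (loadings 0.85) and body mass
  (0.7) share a latent body-size factor, keeping the anthropometry
  realistically correlated while preserving the configured marginals;
  speed loads weakly (0.3) on size. Sitting height is a per-swimmer ratio
  of stature (0.52 ± 0.015, clipped to [0.40, 0.62] — a plausible
  pediatric value, config-exposed because the emulated study reports no
  sitting-height summary). Trial timings are solved back from the drawn v
  and SR (t₁₀ = 10/v, t₃ = 180/SR); t₂₅ = t₁₀·2.5·(1+ε), ε ~ N(0, 0.05²),
  floored at 1.05·t₁₀, leaving the 25-m time partially independent of
  mid-pool speed (it contains wall phases). A consequence: the simulated
  T25 *level* (~36 s before) is not itself a configured target — only its
  Δ% is.
- **Changes.** Each swimmer has a latent maturation-tempo factor
  g ~ N(0,1). Each variable's Δ% composite is loading·g + independent
  noise (loadings in [0,1]; defaults 0.7 for stature/arm span/speed/T25,
  0.6 for mass, 0.4 for SR, 0 for age), standardized **within-sample**
  (ddof = 1) and mapped to the target mean/SD — so the realized cohort Δ%
  moments equal the targets exactly, and the generator's calibration check
  is a check of the mapping rather than a sampling coin-flip. T25 enters
  with a fixed negative sign on the factor (faster development shortens
  the race) while its loading magnitude stays in [0,1]. Deltas are floored
  at −95% (a measured quantity cannot lose 100%); the floor only binds for
  variables with very large change SDs (stroke rate, SD 44.1%) and then
  perturbs the calibrated moments by well under half a standard error at
  n = 200. After-values are before·(1 + Δ%/100); timings are re-solved
  from the after kinematics. Maturity offset is never drawn — it emerges
  from the generated anthropometrics, as in real data.
- **What it does not emulate.** Measurement error in the stopwatch
  readings, non-normal (skewed) change distributions, dropout, more than
  two time points, and any physiology beyond the summary statistics.
  Passing tests therefore show the pipeline recovers structure the
  generator put in; they do not certify the biological claims of any real
  cohort.

Cohorts need at least two swimmers (within-sample calibration is undefined
for one); an empty configuration is an error. Identical seeds give
bit-identical cohorts.

## GGM sampler

For validating the network estimator, `sample_ggm` builds a standardized
precision Θ = I − C with the requested partial correlations (random signs)
on a random edge set, keeping Θ strictly diagonally dominant (off-diagonal
row sums ≤ 0.9): structures are drawn under a node-degree cap whenever the
cap leaves room for the requested edge count, otherwise by rejection, with
diagonal inflation + restandardization as a last resort (in which case the
recorded truth holds the shrunken realized values). The dominance bound
keeps the implied covariance well-conditioned — without it, near-singular
truths produce pathological marginal correlations that no sparse estimator
could disentangle, which would test conditioning rather than recovery.
Data are Θ⁻¹-Cholesky transforms of standard normal draws, reproducible
per seed.

## Numerical conventions

- Edge presence: |partial correlation| > 1e-8, used consistently for E in
  the EBIC, for reports, and for graphs.
- Report rounding: 2 dp for weight matrices and centrality z-scores;
  full-precision companions are always written.
- All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); reruns with the same seed and
  configuration produce byte-identical numeric outputs.
- Exit codes of the CLI: 0 success, 2 validation failure, 3 convergence
  failure.

## Problem sizes used by the test suite

The suite validates the solver on random instances of p ≤ 6 against an
independent solver, edge recovery at p = 10, 20% density, |pcor| ∈
[0.3, 0.4], n = 500 over 20 seeds (mean sensitivity/specificity
thresholds 0.7/0.85), centrality against brute-force path enumeration on
graphs of ≤ 6 nodes, and the end-to-end pipeline on simulated cohorts of
20–200 swimmers. These sizes exercise every code path at desk scale while
keeping the default test run fast.

## Known limitations

- The published weight and centrality tables of the emulated study cannot
  be reproduced numerically (raw data undeposited); the network stage is
  validated by property and simulation instead.
- Pearson correlations treat the gender node numerically; polychoric
  alternatives are out of scope.
- Penalized-likelihood EBIC selection retains weak false edges at large
  n (see above); bootstrapped edge-stability intervals are out of scope.
- The arm-span effect size printed in the emulated study's table (0.41)
  is not consistent with its own printed summary statistics (the pooled-SD
  formula gives 0.66); the package reproduces the arithmetic, not the
  misprint.
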