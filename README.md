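# swimnet

Seasonal change analysis for age-group swimmers: stroke kinematics and
somatic maturation from paired field measurements, paired effect-size
statistics, and regularized partial-correlation networks over the seasonal
changes.

## The problem

Over a competitive season, young (≤12 y) swimmers change simultaneously in
body size, biological maturation, and technique, and these changes are
interdependent: growth alters propulsion and drag, maturation alters
coordination, training alters stroke mechanics. Summarizing each variable's
before/after change in isolation misses this structure. `swimnet`
implements the full analysis chain a sports scientist needs to study it in
a paired (before / after ~47 weeks) cohort design, for the two simultaneous
techniques (breaststroke and butterfly):

1. **Kinematics** from stopwatch timings of a 25-m all-out swim:
   mid-pool speed *v* = 10 m / t₁₀, stroke rate SR = 3 / t₃cycles
   (reported in cycles·min⁻¹), stroke length SL = *v*/SR, and stroke index
   SI = *v*·SL (an indirect efficiency measure).
2. **Maturity offset** (predicted years from peak height velocity, PHV)
   from the sex-specific Mirwald anthropometric regressions on age, sitting
   height, leg length (stature − sitting height) and the mass/stature
   ratio; negative = pre-PHV.
3. **Paired effect sizes**: per variable, before/after mean ± SD with
   t-based 95% CIs, paired t-tests, Hedges' g computed as
   |Δmean| / √((SD₁² + SD₂²)/2) with Hopkins magnitude bands
   (trivial < 0.2 ≤ small < 0.6 ≤ moderate < 1.2 ≤ large < 2.0 ≤ very
   large < 4.0 ≤ nearly perfect), and the mean ± SD of the individual
   relative changes Δ% = 100·(after − before)/before.
4. **Network estimation**: a pairwise Markov random field over the n × 11
   change matrix (dichotomous gender, coded 1 = girls / 2 = boys, plus ten
   Δ% variables). The Pearson correlation matrix is fed to the graphical
   lasso, which maximizes log det Θ − tr(SΘ) − λΣ_{i≠j}|θ_ij|; the penalty
   λ is selected on a 100-point log-spaced path by minimizing the extended
   Bayesian information criterion EBIC = −2ℓ + E·log n + 4·E·γ·log p with
   γ = 0.25. Edge weights are the regularized partial correlations
   w_ij = −θ_ij/√(θ_ii θ_jj).
5. **Centrality**: betweenness, closeness and strength on the weighted
   network (shortest paths on lengths 1/|w|), z-scored across nodes.

Because studies of this kind rarely deposit raw athlete data, the package
includes a first-class synthetic cohort generator whose defaults match the
published group summaries of a 47-week season in 20 swimmers (11 girls, 9
boys), plus a Gaussian-graphical-model sampler with exact ground truth for
validating the network estimator.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_effect_sizes.py
python analysis/03_estimate_networks.py
python analysis/04_centrality.py
```

The first script writes `results/cohort.csv` (20 swimmers, seed 2022); the
second prints the effect-size table, e.g.:

```
  T25 (FLY): g = 1.63 [large], Δ = -26.5 ± 11.0 %
  v (FLY): g = 1.34 [large], Δ = 41.0 ± 25.3 %
  v (BREAST): g = 0.98 [moderate], Δ = 28.5 ± 19.7 %
  ...
  height: g = 0.38 [small], Δ = 3.8 ± 1.4 %
```

i.e. in this simulated cohort the 25-m butterfly time dropped by 26.5% on
average (a large standardized change), while height grew only 3.8% — the
same qualitative picture as the real season: technique and performance
change far more than body size. The Δ% columns equal the configured targets
exactly by construction; the g values are emergent (they also depend on the
simulated between-swimmer spread).

The third script estimates the networks and reports, per technique, the
selected penalty, the edge count and the strongest regularized partial
correlations:

```
BREAST: lambda = 0.2103, E = 18 edges, EBIC = 206.30
  strongest associations:
    ΔSL – ΔSI: +0.67
    Δarm_span – ΔT25: -0.55
    ΔSR – ΔSL: -0.40
```

The fourth computes z-scored centralities; with this seed the 25-m-time
change is the highest-strength node in both techniques.

The same pipeline runs on any cohort CSV (schema in the module docs of
`swimnet.io`) via the CLI:

```bash
swimnet simulate --seed 2022 --out cohort.csv
swimnet validate cohort.csv
swimnet run --input cohort.csv --out-dir out/
```

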