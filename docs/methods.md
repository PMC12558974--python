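# Methods

## Scope and data model

The package analyses self-reported survey data: one row per user with
demographics (age, gender), hair indicators (hairfall rate 1–5/day,
density and strength 1–10, thickness 1–5), lifestyle fields (sleep hours,
wash frequency 1–7/week, shampoo/conditioner use), stress metrics (daily
level 1–10, stressed days per week 0–7) and weekly nutrient intake events
(protein, iron, omega-3, each 0–7). Stress frequency is interpreted as
*days per week* (0–7), consistent with the division by 7 in the stress
score; intake frequencies likewise count days on which the nutrient was
consumed.

Because the survey data that motivated the method is private, all testing
runs on synthetic cohorts. The generator draws ordinal fields uniformly
within their declared bounds, sleeping hours from Normal(7, 1) clipped to
[3, 12] h, and intake frequencies from Binomial(7, p) with per-nutrient
propensities (protein 0.6; iron 0.45 female / 0.55 male, exercising the
gender-specific RDA path; omega-3 0.35). These choices are deliberately
plain — uniform ordinals maximise boundary coverage, the binomial is the
natural model for days-per-week counts — and every parameter is
overridable in `CohortConfig`. What the generator does **not** emulate:
real covariance between stress, sleep and diet; demographic skew;
self-report biases; missingness patterns. Passing tests therefore
establish that the formulas, rules and models are implemented and
composed correctly, not that they are clinically validated on real
populations.

## Derived indices

All indices are literal arithmetic on the survey fields (see README for
the formulas). Numerical notes:

- The HFI denominator `Σ ratios + 1` is ≥ 1 by construction, so the index
  is finite for every admissible input; no epsilon guards are needed.
- The intake ratio `freq × RDA_day / RDA_week` reduces to `freq/7` when
  `RDA_week = 7 × RDA_day` (the default); the full form is kept because
  the weekly requirement is independently overridable.
- The deficiency flag is `NDS > 0` (strict); the threshold is exposed in
  config. HFI magnitudes depend directly on raw inputs — the formula is
  implemented literally, with no hidden standardisation of stress, sleep
  or rate inputs.

## Scalp-score regression and EM refinement

The scalp score is an OLS fit on (shampoo type, conditioner use, hair
strength). Rank-deficient designs raise an error naming the collinear
columns (found via pivoted QR) rather than silently pseudo-inverting.

The EM refinement treats observed scores `Yᵢ` as noisy realisations of a
latent score: E-step `ẑᵢ = μ + ρ(Yᵢ − μ)` for observed entries and
`ẑᵢ = μ` for missing ones; M-step re-estimates `μ = mean(ẑ)` and
`σ² = var(ẑ)` (population variance, matching the 1/N form of the M-step).
`ρ ∈ [0,1]` (default 0.5, configurable) weights observation confidence:
ρ=1 reproduces the data exactly, ρ=0 collapses everything to the mean.
Iteration starts from the observed-data moments and stops when both
parameter increments fall below `tol` (default 1e-10) or at `max_iter`
(500). The fixed point is the observed mean; convergence is geometric
with rate `(1 − ρ)·n_obs/n`, so the iteration cap is generous.

## Preprocessing

Imputation defaults: mean for continuous, median for ordinal, mode for
categorical fields; observed cells are never altered, and a fully missing
field is an error. Encoding: booleans → {0,1}; ordered categories → 0-based
rank under a documented default order (shampoo organic < mild < chemical
by chemical load; scalp dry < normal < oily < dandruff); range labels
(water intake) → interval midpoints. Scaling supports z-score and min-max
with recorded per-column state for exact inversion; a zero-variance
column under z-score raises rather than emitting zeros, to surface
degenerate synthetic configurations early.

SMOTE is implemented directly (with sklearn's `NearestNeighbors` for the
neighbour search) because the balancer must record, for every synthetic
row, the parent pair and interpolation coefficient — bookkeeping the
tests use to verify that each synthetic point lies on its generating
segment. k defaults to 5 (the classical choice) and is clamped to the
minority size minus one. The default balancing target is the
`hairfall_problem` flag.

## Matching

Exact matching compares the configurable attribute list {age,
supplement_used, hereditary, protein_freq, iron_freq, omega_freq}; ties
break to the lowest row index. The clustered fallback runs Lloyd's
k-means from a seeded k-means++ initialisation (k defaults to
`ceil(sqrt(n/2))` capped at 10) on z-scored features, then finds the
closest record by Euclidean distance using the clustering as an
accelerator: clusters are visited in order of centroid distance and
pruned with the triangle inequality (`d(q, centroid) − radius > best`),
so the returned record is the exact global nearest neighbour. A
restrict-to-one-cluster search was considered and rejected: on
unstructured data it returns the true nearest neighbour for only ~2/3 of
queries, which is a poor foundation for downstream severity deltas.

## Severity rules

Deltas are absolute values — a drop in HFI is as anomalous as a rise; the
sign is kept in provenance. The operators deliberately mix strict and
inclusive comparisons (severe: ΔHFI > 1.5 **or** ΔRate > 2; mild:
ΔHFI > 0.8 **or** ΔRate ≥ 1) and the boundaries are unit-tested
explicitly. Two named profiles ship — "default" (1.5/0.8) and
"case-study" (1.0/0.5) — because the source material states both;
neither is endorsed. Forecast severity is the indicator `ŷ ≥ τ`
(inclusive at the threshold), default τ = 1.5.

## Recommendation

Per-nutrient deficit `max(0, (1 − ratio) × RDA_day)` is a reconstruction:
it has the right units (g/day, mg/day), is monotone decreasing in intake
and zero at full adherence. Lifestyle rules fire in fixed order (iron,
scalp, stress) with thresholds θ₁ = 0.8 (iron ratio floor), θ₂ = 0.5
(scalp score floor, applied to the EM-refined score when present),
θ₃ = 5.0 (stress score ceiling); all three are config-exposed defaults,
not clinically derived. The deficiency trajectory compares consecutive
NDS values: both ≤ 0 → none; crossing into positive → new; positive but
shrinking → improving; otherwise persistent.

## Forecasting

Architecture (hidden width H): each input variable (past target + dynamic
covariates) is embedded to H; a GRN over the window-averaged inputs
yields softmax variable-selection weights; the weighted embedding
sequence feeds an LSTM encoder whose initial state is a tanh embedding of
the static covariates; the decoder unrolls over the horizon with zero
input placeholders (future covariates are unknown in pure forecasting —
an explicit interpretation); single-head scaled dot-product attention
from decoder states over encoder states gives per-step contexts; the
output layer maps `[h̃; c]` to the forecast. `heads > 1` averages
per-head contexts behind a flag. The GRN's gate is a separate learned
projection; with all-zero weights the block reduces exactly to
LayerNorm(x). LayerNorm uses no learned affine terms, so its unit-moment
property is directly testable (ε = 1e-10).

Targets are normalised **per window**, anchored at the last observed
value and scaled by the global training standard deviation; covariates
are standardised globally. Window-relative anchoring is what lets the
model extrapolate trends (a globally standardised model cannot forecast
levels outside its training range) and makes the persistence baseline the
zero-output special case, which stabilises behaviour on near-random
series. Training uses Adam on the mean squared horizon loss with seeded
shuffled minibatches and optional dropout on the embedding sequence
(training only); everything is deterministic given the seed. Windows are
split by time: a window is a training example only if its entire forecast
span precedes the split point.

Defaults follow the published tuning (hidden 128, learning rate 3e-4,
heads 4 considered but 1 implemented as primary, dropout 0.1, batch 64,
window 30 days, horizon 14). The test suite and acceptance script run a
scaled-down configuration (hidden 8–24, 10–150 epochs, learning rate
3e-3, 60–200-day series) — small problems train better with the larger
step size, and the properties under test (normalisations, skill vs
persistence, determinism) are size-independent.

The autodiff tape supports exactly the operators the model needs
(broadcast arithmetic with gradient unbroadcasting, batched matmul,
sigmoid/tanh/ELU/exp, reductions, slicing/stack/concat, stable softmax);
gradients are verified against central finite differences at 1e-5
tolerance.

## Evaluation

Classification metrics follow the standard confusion-matrix definitions;
a zero denominator yields an explicit `None` rather than a silent 0, so
degenerate classifiers remain visible in comparison tables. Severity
labels binarise as anomaly = {mild, severe} by default; a strict mode
counts only severe. Regression metrics are MSE and `R² = 1 − SS_res/SS_tot`
(undefined for zero-variance truth). The comparison harness emits one
metrics row per model over a shared truth vector.

## Known limitations

- Synthetic cohorts have independent fields; correlation-sensitive
  behaviour (e.g. confounded stress/sleep effects on HFI) is untested
  against realistic dependence structures.
- The TFT is a small, single-target implementation: no quantile heads,
  no known-future covariates, no GPU path.
- RDA defaults cover a single adult age band; finer age banding must be
  supplied via the JSON table.
- Severity thresholds and lifestyle θ values are conventions to be
  calibrated per deployment, not clinical constants.
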