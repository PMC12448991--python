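# Methods note

This note records the models, parameter choices and numerical decisions baked
into the package. Every number quoted here is either a design constant, a
documented default, or computed by the test suite / `scripts/acceptance.py`;
no empirical claims beyond those computations are made.

## Stimulus design

Fifteen cubes in three subsets share one middle cube (750 cm³, 375 g,
0.5 g/cm³):

- **equal density** — volumes {550, 650, 700, 750, 800, 850, 950} cm³ at
  0.5 g/cm³, so weight scales with size;
- **equal weight** — volumes {550, 650, 750, 850, 950} cm³ all at exactly
  375 g (density ratios between pair members span ≈ 0.58–0.89), the
  size–weight-illusion subset;
- **increasing density** — the same five volumes with density increasing
  linearly in volume (slope 0.00045 g/cm³ per cm³ through the middle cube),
  so larger cubes are disproportionately heavier.

All C(15,2) = 105 unordered pairs are lifted. The 14 pairs containing the
shared middle cube appear three times, giving 91 + 42 = 133 base entries;
each is presented in both left/right orders for 266 trials per participant,
split evenly over two sessions. Trial order is shuffled per seed.

## Response generation (synthetic cohorts)

No human dataset ships with the package; cohorts are synthesised so that
every pipeline stage has known ground truth. Each observer produces, per
trial and per object, a magnitude estimate in scale units
(`grams / 7.5`, the reference anchor "50" = 375 g):

```
raw_units = scale_factor · (model_prediction + ε) / 7.5,   ε ~ N(0, noise_sd)
```

Defaults and rationale:

- `noise_sd = 25 g` — additive Gaussian response noise; large enough that
  recovery is a real statistical problem, small enough that a 30-observer
  cohort recovers the generating coefficients within 10–15 %.
- `scale_factor` — log-normal across observers, median 1, log-SD
  `scale_spread = 0.2`; emulates idiosyncratic use of the open magnitude
  scale (roughly ±20 % typical spread) and gives the multiplicative
  normalisation step real work to do.
- `outlier_rate = 0.004`, `outlier_magnitude = 8` (× noise SD) — rare gross
  errors (slips, misreadings) planted with a flag so removal sensitivity is
  measurable; the 0.4 % rate matches the order of magnitude the outlier
  pipeline is designed for.
- Per-observer RNG streams come from `SeedSequence([master_seed, index])`,
  so cohorts are reproducible and prefix-stable (adding observers never
  changes existing ones).

The generator can use the descriptive model, the cue-combination rule or an
efficient-coding ratio prior as ground truth. The synthetic data do **not**
emulate learning across sessions, trial-order effects, lifting dynamics or
any weight-dependent (Weber-like) noise scaling unless explicitly enabled.

## Preprocessing

1. **Grams transform** — estimates × 7.5.
2. **Multiplicative normalisation** — each participant's estimates are
   scaled by (pooled grand mean / participant grand mean), equalising
   participant means exactly (tested to 1e-9 g). The step is idempotent.
3. **Iterative outlier removal** — three passes at 5, 4 and 3.5 SDs. Each
   pass computes mean and SD (ddof = 1) per (pair, cube) cell over retained
   records, flags exceedances, and re-normalises before the next pass.
   Cells with fewer than 3 contributing participants are skipped with a
   warning. On default 30-observer cohorts this removes ≈ 0.3–0.5 % of
   estimates and catches ≥ 95 % of planted 8-SD outliers.

## Descriptive model fitting

The model is linear in (C, β₁…β₅) once σ is fixed, so fitting uses variable
projection: an inner ordinary-least-squares solve (`numpy.linalg.lstsq`)
profiled over a bounded scalar search for σ. σ is constrained to
[1, 1000] g; the multi-start loop (default 16 starts, log-spaced jittered
initial σ) makes the 1-D landscape search robust, and diagnostics flag fits
where σ lands on a bound. This is equivalent to full 7-parameter nonlinear
least squares at its optimum but is faster and immune to poor conditioning
between the linear coefficients. Restricted variants (component ladder,
cross-validation) reuse the same machinery with columns removed.

## Efficient-coding ratio model

The prior over (log volume ratio, log weight ratio) is a mixture of K
origin-centred bivariate Gaussians (default K = 3: 9 shape parameters + 2
free mixture weights + the bias scale C_b = 12 free parameters). For a pair
at log volume ratio v, the model renormalises the 1-D slice q(·) = p(· | v)
and predicts

```
bias(v, w) = C_b · d/dw [ 1 / q(w)² ],    variance(v, w) ∝ 1 / q(w)²
```

— percepts are repelled from high-prior-density regions, and discrimination
is best where density is high. Gradients are analytic (verified against
central finite differences to 1e-6). Numerical guards: slice densities are
floored at 1e-12 (points beyond the prior's effective support raise an
error for bias and cap-with-warning for variance); fitting uses multi-start
Levenberg–Marquardt with non-finite candidate parameter vectors rejected via
a large residual fill, and an early stop when the residual is below 1e-4 of
the field's total sum of squares. A single-object variant (free component
means over absolute log volume / log weight) scores one cube at a time.

## Competitor models

- **Sub-prior Bayesian mixture** — three ridge-shaped Gaussians over the
  ratio plane (slopes anchored near 1, −0.5 and 2.5: equal density, smaller
  is denser/heavier, smaller is much lighter) plus diagonal sensory noise;
  13 raw parameters. Posterior means and component evidences are closed-form
  (Gaussian conjugacy, analytic 2×2 inverses); predictions match a
  brute-force 2-D integration oracle to 1e-3.
- **Cue combination** — `ŵ = β₁wˣ + β₂dʸ` per object, pair context ignored
  by construction. (β₁, β₂) are profiled by least squares; only the
  exponents are optimised (Nelder–Mead over log exponents, multi-start).

Both are re-fitted to whatever data they must explain; no published
parameter values are hard-coded.

## Evaluation

The **bias field** is the shared derived dataset: one row per unique pair,
orientation fixed by the lexicographically smaller cube id, holding the true
log ratios, the mean bias in perceived log weight ratio and the per-trial
response variance. All models are scored against it so their errors are
commensurable. Model comparison ranks on leave-one-participant-out
cross-validation error when available, otherwise SSR. Variance structure is
summarised by OLS R² of response variance on |log weight ratio|, |log volume
ratio| and both (statsmodels).

## Problem sizes and runtimes

Defaults used by tests and scripts: 30 observers × 266 trials × 2 estimates
= 15 960 records for parameter recovery (fit ≈ seconds); 105-pair bias
fields for the ratio-space models; the cross-validated model-ordering check
uses 10 replicates of 10 observers with leave-one-participant-out folds
(≈ 5 minutes), and the full acceptance script runs in well under a minute.

## Limitations

- Synthetic ground truth only; the package reproduces structural and
  recovery claims, not empirical fit statistics on human data.
- The gate's σ search is bounded to [1, 1000] g; data generated far outside
  that range will pin σ to a bound (flagged in diagnostics).
- The ratio prior is origin-centred by design for paired data; asymmetric
  empirical fields are absorbed into correlations and C_b rather than
  component means (except in the single-object variant).
- Response variance pooling is per-trial across participants; alternative
  poolings (within participant first) are not implemented.
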