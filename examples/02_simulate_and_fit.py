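"""Simulate a cohort from the gated descriptive model and refit it.

Thirty synthetic observers each complete the 266-trial design.  Responses are
generated from the full descriptive model with its published coefficients
plus additive Gaussian noise (SD 25 g), passed through the standard
preprocessing (grams transform, multiplicative normalisation, iterative
outlier removal), and the model is refit from scratch.  Recovered values
should land within a few percent of the generating ones.
"""

from weightsense import descriptive, preprocess, synth
from weightsense.descriptive import PUBLISHED_COEFFICIENTS
from weightsense.stimuli import build_stimulus_set

cubes = build_stimulus_set()
observers = synth.make_observer_cohort(30, master_seed=1)
raw = synth.simulate_cohort(
    cubes, observers, synth.default_generating_model(), trial_seed=1
)
print(f"simulated {len(raw)} estimates from {len(observers)} observers")

processed, report = preprocess.preprocess(raw)
records = preprocess.retained(processed)
rep = report.to_dict()
print(f"outlier removal: {rep['total_removed']} estimates "
      f"({100 * rep['fraction_removed']:.2f}%) over passes {rep['thresholds']}")

coeffs, diag = descriptive.fit(records, cubes, n_starts=16, seed=1)
print(f"\nfit on {diag.n_records} records, R^2 = {diag.r2:.4f}\n")
print(f"{'':>8}  {'generating':>12}  {'recovered':>12}")
for name in ("beta1", "beta2", "beta3", "beta4", "beta5", "sigma"):
    gen = getattr(PUBLISHED_COEFFICIENTS, name)
    got = getattr(coeffs, name)
    print(f"{name:>8}  {gen:12.4g}  {got:12.4g}")
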