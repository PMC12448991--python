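"""Fit the efficient-coding ratio model to an empirical bias field.

The per-pair bias field (mean bias in perceived log weight ratio, per unique
pair) is built from a simulated cohort, then explained by a mixture-of-
Gaussians prior over (log volume ratio, log weight ratio): perceived ratios
are repelled from regions where the prior is dense, with bias proportional to
the slope of 1 / prior-slice-density squared.
"""

import numpy as np

from weightsense import effcoding, evaluate, preprocess, synth
from weightsense.stimuli import build_stimulus_set

cubes = build_stimulus_set()
observers = synth.make_observer_cohort(30, master_seed=2)
raw = synth.simulate_cohort(
    cubes, observers, synth.default_generating_model(), trial_seed=2
)
processed, _ = preprocess.preprocess(raw)
field = evaluate.build_bias_field(preprocess.retained(processed), cubes)
print(f"bias field: {len(field)} pairs, "
      f"mean |bias| = {field['bias'].abs().mean():.4f} log units")

prior, report = effcoding.fit_ratio_model(field, K=3, seed=0, n_starts=16)
print(f"\nK=3 prior, {report.n_free_parameters} free parameters, "
      f"R^2 = {report.r2:.3f} on {report.n_points} pairs")
for k, c in enumerate(prior.components, 1):
    print(f"  component {k}: sd_logV={c.sd_logV:.3f}  sd_logW={c.sd_logW:.3f}  "
          f"rho={c.correlation:+.3f}  weight={c.weight:.3f}")
print(f"  C_b = {prior.C_b:.4g}")

# the same prior predicts where responses are most variable
var = evaluate.variance_regressions(field)
print(f"\nresponse-variance regressions (R^2): "
      f"|logW| {var['r2_abs_logW']:.3f}, |logV| {var['r2_abs_logV']:.3f}, "
      f"both {var['r2_both']:.3f}")
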