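"""Compare the descriptive model with two published alternatives.

All three models are scored on the same response vector — the per-pair bias
in perceived log weight ratio — so their sums of squared residuals are
directly comparable.  On data generated by the gated descriptive model, the
single-object cue-combination rule and the three-ridge sub-prior Bayesian
model both underfit, because neither lets the other object's density act on
the judged object when the two weights are similar.
"""

import numpy as np

from weightsense import competitors, descriptive, evaluate, preprocess, synth
from weightsense.stimuli import build_stimulus_set

cubes = build_stimulus_set()
lookup = {c.cube_id: c for c in cubes}
observers = synth.make_observer_cohort(30, master_seed=3)
raw = synth.simulate_cohort(
    cubes, observers, synth.default_generating_model(), trial_seed=3
)
processed, _ = preprocess.preprocess(raw)
records = preprocess.retained(processed)
field = evaluate.build_bias_field(records, cubes)
obs = field["bias"].to_numpy()


def pair_bias(single_object_predict):
    out = []
    for row in field.itertuples():
        a, b = row.pair_id.split("|")
        out.append(
            np.log(single_object_predict(a, b) / single_object_predict(b, a))
            - row.logW_ratio
        )
    return np.asarray(out)


coeffs, _ = descriptive.fit(records, cubes, n_starts=16, seed=0)
pred_d = pair_bias(lambda a, b: descriptive.predict(lookup[a], lookup[b], coeffs))

cc, _ = competitors.fit_cue_combination(records, cubes, seed=0, n_starts=8)
pred_c = pair_bias(lambda a, b: competitors.cue_combination_predict(cc, lookup[a]))

sp, sp_report = competitors.fit_subprior_model(field, seed=0, n_starts=8)
pred_s = np.asarray(sp_report["predictions"])

reports = [
    evaluate.FitReport("descriptive", 7, float(np.sum((obs - pred_d) ** 2)),
                       evaluate.r_squared(obs, pred_d), pred_d, obs),
    evaluate.FitReport("cue_combination", 4, float(np.sum((obs - pred_c) ** 2)),
                       evaluate.r_squared(obs, pred_c), pred_c, obs),
    evaluate.FitReport("subprior", 13, float(np.sum((obs - pred_s) ** 2)),
                       evaluate.r_squared(obs, pred_s), pred_s, obs),
]
table = evaluate.compare_models(reports)
print("bias-field fit, 105 pairs (in-sample SSR ranking):\n")
print(table.to_string(index=False))
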