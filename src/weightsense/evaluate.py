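"""Shared metrics, bias-field construction and model comparison.

The bias field is the central derived dataset for the ratio-space models: one
row per unique stimulus pair, holding the pair's true log volume and log
weight ratios, the mean empirical bias in perceived log weight ratio, and the
across-trial variance of the per-trial log estimate ratios.  Orientation is
fixed by the pair id (object 1 = lexicographically smaller cube id); natural
logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FitReport",
    "r_squared",
    "build_bias_field",
    "variance_regressions",
    "compare_models",
]


@dataclass
class FitReport:
    """One model's fit on a shared response vector."""

    model_name: str
    n_params: int
    ssr: float
    r2: float
    predictions: np.ndarray
    observed: np.ndarray
    cv_error: float | None = None


def r_squared(observed, predicted) -> float:
    """Proportion of variance explained: 1 − SSR/SST."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(obs) < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed vector is constant; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def build_bias_field(records: pd.DataFrame, cubes) -> pd.DataFrame:
    """Per-pair empirical bias and variance of perceived log weight ratio.

    ``records`` must contain both objects' retained estimates per trial
    (columns participant_id, trial_index, pair_id, cube_id, normalised).
    For each trial the log ratio of the two estimates is taken with object 1
    the lexicographically smaller cube id; the pair's bias is the mean of
    these log ratios minus the true log weight ratio.  Pairs with fewer than
    two retained trials contribute no variance (NaN, flagged ``low_n``).
    """
    lookup = {c.cube_id: c for c in cubes}
    rows = []
    for pair_id, grp in records.groupby("pair_id", sort=True):
        id_a, id_b = pair_id.split("|")
        ca, cb = lookup[id_a], lookup[id_b]
        ratios = []
        for (_, _), trial in grp.groupby(["participant_id", "trial_index"], sort=False):
            est = dict(zip(trial["cube_id"], trial["normalised"]))
            if id_a in est and id_b in est and est[id_a] > 0 and est[id_b] > 0:
                ratios.append(np.log(est[id_a] / est[id_b]))
        if not ratios:
            continue
        ratios = np.asarray(ratios)
        true_logW = np.log(ca.weight / cb.weight)
        rows.append(
            {
                "pair_id": pair_id,
                "logV_ratio": np.log(ca.volume / cb.volume),
                "logW_ratio": true_logW,
                "bias": float(ratios.mean() - true_logW),
                "response_variance": float(np.var(ratios, ddof=1))
                if len(ratios) >= 2
                else float("nan"),
                "n_trials": len(ratios),
                "low_n": len(ratios) < 2,
            }
        )
    return pd.DataFrame.from_records(rows)


def variance_regressions(bias_field: pd.DataFrame) -> dict:
    """OLS R² of response variance on |logW ratio|, |logV ratio|, and both."""
    ok = bias_field["response_variance"].notna()
    if ok.sum() < 10:
        raise ValueError("need at least 10 pairs with defined response variance")
    y = bias_field.loc[ok, "response_variance"].to_numpy(dtype=float)
    aw = np.abs(bias_field.loc[ok, "logW_ratio"].to_numpy(dtype=float))
    av = np.abs(bias_field.loc[ok, "logV_ratio"].to_numpy(dtype=float))

    def ols_r2(X):
        model = sm.OLS(y, sm.add_constant(X)).fit()
        return float(model.rsquared)

    return {
        "r2_abs_logW": ols_r2(aw),
        "r2_abs_logV": ols_r2(av),
        "r2_both": ols_r2(np.column_stack([aw, av])),
        "n_pairs": int(ok.sum()),
    }


def compare_models(reports: list[FitReport]) -> pd.DataFrame:
    """Rank fitted models on a common response vector.

    Ranking uses cross-validation error when every report carries one,
    otherwise SSR.  Reports evaluated on different response vectors are
    rejected.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    ref = reports[0].observed
    for r in reports[1:]:
        if len(r.observed) != len(ref) or not np.allclose(r.observed, ref):
            raise ValueError(
                f"report {r.model_name!r} was evaluated on a different response vector"
            )
    table = pd.DataFrame(
        {
            "model": [r.model_name for r in reports],
            "n_params": [r.n_params for r in reports],
            "ssr": [r.ssr for r in reports],
            "r2": [r.r2 for r in reports],
            "cv_error": [r.cv_error for r in reports],
        }
    )
    key = "cv_error" if table["cv_error"].notna().all() else "ssr"
    table = table.sort_values(key, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
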