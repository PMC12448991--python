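"""Efficient-coding Bayesian models of weight-ratio perception.

Under efficient coding, sensory resources follow the stimulus prior p(θ):
frequent stimuli are encoded precisely, rare ones coarsely.  Combined with a
symmetric (L2) loss this skews likelihoods away from the prior peak and
produces *repulsive* biases, with magnitude proportional to the slope of the
squared reciprocal of the prior:

    b(θ0) = C_b * d/dθ [ 1 / p(θ)^2 ]  evaluated at θ0,

and response variability proportional to 1 / p(θ)^2 (discrimination threshold
∝ 1/p).

The ratio model places a mixture of K origin-centred bivariate Gaussians over
(log volume ratio, log weight ratio) of an object pair.  Volume ratios are
treated as noiselessly perceived, so predictions come from the 1-D conditional
slice of the prior at the true log volume ratio, renormalised to a proper
density (the bias constant C_b absorbs normalisation constants).

A single-object variant places the prior over (log volume, log weight) of
individual objects with free component means, reproducing the structure of
efficient-coding accounts of single-object heaviness biases; by construction
its predictions cannot depend on the other object in a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GaussComponent",
    "RatioPrior",
    "prior_density",
    "predict_bias",
    "predict_variance",
    "fit_ratio_model",
    "fit_single_object_model",
    "RatioFitReport",
]

DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class GaussComponent:
    """One bivariate Gaussian component over (logV, logW)."""

    sd_logV: float
    sd_logW: float
    correlation: float
    weight: float
    mean_logV: float = 0.0
    mean_logW: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd_logV > 0 and self.sd_logW > 0):
            raise ValueError("component SDs must be positive")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("mixture weight must lie in (0, 1]")


@dataclass(frozen=True)
class RatioPrior:
    """Mixture-of-Gaussians prior plus the repulsion-bias scale C_b.

    For the ratio model all component means are fixed at the origin; the
    single-object variant uses free means.  With K components the free
    parameter count is 3K (shapes) + (K − 1) (weights) + 1 (C_b): 12 for K=3.
    """

    components: tuple
    C_b: float
    density_floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if not self.density_floor > 0:
            raise ValueError("density_floor must be positive")

    @property
    def n_free_parameters(self) -> int:
        k = len(self.components)
        free_means = any(
            (c.mean_logV, c.mean_logW) != (0.0, 0.0) for c in self.components
        )
        return 3 * k + (k - 1) + 1 + (2 * k if free_means else 0)


def prior_density(prior: RatioPrior, logV, logW):
    """Mixture density at (logV, logW), floored at ``density_floor``."""
    logV, logW = np.broadcast_arrays(
        np.asarray(logV, dtype=float), np.asarray(logW, dtype=float)
    )
    dens = np.zeros(logV.shape)
    for c in prior.components:
        cov = np.array(
            [
                [c.sd_logV**2, c.correlation * c.sd_logV * c.sd_logW],
                [c.correlation * c.sd_logV * c.sd_logW, c.sd_logW**2],
            ]
        )
        pts = np.stack(
            [logV - c.mean_logV, logW - c.mean_logW], axis=-1
        )
        dens = dens + c.weight * stats.multivariate_normal(mean=[0, 0], cov=cov).pdf(pts)
    return np.maximum(dens, prior.density_floor)


def _slice_params(prior: RatioPrior, logV):
    """1-D conditional mixture p(logW | logV): weights, means, SDs.

    Component k conditions as a Gaussian with mean
    mu_k + rho_k (sd_W/sd_V) (logV − nu_k) and SD sd_W sqrt(1 − rho_k²);
    its slice weight is proportional to its marginal density at logV.
    Vectorised over ``logV``: returns arrays of shape (n, K), (n, K), (K,).
    """
    logV = np.atleast_1d(np.asarray(logV, dtype=float))
    w = np.array([c.weight for c in prior.components])
    nu = np.array([c.mean_logV for c in prior.components])
    mu0 = np.array([c.mean_logW for c in prior.components])
    sv = np.array([c.sd_logV for c in prior.components])
    sw = np.array([c.sd_logW for c in prior.components])
    rho = np.array([c.correlation for c in prior.components])
    dv = logV[:, None] - nu
    marg = np.exp(-0.5 * (dv / sv) ** 2) / (sv * np.sqrt(2 * np.pi))
    lam = w * marg
    total = lam.sum(axis=1)
    if np.any(total <= prior.density_floor):
        raise ValueError(
            "prior mass at some logV is at the density floor; stimulus lies "
            "outside the prior's support"
        )
    mu = mu0 + rho * (sw / sv) * dv
    sd = sw * np.sqrt(1.0 - rho**2)
    return lam / total[:, None], mu, sd


def _slice_density_and_grad(prior: RatioPrior, logV, logW):
    """q(logW | logV) and dq/dlogW, elementwise over paired arrays."""
    lam, mu, sd = _slice_params(prior, logV)
    logW = np.atleast_1d(np.asarray(logW, dtype=float))
    dev = logW[:, None] - mu
    comp = lam * np.exp(-0.5 * (dev / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    q = comp.sum(axis=1)
    dq = (comp * (-dev / sd**2)).sum(axis=1)
    return q, dq


def predict_bias(prior: RatioPrior, logV, logW_true):
    """Repulsion bias in log weight ratio at the true stimulus value.

    Evaluates C_b · d/dθ [1/q(θ)²] = −2 C_b q'(θ)/q(θ)³ on the renormalised
    conditional slice q = p(logW | logV).  Accepts scalars or paired arrays.
    """
    q, dq = _slice_density_and_grad(prior, logV, logW_true)
    scalar = np.isscalar(logW_true) or np.ndim(logW_true) == 0
    if np.any(q <= prior.density_floor):
        raise ValueError(
            "conditional slice density at the density floor; stimulus outside "
            "the prior's support"
        )
    bias = -2.0 * prior.C_b * dq / q**3
    return float(bias[0]) if scalar else bias


def predict_variance(
    prior: RatioPrior, logV: float, logW, variance_scale: float
) -> float:
    """Predicted response variance ∝ 1/q(θ)² on the conditional slice."""
    if not variance_scale > 0:
        raise ValueError("variance_scale must be positive")
    q, _ = _slice_density_and_grad(prior, logV, logW)
    scalar = np.isscalar(logW) or np.ndim(logW) == 0
    capped = q <= prior.density_floor
    if capped.any():
        warnings.warn("slice density at floor; variance capped", stacklevel=2)
        q = np.maximum(q, prior.density_floor)
    var = variance_scale / q**2
    return float(var[0]) if scalar else var


# ---------------------------------------------------------------------------
# fitting


@dataclass
class RatioFitReport:
    ssr: float
    r2: float
    n_points: int
    n_free_parameters: int
    n_starts: int
    variance_scale: float | None = None
    degenerate_components: list = field(default_factory=list)


def _pack_free(K: int, free_means: bool):
    """Number of raw optimiser parameters for K components."""
    return 3 * K + (K - 1) + 1 + (2 * K if free_means else 0)


def _unpack(theta: np.ndarray, K: int, free_means: bool) -> RatioPrior:
    """Raw vector -> RatioPrior.  log-SDs, atanh-correlations, weight logits."""
    i = 0
    comps = []
    raw = []
    for _ in range(K):
        sdv = float(np.exp(theta[i])); sdw = float(np.exp(theta[i + 1]))
        rho = float(np.tanh(theta[i + 2]))
        raw.append((sdv, sdw, rho))
        i += 3
    logits = np.concatenate([theta[i : i + K - 1], [0.0]])
    i += K - 1
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    C_b = float(theta[i]); i += 1
    means = [(0.0, 0.0)] * K
    if free_means:
        means = [(float(theta[i + 2 * k]), float(theta[i + 2 * k + 1])) for k in range(K)]
    for k in range(K):
        sdv, sdw, rho = raw[k]
        comps.append(
            GaussComponent(
                sd_logV=sdv, sd_logW=sdw, correlation=rho, weight=float(w[k]),
                mean_logV=means[k][0], mean_logW=means[k][1],
            )
        )
    return RatioPrior(components=tuple(comps), C_b=C_b)


def _bias_predictions(prior: RatioPrior, logV: np.ndarray, logW: np.ndarray):
    return np.asarray(predict_bias(prior, logV, logW))


def _fit_prior(
    logV: np.ndarray,
    logW: np.ndarray,
    bias: np.ndarray,
    K: int,
    seed: int,
    n_starts: int,
    free_means: bool,
):
    """Multi-start least squares over the raw parameter vector."""
    rng = np.random.default_rng(seed)
    span_v = max(np.abs(logV).max(), 0.1)
    span_w = max(np.abs(logW).max(), 0.1)
    n_par = _pack_free(K, free_means)

    def residuals(theta):
        with np.errstate(all="ignore"):
            try:
                prior = _unpack(theta, K, free_means)
                pred = _bias_predictions(prior, logV, logW)
            except (ValueError, FloatingPointError):
                return np.full(len(bias), 1e3)
            if not np.all(np.isfinite(pred)):
                return np.full(len(bias), 1e3)
            return pred - bias

    sst = float(np.sum((bias - bias.mean()) ** 2))
    # a start that already explains >99.99% of the variance cannot be beaten
    # meaningfully; stop early (keeps multi-start deterministic given seed)
    good_enough = 0.5 * max(sst, 1e-300) * 1e-4

    best = None
    for s in range(n_starts):
        theta0 = np.zeros(n_par)
        i = 0
        for _ in range(K):
            # SDs spanning the stimulus range, jittered
            theta0[i] = np.log(span_v * np.exp(rng.uniform(-1.0, 1.5)))
            theta0[i + 1] = np.log(span_w * np.exp(rng.uniform(-1.0, 1.5)))
            theta0[i + 2] = rng.uniform(-1.0, 1.0)
            i += 3
        theta0[i : i + K - 1] = rng.uniform(-0.5, 0.5, size=K - 1)
        i += K - 1
        scale0 = np.std(bias) if np.std(bias) > 0 else 1.0
        theta0[i] = scale0 * rng.uniform(0.05, 1.0) * (1 if s % 2 == 0 else -1)
        i += 1
        if free_means:
            theta0[i::2][: K] = rng.uniform(-span_v, span_v, size=K)
            theta0[i + 1 :: 2][: K] = rng.uniform(-span_w, span_w, size=K)
        try:
            res = optimize.least_squares(
                residuals, theta0, method="lm", max_nfev=4000
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= good_enough:
            break
    if best is None:
        raise RuntimeError("ratio-prior fit failed to converge from any start")
    return best


def fit_ratio_model(
    bias_field: pd.DataFrame,
    K: int = 3,
    seed: int = 0,
    n_starts: int = 16,
) -> tuple[RatioPrior, RatioFitReport]:
    """Fit the origin-centred mixture prior to an empirical bias field.

    ``bias_field`` needs columns logV_ratio, logW_ratio, bias (one row per
    unique pair).  Minimises the SSR between empirical and predicted biases
    over the 3K + (K−1) + 1 free parameters (12 for K=3).
    """
    if not 1 <= K <= 5:
        raise ValueError("K must lie in 1..5")
    logV = bias_field["logV_ratio"].to_numpy(dtype=float)
    logW = bias_field["logW_ratio"].to_numpy(dtype=float)
    bias = bias_field["bias"].to_numpy(dtype=float)
    best = _fit_prior(logV, logW, bias, K, seed, n_starts, free_means=False)
    prior = _unpack(best.x, K, free_means=False)
    pred = _bias_predictions(prior, logV, logW)
    ssr = float(np.sum((pred - bias) ** 2))
    sst = float(np.sum((bias - bias.mean()) ** 2))
    degenerate = [
        k
        for k, c in enumerate(prior.components)
        if min(c.sd_logV, c.sd_logW) < 1e-4 or max(c.sd_logV, c.sd_logW) > 1e3
    ]
    if degenerate:
        warnings.warn(f"degenerate prior components: {degenerate}", stacklevel=2)
    report = RatioFitReport(
        ssr=ssr,
        r2=1.0 - ssr / sst if sst > 0 else float("nan"),
        n_points=len(bias),
        n_free_parameters=prior.n_free_parameters,
        n_starts=n_starts,
        degenerate_components=degenerate,
    )
    return prior, report


def fit_variance_scale(
    prior: RatioPrior, bias_field: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Least-squares global scale mapping 1/q² to empirical response variance."""
    pred_shape = np.array(
        [
            predict_variance(prior, v, w, 1.0)
            for v, w in zip(bias_field["logV_ratio"], bias_field["logW_ratio"])
        ]
    )
    emp = bias_field["response_variance"].to_numpy(dtype=float)
    ok = np.isfinite(emp)
    scale = float(
        np.dot(pred_shape[ok], emp[ok]) / np.dot(pred_shape[ok], pred_shape[ok])
    )
    return scale, pd.Series(scale * pred_shape, index=bias_field.index)


def fit_single_object_model(
    records: pd.DataFrame,
    cubes,
    K: int = 1,
    seed: int = 0,
    n_starts: int = 16,
) -> tuple[RatioPrior, RatioFitReport]:
    """Efficient-coding model over single objects' (log volume, log weight).

    Empirical per-object bias is the mean over all retained records of
    log(normalised estimate) − log(true weight), one value per cube; the prior
    components have free means (absolute object space is not origin-centred).
    Predictions depend only on the judged object, never on its pair context.
    """
    lookup = {c.cube_id: c for c in cubes}
    per_cube = records.groupby("cube_id")["normalised"].apply(
        lambda v: float(np.mean(np.log(v)))
    )
    logV = np.array([np.log(lookup[c].volume) for c in per_cube.index])
    logW = np.array([np.log(lookup[c].weight) for c in per_cube.index])
    bias = per_cube.to_numpy() - logW
    best = _fit_prior(logV, logW, bias, K, seed, n_starts, free_means=True)
    prior = _unpack(best.x, K, free_means=True)
    pred = _bias_predictions(prior, logV, logW)
    ssr = float(np.sum((pred - bias) ** 2))
    sst = float(np.sum((bias - bias.mean()) ** 2))
    report = RatioFitReport(
        ssr=ssr,
        r2=1.0 - ssr / sst if sst > 0 else float("nan"),
        n_points=len(bias),
        n_free_parameters=prior.n_free_parameters,
        n_starts=n_starts,
    )
    return prior, report
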