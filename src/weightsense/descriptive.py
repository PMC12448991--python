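"""Descriptive model of perceived weight for object pairs.

The perceived weight of the judged object in a pair is modelled as

    w_hat_1 = C + b1*w1 + b2*d1 + b3*w2 + (b4*d1 + b5*d2) * N(|w1 - w2|; 0, s)

where (w1, d1) are the judged object's weight and density, (w2, d2) the other
object's, and N(.; 0, s) is the *normalised* Gaussian pdf with SD ``s``
evaluated at the absolute weight difference.  The Gaussian gate amplifies the
influence of both objects' densities when the two weights are similar — the
regime of classic size-weight-illusion stimuli.  Subtracting the two
within-pair predictions gives the difference form

    w_hat_1 - w_hat_2 = (b1-b3)(w1-w2) + b2(d1-d2) + (b4-b5)(d1-d2) N(|w1-w2|; 0, s)

which follows algebraically (the intercept and symmetric terms cancel).

Fitting minimises the summed squared residuals (SSR) over pooled, preprocessed
estimates.  For fixed gate SD the model is linear in (C, b1..b5), so the fit
profiles out the linear block by ordinary least squares and optimises only the
gate SD, with multiple seeded starts over its [1, 1000] g range.

``PUBLISHED_COEFFICIENTS`` carries the reported fit on the study's own data
(the intercept was not reported and is set to 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimuli import CubeSpec, StimulusPair

__all__ = [
    "DescriptiveCoefficients",
    "PUBLISHED_COEFFICIENTS",
    "ModelVariant",
    "VARIANTS",
    "ComponentLadder",
    "gate",
    "predict",
    "predict_difference",
    "design_matrix",
    "fit",
    "component_ladder",
    "loo_cv",
]

SIGMA_BOUNDS = (1.0, 1000.0)  # g; gate SD search range


@dataclass(frozen=True)
class DescriptiveCoefficients:
    """Coefficients of the descriptive model.

    Units: C grams; beta1, beta3 dimensionless; beta2 g per (g/cm^3);
    beta4, beta5 g^2 per (g/cm^3) (the gate pdf carries 1/g); sigma grams.
    """

    C: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C, self.beta1, self.beta2, self.beta3, self.beta4, self.beta5]
        )


#: coefficients reported for the human dataset (intercept unreported, set 0)
PUBLISHED_COEFFICIENTS = DescriptiveCoefficients(
    C=0.0, beta1=1.23, beta2=126.43, beta3=0.13, beta4=27814.0, beta5=-17919.0,
    sigma=76.44,
)


def gate(delta_w, sigma: float):
    """Normalised Gaussian pdf N(|dw|; 0, sigma) in 1/g. Even in ``delta_w``."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return stats.norm.pdf(np.abs(delta_w), loc=0.0, scale=sigma)


def predict(judged: CubeSpec, other: CubeSpec, coeffs: DescriptiveCoefficients) -> float:
    """Predicted perceived weight (g) of ``judged`` in the context of ``other``."""
    g = gate(judged.weight - other.weight, coeffs.sigma)
    return float(
        coeffs.C
        + coeffs.beta1 * judged.weight
        + coeffs.beta2 * judged.density
        + coeffs.beta3 * other.weight
        + (coeffs.beta4 * judged.density + coeffs.beta5 * other.density) * g
    )


def predict_difference(pair: StimulusPair, coeffs: DescriptiveCoefficients) -> float:
    """Predicted within-pair difference in perceived weight (a minus b), in g."""
    a, b = pair.cube_a, pair.cube_b
    g = gate(a.weight - b.weight, coeffs.sigma)
    return float(
        (coeffs.beta1 - coeffs.beta3) * (a.weight - b.weight)
        + coeffs.beta2 * (a.density - b.density)
        + (coeffs.beta4 - coeffs.beta5) * (a.density - b.density) * g
    )


# ---------------------------------------------------------------------------
# model variants (used by fit, the component ladder and cross-validation)

#: canonical component order, as in the model schematic; also the ladder
#: tie-break order
COMPONENTS = (
    "weight_judged",
    "density_judged",
    "weight_other",
    "gated_density_judged",
    "gated_density_other",
)


@dataclass(frozen=True)
class ModelVariant:
    """A restricted form of the descriptive model.

    ``components`` selects terms from :data:`COMPONENTS`; ``use_volume``
    substitutes each object's volume for its density in the selected terms.
    """

    name: str
    components: tuple
    use_volume: bool = False

    @property
    def has_gate(self) -> bool:
        return any(c.startswith("gated") for c in self.components)

    @property
    def n_params(self) -> int:
        return 1 + len(self.components) + (1 if self.has_gate else 0)


VARIANTS: dict[str, ModelVariant] = {
    "full": ModelVariant("full", COMPONENTS),
    "linear": ModelVariant("linear", COMPONENTS[:3]),
    "judged_only": ModelVariant("judged_only", ("weight_judged", "density_judged")),
    "volume_full": ModelVariant("volume_full", COMPONENTS, use_volume=True),
    "volume_linear": ModelVariant("volume_linear", COMPONENTS[:3], use_volume=True),
}


def _features(records: pd.DataFrame, cubes: list[CubeSpec]) -> pd.DataFrame:
    """Per-record physical features of the judged and other object."""
    lookup = {c.cube_id: c for c in cubes}
    missing = set(records["cube_id"]) | set(records["other_cube_id"])
    missing -= set(lookup)
    if missing:
        raise ValueError(f"records reference unknown cube ids: {sorted(missing)}")

    def col(ids, attr):
        return np.array([getattr(lookup[i], attr) for i in ids])

    out = pd.DataFrame(index=records.index)
    out["w1"] = col(records["cube_id"], "weight")
    out["d1"] = col(records["cube_id"], "density")
    out["v1"] = col(records["cube_id"], "volume")
    out["w2"] = col(records["other_cube_id"], "weight")
    out["d2"] = col(records["other_cube_id"], "density")
    out["v2"] = col(records["other_cube_id"], "volume")
    return out


def design_matrix(
    feats: pd.DataFrame, sigma: float, variant: ModelVariant = VARIANTS["full"]
) -> np.ndarray:
    """Columns: intercept followed by the variant's components at gate SD sigma."""
    g = gate(feats["w1"].to_numpy() - feats["w2"].to_numpy(), sigma)
    j = "v" if variant.use_volume else "d"
    term = {
        "weight_judged": feats["w1"].to_numpy(),
        "density_judged": feats[f"{j}1"].to_numpy(),
        "weight_other": feats["w2"].to_numpy(),
        "gated_density_judged": feats[f"{j}1"].to_numpy() * g,
        "gated_density_other": feats[f"{j}2"].to_numpy() * g,
    }
    cols = [np.ones(len(feats))] + [term[c] for c in variant.components]
    return np.column_stack(cols)


@dataclass
class FitDiagnostics:
    ssr: float
    r2: float
    n_records: int
    n_starts: int
    sigma_at_bound: bool
    per_start_sigma: list


def _profiled_ssr(sigma, X_builder, y):
    X = X_builder(sigma)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def _fit_variant(
    feats: pd.DataFrame,
    y: np.ndarray,
    variant: ModelVariant,
    n_starts: int,
    seed: int,
    sigma_init: float | None = None,
):
    """Profiled least squares: OLS in the linear block, multi-start over sigma.

    Returns (linear coefficients incl. intercept, sigma, ssr, diagnostics).
    For gate-free variants sigma is irrelevant and reported as NaN.
    """
    X_builder = lambda s: design_matrix(feats, s, variant)
    if not variant.has_gate:
        ssr, coef = _profiled_ssr(SIGMA_BOUNDS[0], X_builder, y)
        return coef, float("nan"), ssr, []

    rng = np.random.default_rng(seed)
    lo, hi = SIGMA_BOUNDS
    starts = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_starts))
    if sigma_init is not None:
        starts[0] = np.clip(sigma_init, lo, hi)
    best = None
    per_start = []
    for s0 in starts:
        res = optimize.minimize_scalar(
            lambda s: _profiled_ssr(s, X_builder, y)[0],
            bounds=(max(lo, s0 / 4.0), min(hi, s0 * 4.0)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        per_start.append(float(res.x))
        if best is None or res.fun < best.fun:
            best = res
    # polish over the full range around the winner
    res = optimize.minimize_scalar(
        lambda s: _profiled_ssr(s, X_builder, y)[0],
        bounds=(max(lo, best.x / 8.0), min(hi, best.x * 8.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if res.fun > best.fun:
        res = best
    ssr, coef = _profiled_ssr(res.x, X_builder, y)
    return coef, float(res.x), ssr, per_start


def _r2(y: np.ndarray, ssr: float) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ssr / sst


def fit(
    records: pd.DataFrame,
    cubes: list[CubeSpec],
    init: DescriptiveCoefficients | None = None,
    n_starts: int = 16,
    seed: int = 0,
    variant: ModelVariant = VARIANTS["full"],
) -> tuple[DescriptiveCoefficients, FitDiagnostics]:
    """Fit the descriptive model to preprocessed estimates by pooled SSR.

    ``records`` needs columns cube_id, other_cube_id and normalised (grams).
    Restricted variants return zero for excluded coefficients.
    """
    feats = _features(records, cubes)
    y = records["normalised"].to_numpy(dtype=float)
    coef, sig, ssr, per_start = _fit_variant(
        feats, y, variant, n_starts, seed,
        sigma_init=init.sigma if init is not None else None,
    )
    named = dict(zip(("C",) + variant.components, coef))
    beta = {
        "beta1": named.get("weight_judged", 0.0),
        "beta2": named.get("density_judged", 0.0),
        "beta3": named.get("weight_other", 0.0),
        "beta4": named.get("gated_density_judged", 0.0),
        "beta5": named.get("gated_density_other", 0.0),
    }
    sigma_out = sig if variant.has_gate else 1.0
    at_bound = variant.has_gate and (
        sig <= SIGMA_BOUNDS[0] * 1.001 or sig >= SIGMA_BOUNDS[1] * 0.999
    )
    if at_bound:
        warnings.warn(f"gate SD pinned to bound: sigma={sig:.3g} g", stacklevel=2)
    coeffs = DescriptiveCoefficients(C=named["C"], sigma=sigma_out, **beta)
    diag = FitDiagnostics(
        ssr=ssr, r2=_r2(y, ssr), n_records=len(y), n_starts=n_starts,
        sigma_at_bound=at_bound, per_start_sigma=per_start,
    )
    return coeffs, diag


# ---------------------------------------------------------------------------
# component ladder and cross-validation


@dataclass
class ComponentLadder:
    """Greedy forward-selection path over the five model components."""

    order: list
    r2: list
    ssr: list

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": self.order, "r2": self.r2, "ssr": self.ssr})


def component_ladder(
    records: pd.DataFrame,
    cubes: list[CubeSpec],
    seed: int = 0,
    n_starts: int = 8,
) -> ComponentLadder:
    """Add components one at a time, each step taking the largest R^2 gain.

    Starts from the intercept-only model and refits all active parameters at
    every step.  Ties are broken by the canonical component order, with a
    warning.
    """
    feats = _features(records, cubes)
    y = records["normalised"].to_numpy(dtype=float)
    active: list[str] = []
    order, r2s, ssrs = [], [], []
    remaining = list(COMPONENTS)
    while remaining:
        results = []
        for comp in remaining:
            var = ModelVariant("trial", tuple(active + [comp]))
            _, _, ssr, _ = _fit_variant(feats, y, var, n_starts, seed)
            results.append((comp, ssr))
        best_ssr = min(s for _, s in results)
        winners = [c for c, s in results if s <= best_ssr * (1 + 1e-12)]
        if len(winners) > 1:
            warnings.warn(
                f"component ladder tie between {winners}; using canonical order",
                stacklevel=2,
            )
        pick = min(winners, key=COMPONENTS.index)
        active.append(pick)
        remaining.remove(pick)
        order.append(pick)
        ssrs.append(best_ssr)
        r2s.append(_r2(y, best_ssr))
    return ComponentLadder(order=order, r2=r2s, ssr=ssrs)


def loo_cv(
    records: pd.DataFrame,
    cubes: list[CubeSpec],
    model_variants: list[ModelVariant] | None = None,
    seed: int = 0,
    n_starts: int = 8,
) -> pd.DataFrame:
    """Leave-one-participant-out cross-validation over model variants.

    Each fold fits on all-but-one participant and scores SSR on the held-out
    participant's normalised estimates; fold SSRs are summed.  Returns a table
    (variant, n_params, cv_ssr, converged) sorted by cv_ssr.
    """
    model_variants = model_variants or list(VARIANTS.values())
    participants = records["participant_id"].unique()
    if len(participants) < 3:
        raise ValueError("leave-one-out CV needs at least 3 participants")
    feats_all = _features(records, cubes)
    y_all = records["normalised"].to_numpy(dtype=float)
    rows = []
    for variant in model_variants:
        total = 0.0
        ok = True
        for p in participants:
            held = (records["participant_id"] == p).to_numpy()
            try:
                coef, sig, _, _ = _fit_variant(
                    feats_all[~held], y_all[~held], variant, n_starts, seed
                )
            except (np.linalg.LinAlgError, ValueError):
                ok = False
                break
            X_out = design_matrix(
                feats_all[held], sig if variant.has_gate else 1.0, variant
            )
            resid = y_all[held] - X_out @ coef
            total += float(resid @ resid)
        rows.append(
            {
                "variant": variant.name,
                "n_params": variant.n_params,
                "cv_ssr": total if ok else float("nan"),
                "converged": ok,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        "cv_ssr", na_position="last", kind="stable"
    ).reset_index(drop=True)
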