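"""Synthetic magnitude-estimation data with the study's statistical structure.

The generator forward-simulates a cohort of observers lifting cube pairs and
reporting each cube's weight in arbitrary units anchored to a reference cube
(375 g labelled "50", i.e. 7.5 g per unit).  Each observer has an idiosyncratic
multiplicative response scale, additive Gaussian response noise in grams, and a
small rate of gross outlier responses, emulating the features the preprocessing
pipeline is designed to remove.  Defaults mirror the study: 30 participants,
266 trials each, ~0.4% outliers.

Any of the package's perceptual models can act as the generating model, so
downstream fits can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import descriptive
from .stimuli import CubeSpec, build_trial_list, enumerate_pairs

__all__ = [
    "GRAMS_PER_UNIT",
    "ObserverProfile",
    "GeneratingModel",
    "make_observer_cohort",
    "simulate_session",
    "simulate_cohort",
]

#: reference cube: 375 g reported as "50" arbitrary units
GRAMS_PER_UNIT = 7.5


@dataclass(frozen=True)
class ObserverProfile:
    """Response idiosyncrasies of one simulated participant.

    ``scale_factor`` multiplies the internal estimate before report (unit-free);
    ``noise_sd`` is additive Gaussian response noise in grams; outliers displace
    a response by ±``outlier_magnitude`` × ``noise_sd`` grams with probability
    ``outlier_rate``.
    """

    participant_id: str
    scale_factor: float = 1.0
    noise_sd: float = 25.0
    outlier_rate: float = 0.004
    outlier_magnitude: float = 8.0
    seed: int = 0
    weber_noise: bool = False  # magnitude-proportional noise option

    def __post_init__(self) -> None:
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratingModel:
    """Which perceptual model produces the simulated internal estimates."""

    model_kind: str  # descriptive | cue_combination | effcoding_ratio
    parameters: object

    def __post_init__(self) -> None:
        kinds = {"descriptive", "cue_combination", "effcoding_ratio"}
        if self.model_kind not in kinds:
            raise ValueError(f"model_kind must be one of {sorted(kinds)}")


def default_generating_model() -> GeneratingModel:
    """Descriptive model with the published coefficients (intercept 0)."""
    return GeneratingModel("descriptive", descriptive.PUBLISHED_COEFFICIENTS)


def _derived_seed(master_seed: int, index: int) -> int:
    """Stable per-observer seed; adding observers never reshuffles earlier ones."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_observer_cohort(
    n: int,
    base: ObserverProfile | None = None,
    scale_spread: float = 0.2,
    master_seed: int = 0,
) -> list[ObserverProfile]:
    """Cohort of ``n`` observers with log-normal scale factors.

    scale_factor ~ LogNormal(log median = log(base.scale_factor),
    log-SD = ``scale_spread``); each observer gets a seed derived from
    ``master_seed`` and their index.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if scale_spread < 0:
        raise ValueError("scale_spread must be non-negative")
    base = base or ObserverProfile(participant_id="P")
    profiles = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), i, 1]))
        scale = float(base.scale_factor * np.exp(scale_spread * rng.standard_normal()))
        profiles.append(
            replace(
                base,
                participant_id=f"P{i + 1:02d}",
                scale_factor=scale,
                seed=_derived_seed(master_seed, i),
            )
        )
    return profiles


def _pair_predictions(
    model: GeneratingModel, judged: CubeSpec, other: CubeSpec
) -> float:
    """Model-predicted perceived weight of ``judged`` in grams."""
    if model.model_kind == "descriptive":
        return descriptive.predict(judged, other, model.parameters)
    if model.model_kind == "cue_combination":
        from . import competitors

        return competitors.cue_combination_predict(model.parameters, judged)
    # effcoding_ratio: bias the pair's true log weight ratio, preserve the
    # geometric-mean weight, and split the biased ratio over the two objects
    from . import effcoding

    prior = model.parameters
    logv = np.log(judged.volume / other.volume)
    logw = np.log(judged.weight / other.weight)
    bias = effcoding.predict_bias(prior, logv, logw)
    gm = np.sqrt(judged.weight * other.weight)
    return float(gm * np.exp((logw + bias) / 2.0))


def simulate_session(
    trials: pd.DataFrame,
    cubes: list[CubeSpec],
    observer: ObserverProfile,
    model: GeneratingModel | None = None,
) -> pd.DataFrame:
    """Simulate one observer's raw estimates for a trial list.

    Each trial yields two rows (one per cube): raw_units = scale_factor ×
    (prediction + noise) / GRAMS_PER_UNIT, with occasional outlier
    displacement.  Reproducible from ``observer.seed``.

    Columns: participant_id, session, trial_index, cube_id, other_cube_id,
    position, pair_id, raw_units, planted_outlier.
    """
    model = model or default_generating_model()
    lookup = {c.cube_id: c for c in cubes}
    unknown = (set(trials["left_cube"]) | set(trials["right_cube"])) - set(lookup)
    if unknown:
        raise ValueError(f"trial list references unknown cubes: {sorted(unknown)}")
    rng = np.random.default_rng(observer.seed)
    rows = []
    for t in trials.itertuples():
        for judged_id, other_id, position in (
            (t.left_cube, t.right_cube, "left"),
            (t.right_cube, t.left_cube, "right"),
        ):
            judged, other = lookup[judged_id], lookup[other_id]
            pred = _pair_predictions(model, judged, other)
            sd = observer.noise_sd
            if observer.weber_noise:
                sd = sd * pred / 375.0
            grams = pred + rng.normal(0.0, sd) if sd > 0 else pred
            outlier = bool(rng.random() < observer.outlier_rate)
            if outlier:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                grams += sign * observer.outlier_magnitude * observer.noise_sd
            rows.append(
                {
                    "participant_id": observer.participant_id,
                    "session": t.session,
                    "trial_index": t.trial_index,
                    "cube_id": judged_id,
                    "other_cube_id": other_id,
                    "position": position,
                    "pair_id": t.pair_id,
                    "raw_units": observer.scale_factor * grams / GRAMS_PER_UNIT,
                    "planted_outlier": outlier,
                }
            )
    return pd.DataFrame.from_records(rows)


def simulate_cohort(
    cubes: list[CubeSpec],
    observers: Iterable[ObserverProfile],
    model: GeneratingModel | None = None,
    trial_seed: int = 0,
) -> pd.DataFrame:
    """Simulate every observer on their own randomised 266-trial list."""
    pairs = enumerate_pairs(cubes)
    middle = [c for c in cubes if c.subset == "shared_middle"]
    middle_id = middle[0].cube_id if middle else cubes[0].cube_id
    frames = []
    for i, obs in enumerate(observers):
        trials = build_trial_list(
            pairs,
            middle_id=middle_id,
            seed=_derived_seed(trial_seed, i),
            participant_id=obs.participant_id,
        )
        frames.append(simulate_session(trials, cubes, obs, model))
    return pd.concat(frames, ignore_index=True)
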