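"""Shared fixtures: the default stimulus set and a reference synthetic cohort.

The expensive fixtures are session-scoped so that simulation and
preprocessing run once and are shared by the recovery, bias-field and
model-comparison tests.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import weightsense as ws

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from weightsense import descriptive, preprocess, synth


@pytest.fixture(scope="session")
def cubes():
    return ws.build_stimulus_set()


@pytest.fixture(scope="session")
def pairs(cubes):
    return ws.enumerate_pairs(cubes)


@pytest.fixture(scope="session")
def cube_lookup(cubes):
    return {c.cube_id: c for c in cubes}


@pytest.fixture(scope="session")
def cohort_raw(cubes):
    """30 observers x 266 trials simulated from the published descriptive
    coefficients (intercept 0), additive noise SD 25 g, fixed seed."""
    observers = synth.make_observer_cohort(30, master_seed=20240901)
    return synth.simulate_cohort(cubes, observers, trial_seed=20240901)


@pytest.fixture(scope="session")
def cohort_processed(cohort_raw):
    processed, report = preprocess.preprocess(cohort_raw)
    return preprocess.retained(processed), report


@pytest.fixture(scope="session")
def noiseless_records(cubes):
    """Zero-noise, unit-scale cohort of 5 observers: the exact-recovery limit."""
    base = synth.ObserverProfile(
        participant_id="P", noise_sd=0.0, outlier_rate=0.0, scale_factor=1.0
    )
    observers = synth.make_observer_cohort(5, base=base, scale_spread=0.0, master_seed=11)
    raw = synth.simulate_cohort(cubes, observers, trial_seed=11)
    processed, _ = preprocess.preprocess(raw)
    return preprocess.retained(processed)


def make_records(values, participants=None, pair="A|B", cube="A"):
    """Minimal estimate frame for preprocessing unit tests: one value per
    participant in a single condition cell."""
    n = len(values)
    participants = participants or [f"P{i:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": participants,
            "trial_index": np.arange(1, n + 1),
            "cube_id": cube,
            "other_cube_id": "B",
            "position": "left",
            "pair_id": pair,
            "raw_units": np.asarray(values, dtype=float),
        }
    )
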