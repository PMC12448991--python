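"""Shared metrics, bias-field construction and model comparison."""

import numpy as np
import pandas as pd
import pytest

from weightsense import descriptive, effcoding, synth
from weightsense.descriptive import DescriptiveCoefficients, PUBLISHED_COEFFICIENTS
from weightsense.evaluate import (
    FitReport,
    build_bias_field,
    compare_models,
    r_squared,
    variance_regressions,
)


class TestRSquared:
    def test_hand_computed_case(self):
        # SST = 2 around mean 2; SSR = 1 -> R^2 = 0.5
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_perfect_prediction(self):
        assert r_squared([1.0, 5.0, -2.0], [1.0, 5.0, -2.0]) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_matches_two_pass_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        obs = rng.normal(size=50)
        pred = obs + rng.normal(0, 0.3, size=50)
        ssr = sum((o - p) ** 2 for o, p in zip(obs, pred))
        sst = sum((o - obs.mean()) ** 2 for o in obs)
        assert r_squared(obs, pred) == pytest.approx(1 - ssr / sst, rel=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0, 3.0])


def _exact_cohort(cubes, coeffs, n_observers=3, seed=9):
    """Noise-free cohort generated from a descriptive model."""
    base = synth.ObserverProfile(participant_id="P", noise_sd=0.0, outlier_rate=0.0)
    observers = synth.make_observer_cohort(
        n_observers, base=base, scale_spread=0.0, master_seed=seed
    )
    raw = synth.simulate_cohort(
        cubes, observers, synth.GeneratingModel("descriptive", coeffs), trial_seed=seed
    )
    raw["normalised"] = raw["raw_units"] * synth.GRAMS_PER_UNIT
    return raw


class TestBuildBiasField:
    def test_veridical_observer_has_zero_bias(self, cubes):
        veridical = DescriptiveCoefficients(
            C=0.0, beta1=1.0, beta2=0.0, beta3=0.0, beta4=0.0, beta5=0.0, sigma=76.44
        )
        field = build_bias_field(_exact_cohort(cubes, veridical), cubes)
        assert len(field) == 105
        assert np.abs(field["bias"]).max() < 1e-12

    def test_swi_sign_under_published_model(self, cubes):
        # equal-weight pair: the smaller (denser) object is judged heavier, so
        # with object 1 the lexicographically smaller id W550 (the small cube)
        # the bias in log estimate ratio is positive
        field = build_bias_field(_exact_cohort(cubes, PUBLISHED_COEFFICIENTS), cubes)
        row = field.set_index("pair_id").loc["W550|W950"]
        assert row["logW_ratio"] == pytest.approx(0.0, abs=1e-12)
        assert row["bias"] > 0

    def test_orientation_fixed_by_pair_id(self, cubes):
        records = _exact_cohort(cubes, PUBLISHED_COEFFICIENTS)
        field = build_bias_field(records, cubes)
        lookup = {c.cube_id: c for c in cubes}
        for row in field.itertuples():
            a, b = row.pair_id.split("|")
            assert a < b
            assert row.logV_ratio == pytest.approx(
                np.log(lookup[a].volume / lookup[b].volume), rel=1e-12
            )

    def test_variance_nan_flagged_for_single_trial_pairs(self, cubes):
        lookup = {c.cube_id: c for c in cubes}
        a, b = cubes[0], cubes[1]
        records = pd.DataFrame(
            {
                "participant_id": ["P01"] * 2,
                "trial_index": [1, 1],
                "pair_id": ["|".join(sorted([a.cube_id, b.cube_id]))] * 2,
                "cube_id": [a.cube_id, b.cube_id],
                "normalised": [a.weight, b.weight],
            }
        )
        field = build_bias_field(records, cubes)
        assert len(field) == 1
        assert field["low_n"].iloc[0]
        assert np.isnan(field["response_variance"].iloc[0])

    def test_noisy_cohort_covers_all_pairs(self, cohort_processed, cubes):
        records, _ = cohort_processed
        field = build_bias_field(records, cubes)
        assert len(field) == 105
        assert (field["n_trials"] >= 30).all()
        assert not field["low_n"].any()


class TestVarianceRegressions:
    def test_affine_in_abs_logW_gives_unit_r2(self, cubes):
        from weightsense.stimuli import enumerate_pairs

        pairs = enumerate_pairs(cubes)
        logW = np.array([np.log(p.cube_a.weight / p.cube_b.weight) for p in pairs])
        logV = np.array([np.log(p.cube_a.volume / p.cube_b.volume) for p in pairs])
        field = pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in pairs],
                "logV_ratio": logV,
                "logW_ratio": logW,
                "response_variance": 0.01 + 0.05 * np.abs(logW),
            }
        )
        out = variance_regressions(field)
        assert out["r2_abs_logW"] == pytest.approx(1.0, abs=1e-10)
        assert out["r2_both"] == pytest.approx(1.0, abs=1e-10)
        assert out["r2_abs_logV"] < 1.0
        assert out["n_pairs"] == 105

    def test_isotropic_prior_variance_field_tracks_weight_ratio(self, cubes):
        # with an uncorrelated prior the renormalised slice is the same at
        # every logV, so predicted variance is a function of |logW| alone and
        # the |logW| regression dominates the |logV| one
        from weightsense.stimuli import enumerate_pairs

        prior = effcoding.RatioPrior(
            components=(effcoding.GaussComponent(0.6, 0.6, 0.0, 1.0),), C_b=0.005
        )
        pairs = enumerate_pairs(cubes)
        rows = []
        for p in pairs:
            lv = np.log(p.cube_a.volume / p.cube_b.volume)
            lw = np.log(p.cube_a.weight / p.cube_b.weight)
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "logV_ratio": lv,
                    "logW_ratio": lw,
                    "response_variance": effcoding.predict_variance(prior, lv, lw, 1e-3),
                }
            )
        field = pd.DataFrame.from_records(rows)
        out = variance_regressions(field)
        assert out["r2_abs_logW"] > out["r2_abs_logV"]
        # function of logW alone: the slice is identical at every logV
        for lv in (-0.5, 0.0, 0.4):
            assert effcoding.predict_variance(prior, lv, 0.3, 1e-3) == pytest.approx(
                effcoding.predict_variance(prior, 0.1, 0.3, 1e-3), rel=1e-12
            )

    def test_requires_enough_pairs(self):
        field = pd.DataFrame(
            {
                "logV_ratio": np.linspace(-1, 1, 5),
                "logW_ratio": np.linspace(-1, 1, 5),
                "response_variance": np.ones(5),
            }
        )
        with pytest.raises(ValueError, match="10"):
            variance_regressions(field)


class TestCompareModels:
    def _report(self, name, n_params, pred, obs, cv=None):
        ssr = float(np.sum((np.asarray(obs) - np.asarray(pred)) ** 2))
        return FitReport(
            model_name=name,
            n_params=n_params,
            ssr=ssr,
            r2=r_squared(obs, pred),
            predictions=np.asarray(pred, dtype=float),
            observed=np.asarray(obs, dtype=float),
            cv_error=cv,
        )

    def test_ranks_by_ssr_without_cv(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        good = self._report("good", 3, [1.1, 2.0, 2.9, 4.0], obs)
        bad = self._report("bad", 2, [2.0, 2.0, 2.0, 2.0], obs)
        table = compare_models([bad, good])
        assert list(table["model"]) == ["good", "bad"]
        assert list(table["rank"]) == [1, 2]

    def test_cv_error_overrides_in_sample_fit(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        overfit = self._report("overfit", 9, obs, obs, cv=5.0)
        honest = self._report("honest", 2, [1.1, 2.0, 2.9, 4.1], obs, cv=0.2)
        table = compare_models([overfit, honest])
        assert table["model"].iloc[0] == "honest"

    def test_mismatched_response_vectors_rejected(self):
        a = self._report("a", 1, [1.0, 2.0], [1.0, 2.0])
        b = self._report("b", 1, [1.0, 3.0], [1.0, 3.0])
        with pytest.raises(ValueError, match="different response"):
            compare_models([a, b])

    def test_single_report_rejected(self):
        a = self._report("a", 1, [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_models([a])
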