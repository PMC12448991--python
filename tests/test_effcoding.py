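"""Efficient-coding Bayesian ratio model: density, bias law, variance, fits."""

import numpy as np
import pandas as pd
import pytest

import weightsense as ws
from weightsense import effcoding as ec
from weightsense.effcoding import (
    GaussComponent,
    RatioPrior,
    fit_ratio_model,
    fit_single_object_model,
    predict_bias,
    predict_variance,
    prior_density,
)


@pytest.fixture(scope="module")
def mixture_prior():
    return RatioPrior(
        components=(
            GaussComponent(0.35, 0.45, 0.6, 0.5),
            GaussComponent(0.6, 0.3, -0.2, 0.3),
            GaussComponent(1.0, 1.0, 0.0, 0.2),
        ),
        C_b=0.005,
    )


@pytest.fixture(scope="module")
def pair_grid(pairs):
    logV = np.array([np.log(p.cube_a.volume / p.cube_b.volume) for p in pairs])
    logW = np.array([np.log(p.cube_a.weight / p.cube_b.weight) for p in pairs])
    return logV, logW, [p.pair_id for p in pairs]


class TestPriorDensity:
    def test_single_isotropic_component_peaks_at_origin(self):
        prior = RatioPrior((GaussComponent(0.5, 0.5, 0.0, 1.0),), C_b=1.0)
        centre = prior_density(prior, 0.0, 0.0)
        grid = np.linspace(-1, 1, 21)
        vals = prior_density(prior, grid[:, None], grid[None, :])
        assert centre == vals.max()

    def test_mixture_is_weighted_sum_of_components(self, mixture_prior):
        pt = (0.2, -0.3)
        total = prior_density(mixture_prior, *pt)
        parts = 0.0
        for c in mixture_prior.components:
            solo = RatioPrior(
                (GaussComponent(c.sd_logV, c.sd_logW, c.correlation, 1.0),), C_b=1.0
            )
            parts += c.weight * prior_density(solo, *pt)
        assert total == pytest.approx(float(parts), rel=1e-12)

    def test_integrates_to_one(self, mixture_prior):
        g = np.linspace(-8, 8, 801)
        dens = prior_density(mixture_prior, g[:, None], g[None, :])
        integral = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_origin_symmetry(self, mixture_prior):
        pts = np.random.default_rng(0).uniform(-1, 1, size=(20, 2))
        a = prior_density(mixture_prior, pts[:, 0], pts[:, 1])
        b = prior_density(mixture_prior, -pts[:, 0], -pts[:, 1])
        assert np.allclose(a, b, rtol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GaussComponent(-0.1, 0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            GaussComponent(0.5, 0.5, 1.5, 1.0)
        with pytest.raises(ValueError, match="sum to 1"):
            RatioPrior((GaussComponent(0.5, 0.5, 0.0, 0.5),), C_b=1.0)


class TestPredictBias:
    def test_single_gaussian_slice_matches_closed_form(self):
        # for a renormalised Gaussian slice q = N(0, s):
        # C_b d/dt [1/q^2] = C_b (2 pi s^2) (2 t / s^2) exp(t^2 / s^2)
        C_b, s = 0.01, 0.4
        prior = RatioPrior((GaussComponent(0.3, s, 0.0, 1.0),), C_b=C_b)
        for t in (0.05, 0.2, -0.35, 0.6):
            closed = C_b * (2 * np.pi * s**2) * (2 * t / s**2) * np.exp(t**2 / s**2)
            assert predict_bias(prior, 0.0, t) == pytest.approx(closed, rel=1e-6)

    def test_zero_at_slice_centre(self, mixture_prior):
        assert predict_bias(mixture_prior, 0.0, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_odd_under_joint_sign_flip(self, mixture_prior):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v, w = rng.uniform(-0.5, 0.5, size=2)
            assert predict_bias(mixture_prior, -v, -w) == pytest.approx(
                -predict_bias(mixture_prior, v, w), rel=1e-9, abs=1e-12
            )

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        h = 1e-5
        for _ in range(10):
            prior = RatioPrior(
                components=(
                    GaussComponent(
                        rng.uniform(0.2, 0.8),
                        rng.uniform(0.2, 0.8),
                        rng.uniform(-0.7, 0.7),
                        0.6,
                    ),
                    GaussComponent(
                        rng.uniform(0.2, 0.8),
                        rng.uniform(0.2, 0.8),
                        rng.uniform(-0.7, 0.7),
                        0.4,
                    ),
                ),
                C_b=rng.uniform(0.001, 0.05),
            )
            v, w = rng.uniform(-0.4, 0.4, size=2)

            def inv_q2(t):
                q, _ = ec._slice_density_and_grad(prior, v, t)
                return 1.0 / q[0] ** 2

            fd = prior.C_b * (inv_q2(w + h) - inv_q2(w - h)) / (2 * h)
            assert predict_bias(prior, v, w) == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_out_of_support_stimulus_rejected(self):
        prior = RatioPrior((GaussComponent(0.05, 0.05, 0.0, 1.0),), C_b=1.0)
        with pytest.raises(ValueError, match="support"):
            predict_bias(prior, 5.0, 0.0)


class TestPredictVariance:
    def test_reciprocal_square_law(self, mixture_prior):
        # variance scales as 1/q^2: quadruple scale -> quadruple variance,
        # and points with double the density have a quarter of the variance
        v = 0.1
        var1 = predict_variance(mixture_prior, v, 0.0, 1.0)
        var4 = predict_variance(mixture_prior, v, 0.0, 4.0)
        assert var4 == pytest.approx(4 * var1, rel=1e-12)
        q0, _ = ec._slice_density_and_grad(mixture_prior, v, 0.0)
        q1, _ = ec._slice_density_and_grad(mixture_prior, v, 0.5)
        ratio = (q0[0] / q1[0]) ** 2
        assert predict_variance(mixture_prior, v, 0.5, 1.0) == pytest.approx(
            ratio * var1, rel=1e-12
        )

    def test_gaussian_slice_minimum_at_centre(self):
        prior = RatioPrior((GaussComponent(0.3, 0.4, 0.0, 1.0),), C_b=1.0)
        grid = np.linspace(-1, 1, 41)
        var = predict_variance(prior, 0.0, grid, 1.0)
        assert np.argmin(var) == 20

    def test_invalid_scale_rejected(self, mixture_prior):
        with pytest.raises(ValueError):
            predict_variance(mixture_prior, 0.0, 0.0, 0.0)


class TestFitRatioModel:
    def test_k3_prior_has_12_free_parameters(self, mixture_prior):
        assert mixture_prior.n_free_parameters == 12

    def test_noiseless_self_consistency(self, pair_grid, mixture_prior):
        logV, logW, pids = pair_grid
        bias = predict_bias(mixture_prior, logV, logW)
        field = pd.DataFrame(
            {"pair_id": pids, "logV_ratio": logV, "logW_ratio": logW, "bias": bias}
        )
        prior, report = fit_ratio_model(field, K=3, seed=0, n_starts=16)
        assert report.n_free_parameters == 12
        assert report.r2 > 0.99

    def test_zero_bias_field_fits_to_zero(self, pair_grid):
        logV, logW, pids = pair_grid
        field = pd.DataFrame(
            {
                "pair_id": pids,
                "logV_ratio": logV,
                "logW_ratio": logW,
                "bias": np.zeros(len(pids)),
            }
        )
        prior, report = fit_ratio_model(field, K=1, seed=0, n_starts=4)
        pred = predict_bias(prior, logV, logW)
        assert report.ssr < 1e-10
        assert np.abs(pred).max() < 1e-5

    def test_invalid_k_rejected(self, pair_grid):
        logV, logW, pids = pair_grid
        field = pd.DataFrame(
            {"pair_id": pids, "logV_ratio": logV, "logW_ratio": logW, "bias": logW}
        )
        with pytest.raises(ValueError, match="K"):
            fit_ratio_model(field, K=9)


class TestSingleObjectModel:
    def test_recovers_planted_single_object_bias_field(self, cubes):
        # plant biases from a known single-object prior over (logV, logW),
        # synthesise exact estimates, refit, and check the bias field
        true = RatioPrior(
            components=(
                GaussComponent(
                    0.5, 0.6, 0.7, 1.0, mean_logV=np.log(750.0), mean_logW=np.log(360.0)
                ),
            ),
            C_b=0.002,
        )
        rows = []
        for c in cubes:
            b = predict_bias(true, np.log(c.volume), np.log(c.weight))
            for rep, p in enumerate(["P01", "P02", "P03"]):
                rows.append(
                    {
                        "participant_id": p,
                        "trial_index": rep + 1,
                        "cube_id": c.cube_id,
                        "normalised": c.weight * np.exp(b),
                    }
                )
        records = pd.DataFrame.from_records(rows)
        prior, report = fit_single_object_model(records, cubes, K=1, seed=0, n_starts=16)
        assert report.r2 > 0.95

    def test_prediction_ignores_pair_context(self, cubes):
        # the model scores one cube at a time: its predicted bias is a
        # function of (log volume, log weight) only, whatever the pair
        prior = RatioPrior(
            components=(
                GaussComponent(
                    0.5, 0.6, 0.5, 1.0, mean_logV=np.log(750.0), mean_logW=np.log(375.0)
                ),
            ),
            C_b=0.002,
        )
        c = cubes[3]
        b = predict_bias(prior, np.log(c.volume), np.log(c.weight))
        assert np.isscalar(b) or np.ndim(b) == 0
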