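import math

import numpy as np
import pandas as pd
import pytest

from avitrend.covariates import CovariateRaster
from avitrend.inference import MCMCConfig, PosteriorSamples
from avitrend.model import ModelSpec, u_from_scale
from avitrend.trends import (
    DensitySurface,
    classify_trend,
    classify_trend_from_summary,
    classify_trend_table,
    density_from_prediction,
    moving_window_mean,
    percent_change,
    phase_expectation,
    predict_density_map,
    published_trend_summary,
    scale_posterior_mode,
    training_quantile_bounds,
)


class TestPercentChange:
    def test_zero(self):
        assert percent_change(0.0) == 0.0

    def test_threshold_identity(self):
        assert percent_change(np.log(1.01)) == pytest.approx(1.0)

    def test_negative_closed_form(self):
        assert percent_change(-np.log(1.01)) == pytest.approx(100 * (1 / 1.01 - 1))


class TestClassifyTrend:
    def test_all_positive_draws(self):
        tc = classify_trend(np.full(500, 0.05))
        assert tc.pr_increase == 1.0
        assert tc.label == "increasing"

    def test_symmetric_small_draws_neither(self):
        draws = np.concatenate([np.full(250, 0.001), np.full(250, -0.001)])
        tc = classify_trend(draws)
        assert tc.pr_increase == 0.0 and tc.pr_decrease == 0.0
        assert tc.label == "neither"

    def test_cannot_be_both_increasing_and_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tc = classify_trend(rng.normal(0, 0.05, 300))
            assert not (tc.pr_increase >= 0.9 and tc.pr_decrease >= 0.9)

    def test_invariant_to_order_and_thinning(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.02, 0.01, 2000)
        a = classify_trend(draws)
        b = classify_trend(rng.permutation(draws))
        assert a.label == b.label and a.pr_increase == b.pr_increase
        c = classify_trend(draws[::4])
        assert abs(c.pr_increase - a.pr_increase) < 0.05

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            classify_trend(np.zeros(50))


class TestSummaryRule:
    def test_rule_against_published_table(self):
        t = published_trend_summary()
        out = classify_trend_table(t)
        q = out[out.label != "neither"]
        assert len(q) == 22
        assert (q.label == "increasing").sum() == 14
        assert (q.label == "decreasing").sum() == 8

    def test_boundary_inclusive(self):
        assert classify_trend_from_summary(0.05, 0.90) == "increasing"
        assert classify_trend_from_summary(-0.05, 0.90) == "decreasing"
        assert classify_trend_from_summary(0.05, 0.899) == "neither"

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            classify_trend_from_summary(0.0, 1.5)


class TestDensityConversion:
    def test_closed_form(self):
        assert density_from_prediction(1.0, 125.0) == pytest.approx(
            1 / (math.pi * 0.125**2), rel=1e-12
        )
        assert density_from_prediction(1.0, 125.0) == pytest.approx(20.37, abs=0.01)

    def test_inverse_square(self):
        d1 = density_from_prediction(3.0, 100.0)
        d2 = density_from_prediction(3.0, 200.0)
        assert d1 == pytest.approx(4 * d2)

    def test_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n, r = rng.uniform(0.1, 50), rng.uniform(50, 400)
            assert density_from_prediction(n, r) == pytest.approx(
                n / (math.pi * (r / 1000) ** 2), rel=1e-12
            )

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            density_from_prediction(1.0, 0.0)


def test_scale_posterior_mode_histogram():
    rng = np.random.default_rng(3)
    draws = np.concatenate([rng.normal(1500, 80, 900), rng.uniform(0, 3000, 100)])
    mode = scale_posterior_mode(draws)
    assert 1300 <= mode <= 1700


class TestPhaseExpectation:
    def test_sagebrush(self):
        assert phase_expectation(0.5, -0.3, 0.1) == "sagebrush"

    def test_early_successional(self):
        assert phase_expectation(0.5, 0.3, 0.1) == "early-successional PJ (Phase I-II)"

    def test_late_successional(self):
        assert phase_expectation(-0.2, 0.3, 0.1) == "late-successional PJ (Phase III)"
        assert phase_expectation(-0.1, 0.4, -0.2) == "late-successional PJ (Phase III)"

    def test_none(self):
        assert phase_expectation(-0.1, -0.2, 0.3) == "none"


def test_moving_window_mean_constant_field():
    r = CovariateRaster("c", 2020, np.full((40, 40), 3.5), 100.0, (0.0, 4000.0))
    out = moving_window_mean(r, 500.0)
    assert np.allclose(out, 3.5)


def test_moving_window_matches_buffer_mean_interior():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(50, 50))
    r = CovariateRaster("c", 2020, vals, 100.0, (0.0, 5000.0))
    out = moving_window_mean(r, 300.0)
    from avitrend.covariates import buffer_means

    # compare at an interior pixel center
    row, col = 25, 25
    cx, cy = (col + 0.5) * 100.0, 5000.0 - (row + 0.5) * 100.0
    expected = buffer_means(r, cx, cy, np.array([300.0]))[0]
    assert out[row, col] == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# prediction surface with a hand-built posterior


def make_samples(spec, radii, n_draws=200, seed=0, gamma_val=0.5, scale_m=500.0,
                 b0=0.2, a0=5.0):
    """Posterior container with known, nearly-degenerate draws."""
    rng = np.random.default_rng(seed)
    names = []
    names += [f"beta0[{b}]" for b in ["10"]] + ["mu[10]"]
    names += [f"gamma[{n}]" for n in spec.gamma_names]
    names += [f"scale_u[{n}]" for n in spec.scaled]
    names += ["alpha", "A_date", "A_date2", "tau0", "tau_exp", "tau_sun", "a0"]
    names += [f"spl[{k}]" for k in range(2)]
    names += ["log_omega"]
    theta = np.zeros((1, n_draws, len(names)))
    idx = {n: i for i, n in enumerate(names)}
    theta[:, :, idx["beta0[10]"]] = b0
    for n in spec.gamma_names:
        theta[:, :, idx[f"gamma[{n}]"]] = gamma_val + rng.normal(0, 0.01, n_draws)
    for n in spec.scaled:
        theta[:, :, idx[f"scale_u[{n}]"]] = u_from_scale(scale_m, radii)
    theta[:, :, idx["a0"]] = a0  # psi ~ 1
    mu_wish = np.zeros((1, n_draws, 2))
    mu_wish[:, :, 0] = b0
    return PosteriorSamples(
        names=names,
        theta=theta,
        eta=None,
        mu_wish=mu_wish,
        sigma_w=np.tile(np.eye(2), (1, n_draws, 1, 1)),
        seed=0,
        config=MCMCConfig(),
        scale_names=list(spec.scaled),
        radii=radii,
    )


@pytest.fixture()
def toy_prediction():
    from avitrend.abundance import tps_basis

    spec = ModelSpec(fixed=[], scaled=["c"], k_spline=3, include_survey_effect=False)
    radii = np.arange(0.0, 1100.0, 100.0)
    rng = np.random.default_rng(5)
    vals = np.linspace(-1, 1, 30)[None, :] * np.ones((30, 1))  # east-west gradient
    raster = CovariateRaster("c", 2020, vals.copy(), 100.0, (0.0, 3000.0))
    coords = rng.uniform(0, 3000, (40, 2))
    basis, _ = tps_basis(coords, k=3, seed=0)
    samples = make_samples(spec, radii)
    return spec, raster, basis, samples


def test_constant_covariates_give_constant_surface(toy_prediction):
    spec, raster, basis, samples = toy_prediction
    flat = CovariateRaster("c", 2020, np.zeros((20, 20)), 100.0, (0.0, 2000.0))
    surf = predict_density_map(
        samples, basis, {"c": flat}, spec, maxd=125.0,
    )
    vals = surf.density[np.isfinite(surf.density)]
    expected = density_from_prediction(np.exp(0.2), 125.0)
    assert np.allclose(vals, expected, rtol=0.05)


def test_pixels_match_bruteforce_posterior_loop(toy_prediction):
    spec, raster, basis, samples = toy_prediction
    surf = predict_density_map(samples, basis, {"c": raster}, spec, maxd=125.0)
    mode = scale_posterior_mode(samples.extract("scale[c]"))
    smoothed = moving_window_mean(raster, mode)
    x, y = raster.pixel_centers()
    idx = {n: i for i, n in enumerate(samples.names)}
    theta = samples.theta[0]
    from scipy.special import expit

    rng = np.random.default_rng(6)
    for _ in range(8):
        row, col = rng.integers(3, 27, 2)
        Z = basis.design(np.array([[x[col], y[row]]]))
        eta = (
            samples.mu_wish[0, :, 0]
            + theta[:, idx["gamma[c]"]] * smoothed[row, col]
        )
        psi = expit(theta[:, idx["a0"]] + (Z @ theta[:, [idx["spl[0]"], idx["spl[1]"]]].T)[0])
        expected = density_from_prediction(np.median(psi * np.exp(eta)), 125.0)
        got = surf.density[row, col]
        assert got == pytest.approx(expected, rel=1e-8)


def test_qa_mask_flags_out_of_range_pixels(toy_prediction):
    spec, raster, basis, samples = toy_prediction
    tq = {"c": (-0.5, 0.5)}  # gradient spans [-1, 1]: tails must be masked
    surf = predict_density_map(
        samples, basis, {"c": raster}, spec, maxd=125.0, training_quantiles=tq,
    )
    assert surf.qa_mask[15, 1] == 1
    assert surf.qa_mask[15, 15] == 0
    assert np.isnan(surf.density[15, 1])


def test_density_monotone_in_positive_coefficient(toy_prediction):
    spec, raster, basis, samples = toy_prediction
    surf = predict_density_map(samples, basis, {"c": raster}, spec, maxd=125.0)
    row = surf.density[15]
    ok = np.isfinite(row)
    assert np.all(np.diff(row[ok]) > -1e-9)


def test_missing_raster_errors(toy_prediction):
    spec, raster, basis, samples = toy_prediction
    with pytest.raises(ValueError, match="missing covariate raster"):
        predict_density_map(samples, basis, {}, spec, maxd=125.0)


def test_training_quantile_bounds():
    v = np.arange(1000.0)
    lo, hi = training_quantile_bounds(v)
    assert lo == pytest.approx(np.quantile(v, 0.025))
    assert hi == pytest.approx(np.quantile(v, 0.975))
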