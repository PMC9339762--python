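"""Grouped log-log OLS: closed-form equivalence, recovery, confidence bands."""

import math

import numpy as np
import pytest
from scipy import stats

from ecodemand import (
    DensityObservation,
    SyntheticSpec,
    ValidationError,
    confidence_band,
    fit_loglog,
    generate_density_dataset,
    to_standard_form,
)
from ecodemand.catalogue import BiologicalClass, Resource, TrophicLevel
from conftest import slope_recovery_replicates


def closed_form_ols(x, y):
    """Independent textbook OLS via two-pass sums: the oracle the module's
    statsmodels-backed fit must agree with."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / n + xbar ** 2 / sxx))
    syy = ((y - ybar) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / syy
    return slope, intercept, se_slope, se_intercept, math.sqrt(s2), r2


def make_observations(log_masses, log_densities, taxon_class="mammal",
                      trophic="carnivore"):
    return [
        DensityObservation(species_name=f"sp{i}", taxon_class=taxon_class,
                           trophic=trophic, mass_kg=10.0 ** lm,
                           density_per_km2=10.0 ** ld)
        for i, (lm, ld) in enumerate(zip(log_masses, log_densities))
    ]


def test_noiseless_collinear_recovery():
    """Points exactly on log10 rho = -1.018 log10 M + log10 2.74 come back
    with the generating line and vanishing standard errors."""
    lm = np.linspace(-2, 3, 10)
    ld = -1.018 * lm + math.log10(2.74)
    fits, failures = fit_loglog(make_observations(lm, ld))
    assert not failures
    (fit,) = fits.values()
    assert fit.slope_b == pytest.approx(-1.018, abs=1e-12)
    assert fit.intercept_log10_a == pytest.approx(math.log10(2.74), abs=1e-12)
    assert fit.se_b < 1e-10 and fit.se_intercept < 1e-10
    assert fit.n_points == 10


def test_matches_closed_form_ols():
    rng = np.random.default_rng(7)
    lm = rng.uniform(-2, 3, 200)
    ld = -0.9 * lm + 1.2 + rng.normal(0, 0.5, 200)
    fits, _ = fit_loglog(make_observations(lm, ld))
    (fit,) = fits.values()
    slope, intercept, se_b, se_a, resid_sd, r2 = closed_form_ols(lm, ld)
    assert fit.slope_b == pytest.approx(slope, rel=1e-8)
    assert fit.intercept_log10_a == pytest.approx(intercept, rel=1e-8)
    assert fit.se_b == pytest.approx(se_b, rel=1e-8)
    assert fit.se_intercept == pytest.approx(se_a, rel=1e-8)
    assert fit.residual_sd == pytest.approx(resid_sd, rel=1e-8)
    assert fit.r_squared == pytest.approx(r2, rel=1e-8)


def test_scale_equivariance():
    """Multiplying all densities by 10 shifts the intercept by exactly +1
    and leaves slope, SEs and R^2 unchanged."""
    rng = np.random.default_rng(11)
    lm = rng.uniform(-2, 3, 150)
    ld = -0.7 * lm + 0.4 + rng.normal(0, 0.3, 150)
    (fit,) = fit_loglog(make_observations(lm, ld))[0].values()
    (fit10,) = fit_loglog(make_observations(lm, ld + 1.0))[0].values()
    assert fit10.intercept_log10_a == pytest.approx(
        fit.intercept_log10_a + 1.0, abs=1e-10)
    assert fit10.slope_b == pytest.approx(fit.slope_b, abs=1e-12)
    assert fit10.se_b == pytest.approx(fit.se_b, rel=1e-10)
    assert fit10.se_intercept == pytest.approx(fit.se_intercept, rel=1e-10)
    assert fit10.r_squared == pytest.approx(fit.r_squared, rel=1e-10)


def test_default_grouping_pools_reptiles_and_insects():
    rng = np.random.default_rng(3)
    obs = []
    for trophic in ("herbivore", "carnivore"):
        lm = rng.uniform(-2, 1, 20)
        obs += make_observations(lm, -0.6 * lm + 2.0, "reptile", trophic)
        lm = rng.uniform(-2, 1, 20)
        obs += make_observations(lm, -0.9 * lm + 1.0, "mammal", trophic)
    fits, failures = fit_loglog(obs)
    assert not failures
    keys = set(fits)
    assert (BiologicalClass.REPTILE, TrophicLevel.ALL) in keys
    assert (BiologicalClass.MAMMAL, TrophicLevel.HERBIVORE) in keys
    assert (BiologicalClass.MAMMAL, TrophicLevel.CARNIVORE) in keys
    assert fits[(BiologicalClass.REPTILE, TrophicLevel.ALL)].n_points == 40


def test_small_or_degenerate_groups_fail_without_aborting_others():
    lm = np.linspace(-1, 2, 12)
    good = make_observations(lm, -1.0 * lm + 0.5, "mammal", "herbivore")
    tiny = make_observations([0.0, 1.0], [0.5, -0.5], "bird", "carnivore")
    flat = make_observations([1.0] * 5, np.linspace(0, 1, 5),
                             "mammal", "omnivore")
    fits, failures = fit_loglog(good + tiny + flat)
    assert (BiologicalClass.MAMMAL, TrophicLevel.HERBIVORE) in fits
    assert "insufficient observations" in failures[
        (BiologicalClass.BIRD, TrophicLevel.CARNIVORE)]
    assert "unidentifiable" in failures[
        (BiologicalClass.MAMMAL, TrophicLevel.OMNIVORE)]


def test_to_standard_form_and_round_trip():
    lm = np.linspace(-2, 3, 10)
    ld = -1.018 * lm + math.log10(2.74)
    (fit,) = fit_loglog(make_observations(lm, ld))[0].values()
    model = to_standard_form(fit)
    assert model.resource is Resource.LAND_DENSITY
    assert model.coefficient_a == pytest.approx(2.74, rel=1e-12)
    assert model.exponent_b == pytest.approx(-1.018, abs=1e-12)
    # round trip: log-transform of the standard form recovers the fit
    assert math.log10(model.coefficient_a) == pytest.approx(
        fit.intercept_log10_a, abs=1e-12)
    assert model.se_log10_a == fit.se_intercept
    assert model.se_b == fit.se_b


def test_confidence_band_closed_form_at_centroid_and_shape():
    rng = np.random.default_rng(5)
    lm = rng.uniform(-2, 3, 80)
    ld = -0.8 * lm + 1.0 + rng.normal(0, 0.4, 80)
    (fit,) = fit_loglog(make_observations(lm, ld))[0].values()
    centre_mass = 10.0 ** fit.mean_log10_mass
    band = confidence_band(fit, [centre_mass], level=0.95)
    half = (band[0, 1] - band[0, 0]) / 2.0
    tq = stats.t.ppf(0.975, fit.n_points - 2)
    assert half == pytest.approx(tq * fit.residual_sd
                                 / math.sqrt(fit.n_points), rel=1e-10)
    # hyperbolic shape: width non-decreasing away from the centroid
    grid = np.geomspace(1e-3, 1e4, 60)
    widths = np.diff(confidence_band(fit, grid), axis=1).ravel()
    centre_idx = np.argmin(np.abs(np.log10(grid) - fit.mean_log10_mass))
    assert np.all(np.diff(widths[centre_idx:]) >= -1e-12)
    assert np.all(np.diff(widths[:centre_idx + 1]) <= 1e-12)
    assert confidence_band(fit, []).shape == (0, 2)


def test_band_contains_true_line_on_synthetic_fit():
    spec = SyntheticSpec(true_slope=-0.9, true_log10_a=1.2, noise_sd_log10=0.5,
                         n_points=500, seed=42)
    (fit,) = fit_loglog(generate_density_dataset(spec))[0].values()
    grid = np.geomspace(10 ** -2, 10 ** 3, 101)
    band = confidence_band(fit, grid, level=0.95)
    truth = spec.true_log10_a + spec.true_slope * np.log10(grid)
    inside = (band[:, 0] <= truth) & (truth <= band[:, 1])
    assert inside.mean() >= 0.90


def test_synthetic_estimate_within_three_se_of_truth():
    spec = SyntheticSpec(true_slope=-0.9, true_log10_a=1.2, noise_sd_log10=0.5,
                         n_points=500, seed=99)
    (fit,) = fit_loglog(generate_density_dataset(spec))[0].values()
    assert abs(fit.slope_b - spec.true_slope) <= 3 * fit.se_b
    assert abs(fit.intercept_log10_a - spec.true_log10_a) <= 3 * fit.se_intercept


def test_monte_carlo_recovery_and_coverage():
    """Over 200 replicates at n=500, the slope estimator is nearly unbiased
    and its 95% t-interval covers the truth at a rate statistically
    consistent with nominal (exact central 99% binomial region for 200
    trials at p=0.95: [0.905, 0.985])."""
    slopes, ses = slope_recovery_replicates()
    bias = slopes.mean() - (-0.9)
    assert abs(bias) < 0.02
    tq = stats.t.ppf(0.975, 500 - 2)
    covered = np.abs(slopes - (-0.9)) <= tq * ses
    assert 0.905 <= covered.mean() <= 0.985


def test_invalid_inputs_rejected():
    with pytest.raises(ValidationError):
        fit_loglog([])
    with pytest.raises(ValidationError):
        fit_loglog([DensityObservation("x", "mammal", "herbivore", 1.0, 1.0)],
                   grouping="bogus")
    with pytest.raises(ValidationError):
        DensityObservation("x", "mammal", "herbivore", -1.0, 1.0)
    lm = np.linspace(-1, 1, 5)
    (fit,) = fit_loglog(make_observations(lm, -lm))[0].values()
    with pytest.raises(ValidationError):
        confidence_band(fit, [1.0], level=1.5)
    with pytest.raises(ValidationError):
        confidence_band(fit, [-1.0])
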