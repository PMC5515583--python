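import numpy as np
import pytest
from scipy.integrate import quad

import wincoal as wc
from wincoal.distributions import (
    GammaMixture,
    PiecewiseExponential,
    distribution_functions,
    fit_gamma_mixture,
    fit_piecewise_exponential,
    laplace_derivative,
    select_z_star,
)
from wincoal.richards import LaplaceCurve


def quad_laplace(dist, z):
    """Adaptive-quadrature oracle for E[exp(-z*t)], split at knots and scales."""
    scale = dist.mean()
    pts = set(np.geomspace(scale * 1e-8, scale * 1e4, 25))
    if hasattr(dist, "times"):
        pts.update(dist.times[1:])
    if z > 0:
        pts.update(np.geomspace(1e-3 / z, 1e2 / z, 10))
    pts = sorted(p for p in pts if p > 0)
    total, lo = 0.0, 0.0
    for hi in pts:
        v, _ = quad(lambda t: np.exp(-z * t) * dist.pdf(t), lo, hi, limit=200)
        total += v
        lo = hi
    v, _ = quad(lambda t: np.exp(-z * t) * dist.pdf(t), lo, np.inf, limit=200)
    return total + v


def exp_curve(theta, J, sigma=1e-4, zspan=(10, 1e5)):
    z = np.geomspace(*zspan, J)
    return LaplaceCurve(z=z, values=1.0 / (1.0 + theta * z), sigma=np.full(J, sigma), pi_hat=theta)


# ---------------------------------------------------------------- closed forms


def test_gamma_single_component_closed_form():
    gm = GammaMixture(weights=[1.0], shapes=[1.0], scales=[0.01])
    z = np.array([0.0, 10.0, 1e3])
    assert np.allclose(gm.laplace(z), 1.0 / (1.0 + 0.01 * z))


def test_piecewise_single_rate_closed_form():
    pe = PiecewiseExponential(times=[0.0], rates=[250.0])
    z = np.array([0.0, 10.0, 1e4])
    assert np.allclose(pe.laplace(z), 1.0 / (1.0 + z / 250.0))


@pytest.mark.parametrize("z", [0.0, 1.0, 37.0, 1e4])
def test_quadrature_oracle_agreement(z):
    gm = GammaMixture(weights=[0.4, 0.6], shapes=[0.8, 3.0], scales=[0.002, 0.03])
    pe = PiecewiseExponential(times=[0.0, 1e-3, 8e-3], rates=[400.0, 120.0, 800.0])
    assert float(gm.laplace(z)) == pytest.approx(quad_laplace(gm, z), abs=1e-8)
    assert float(pe.laplace(z)) == pytest.approx(quad_laplace(pe, z), abs=1e-8)


def test_complete_monotonicity():
    """Transforms of nonnegative variables are nonincreasing and convex in z."""
    rng = np.random.default_rng(2)
    z = np.geomspace(1e-2, 1e5, 60)
    for _ in range(10):
        gm = GammaMixture(
            weights=rng.dirichlet([1, 1]), shapes=rng.uniform(0.5, 5, 2),
            scales=rng.uniform(1e-4, 0.1, 2),
        )
        v = gm.laplace(z)
        assert np.all(np.diff(v) <= 1e-14)
        assert np.all(np.diff(np.diff(v) / np.diff(z)) >= -1e-12)


def test_laplace_derivative_matches_mean():
    gm = GammaMixture(weights=[0.5, 0.5], shapes=[1.0, 2.0], scales=[0.01, 0.002])
    assert -laplace_derivative(gm, 0.0) == pytest.approx(gm.mean(), rel=1e-10)
    pe = PiecewiseExponential(times=[0.0, 5e-3], rates=[100.0, 300.0])
    assert -laplace_derivative(pe, 0.0) == pytest.approx(pe.mean(), rel=1e-10)


# ------------------------------------------------------------------- fitting


def test_gamma_fit_recovers_exponential():
    curve = exp_curve(theta=1e-3, J=8)
    gm = fit_gamma_mixture(curve, restarts=20, seed=0)
    assert gm.n_components == 3  # floor((J+1)/3)
    model = gm.laplace(curve.z)
    assert np.all(np.abs(model - curve.values) <= 3 * curve.sigma)


def test_gamma_fit_point_mass_recovery():
    z = np.geomspace(10, 1e5, 10)
    w0 = 0.3
    vals = w0 + (1 - w0) / (1 + 1e-3 * z)
    curve = LaplaceCurve(z=z, values=vals, sigma=np.full(10, 1e-4), pi_hat=1e-3)
    gm = fit_gamma_mixture(curve, allow_point_mass=True, restarts=30, seed=1)
    assert gm.w0 == pytest.approx(w0, abs=0.05)


def test_gamma_fit_perfect_curve_zero_residual():
    curve = exp_curve(theta=1e-3, J=8)
    gm = fit_gamma_mixture(curve, restarts=20, seed=0)
    assert gm.scaled_error < 1.0


def test_piecewise_fit_constant_rate_recovery():
    theta = 1e-3
    curve = exp_curve(theta, J=12)
    pe = fit_piecewise_exponential(curve, seed=0)
    logc = np.log(pe.rates)
    assert np.std(logc) < 0.2  # near-constant hazard
    assert np.median(pe.rates) == pytest.approx(1 / theta, rel=0.15)


def test_piecewise_knot_placement_rule():
    # value 0.95 at z* = 1e2 with z_J = 1e5: knots span [5e-6, 1e-2]
    theta = (1 / 0.95 - 1) / 1e2
    z = np.geomspace(1e2, 1e5, 10)
    curve = LaplaceCurve(z=z, values=1 / (1 + theta * z), sigma=np.full(10, 1e-4), pi_hat=theta)
    assert select_z_star(curve) == pytest.approx(1e2)
    pe = fit_piecewise_exponential(curve, seed=0)
    assert pe.times[0] == 0.0
    assert pe.times[1] == pytest.approx(5e-6, rel=1e-9)
    assert pe.times[-1] == pytest.approx(1e-2, rel=1e-9)


def test_penalty_weight_smooths_rates():
    rng = np.random.default_rng(4)
    z = np.geomspace(10, 1e5, 14)
    vals = 1 / (1 + 1e-3 * z) * (1 + rng.normal(0, 0.01, 14))
    vals = np.minimum.accumulate(np.clip(vals, 0, 1))
    curve = LaplaceCurve(z=z, values=vals, sigma=np.full(14, 5e-3), pi_hat=1e-3)
    spreads = []
    for w in [0.1, 1.0, 10.0]:
        pe = fit_piecewise_exponential(curve, penalty_weight=w, seed=0)
        spreads.append(np.var(np.log(pe.rates)))
    assert spreads[0] >= spreads[1] >= spreads[2]


def test_round_trip_within_error_bars(constant_results):
    """The fitted transform reproduces the estimated curve at every retained z."""
    assert np.all(np.abs(constant_results.transform_residuals()) <= 3.0)


def test_both_forms_give_similar_cdfs(constant_model):
    pe = constant_model.fit(form="piecewise_exponential", seed=0).distribution
    gm = constant_model.fit(form="gamma_mixture", seed=0).distribution
    t = np.geomspace(1e-5, 0.05, 200)
    assert np.max(np.abs(pe.cdf(t) - gm.cdf(t))) < 0.12


# --------------------------------------------------- densities, CDFs, sampling


def test_distribution_functions_exponential():
    pe = PiecewiseExponential(times=[0.0], rates=[3.0])
    t = np.array([0.0, 0.1, 1.0])
    dens, cdf = distribution_functions(pe, t)
    assert np.allclose(cdf, 1 - np.exp(-3 * t))
    assert np.allclose(dens, 3 * np.exp(-3 * t))


def test_gamma_cdf_matches_quadrature():
    gm = GammaMixture(weights=[0.3, 0.7], shapes=[0.7, 4.0], scales=[0.01, 0.001])
    for t in [1e-4, 1e-3, 5e-3, 0.1]:
        num, _ = quad(gm.pdf, 0, t, limit=300)
        assert float(gm.cdf(t)) == pytest.approx(num, abs=1e-8)


def test_cdf_monotone_and_point_mass():
    gm = GammaMixture(weights=[0.7], shapes=[2.0], scales=[0.01], w0=0.3)
    t = np.geomspace(1e-6, 1.0, 100)
    c = gm.cdf(t)
    assert np.all(np.diff(c) >= 0)
    assert float(gm.cdf(0.0)) == pytest.approx(0.3)
    assert float(gm.laplace(1e12)) == pytest.approx(0.3, abs=1e-6)


@pytest.mark.parametrize("dist", [
    GammaMixture(weights=[0.5, 0.5], shapes=[1.0, 3.0], scales=[0.01, 0.002]),
    PiecewiseExponential(times=[0.0, 2e-3, 1e-2], rates=[300.0, 80.0, 500.0]),
])
def test_sampling_matches_cdf(dist):
    rng = np.random.default_rng(8)
    x = dist.rvs(20_000, rng)
    from wincoal.derived import ks_distance
    assert ks_distance(dist.cdf, x) < 0.015
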