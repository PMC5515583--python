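"""Parametric coalescence-time distributions and Laplace-curve inversion.

Inverting a Laplace transform from noisy point estimates is ill-posed, so
the estimated curve is fitted with one of two parametric families whose
transforms are available in closed form: a mixture of gamma distributions
(optionally with a point mass at zero, relevant for branch classes that
can be empty), or a piecewise-exponential density whose piecewise-constant
hazard is, for pairwise times, the instantaneous coalescence rate
1/Ne(t). Fitting minimizes the scaled squared error
``sum_j (model(z_j) - estimate_j)^2 / sigma_j^2`` with seeded stochastic
restarts around a deterministic initialization (a basin-hopping-style
best-of-many-local-minima search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import ConvergenceError
from .richards import LaplaceCurve

__all__ = [
    "GammaMixture",
    "PiecewiseExponential",
    "fit_gamma_mixture",
    "fit_piecewise_exponential",
    "distribution_functions",
    "laplace_derivative",
]


@dataclass
class GammaMixture:
    """Mixture of gamma densities, with an optional point mass at t=0.

    ``weights`` (a_i), ``shapes`` (k_i) and ``scales`` (theta_i, in the
    same scaled-time units as the transform argument's reciprocal) must be
    positive; weights plus the point mass sum to 1.
    """

    weights: np.ndarray
    shapes: np.ndarray
    scales: np.ndarray
    w0: float = 0.0
    scaled_error: float = np.nan

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.shapes = np.atleast_1d(np.asarray(self.shapes, dtype=float))
        self.scales = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if np.any(self.weights <= 0) or np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("gamma-mixture parameters must be positive")
        if self.w0 < 0:
            raise ValueError("point mass must be nonnegative")
        tot = self.weights.sum() + self.w0
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"weights + point mass must sum to 1 (got {tot})")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def laplace(self, z):
        """E[exp(-z*t)]: w0 + sum_i a_i (1 + theta_i z)^{-k_i}; accepts complex z."""
        z = np.asarray(z)
        zz = z[..., None]
        return self.w0 + np.sum(self.weights * (1.0 + self.scales * zz) ** (-self.shapes), axis=-1)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = t[..., None]
        return np.sum(self.weights * gamma_dist.pdf(tt, self.shapes, scale=self.scales), axis=-1)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = t[..., None]
        out = self.w0 + np.sum(self.weights * gammainc(self.shapes, np.maximum(tt, 0.0) / self.scales), axis=-1)
        return np.where(t < 0, 0.0, out)

    def mean(self) -> float:
        return float(np.dot(self.weights, self.shapes * self.scales))

    def rvs(self, size: int, rng) -> np.ndarray:
        probs = np.concatenate(([self.w0], self.weights))
        comp = rng.choice(len(probs), size=size, p=probs / probs.sum())
        out = np.zeros(size)
        for i in range(self.n_components):
            m = comp == i + 1
            if m.any():
                out[m] = rng.gamma(self.shapes[i], self.scales[i], size=int(m.sum()))
        return out


@dataclass
class PiecewiseExponential:
    """Density with piecewise-constant hazard ``rates[i]`` on ``[times[i], times[i+1])``.

    ``times`` starts at 0 and the last interval extends to infinity; the
    density integrates to 1 by construction.
    """

    times: np.ndarray
    rates: np.ndarray
    scaled_error: float = np.nan

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.times[0] != 0.0:
            raise ValueError("first knot must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knots must be strictly increasing")
        if len(self.rates) != len(self.times):
            raise ValueError("need one rate per knot interval")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    @property
    def _cumhaz_at_knots(self) -> np.ndarray:
        d = np.diff(self.times)
        return np.concatenate(([0.0], np.cumsum(self.rates[:-1] * d)))

    def _interval(self, t):
        return np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.rates) - 1)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        i = self._interval(t)
        S = self._cumhaz_at_knots
        return np.where(t < 0, 1.0, np.exp(-(S[i] + self.rates[i] * (t - self.times[i]))))

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        i = self._interval(t)
        return np.where(t < 0, 0.0, self.rates[i] * self.survival(t))

    def cdf(self, t):
        return 1.0 - self.survival(t)

    def mean(self) -> float:
        S = np.exp(-self._cumhaz_at_knots)
        d = np.diff(self.times)
        body = np.sum(S[:-1] * (1.0 - np.exp(-self.rates[:-1] * d)) / self.rates[:-1])
        return float(body + S[-1] / self.rates[-1])

    def laplace(self, z):
        """Closed-form E[exp(-z*t)]; accepts complex z (used for derivatives)."""
        z = np.asarray(z)
        zz = z[..., None]
        t = self.times
        c = self.rates
        S = self._cumhaz_at_knots
        head = np.exp(-zz * t - S) / (1.0 + zz / c)
        d = np.diff(t)
        # last interval extends to infinity, so its bracket is exactly 1
        body = head[..., :-1] * (1.0 - np.exp(-(c[:-1] + zz) * d))
        return np.sum(body, axis=-1) + head[..., -1]

    def rvs(self, size: int, rng) -> np.ndarray:
        E = rng.exponential(size=size)
        S = self._cumhaz_at_knots
        i = np.clip(np.searchsorted(S, E, side="right") - 1, 0, len(self.rates) - 1)
        return self.times[i] + (E - S[i]) / self.rates[i]


def laplace_derivative(dist, z: float) -> float:
    """d/dz E[exp(-z*t)] by complex-step differentiation (machine precision)."""
    h = 1e-30
    return float(np.imag(dist.laplace(np.asarray(z, dtype=complex) + 1j * h)) / h)


def _curve_arrays(curve: LaplaceCurve):
    return curve.z, curve.values, np.maximum(curve.sigma, 1e-12)


def fit_gamma_mixture(
    curve: LaplaceCurve,
    allow_point_mass: bool = False,
    restarts: int = 50,
    seed: int = 0,
    perturbation: float = 0.5,
) -> GammaMixture:
    """Fit a gamma mixture with ``floor((J+1)/3)`` components to the curve.

    Global search by seeded random restarts around a quantile-spread
    initialization, each refined with bounded L-BFGS; the best local
    minimum is returned with its scaled squared error.
    """
    z, v, s = _curve_arrays(curve)
    J = curve.J
    if J < 3:
        raise ValueError("need at least 3 retained transform points")
    m = (J + 1) // 3
    rng = np.random.default_rng(seed)
    zmin, zmax = z.min(), z.max()

    n_w = m + 1 if allow_point_mass else m

    def unpack(x):
        logits = x[:n_w]
        logk = x[n_w:n_w + m]
        logth = x[n_w + m:]
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        if allow_point_mass:
            return w[:m], np.exp(logk), np.exp(logth), w[m]
        return w, np.exp(logk), np.exp(logth), 0.0

    def residuals(x):
        w, k, th, w0 = unpack(x)
        model = w0 + np.sum(w * (1.0 + th * z[:, None]) ** (-k), axis=1)
        return (model - v) / s

    def objective(x):
        return float(np.sum(residuals(x) ** 2))

    th0 = np.geomspace(0.5 / zmax, 2.0 / zmin, m)
    x_base = np.concatenate([np.zeros(n_w), np.zeros(m), np.log(th0)])
    if allow_point_mass:
        x_base[m] = -2.0  # start the atom small
        # timescales below the resolvable range are indistinguishable from
        # the atom; bound the components so the point mass absorbs them
        th_lo = 0.5 / zmax
    else:
        th_lo = th0[0] * 1e-3
    # shapes are capped: components much narrower than the transform can
    # resolve act as spurious spikes (the mixture's regularization, in the
    # same spirit as the piecewise form's smoothness penalty)
    bounds = (
        [(-20.0, 20.0)] * n_w
        + [(np.log(1e-2), np.log(20.0))] * m
        + [(np.log(th_lo), np.log(th0[-1] * 1e3))] * m
    )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best_x, best_f = None, np.inf
    for r in range(max(restarts, 1)):
        x0 = x_base if r == 0 else x_base + rng.normal(0.0, perturbation, size=x_base.shape)
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", max_nfev=3000)
        except Exception:
            continue
        f = float(2.0 * res.cost)
        if np.isfinite(f) and f < best_f:
            best_f, best_x = f, res.x
    if best_x is None:
        raise ConvergenceError("gamma-mixture fit failed across all restarts")
    w, k, th, w0 = unpack(best_x)
    return GammaMixture(weights=w, shapes=k, scales=th, w0=w0, scaled_error=best_f)


def select_z_star(curve: LaplaceCurve, target: float = 0.95) -> float:
    """z* where the curve is closest to ``target``; smallest z if all below."""
    if np.all(curve.values < target):
        return float(curve.z[0])
    return float(curve.z[np.argmin(np.abs(curve.values - target))])


def fit_piecewise_exponential(
    curve: LaplaceCurve,
    penalty_weight: float = 1.0,
    restarts: int = 5,
    seed: int = 0,
    perturbation: float = 0.5,
) -> PiecewiseExponential:
    """Fit a piecewise-exponential density with fixed log-spaced knots.

    Knots are spread evenly in log time between ``1/(2*z_J)`` (z_J the
    largest retained z) and ``1/z*`` (where the curve passes ~0.95); the
    rates are optimized with a quadratic smoothness penalty on
    ``log(c_{i+1}/c_i)``.
    """
    z, v, s = _curve_arrays(curve)
    J = curve.J
    if J < 3:
        raise ValueError("need at least 3 retained transform points")
    zJ = z.max()
    zstar = select_z_star(curve)
    t_lo, t_hi = 1.0 / (2.0 * zJ), 1.0 / zstar
    if t_hi <= t_lo:
        t_hi = t_lo * 10.0
    interior = np.geomspace(t_lo, t_hi, J - 1)
    times = np.concatenate(([0.0], interior))
    m = len(times)
    S_pref = np.diff(times)
    rng = np.random.default_rng(seed)

    sqrt_pen = np.sqrt(penalty_weight)

    def residuals(logc):
        pe = PiecewiseExponential(times=times, rates=np.exp(logc))
        fit_res = (pe.laplace(z) - v) / s
        return np.concatenate([fit_res, sqrt_pen * np.diff(logc)])

    mean_guess = (1.0 - v[0]) / z[0] if v[0] < 1 else curve.pi_hat
    mean_guess = max(mean_guess, 1e-12)
    x_base = np.full(m, -np.log(mean_guess))
    lo, hi = x_base - 25.0, x_base + 25.0
    best_x, best_f = None, np.inf
    for r in range(max(restarts, 1)):
        x0 = np.clip(x_base if r == 0 else x_base + rng.normal(0.0, perturbation, size=m), lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", max_nfev=3000)
        except Exception:
            continue
        f = float(2.0 * res.cost)
        if np.isfinite(f) and f < best_f:
            best_f, best_x = f, res.x
    if best_x is None:
        raise ConvergenceError("piecewise-exponential fit failed across all restarts")
    pe = PiecewiseExponential(times=times, rates=np.exp(best_x))
    model = pe.laplace(z)
    pe.scaled_error = float(np.sum(((model - v) / s) ** 2))
    return pe


def distribution_functions(dist, t) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic (density, CDF) of a fitted distribution at time(s) ``t``."""
    return dist.pdf(t), dist.cdf(t)
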