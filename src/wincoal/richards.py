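"""Combining transform estimates across window lengths.

At a fixed transform variable ``z`` the quantity ``p_L(z/L) = E[exp(-z*mu*T_L)]``
is flat in ``L`` at both extremes: for small windows it approaches the
single-locus transform (the target of inference), for large windows the
averaging narrows the distribution of ``T_L`` around its mean and the
value approaches ``exp(-pi_hat*z)``. The crossover happens at window
lengths comparable to the typical recombination block. We interpolate
between the two limits with a generalized logistic (Richards) sigmoid in
``log L`` and take the fitted left asymptote as the estimate of the
single-locus transform; the fitted transition length is informative about
recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError

from .transform import TauTable, TransformPoint, tau_shrinkage, transform_point
from .windows import CountHistogram

__all__ = ["RichardsFit", "LaplaceCurve", "choose_z_grid", "transform_profile", "fit_richards", "assemble_curve", "estimate_laplace_curve"]


@dataclass
class RichardsFit:
    """Richards-sigmoid fit of ``p_L(z/L)`` against ``log L`` at one ``z``.

    ``a`` is the left (small-window) asymptote — the estimate of the
    single-locus transform — and ``b`` the fixed right asymptote
    ``exp(-pi_hat*z)``; ``Lx`` is the transition window length in bases.
    """

    z: float
    a: float = np.nan
    b: float = np.nan
    c: float = np.nan
    nu: float = np.nan
    Lx: float = np.nan
    a_err: float = np.nan
    Lx_err: float = np.nan
    converged: bool = False
    degenerate: bool = False
    n_points: int = 0
    chi2: float = np.nan
    lowest_point: Optional[TransformPoint] = None
    L_range: Optional[tuple] = None  # (min, max) window length entering the fit

    def predict(self, L) -> np.ndarray:
        """Evaluate the fitted sigmoid at window length(s) ``L``."""
        u = np.log(np.asarray(L, dtype=float))
        return _sigmoid(u, self.a, self.b, self.c, self.nu, np.log(self.Lx))

    @property
    def L_mid(self) -> float:
        """Window length where the curve crosses halfway between asymptotes.

        Unlike the raw ``Lx`` location parameter this is invariant to the
        (c, nu) shape degeneracy, so it is the quantity compared across
        chromosomes when estimating relative recombination rates.
        """
        return float(self.Lx * (2.0**self.nu - 1.0) ** (-1.0 / self.c))


@dataclass
class LaplaceCurve:
    """Estimated single-locus Laplace transform on a grid of ``z`` with errors."""

    z: np.ndarray
    values: np.ndarray
    sigma: np.ndarray
    pi_hat: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        order = np.argsort(self.z)
        self.z, self.values, self.sigma = self.z[order], self.values[order], self.sigma[order]
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("transform values outside [0, 1]")
        if np.any(np.diff(self.values) > 0):
            raise ValueError("transform values must be nonincreasing in z")

    @property
    def J(self) -> int:
        return len(self.z)


def choose_z_grid(
    pi_hat: float,
    L0: float,
    Lmax: float,
    span: tuple = (1e-2, 1e3),
    count: int = 32,
) -> np.ndarray:
    """Log-uniform grid of z such that pi_hat*z spans ``span``, capped at ``Lmax``.

    The cap reflects that the plug-in estimator is only accurate for
    arguments near 1, so z beyond the largest usable window length cannot
    be resolved.
    """
    if pi_hat <= 0:
        raise ValueError("pi_hat must be positive (no polymorphism)")
    lo = span[0] / pi_hat
    hi = min(span[1] / pi_hat, float(Lmax))
    if hi <= lo:
        raise ValueError("empty z grid: Lmax below the lower end of the span")
    return np.geomspace(lo, hi, count)


def transform_profile(
    hists: Dict[int, CountHistogram],
    z: float,
    taus: Optional[Dict[int, TauTable]] = None,
) -> List[TransformPoint]:
    """Plug-in transform at argument ``z/L`` for every scale, at fixed ``z``."""
    pts = []
    for L in sorted(hists):
        tau = taus[L] if taus else None
        pts.append(transform_point(hists[L], z / L, tau=tau))
    return pts


def _sigmoid(u, a, b, c, nu, ux):
    # Richards curve in u = log L: left asymptote a, right asymptote b
    t = np.exp(np.clip(-c * (u - ux), -500, 500))
    return a + (b - a) * (1.0 + t) ** (-1.0 / nu)


def fit_richards(
    points: Sequence[TransformPoint],
    b_fixed: float,
    z: float = np.nan,
    rel_err_threshold: float = 0.1,
    min_points: int = 4,
) -> RichardsFit:
    """Weighted Richards-sigmoid fit over window lengths at fixed ``z``.

    Only points with positive value and relative standard error below the
    threshold enter the fit (weights 1/stderr^2); the right asymptote is
    fixed at ``exp(-pi_hat*z)``. Multi-start over the transition length,
    initialized at each data length, guards against the fit's
    multi-modality in (c, nu, Lx).
    """
    usable = [
        p for p in points
        if p.usable and p.value > 0 and p.stderr / p.value <= rel_err_threshold
    ]
    fit = RichardsFit(z=z, b=b_fixed, n_points=len(usable))
    if len(usable) < min_points:
        return fit
    usable.sort(key=lambda p: p.L)
    fit.lowest_point = usable[0]
    fit.L_range = (usable[0].L, usable[-1].L)
    u = np.log(np.array([p.L for p in usable], dtype=float))
    y = np.array([np.clip(p.value, 0.0, 1.0) for p in usable])
    s = np.array([max(p.stderr, 1e-12) for p in usable])

    def resid(theta):
        a, c, nu, ux = theta
        return (_sigmoid(u, a, b_fixed, c, nu, ux) - y) / s

    lo = [0.0, 1e-3, 1e-3, np.log(1.0 + 1e-6)]
    hi = [1.0, 60.0, 60.0, np.log(1e15)]
    a0 = float(np.clip(y[0], 1e-6, 1 - 1e-6))
    starts = [np.array([a0, 2.0, 1.0, ui]) for ui in u]
    starts.append(np.array([a0, 2.0, 1.0, u[-1] + 3.0]))
    starts.append(np.array([a0, 0.5, 1.0, 0.5 * (u[0] + u[-1])]))
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and not np.isfinite(best.cost):
        return fit
    a, c, nu, ux = best.x
    fit.a, fit.c, fit.nu, fit.Lx = float(a), float(c), float(nu), float(np.exp(ux))
    fit.chi2 = float(2.0 * best.cost)
    fit.converged = True
    # covariance from the whitened Jacobian
    try:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            JtJ = best.jac.T @ best.jac
            cov = np.linalg.pinv(JtJ)
        fit.a_err = float(np.sqrt(max(cov[0, 0], 0.0)))
        fit.Lx_err = float(fit.Lx * np.sqrt(max(cov[3, 3], 0.0)))
    except np.linalg.LinAlgError:
        fit.converged = False
        return fit
    span = max(y.max() - y.min(), 0.0)
    fit.degenerate = span <= 2.0 * float(np.median(s))  # flat curve: no scale dependence
    return fit


def assemble_curve(
    fits: Sequence[RichardsFit],
    pi_hat: float,
    retention_sigma: float = 3.0,
    sigma_floor: float = 1e-10,
) -> LaplaceCurve:
    """Retain trusted left asymptotes and assemble the single-locus transform.

    An asymptote is trusted only when it is within ``retention_sigma``
    combined standard errors of the lowest usable-length data point, i.e.
    when the data actually reach the asymptotic regime; retained values
    must also be nonincreasing in z (violating points are dropped against
    the running minimum).
    """
    zs, vals, sigs = [], [], []
    running_min = np.inf
    for f in sorted(fits, key=lambda f: f.z):
        if not f.converged or f.lowest_point is None:
            continue
        tol = retention_sigma * np.hypot(f.a_err, f.lowest_point.stderr)
        if abs(f.a - f.lowest_point.value) > tol:
            continue
        v = float(np.clip(f.a, 0.0, 1.0))
        if v > running_min:
            continue
        running_min = v
        zs.append(f.z)
        vals.append(v)
        sigs.append(max(f.a_err, sigma_floor))
    if not zs:
        raise ConvergenceError("no trusted asymptotes")
    return LaplaceCurve(z=np.array(zs), values=np.array(vals), sigma=np.array(sigs), pi_hat=pi_hat)


def estimate_laplace_curve(
    hists: Dict[int, CountHistogram],
    pi_hat: float,
    z_grid: Optional[np.ndarray] = None,
    z_span: tuple = (1e-2, 1e3),
    z_count: int = 32,
    rel_err_threshold: float = 0.1,
    retention_sigma: float = 3.0,
    min_points: int = 4,
):
    """Full multiscale combination: grid -> profiles -> sigmoid fits -> curve.

    Returns ``(LaplaceCurve, list[RichardsFit])``.
    """
    scales = sorted(hists)
    if z_grid is None:
        z_grid = choose_z_grid(pi_hat, scales[0], scales[-1], span=z_span, count=z_count)
    taus = {L: tau_shrinkage(hists[L]) for L in scales}
    fits = []
    for z in z_grid:
        pts = transform_profile(hists, z, taus=taus)
        b = float(np.exp(-pi_hat * z))
        fits.append(fit_richards(pts, b_fixed=b, z=z, rel_err_threshold=rel_err_threshold, min_points=min_points))
    curve = assemble_curve(fits, pi_hat, retention_sigma=retention_sigma)
    return curve, fits
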