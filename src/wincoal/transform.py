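"""Plug-in estimation of the Laplace transform of window-averaged coalescence times.

Under the infinite-sites model the SNP count of a window of length ``L``
is Poisson with mean ``tau_L = mu*L*T_L``, so the count distribution is a
Poisson mixture over the genome-wide distribution of ``tau_L``. The
Laplace transform ``E[exp(-z*tau_L)]`` then has the unbiased plug-in
estimator

    sum_n (K_n/K) * (1 - z)**n

over the observed count histogram, whose sampling variance from the
mutation process alone is

    (1/K) * E[exp(-z*(2-z)*tau) - exp(-2*z*tau)],

evaluated under a rough per-window estimate of ``tau`` obtained by
shrinking the observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import logsumexp

from .windows import CountHistogram

__all__ = ["TauTable", "TransformPoint", "plugin_transform", "tau_shrinkage", "transform_stderr", "transform_point"]

_LOG_MAX = 700.0  # exp overflow guard


@dataclass
class TauTable:
    """Estimated scaled coalescence time (expected SNPs per window) for each observed count."""

    n_values: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values, dtype=np.int64)
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("tau estimates must be positive")
        if np.any(np.diff(self.tau) < 0):
            raise ValueError("tau estimates must be nondecreasing in n")

    def __getitem__(self, n: int) -> float:
        idx = np.searchsorted(self.n_values, n)
        if idx >= len(self.n_values) or self.n_values[idx] != n:
            raise KeyError(n)
        return float(self.tau[idx])


def plugin_transform(hist: CountHistogram, z: float) -> float:
    """Plug-in estimate of E[exp(-z*tau_L)] from the count histogram.

    Exact finite sum over observed counts. ``z=0`` gives 1 (normalization)
    and ``z=1`` gives exactly the zero-SNP window fraction. For ``z > 2``
    the alternating terms can be astronomically large; they are summed in
    signed log space and the result may overflow to +/-inf, which callers
    must screen with the standard error.
    """
    if z < 0:
        raise ValueError("z must be >= 0")
    n = hist.n_values.astype(float)
    w = hist.weights
    base = 1.0 - z
    if abs(base) <= 1.0:
        return float(np.dot(w, base ** n))
    # |1-z| > 1: signed log-space accumulation
    logmag = n * np.log(abs(base)) + np.log(w)
    signs = np.where(hist.n_values % 2 == 0, 1.0, np.sign(base))
    total, sign = logsumexp(logmag, b=signs, return_sign=True)
    if total > _LOG_MAX:
        return float(sign * np.inf)
    return float(sign * np.exp(total))


def simple_shrinkage(hist: CountHistogram) -> TauTable:
    """Count-based rule: tau(n) = n*(1 - 1/(n + K_n + 1)), tau(0) = ln2/K0.

    Satisfies 0 < tau(n) <= n and tau(n)/n -> 1. The zero-count value is
    the largest tau consistent (at even odds) with seeing no mutations in
    K0 windows; it is capped at the smallest positive-count estimate so
    the table stays nondecreasing.
    """
    n = hist.n_values.astype(float)
    tau = np.empty_like(n)
    pos = hist.n_values >= 1
    tau[pos] = n[pos] * (1.0 - 1.0 / (n[pos] + hist.k_n[pos] + 1.0))
    if (~pos).any():
        t0 = np.log(2.0) / max(hist.K0, 1)
        if pos.any():
            t0 = min(t0, float(tau[pos].min()))
        tau[~pos] = t0
    return TauTable(n_values=hist.n_values, tau=tau)


def empirical_bayes_shrinkage(hist: CountHistogram, min_count: int = 5) -> TauTable:
    """Robbins-style estimate of E[tau | n] from the count ensemble.

    For a Poisson mixture the posterior mean is exactly
    ``(n+1) * P(n+1)/P(n)``; the plug-in uses ``(n+1) * K_{n+1}/K_n``
    wherever the cell is populated (``K_n >= min_count`` and the next cell
    observed), falling back to :func:`simple_shrinkage` elsewhere. Values
    are monotonized (cumulative max) and capped at n for n >= 1, keeping
    the stated shrinkage properties while being far more accurate when
    most windows carry few mutations — which is what the error model of
    the plug-in transform needs.
    """
    freq = hist.freq
    fallback = simple_shrinkage(hist).tau
    raw = fallback.copy()
    for i, n in enumerate(hist.n_values):
        k_n = freq[int(n)]
        k_next = freq.get(int(n) + 1, 0)
        if k_n >= min_count and k_next > 0:
            raw[i] = (n + 1.0) * k_next / k_n
    tau = np.maximum.accumulate(raw)
    pos = hist.n_values >= 1
    tau[pos] = np.minimum(tau[pos], hist.n_values[pos].astype(float))
    tau = np.maximum(tau, 1e-12)
    if (~pos).any() and pos.any():
        tau[~pos] = np.minimum(tau[~pos], tau[pos].min())
    return TauTable(n_values=hist.n_values, tau=tau)


def tau_shrinkage(
    hist: CountHistogram,
    shrinkage: Optional[Callable[[CountHistogram], TauTable]] = None,
) -> TauTable:
    """Per-window scaled-time estimates from observed SNP counts.

    The default is the Robbins empirical-Bayes rule
    (:func:`empirical_bayes_shrinkage`); pass ``shrinkage=`` to swap in a
    different estimator (e.g. :func:`simple_shrinkage`).
    """
    rule = shrinkage or empirical_bayes_shrinkage
    return rule(hist)


def transform_stderr(hist: CountHistogram, tau: TauTable, z: float) -> float:
    """Standard error of the plug-in transform from mutation stochasticity.

    Computes sqrt((1/K) * E[exp(-z*(2-z)*tau) - exp(-2*z*tau)]) with the
    expectation over the empirical tau table weighted by K_n/K. Negative
    values from rounding are clipped to zero; for z > 2 the first exponent
    is positive and the result may overflow to +inf.
    """
    if z < 0:
        raise ValueError("z must be >= 0")
    if z == 0:
        return 0.0
    w = hist.weights
    t = tau.tau
    with np.errstate(over="ignore", under="ignore"):
        e1 = np.exp(np.minimum(-z * (2.0 - z) * t, _LOG_MAX))
        e2 = np.exp(-2.0 * z * t)
        var = float(np.dot(w, e1 - e2)) / hist.K
    if not np.isfinite(var):
        return np.inf
    return np.sqrt(max(var, 0.0))


@dataclass
class TransformPoint:
    """One transform estimate: argument ``z`` at window length ``L``, with its standard error."""

    L: int
    z: float
    value: float
    stderr: float

    @property
    def usable(self) -> bool:
        return np.isfinite(self.value) and np.isfinite(self.stderr)


def transform_point(hist: CountHistogram, z: float, tau: Optional[TauTable] = None) -> TransformPoint:
    """Evaluate the plug-in transform and its standard error at argument ``z``."""
    if tau is None:
        tau = tau_shrinkage(hist)
    return TransformPoint(
        L=hist.L,
        z=z,
        value=plugin_transform(hist, z),
        stderr=transform_stderr(hist, tau, z),
    )
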