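"""Downstream quantities from fitted coalescence-time distributions.

The survival function of identity-by-descent (IBD) block map lengths
follows directly from the Laplace transform of the coalescence time: a
block ending at a crossover that happened at map rate r per unit time
survives length r with probability proportional to the transform's
derivative, P(r_block > r) = p'(r) / p'(0). The piecewise-exponential
form's hazard gives the effective-population-size trajectory Ne(t).
Cross-chromosome comparisons of the sigmoid transition lengths yield
relative recombination rates, with residual-variation diagnostics for
coalescence patterns that recombination rescaling cannot explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import PiecewiseExponential, laplace_derivative
from .richards import RichardsFit

__all__ = [
    "IBDSurvival",
    "ibd_survival",
    "ne_trajectory",
    "relative_recombination",
    "residual_iqr_test",
    "make_mc_asymptote_simulator",
    "ks_distance",
]

#: Kingman-pairwise fraction of recombination events that change the tree.
GHOST_TREE_CHANGE_FRACTION = 2.0 / 3.0


@dataclass
class IBDSurvival:
    """Survival function of IBD block map lengths (Morgans).

    Built from a fitted distribution in mutation-scaled time tau = mu*T,
    so ``mu`` converts the transform argument to natural-time units.
    With ``ghost_correction`` the map rate is scaled by 2/3, the
    Kingman-pairwise fraction of recombination events that actually
    change the tree (tree-preserving "ghost" events do not end blocks).
    """

    dist: object
    mu: float
    ghost_correction: bool = False

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        self._d0 = laplace_derivative(self.dist, 0.0)

    @property
    def mean_T(self) -> float:
        """Mean coalescence time in natural (T) units: -p'(0)."""
        return -self._d0 / self.mu

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        scale = GHOST_TREE_CHANGE_FRACTION if self.ghost_correction else 1.0
        flat = np.atleast_1d(r)
        out = np.array([laplace_derivative(self.dist, scale * ri / self.mu) for ri in flat])
        out = out / self._d0
        return out.reshape(r.shape) if r.shape else float(out[0])


def ibd_survival(dist, r, mu: float, ghost_correction: bool = False):
    """P(block map length > r Morgans) for a fitted distribution; see :class:`IBDSurvival`."""
    return IBDSurvival(dist, mu, ghost_correction)(r)


def ne_trajectory(pe: PiecewiseExponential, mu: Optional[float] = None):
    """Stepwise Ne(t) from a piecewise-exponential pairwise fit.

    Without ``mu`` the result is in mutation-scaled units: times are tau
    and Ne is 1/c_i (the inverse instantaneous coalescence rate per unit
    tau). With ``mu`` per generation, times become TMRCA generations
    (tau / (2*mu), since the pairwise statistic is twice the TMRCA) and
    sizes become Ne = 1/(4*mu*c_i) diploid individuals.
    """
    if not isinstance(pe, PiecewiseExponential):
        raise TypeError("Ne(t) requires the piecewise-exponential form (piecewise-constant hazard)")
    t = pe.times.copy()
    ne = 1.0 / pe.rates
    if mu is not None:
        t = t / (2.0 * mu)
        ne = ne / (4.0 * mu)
    return t, ne


@dataclass
class ChromosomeComparison:
    """Per-chromosome recombination-rate ratios and coalescence-shape flags."""

    table: pd.DataFrame
    reference: str

    def __str__(self) -> str:
        return f"relative recombination rates (reference {self.reference}):\n{self.table}"


def _trusted_asymptote(f: RichardsFit, retention_sigma: float = 3.0) -> bool:
    """Same trust rule as curve assembly: the fitted asymptote must be
    consistent with the lowest usable-length data point."""
    if not f.converged or f.lowest_point is None or not np.isfinite(f.a_err):
        return False
    tol = retention_sigma * np.hypot(f.a_err, f.lowest_point.stderr)
    return abs(f.a - f.lowest_point.value) <= tol


def _lx_identified(f: RichardsFit, min_amplitude: float = 0.05, max_rel_err: float = 1.5) -> bool:
    """Is the transition length actually constrained by this fit?

    Requires a non-degenerate converged fit whose sigmoid amplitude
    (a - b) is appreciable and whose midpoint falls inside the range of
    window lengths that entered the fit; otherwise the location is a
    boundary or noise artifact.
    """
    if not f.converged or f.degenerate or f.L_range is None:
        return False
    if not (np.isfinite(f.Lx_err) and f.Lx_err > 0):
        return False
    if abs(f.a - f.b) < min_amplitude:
        return False
    lo, hi = f.L_range
    if not (2.0 * lo <= f.L_mid <= hi / 2.0):
        return False
    return f.Lx_err / f.Lx <= max_rel_err


def _lx_ratio(
    ref_fits: Dict[float, RichardsFit],
    fits: Dict[float, RichardsFit],
    min_amplitude: float = 0.1,
    max_z_used: int = 4,
):
    """Weighted midpoint-length ratio Lmid_ref/Lmid over shared z values.

    Only z where both curves transition with substantial amplitude carry
    information about the horizontal rescaling. Among those, the smallest
    z are preferred: the plug-in transform is accurate for arguments near
    one, so at small z the curve is pinned over the widest range of
    window lengths and the midpoint is least biased. The ratio is the
    inverse-variance weighted mean over (at most) the ``max_z_used``
    smallest such z.
    """
    cand = []
    for z in sorted(fits):
        f, fr = fits[z], ref_fits.get(z)
        if fr is None or not (_lx_identified(f) and _lx_identified(fr)):
            continue
        if min(abs(f.a - f.b), abs(fr.a - fr.b)) < min_amplitude:
            continue
        ratio = fr.L_mid / f.L_mid
        rel_var = (f.Lx_err / f.Lx) ** 2 + (fr.Lx_err / fr.Lx) ** 2
        cand.append((ratio, rel_var))
        if len(cand) >= max_z_used:
            break
    if not cand:
        return np.nan, np.nan
    ratios = np.array([r for r, _ in cand])
    weights = np.array([1.0 / (rv * r**2) for r, rv in cand])
    mean = float(np.sum(weights * ratios) / np.sum(weights))
    err = float(1.0 / np.sqrt(np.sum(weights)))
    return mean, err


def relative_recombination(
    fits_by_chrom: Dict[str, Sequence[RichardsFit]],
    reference: str,
    pi_by_chrom: Optional[Dict[str, float]] = None,
    outlier_sigma: float = 5.0,
) -> ChromosomeComparison:
    """Relative recombination rates from window-length rescalings.

    Chromosomes sharing a coalescent history but differing in crossover
    rate show horizontally shifted transform-vs-window-length curves, so
    ``rate_i / rate_ref = Lmid_ref / Lmid_i`` (midpoint window lengths),
    averaged over the most informative z. A chromosome whose left
    asymptotes deviate from the cross-chromosome consensus by more than
    ``outlier_sigma`` robust spreads (compared at matched pi_hat*z when
    densities are supplied) is flagged as a shape outlier: its
    coalescence pattern itself differs, beyond any recombination-rate
    rescaling. Shape flags need at least 4 chromosomes; per-fit errors
    alone cannot calibrate the intrinsic per-chromosome coalescent
    variability.
    """
    if reference not in fits_by_chrom:
        raise ValueError(f"reference chromosome {reference!r} missing")
    by_z = {c: {f.z: f for f in fits if f.converged} for c, fits in fits_by_chrom.items()}
    ref = by_z[reference]
    devs = _shape_deviations(by_z, pi_by_chrom)
    rows = []
    for c in fits_by_chrom:
        dev = devs.get(c, np.nan)
        if c == reference:
            rows.append((c, 1.0, 0.0, dev, bool(dev > outlier_sigma)))
            continue
        rate, err = _lx_ratio(ref, by_z[c])
        rows.append((c, rate, err, dev, bool(dev > outlier_sigma)))
    table = pd.DataFrame(rows, columns=["chrom", "relative_rate", "rate_err", "shape_dev", "shape_outlier"])
    table = table.set_index("chrom")
    if pi_by_chrom:
        table["pi_hat"] = pd.Series(pi_by_chrom)
    table["L_mid"] = pd.Series({
        c: float(np.nanmedian([f.L_mid for f in fits if _lx_identified(f)]) if any(_lx_identified(f) for f in fits) else np.nan)
        for c, fits in fits_by_chrom.items()
    })
    return ChromosomeComparison(table=table, reference=reference)


def _shape_deviations(by_z, pi_by_chrom) -> Dict[str, float]:
    """Sup deviation of each chromosome's asymptote curve from the consensus.

    Curves are compared at matched ``w = pi_hat * z`` (vertical alignment)
    on the overlap of their ranges; the per-w consensus is the median
    across chromosomes and the scale is the MAD-based robust spread,
    floored by the propagated fit errors. Requires >= 4 chromosomes.
    """
    trusted = {
        c: {z: f for z, f in fits.items() if _trusted_asymptote(f)}
        for c, fits in by_z.items()
    }
    names = [c for c in trusted if len(trusted[c]) >= 3]
    if len(names) < 4:
        return {}
    pi = pi_by_chrom or {}
    curves = {}
    for c in names:
        zs = np.array(sorted(trusted[c]))
        w = zs * pi.get(c, 1.0)
        a = np.array([trusted[c][z].a for z in zs])
        e = np.array([trusted[c][z].a_err for z in zs])
        curves[c] = (np.log(w), a, e)
    lo = max(lw[0] for lw, _, _ in curves.values())
    hi = min(lw[-1] for lw, _, _ in curves.values())
    if hi <= lo:
        return {}
    grid = np.linspace(lo, hi, 24)
    A = np.vstack([np.interp(grid, lw, a) for lw, a, _ in curves.values()])
    E = np.vstack([np.interp(grid, lw, e) for lw, _, e in curves.values()])
    med = np.median(A, axis=0)
    mad = 1.4826 * np.median(np.abs(A - med), axis=0)
    base = np.maximum(np.maximum(mad, np.median(E, axis=0)), 1e-12)
    out = {}
    for i, c in enumerate(curves):
        # a point only counts against a chromosome if it is precise there
        scale = np.maximum(base, E[i])
        out[c] = float(np.max(np.abs(A[i] - med) / scale))
    return out


@dataclass
class IQRTestResult:
    observed_iqr: float
    null_quantiles: tuple  # (2.5%, 50%, 97.5%)
    exceeds: bool
    null_iqrs: np.ndarray = field(repr=False, default=None)


def make_mc_asymptote_simulator(z: float, n_times: int) -> Callable:
    """Default null simulator: per-chromosome Monte-Carlo transform estimates.

    Draws ``n_times`` coalescence times per chromosome from the fitted
    distribution and returns the empirical mean of exp(-z*tau) — the
    intrinsic coalescent stochasticity of a finite chromosome with that
    many independent coalescent blocks.
    """

    def simulate(dist, n_chrom: int, rng) -> np.ndarray:
        taus = dist.rvs(n_chrom * n_times, rng).reshape(n_chrom, n_times)
        return np.exp(-z * taus).mean(axis=1)

    return simulate


def residual_iqr_test(
    asymptotes_by_chrom: Sequence[float],
    fitted_dist,
    simulator: Callable,
    n_null: int = 200,
    seed: int = 0,
) -> IQRTestResult:
    """Is cross-chromosome transform variation larger than coalescent chance?

    Builds the null distribution of the interquartile range of
    per-chromosome transform values by repeatedly simulating chromosomes
    from the genome-wide fitted distribution; flags an exceedance when
    the observed IQR lies above the 97.5th null percentile.
    """
    obs = np.asarray(asymptotes_by_chrom, dtype=float)
    if obs.size < 4:
        raise ValueError("need at least 4 chromosomes")
    if simulator is None:
        raise ValueError("a null simulator is required")
    rng = np.random.default_rng(seed)
    q75, q25 = np.percentile(obs, [75, 25])
    observed = float(q75 - q25)
    null = np.empty(n_null)
    for i in range(n_null):
        sim = np.asarray(simulator(fitted_dist, obs.size, rng), dtype=float)
        a, b = np.percentile(sim, [75, 25])
        null[i] = a - b
    lo, med, hi = np.percentile(null, [2.5, 50, 97.5])
    return IQRTestResult(
        observed_iqr=observed,
        null_quantiles=(float(lo), float(med), float(hi)),
        exceeds=bool(observed > hi),
        null_iqrs=null,
    )


def ks_distance(cdf: Callable, empirical_times, weights=None) -> float:
    """Kolmogorov-Smirnov distance between a fitted CDF and an empirical sample.

    ``weights`` (e.g. base spans of ground-truth coalescence tracks) turn
    the sample into a weighted empirical distribution.
    """
    t = np.asarray(empirical_times, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one empirical time")
    order = np.argsort(t)
    t = t[order]
    if weights is None:
        w = np.full(t.size, 1.0 / t.size)
    else:
        w = np.asarray(weights, dtype=float)[order]
        w = w / w.sum()
    ecdf_hi = np.cumsum(w)
    ecdf_lo = ecdf_hi - w
    F = np.asarray(cdf(t), dtype=float)
    return float(np.max(np.maximum(np.abs(F - ecdf_hi), np.abs(F - ecdf_lo))))
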