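"""Model/Results front end for the windowed coalescent analysis.

:class:`CoalescentWindowModel` is built from data (a variant stream,
multihetsep files, or precomputed count histograms); its :meth:`fit`
runs the multiscale transform estimation and parametric inversion and
returns a :class:`CoalescentWindowResults` carrying the estimated
Laplace curve, the fitted coalescence-time distribution, uncertainties
and diagnostics, with ``summary()``, prediction, and plotting methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .branches import BranchClassSpec, snp_density
from .config import PipelineConfig
from .derived import IBDSurvival, ks_distance, ne_trajectory
from .distributions import (
    GammaMixture,
    PiecewiseExponential,
    fit_gamma_mixture,
    fit_piecewise_exponential,
)
from .multihetsep import VariantStream, read_multihetsep
from .richards import LaplaceCurve, RichardsFit, choose_z_grid, estimate_laplace_curve
from .windows import CountHistogram, base_window_counts, count_pyramid

__all__ = ["CoalescentWindowModel", "CoalescentWindowResults"]


class CoalescentWindowModel:
    """Coalescence-time distribution model for windowed SNP-count data.

    Parameters
    ----------
    histograms : dict
        ``L -> CountHistogram`` pooled over chromosomes at every scale.
    pi_hat : float
        Genomic density of selected SNPs per base.
    config : PipelineConfig, optional
    per_chrom : dict, optional
        ``chrom -> (L -> CountHistogram)`` for per-chromosome analyses.
    pi_by_chrom : dict, optional
        Per-chromosome SNP densities matching ``per_chrom``.
    """

    def __init__(
        self,
        histograms: Dict[int, CountHistogram],
        pi_hat: float,
        config: Optional[PipelineConfig] = None,
        per_chrom: Optional[Dict[str, Dict[int, CountHistogram]]] = None,
        pi_by_chrom: Optional[Dict[str, float]] = None,
    ):
        if not histograms:
            raise ValueError("no histograms supplied")
        if pi_hat <= 0:
            raise ValueError("pi_hat must be positive (no polymorphism)")
        self.histograms = dict(sorted(histograms.items()))
        self.pi_hat = float(pi_hat)
        self.config = config or PipelineConfig()
        self.per_chrom = per_chrom
        self.pi_by_chrom = pi_by_chrom

    # -- constructors --------------------------------------------------
    @classmethod
    def from_variant_stream(
        cls,
        stream: VariantStream,
        config: Optional[PipelineConfig] = None,
        chrom_lengths: Optional[Dict[str, int]] = None,
        **overrides,
    ) -> "CoalescentWindowModel":
        cfg = config or PipelineConfig(**overrides)
        spec = BranchClassSpec.parse(cfg.stat)
        wcs = base_window_counts(
            stream, spec, L0=cfg.L0, coverage_floor=cfg.coverage_floor,
            seed=cfg.seed, chrom_lengths=chrom_lengths,
        )
        if not wcs:
            raise ValueError("no windows could be formed from the stream")
        pooled, by_chrom = count_pyramid(wcs, min_valid=cfg.min_valid_windows, per_chromosome=True)
        pi = snp_density(wcs).pi_hat
        pi_by_chrom = {}
        for c, w in wcs.items():
            if w.n_valid and w.counts[w.valid].sum() > 0:
                pi_by_chrom[c] = snp_density(w).pi_hat
        return cls(pooled, pi, config=cfg, per_chrom=by_chrom, pi_by_chrom=pi_by_chrom)

    @classmethod
    def from_multihetsep(cls, paths, config: Optional[PipelineConfig] = None, **overrides):
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = [paths]
        stream = VariantStream.concatenate([read_multihetsep(p) for p in paths])
        return cls.from_variant_stream(stream, config=config, **overrides)

    # -- fitting -------------------------------------------------------
    @property
    def scales(self) -> List[int]:
        return list(self.histograms)

    def estimate_curve(self, z_grid: Optional[np.ndarray] = None):
        """Multiscale Laplace-curve estimation without the inversion step."""
        cfg = self.config
        return estimate_laplace_curve(
            self.histograms, self.pi_hat, z_grid=z_grid,
            z_span=cfg.z_span, z_count=cfg.z_count,
            rel_err_threshold=cfg.rel_err_threshold,
            retention_sigma=cfg.retention_sigma,
        )

    def fit(
        self,
        form: Optional[str] = None,
        seed: Optional[int] = None,
        z_grid: Optional[np.ndarray] = None,
    ) -> "CoalescentWindowResults":
        """Estimate the transform, invert it, and return the results object."""
        cfg = self.config
        form = form or cfg.form
        seed = cfg.seed if seed is None else seed
        curve, fits = self.estimate_curve(z_grid=z_grid)
        if form == "gamma_mixture":
            dist = fit_gamma_mixture(
                curve, allow_point_mass=cfg.allow_point_mass,
                restarts=cfg.restarts, seed=seed,
            )
        else:
            dist = fit_piecewise_exponential(
                curve, penalty_weight=cfg.penalty_weight, seed=seed,
            )
        return CoalescentWindowResults(
            model=self, curve=curve, richards_fits=fits,
            distribution=dist, form=form, seed=seed,
        )

    def richards_by_chromosome(self, z_grid: Optional[np.ndarray] = None):
        """Per-chromosome sigmoid fits on a shared z grid (for rate comparisons)."""
        if not self.per_chrom:
            raise ValueError("model was not built with per-chromosome histograms")
        cfg = self.config
        if z_grid is None:
            scales = self.scales
            z_grid = choose_z_grid(self.pi_hat, scales[0], scales[-1], span=cfg.z_span, count=cfg.z_count)
        out: Dict[str, List[RichardsFit]] = {}
        for c, hists in self.per_chrom.items():
            pi_c = (self.pi_by_chrom or {}).get(c, self.pi_hat)
            if not hists or pi_c <= 0:
                continue
            try:
                _, fits = estimate_laplace_curve(
                    hists, pi_c, z_grid=z_grid,
                    rel_err_threshold=cfg.rel_err_threshold,
                    retention_sigma=cfg.retention_sigma,
                )
            except ValueError:
                fits = []
            if fits:
                out[c] = fits
        return out


@dataclass
class CoalescentWindowResults:
    """Fitted coalescence-time distribution with uncertainties and diagnostics."""

    model: CoalescentWindowModel
    curve: LaplaceCurve
    richards_fits: List[RichardsFit]
    distribution: object
    form: str
    seed: int

    # -- predictions ---------------------------------------------------
    def laplace(self, z):
        """Transform of the fitted distribution at z (mutation-scaled argument)."""
        return self.distribution.laplace(z)

    def pdf(self, t):
        return self.distribution.pdf(t)

    def cdf(self, t):
        return self.distribution.cdf(t)

    @property
    def scaled_error(self) -> float:
        return float(self.distribution.scaled_error)

    @property
    def mean_tau(self) -> float:
        return self.distribution.mean()

    # -- derived quantities ---------------------------------------------
    def ne_trajectory(self, mu: Optional[float] = None):
        return ne_trajectory(self.distribution, mu=mu)

    def ibd_survival(self, mu: float, ghost_correction: bool = False) -> IBDSurvival:
        return IBDSurvival(self.distribution, mu, ghost_correction)

    def ks_distance(self, times, weights=None) -> float:
        return ks_distance(self.cdf, times, weights=weights)

    def transform_residuals(self) -> np.ndarray:
        """(fit - estimate)/sigma at the retained z values."""
        model = np.asarray(self.distribution.laplace(self.curve.z), dtype=float)
        return (model - self.curve.values) / self.curve.sigma

    # -- reporting -------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "J": int(self.curve.J),
            "pi_hat": self.model.pi_hat,
            "scaled_error": self.scaled_error,
            "config_hash": self.model.config.hash,
        }
        if isinstance(self.distribution, PiecewiseExponential):
            d["knots"] = self.distribution.times.tolist()
            d["rates"] = self.distribution.rates.tolist()
        else:
            gm: GammaMixture = self.distribution
            d["parameters"] = {
                "weights": gm.weights.tolist(),
                "shapes": gm.shapes.tolist(),
                "scales": gm.scales.tolist(),
                "point_mass": gm.w0,
            }
        return d

    def summary(self) -> str:
        c = self.curve
        lines = [
            "Coalescence-time distribution from windowed diversity",
            "=" * 56,
            f"statistic:            {self.model.config.stat}",
            f"window scales:        {self.model.scales[0]} .. {self.model.scales[-1]} bp"
            f" ({len(self.model.scales)} scales)",
            f"SNP density pi_hat:   {self.model.pi_hat:.4g} per base",
            f"retained z points:    J = {c.J}  (z in [{c.z[0]:.3g}, {c.z[-1]:.3g}])",
            f"inversion form:       {self.form}",
            f"scaled squared error: {self.scaled_error:.4g}",
            f"mean tau (= mu*T):    {self.mean_tau:.4g}",
        ]
        if isinstance(self.distribution, PiecewiseExponential):
            t, ne = self.ne_trajectory()
            lines.append("piecewise hazard (tau units):")
            for ti, ci in zip(t, 1.0 / ne):
                lines.append(f"  t >= {ti:.4g}: rate {ci:.4g}")
        else:
            gm = self.distribution
            lines.append(f"gamma mixture ({gm.n_components} components, point mass {gm.w0:.3g}):")
            for a, k, th in zip(gm.weights, gm.shapes, gm.scales):
                lines.append(f"  weight {a:.3f}  shape {k:.3g}  scale {th:.4g}")
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------
    def plot_laplace(self, ax=None):
        """Estimated transform points with errors and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.errorbar(c.z, c.values, yerr=c.sigma, fmt="o", ms=4, label="estimated")
        zz = np.geomspace(c.z[0], c.z[-1], 200)
        ax.plot(zz, self.laplace(zz), "-", label=f"fitted ({self.form})")
        ax.set_xscale("log")
        ax.set_xlabel("z")
        ax.set_ylabel("Laplace transform of tau")
        ax.legend()
        return ax

    def plot_cdf(self, ax=None, truth_times=None, truth_weights=None):
        """Fitted CDF on a log-time grid, optionally with an empirical truth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.geomspace(1.0 / (2 * self.curve.z[-1]), 20.0 / self.curve.z[0], 400)
        ax.plot(t, self.cdf(t), label=f"fitted ({self.form})")
        if truth_times is not None:
            ts = np.sort(np.asarray(truth_times, dtype=float))
            if truth_weights is None:
                ecdf = np.arange(1, ts.size + 1) / ts.size
            else:
                w = np.asarray(truth_weights, dtype=float)[np.argsort(truth_times)]
                ecdf = np.cumsum(w) / w.sum()
            ax.plot(ts, ecdf, "k--", label="empirical")
        ax.set_xscale("log")
        ax.set_xlabel("tau = mu*T")
        ax.set_ylabel("CDF")
        ax.legend()
        return ax
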