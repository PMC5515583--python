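"""Windowed SNP counts across a hierarchy of length scales.

The genome is tiled with half-open windows ``[k*L, (k+1)*L)`` in 0-based
coordinates, starting at 0 on every chromosome. Counts at the base scale
are corrected for uneven sequencing coverage (windows below a coverage
floor are dropped, windows above it are binomially thinned to the floor),
then adjacent windows are merged pairwise to produce counts at scales
``L0, 2*L0, 4*L0, ...``. A merged window is valid only if both halves are
valid, which preserves the thinned-coverage guarantee at every scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np

from .branches import BranchClassSpec, select_sites
from .multihetsep import VariantStream

__all__ = [
    "WindowCounts",
    "CountHistogram",
    "base_window_counts",
    "merge_adjacent",
    "histogram",
    "count_pyramid",
]


@dataclass
class WindowCounts:
    """Per-window selected-SNP counts at one window length on one chromosome."""

    L: int
    counts: np.ndarray
    valid: np.ndarray
    chrom: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.counts.shape != self.valid.shape:
            raise ValueError("counts and valid flags must be parallel")
        if np.any(self.counts < 0):
            raise ValueError("negative SNP count")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class CountHistogram:
    """Empirical distribution of SNP counts per valid window at one scale.

    ``n_values`` are the observed counts (sorted), ``k_n`` the number of
    valid windows showing each count; ``K`` is the total number of valid
    windows and ``K0`` the number with zero SNPs.
    """

    L: int
    n_values: np.ndarray
    k_n: np.ndarray
    K: int
    K0: int

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values, dtype=np.int64)
        self.k_n = np.asarray(self.k_n, dtype=np.int64)
        if self.k_n.sum() != self.K:
            raise ValueError("histogram counts do not sum to K")
        if self.K < 1:
            raise ValueError("histogram needs at least one valid window")

    @property
    def freq(self) -> dict:
        return dict(zip(self.n_values.tolist(), self.k_n.tolist()))

    @property
    def weights(self) -> np.ndarray:
        return self.k_n / self.K

    @property
    def total_snps(self) -> int:
        return int(np.dot(self.n_values, self.k_n))


def _window_coverage(sub: VariantStream, L: int, n_windows: int) -> np.ndarray:
    """Fraction of called sites per window, reconstructed from called_since_last.

    The called sites attributed to each record are spread uniformly over
    the gap interval ``(prev_pos, pos]`` since their exact locations are
    not recorded in the format.
    """
    if len(sub) == 0:
        return np.zeros(n_windows)
    ends = sub.pos.astype(float)
    starts = np.concatenate(([0.0], ends[:-1]))
    gaps = ends - starts
    called = np.minimum(sub.called.astype(float), gaps)  # cannot exceed the gap
    density = called / gaps
    # cumulative called sites at the record ends
    cum_end = np.cumsum(called)
    cum_start = cum_end - called
    edges = np.arange(n_windows + 1, dtype=float) * L
    idx = np.searchsorted(ends, edges, side="left")
    C = np.empty_like(edges)
    inside = idx < len(ends)
    C[~inside] = cum_end[-1]
    ii = idx[inside]
    frac = np.clip(edges[inside] - starts[ii], 0.0, None) * density[ii]
    C[inside] = cum_start[ii] + np.minimum(frac, called[ii])
    return np.diff(C) / L


def base_window_counts(
    stream: VariantStream,
    selector: BranchClassSpec,
    L0: int = 80,
    coverage_floor: float = 0.8,
    seed: int = 0,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> Dict[str, WindowCounts]:
    """Base-scale window counts for every chromosome in the stream.

    Windows whose reconstructed called-site fraction is below
    ``coverage_floor`` are flagged invalid; windows above it have their
    SNP counts binomially thinned so that the effective coverage equals
    the floor exactly (seeded).
    """
    if L0 < 1:
        raise ValueError("L0 must be >= 1")
    if not (0 < coverage_floor <= 1):
        raise ValueError(f"coverage_floor={coverage_floor} outside (0, 1]")
    rng = np.random.default_rng(seed)
    out: Dict[str, WindowCounts] = {}
    mask = select_sites(stream, selector)
    for name, sub in stream.by_chromosome():
        sel = mask[stream.chrom == name]
        extent = int(chrom_lengths[name]) if chrom_lengths and name in chrom_lengths else int(sub.pos[-1])
        n_windows = extent // L0
        if n_windows == 0:
            continue
        counts = np.bincount((sub.pos[sel] - 1) // L0, minlength=n_windows)[:n_windows]
        cov = _window_coverage(sub, L0, n_windows)
        valid = cov >= coverage_floor - 1e-9
        # thin windows whose coverage exceeds the floor
        p = np.where(cov > 0, np.clip(coverage_floor / np.maximum(cov, 1e-12), 0.0, 1.0), 1.0)
        thin = valid & (p < 1.0) & (counts > 0)
        if thin.any():
            counts = counts.copy()
            counts[thin] = rng.binomial(counts[thin], p[thin])
        out[name] = WindowCounts(L=L0, counts=counts.astype(np.int64), valid=valid, chrom=str(name))
    return out


def merge_adjacent(wc: WindowCounts) -> WindowCounts:
    """Merge adjacent window pairs: counts add, validity requires both halves."""
    m = len(wc) // 2
    if m < 1:
        raise ValueError("cannot merge fewer than 2 windows")
    c = wc.counts[: 2 * m].reshape(m, 2).sum(axis=1)
    v = wc.valid[: 2 * m].reshape(m, 2).all(axis=1)
    return WindowCounts(L=2 * wc.L, counts=c, valid=v, chrom=wc.chrom)


def histogram(wc) -> CountHistogram:
    """Tabulate SNP counts over valid windows (single ``WindowCounts`` or pooled)."""
    if isinstance(wc, WindowCounts):
        wcs = [wc]
    elif isinstance(wc, dict):
        wcs = list(wc.values())
    else:
        wcs = list(wc)
    if not wcs:
        raise ValueError("no window counts")
    L = wcs[0].L
    vals = []
    for w in wcs:
        if w.L != L:
            raise ValueError("mixed window lengths in histogram")
        vals.append(w.counts[w.valid])
    v = np.concatenate(vals) if vals else np.array([], dtype=np.int64)
    if v.size == 0:
        raise ValueError("zero valid windows")
    n_values, k_n = np.unique(v, return_counts=True)
    K = int(v.size)
    K0 = int(k_n[0]) if n_values.size and n_values[0] == 0 else 0
    return CountHistogram(L=L, n_values=n_values, k_n=k_n, K=K, K0=K0)


def count_pyramid(
    wcs: Dict[str, WindowCounts],
    min_valid: int = 100,
    per_chromosome: bool = False,
):
    """Pooled count histograms at every power-of-two scale.

    Starting from the base-scale counts, windows are merged pairwise until
    fewer than ``min_valid`` valid windows remain genome-wide. Returns a
    dict ``L -> CountHistogram``; with ``per_chromosome=True`` also returns
    ``chrom -> L -> CountHistogram``.
    """
    if isinstance(wcs, WindowCounts):
        wcs = {wcs.chrom or "0": wcs}
    current = dict(wcs)
    pooled: Dict[int, CountHistogram] = {}
    by_chrom: Dict[str, Dict[int, CountHistogram]] = {c: {} for c in current}
    while True:
        n_valid = sum(w.n_valid for w in current.values())
        if n_valid < max(min_valid, 1):
            break
        L = next(iter(current.values())).L
        pooled[L] = histogram(current)
        if per_chromosome:
            for c, w in current.items():
                if w.n_valid > 0:
                    by_chrom[c][L] = histogram(w)
        nxt = {c: merge_adjacent(w) for c, w in current.items() if len(w) >= 2}
        if not nxt:
            break
        current = nxt
    if not pooled:
        raise ValueError(f"fewer than {min_valid} valid windows at the base scale")
    if per_chromosome:
        return pooled, by_chrom
    return pooled
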