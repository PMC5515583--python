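"""Branch-class filtering of segregating sites.

For samples larger than a pair, the distribution of any single tree
statistic (total branch length, tip lengths, lengths of branches ancestral
to a given number of leaves) is inferred by first filtering the variant
stream for mutations that fall on the corresponding branches, then running
the same windowed analysis as for pairwise data. All site classes here are
*folded*: the ancestral state is taken as unknown, so a site's class is its
minor-allele count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .multihetsep import VariantStream

__all__ = ["BranchClassSpec", "DensityEstimate", "site_passes", "select_sites", "snp_density"]

PAIRWISE = "pairwise"
TOTAL = "total"
TIP = "tip"
FREQUENCY_CLASS = "class"


@dataclass(frozen=True)
class BranchClassSpec:
    """Which coalescent-tree branches a site class measures.

    mode: one of ``total``, ``pairwise``, ``tip``, ``class``.
    For ``pairwise``, ``i``/``j`` are haplotype indices; for ``tip``,
    ``i`` is the haplotype index; for ``class``, ``k`` is the folded
    minor-allele count and ``n`` the sample size (1 <= k <= n//2).
    """

    mode: str
    i: Optional[int] = None
    j: Optional[int] = None
    k: Optional[int] = None
    n: Optional[int] = None

    def __post_init__(self):
        if self.mode not in (PAIRWISE, TOTAL, TIP, FREQUENCY_CLASS):
            raise ValueError(f"unknown branch-class mode {self.mode!r}")
        if self.mode == PAIRWISE and (self.i is None or self.j is None or self.i == self.j):
            raise ValueError("pairwise spec needs two distinct haplotype indices")
        if self.mode == TIP and self.i is None:
            raise ValueError("tip spec needs a haplotype index")
        if self.mode == FREQUENCY_CLASS:
            if self.k is None or self.n is None:
                raise ValueError("frequency-class spec needs k and n")
            if not (1 <= self.k <= self.n // 2):
                raise ValueError(f"folded class k={self.k} outside 1..{self.n // 2}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def total() -> "BranchClassSpec":
        return BranchClassSpec(TOTAL)

    @staticmethod
    def pairwise(i: int = 0, j: int = 1) -> "BranchClassSpec":
        return BranchClassSpec(PAIRWISE, i=i, j=j)

    @staticmethod
    def tip(i: int) -> "BranchClassSpec":
        return BranchClassSpec(TIP, i=i)

    @staticmethod
    def frequency_class(k: int, n: int) -> "BranchClassSpec":
        return BranchClassSpec(FREQUENCY_CLASS, k=k, n=n)

    @staticmethod
    def parse(text: str) -> "BranchClassSpec":
        """Parse CLI syntax: ``pairwise``, ``total``, ``tip:<i>``, ``class:<k>:<n>``."""
        parts = text.split(":")
        if parts[0] == PAIRWISE:
            if len(parts) == 3:
                return BranchClassSpec.pairwise(int(parts[1]), int(parts[2]))
            return BranchClassSpec.pairwise()
        if parts[0] == TOTAL:
            return BranchClassSpec.total()
        if parts[0] == TIP and len(parts) == 2:
            return BranchClassSpec.tip(int(parts[1]))
        if parts[0] == FREQUENCY_CLASS and len(parts) == 3:
            return BranchClassSpec.frequency_class(int(parts[1]), int(parts[2]))
        raise ValueError(f"cannot parse branch-class spec {text!r}")

    def __str__(self) -> str:
        if self.mode == PAIRWISE:
            return f"pairwise:{self.i}:{self.j}"
        if self.mode == TIP:
            return f"tip:{self.i}"
        if self.mode == FREQUENCY_CLASS:
            return f"class:{self.k}:{self.n}"
        return self.mode


@dataclass
class DensityEstimate:
    """Genomic density of selected SNPs per base (pi-hat) and the called length it refers to."""

    pi_hat: float
    total_called: float

    def __post_init__(self):
        if not (0 <= self.pi_hat < 1):
            raise ValueError(f"pi_hat={self.pi_hat} outside [0, 1)")


def site_passes(alleles: str, spec: BranchClassSpec) -> bool:
    """Does a site (given its per-haplotype allele string) fall in the branch class?

    Monomorphic sites never pass. Multi-allelic sites count as segregating
    for TOTAL but are excluded from the frequency-based classes, where the
    folded minor count is ambiguous under infinite sites.
    """
    counts = Counter(alleles)
    if len(counts) < 2:
        return False
    if spec.mode == TOTAL:
        return True
    if spec.mode == PAIRWISE:
        return alleles[spec.i] != alleles[spec.j]
    if len(counts) > 2:
        return False
    minor = min(counts.values())
    if spec.mode == TIP:
        if minor != 1:
            return False
        return counts[alleles[spec.i]] == 1
    # frequency class, folded
    return minor == spec.k


def select_sites(stream: VariantStream, spec: BranchClassSpec) -> np.ndarray:
    """Boolean mask over the stream's records for the branch class."""
    cache: dict = {}
    out = np.empty(len(stream), dtype=bool)
    for idx, a in enumerate(stream.alleles):
        hit = cache.get(a)
        if hit is None:
            hit = cache[a] = site_passes(a, spec)
        out[idx] = hit
    return out


def snp_density(wc) -> DensityEstimate:
    """Selected-SNP density per base from valid windows at one scale.

    Accepts a single ``WindowCounts`` or an iterable of them (pooled over
    chromosomes). This is the heterozygosity for the pairwise statistic and
    the matching branch-class SNP density in general.
    """
    from .windows import WindowCounts  # local import to avoid a cycle

    if isinstance(wc, WindowCounts):
        wcs = [wc]
    elif isinstance(wc, dict):
        wcs = list(wc.values())
    else:
        wcs = list(wc)
    if not wcs:
        raise ValueError("no window counts supplied")
    total = 0
    n_valid = 0
    L = wcs[0].L
    for w in wcs:
        if w.L != L:
            raise ValueError("mixed window lengths in snp_density")
        total += int(w.counts[w.valid].sum())
        n_valid += int(w.valid.sum())
    if n_valid == 0:
        raise ValueError("no valid windows")
    called = float(L) * n_valid
    return DensityEstimate(pi_hat=total / called, total_called=called)
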