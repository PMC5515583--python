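"""Coalescent fixture simulation: single-locus samplers and along-genome genomes.

Demographies are specified ms-style: piecewise-exponential population-size
trajectories with event times in units of 4*N0 generations and growth
rates in units of 1/(4*N0), plus an optional admixture event (a split of
the sampled population followed by a later join). The single-locus
coalescence-time sampler is native (structured Kingman event loop with
closed-form intensity inversion); along-genome simulation with crossover
and gene-conversion recombination delegates to msprime and returns both a
multihetsep variant stream and the ground-truth coalescence-time track.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .branches import BranchClassSpec
from .multihetsep import VariantStream

__all__ = [
    "Epoch",
    "Admixture",
    "Demography",
    "SimConfig",
    "TruthTrack",
    "SimulatedGenome",
    "sample_coalescence_times",
    "simulate_genome",
    "preset_demographies",
    "constant_N_transform",
    "expected_pair_tmrca",
]


@dataclass(frozen=True)
class Epoch:
    """One demographic epoch: from ``start`` (4*N0 units) backwards in time.

    ``growth`` is the ms-style exponential growth rate in 1/(4*N0) units
    (positive growth means the population was smaller further in the
    past); ``size`` optionally resets the relative size at the epoch start.
    """

    start: float
    growth: float = 0.0
    size: Optional[float] = None


@dataclass(frozen=True)
class Admixture:
    """The sampled population splits at ``time`` (each lineage moves to a
    second population with probability ``fraction``) and the two join again
    at ``join_time``, all in 4*N0 units backwards in time."""

    time: float
    fraction: float
    join_time: float


@dataclass
class Demography:
    epochs: List[Epoch] = field(default_factory=lambda: [Epoch(0.0)])
    admixture: Optional[Admixture] = None
    N0: float = 1e4

    def __post_init__(self):
        if not self.epochs or self.epochs[0].start != 0.0:
            self.epochs = [Epoch(0.0, 0.0, 1.0)] + list(self.epochs)
        starts = [e.start for e in self.epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if self.admixture is not None:
            ad = self.admixture
            if not (0 < ad.fraction < 1):
                raise ValueError("admixture fraction must be in (0, 1)")
            if ad.join_time <= ad.time:
                raise ValueError("admixture join must postdate the split")
        if self.epochs[-1].growth < 0:
            raise ValueError("final epoch growth must be >= 0 (coalescence must be certain)")
        self._build_tables()

    def _build_tables(self):
        t, lam, alpha = [], [], []
        cur = 1.0
        prev = None
        for e in self.epochs:
            if prev is not None:
                cur = cur * np.exp(-prev.growth * (e.start - prev.start))
            if e.size is not None:
                cur = float(e.size)
            t.append(e.start)
            lam.append(cur)
            alpha.append(e.growth)
            prev = e
        self._t = np.array(t)
        self._lam = np.array(lam)
        self._alpha = np.array(alpha)
        # cumulative pair-coalescence intensity at epoch starts
        U = [0.0]
        for i in range(len(t) - 1):
            U.append(U[-1] + self._segment_U(i, self._t[i + 1]))
        self._U = np.array(U)

    def _segment_U(self, i: int, t_end: float) -> float:
        dt = t_end - self._t[i]
        if self._alpha[i] == 0.0:
            return 2.0 * dt / self._lam[i]
        return 2.0 * (np.exp(self._alpha[i] * dt) - 1.0) / (self._alpha[i] * self._lam[i])

    def relative_size(self, t) -> np.ndarray:
        """Relative population size N(t)/N0 at time(s) t (4*N0 units, backwards)."""
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self._t, t, side="right") - 1, 0, len(self._t) - 1)
        return self._lam[i] * np.exp(-self._alpha[i] * (t - self._t[i]))

    def pair_intensity(self, t) -> np.ndarray:
        """Cumulative pairwise coalescence intensity U(t) = int_0^t 2/lambda."""
        t = np.asarray(t, dtype=float)
        i = np.clip(np.searchsorted(self._t, t, side="right") - 1, 0, len(self._t) - 1)
        dt = t - self._t[i]
        a, lam = self._alpha[i], self._lam[i]
        with np.errstate(over="ignore"):
            seg = np.where(a == 0.0, 2.0 * dt / lam, 2.0 * (np.exp(a * dt) - 1.0) / np.where(a == 0.0, 1.0, a * lam))
        return self._U[i] + seg

    def invert_pair_intensity(self, u) -> np.ndarray:
        """t such that U(t) = u (vectorized closed-form inversion)."""
        u = np.asarray(u, dtype=float)
        i = np.clip(np.searchsorted(self._U, u, side="right") - 1, 0, len(self._t) - 1)
        rem = u - self._U[i]
        a, lam = self._alpha[i], self._lam[i]
        with np.errstate(invalid="ignore"):
            dt = np.where(a == 0.0, rem * lam / 2.0, np.log1p(rem * np.where(a == 0.0, 1.0, a) * lam / 2.0) / np.where(a == 0.0, 1.0, a))
        return self._t[i] + dt


def preset_demographies(N0: float = 1e4) -> Dict[str, Demography]:
    """The three ms-style benchmark demographies.

    ``bottleneck``: growth +10 from t=0.3, -10 from 0.4, 0 from 0.6;
    ``repeated_bottlenecks``: alternating -/+10 switches at
    0.1, 0.3, 0.5, 0.7, 0.9, 1.1; ``admixture``: a 50/50 split of the
    sampled population at t=0.1 rejoining at t=2. Times in 4*N0 units.
    """
    return {
        "bottleneck": Demography(
            epochs=[Epoch(0.3, 10.0), Epoch(0.4, -10.0), Epoch(0.6, 0.0)], N0=N0
        ),
        "repeated_bottlenecks": Demography(
            epochs=[
                Epoch(0.1, -10.0), Epoch(0.3, 10.0), Epoch(0.5, -10.0),
                Epoch(0.7, 10.0), Epoch(0.9, -10.0), Epoch(1.1, 10.0),
            ],
            N0=N0,
        ),
        "admixture": Demography(
            epochs=[], admixture=Admixture(time=0.1, fraction=0.5, join_time=2.0), N0=N0
        ),
    }


def constant_N_transform(theta: float, z) -> np.ndarray:
    """Analytic pairwise transform 1/(1 + theta*z) under constant size, theta = 4*N0*mu."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return 1.0 / (1.0 + theta * np.asarray(z, dtype=float))


def expected_pair_tmrca(dem: Demography, tail_tol: float = 1e-12) -> float:
    """E[pairwise TMRCA] in 4*N0 units, by quadrature of the survival function."""
    from scipy.integrate import quad

    t_hi = float(dem.invert_pair_intensity(-np.log(tail_tol)))
    pieces = [t for t in dem._t if 0.0 < t < t_hi] + [t_hi]
    total, lo = 0.0, 0.0
    for hi in pieces:
        val, _ = quad(lambda t: np.exp(-dem.pair_intensity(t)), lo, hi, limit=200)
        total += val
        lo = hi
    return total


# ---------------------------------------------------------------------------
# single-locus sampling


def _pairwise_times_fast(dem: Demography, n_reps: int, rng) -> np.ndarray:
    return dem.invert_pair_intensity(rng.exponential(size=n_reps))


def _sample_tree_statistic(dem: Demography, spec: BranchClassSpec, n: int, rng) -> float:
    """One realization of the branch statistic via a structured Kingman event loop.

    All populations share the size trajectory (true for the presets); the
    admixture event only gates which lineage pairs may coalesce.
    """
    ad = dem.admixture
    breaks = sorted([ad.time, ad.join_time]) if ad else []
    # lineages: (leafmask, pop)
    lineages = [(1 << i, 0) for i in range(n)]
    t = 0.0
    total = 0.0
    pair_mask = (1 << spec.i) | (1 << spec.j) if spec.mode == "pairwise" else 0
    fold = {spec.k, spec.n - spec.k} if spec.mode == "class" else None

    def class_count() -> int:
        if spec.mode == "total":
            return len(lineages)
        if spec.mode == "tip":
            return sum(1 for m, _ in lineages if m == (1 << spec.i))
        if spec.mode == "class":
            return sum(1 for m, _ in lineages if bin(m).count("1") in fold)
        return 0  # pairwise handled via TMRCA

    while len(lineages) > 1:
        pops = {}
        for _, p in lineages:
            pops[p] = pops.get(p, 0) + 1
        R = sum(k * (k - 1) / 2.0 for k in pops.values())
        if R == 0.0:
            t_next = next(b for b in breaks if b > t)
        else:
            u_target = dem.pair_intensity(t) + rng.exponential() / R
            t_next = float(dem.invert_pair_intensity(u_target))
            pending = [b for b in breaks if t < b < t_next]
            if pending:
                t_next = pending[0]
                R = 0.0  # event is the demographic break, not a coalescence
        dt = t_next - t
        total += class_count() * dt
        t = t_next
        if R == 0.0:
            if ad and t == ad.time:
                lineages = [(m, 1 if rng.random() < ad.fraction else 0) for m, _ in lineages]
            elif ad and t == ad.join_time:
                lineages = [(m, 0) for m, _ in lineages]
            continue
        # choose a population weighted by its pair count, then a uniform pair
        keys = list(pops)
        w = np.array([pops[k] * (pops[k] - 1) / 2.0 for k in keys])
        pop = keys[rng.choice(len(keys), p=w / w.sum())]
        idx = [i for i, (_, p) in enumerate(lineages) if p == pop]
        i1, i2 = rng.choice(len(idx), size=2, replace=False)
        a, b = lineages[idx[i1]], lineages[idx[i2]]
        merged = (a[0] | b[0], pop)
        lineages = [l for k, l in enumerate(lineages) if k not in (idx[i1], idx[i2])]
        lineages.append(merged)
        if spec.mode == "pairwise" and (merged[0] & pair_mask) == pair_mask:
            # the two target haplotypes first share a lineage: T = 2 * TMRCA(i, j)
            return 2.0 * t
    return total if spec.mode != "pairwise" else 2.0 * t


def sample_coalescence_times(
    dem: Demography,
    statistic: BranchClassSpec = None,
    n_reps: int = 1,
    seed: int = 0,
    sample_size: int = 2,
    theta: Optional[float] = None,
) -> np.ndarray:
    """Single-locus branch-statistic lengths under the demography.

    Returns the statistic in units of 4*N0 generations: for the pairwise
    statistic this is the total branch length T = 2*TMRCA of the pair.
    With ``theta`` (= 4*N0*mu) given, returns instead the mutation-scaled
    times tau = theta * T.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if statistic is None:
        statistic = BranchClassSpec.pairwise()
    rng = np.random.default_rng(seed)
    if statistic.mode == "pairwise" and dem.admixture is None:
        out = 2.0 * _pairwise_times_fast(dem, n_reps, rng)
    else:
        n = sample_size
        if statistic.mode == "class" and statistic.n != n:
            n = statistic.n
        out = np.array([_sample_tree_statistic(dem, statistic, n, rng) for _ in range(n_reps)])
    if theta is not None:
        return theta * out
    return out


# ---------------------------------------------------------------------------
# along-genome simulation (msprime)


@dataclass
class SimConfig:
    """Along-genome simulation settings (per-base, per-generation rates)."""

    mu: float
    rho: float = 0.0
    g: float = 0.0
    lam: float = 200.0
    chrom_len: int = 1_000_000
    n_chrom: int = 1
    sample_size: int = 2
    seed: int = 0
    coverage: float = 1.0

    def __post_init__(self):
        if min(self.mu, self.rho, self.g) < 0:
            raise ValueError("rates must be nonnegative")
        if self.g > 0 and self.lam <= 0:
            raise ValueError("gene conversion needs a positive mean tract length")
        if self.chrom_len < 1:
            raise ValueError("chrom_len must be >= 1")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")


@dataclass
class TruthTrack:
    """Ground-truth branch statistic along one chromosome (generations)."""

    chrom: str
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def tau(self, mu: float) -> np.ndarray:
        return mu * self.value

    @property
    def lengths(self) -> np.ndarray:
        return self.right - self.left


@dataclass
class SimulatedGenome:
    stream: VariantStream
    truth: Dict[str, TruthTrack]
    config: SimConfig
    demography: Demography
    n_tree_changes: int = 0

    def truth_times_weights(self, mu: Optional[float] = None):
        """Pooled ground-truth statistic values with base-span weights."""
        vals = np.concatenate([t.value for t in self.truth.values()])
        w = np.concatenate([t.lengths for t in self.truth.values()])
        if mu is not None:
            vals = mu * vals
        return vals, w

    def expected_tree_recombination_events(self) -> float:
        """Expected recombination events on the local trees: rho * sum(span * T).

        For a Kingman pairwise sample about 2/3 of these change the tree;
        the rest are "ghost" events, so the ratio of observed breakpoints
        (``n_tree_changes``) to this quantity tests that scaling.
        """
        return self.config.rho * sum(float(np.dot(t.lengths, t.value)) for t in self.truth.values())


def _to_msprime(dem: Demography):
    import msprime

    D = msprime.Demography()
    g4 = 4.0 * dem.N0
    # ploidy-1 sampling: sizes of 2*N0*lambda reproduce the ms pair rate 1/(2*N0*lambda)
    D.add_population(name="A", initial_size=2.0 * dem.N0 * dem._lam[0],
                     growth_rate=dem._alpha[0] / g4)
    if dem.admixture is not None:
        D.add_population(name="B", initial_size=2.0 * dem.N0)
    for i in range(1, len(dem._t)):
        D.add_population_parameters_change(
            time=dem._t[i] * g4,
            population="A",
            initial_size=2.0 * dem.N0 * dem._lam[i],
            growth_rate=dem._alpha[i] / g4,
        )
    if dem.admixture is not None:
        ad = dem.admixture
        D.add_mass_migration(time=ad.time * g4, source="A", dest="B", proportion=ad.fraction)
        D.add_mass_migration(time=ad.join_time * g4, source="A", dest="B", proportion=1.0)
    D.sort_events()
    return D


def branch_statistic(tree, spec: BranchClassSpec, n: int) -> float:
    """Branch-class total length (generations) on one local tree."""
    if spec.mode == "total":
        return tree.total_branch_length
    if spec.mode == "pairwise":
        return 2.0 * tree.tmrca(spec.i, spec.j)
    if spec.mode == "tip":
        return tree.branch_length(spec.i)
    fold = {spec.k, n - spec.k}
    return sum(tree.branch_length(u) for u in tree.nodes() if tree.num_samples(u) in fold)


def simulate_genome(
    dem: Demography,
    cfg: SimConfig,
    statistic: BranchClassSpec = None,
) -> SimulatedGenome:
    """Simulate multihetsep data plus the ground-truth statistic track.

    Chromosomes are independent replicates. Mutations are Poisson at rate
    mu per base per generation on the local tree; crossovers at rate rho
    and gene-conversion tracts (geometric, mean lam) at initiation rate g.
    The number of tree-changing breakpoints is recorded so tree-preserving
    "ghost" recombination can be quantified against
    :meth:`SimulatedGenome.expected_tree_recombination_events`.
    """
    import msprime

    if statistic is None:
        statistic = BranchClassSpec.total() if cfg.sample_size != 2 else BranchClassSpec.pairwise()
    D = _to_msprime(dem)
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, calleds, alleles = [], [], [], []
    truth: Dict[str, TruthTrack] = {}
    n_changes = 0
    for ci in range(cfg.n_chrom):
        name = str(ci + 1)
        s_anc, s_mut = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
        kwargs = dict(
            samples={"A": cfg.sample_size},
            ploidy=1,
            demography=D,
            sequence_length=cfg.chrom_len,
            recombination_rate=cfg.rho,
            random_seed=s_anc,
        )
        if cfg.g > 0:
            kwargs["gene_conversion_rate"] = cfg.g
            kwargs["gene_conversion_tract_length"] = cfg.lam
        ts = msprime.sim_ancestry(**kwargs)
        n_changes += ts.num_trees - 1
        mts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=s_mut)
        left, right, value = [], [], []
        for tree in ts.trees():
            left.append(tree.interval.left)
            right.append(tree.interval.right)
            value.append(branch_statistic(tree, statistic, cfg.sample_size))
        truth[name] = TruthTrack(
            chrom=name,
            left=np.array(left),
            right=np.array(right),
            value=np.array(value),
        )
        prev = 0
        for var in mts.variants():
            astr = "".join(var.alleles[g] for g in var.genotypes)
            if len(set(astr)) < 2:
                continue
            pos = int(var.site.position) + 1  # 1-based
            if pos <= prev:
                continue
            if cfg.coverage < 1.0 and rng.random() > cfg.coverage:
                continue
            gap = pos - prev
            called = gap if cfg.coverage >= 1.0 else 1 + int(rng.binomial(gap - 1, cfg.coverage))
            chroms.append(name)
            positions.append(pos)
            calleds.append(called)
            alleles.append(astr)
            prev = pos
    stream = VariantStream(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(calleds, dtype=np.int64),
        np.array(alleles, dtype=object),
    )
    return SimulatedGenome(
        stream=stream,
        truth=truth,
        config=cfg,
        demography=dem,
        n_tree_changes=n_changes,
    )
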