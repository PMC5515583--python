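# Methods

## Model

Let T(x) be the local coalescence statistic at genome position x — for a
diploid pair the total branch length of the local tree (twice the TMRCA),
and in general the total length of a chosen class of coalescent-tree
branches. Windows of length L have window-averaged times
T_L = (1/L) Σ T(x) and, under the infinite-sites assumption with per-base
per-generation mutation rate μ, SNP counts that are Poisson with mean
τ_L = μ·L·T_L. The genome-wide SNP-count histogram at scale L is therefore
a Poisson mixture whose mixing distribution is the distribution of τ_L.

The estimand is the Laplace transform of the *single-locus* scaled time,
p̃_τ(z) = ⟨e^{−zτ}⟩, which is model-free: it requires no assumption about
recombination, demography, or selection. Its interpretation is the
homozygosity the sample would show if the mutation rate were multiplied by
z, so large z probes recent coalescence and small z ancient coalescence.

### Plug-in transform and its error

For a histogram {Kₙ} with K valid windows, E[(1−z)ⁿ | τ] = e^{−zτ} gives
the unbiased plug-in estimator p̃̂(z) = Σₙ (Kₙ/K)(1−z)ⁿ. Its variance from
mutation stochasticity alone is (1/K)·E[e^{−z(2−z)τ} − e^{−2zτ}],
evaluated under a per-window estimate of τ given the observed count. The
default estimator is the Robbins empirical-Bayes rule
τ̂(n) = (n+1)·K_{n+1}/Kₙ — the exact posterior mean for a Poisson mixture,
plugged in from the ensemble — monotonized and capped at n, with a
fallback where histogram cells are too sparse (Kₙ < 5 or K_{n+1} = 0):
τ̂(n) = n·(1−1/(n+Kₙ+1)) for n ≥ 1 and τ̂(0) = ln2/K₀, the largest τ
consistent at even odds with K₀ windows showing no mutations. The choice
matters: with the fallback rule alone the error model underestimates the
true mutational replication SD by 30–50% when most windows carry zero or
one SNP (exactly the base-scale regime), while the Robbins rule tracks it
within ~10%; both are exposed behind a `shrinkage=` argument. For
|1−z| > 1 the alternating sum is accumulated in
signed log space; overflow yields ±inf, which downstream screening removes
via the relative-error threshold. Negative variances from rounding are
clipped to zero.

### Multiscale combination

At fixed z, p̃_{τL}(z/L) = ⟨e^{−zμT_L}⟩ is flat in L in both limits: as
L→1 it approaches p̃_τ(z), and for windows much longer than the typical
recombination block it approaches e^{−π̂z}, with π̂ the genomic density of
selected SNPs. We fit a Richards sigmoid in u = log L,
a + (b−a)·(1+(L/Lx)^{−c})^{−1/ν}, with b fixed at e^{−π̂z}, by weighted
least squares (weights 1/σ²) over points whose relative standard error is
below 0.1 (configurable). The fit is multi-modal in (c, ν, Lx), so the
optimizer multi-starts with the transition initialized at every data
length. Standard errors come from the whitened-Jacobian covariance,
treating errors at different L as independent — not strictly true, but the
scales share few mutations and the resulting bars have the right
magnitude on simulations.

An asymptote is *trusted* only when it lies within 3 combined standard
errors of the lowest usable-length data point, i.e. when the data actually
reach the asymptotic regime rather than extrapolating the functional form.
Retained values are forced nonincreasing in z by dropping points against
the running minimum — a true transform is completely monotone, so
violations are estimation noise.

The z grid is log-uniform with π̂·z spanning [10⁻², 10³] (32 points by
default), capped above by the largest window scale, since the plug-in
estimator is only accurate for arguments near one.

### Inversion

Laplace inversion from noisy point estimates is ill-posed, so the curve is
fitted with a parametric family with closed-form transform, minimizing
Σⱼ (model(zⱼ) − p̃̂(zⱼ))²/σⱼ²:

- **Gamma mixture** with ⌊(J+1)/3⌋ components (J retained points), weights
  via softmax, shapes and scales in log space; optional point mass at 0
  (off by default; relevant for folded frequency classes k of n with
  n > k > 3, where some trees have no matching branch — when enabled,
  component timescales are bounded below by the resolvable range so the
  atom, not a vanishing-scale component, absorbs the constant tail).
  Shapes are capped at 20: without the cap the optimizer can fit the
  transform equally well with near-delta components whose spiky density
  is an inversion artifact — the cap is the mixture's counterpart of the
  piecewise form's smoothness penalty. Optimized with 50 seeded random
  restarts (perturbation 0.5 in log-parameter space) around a
  quantile-spread initialization, each refined by bounded trust-region
  least squares — a basin-hopping-style best-of-many-local-minima search.
- **Piecewise exponential**: knots fixed log-uniformly between 1/(2z_J)
  and 1/z*, where z* is the retained z with value closest to 0.95 (the
  smallest z if all values are below 0.95); rates optimized with a
  quadratic penalty on log(c_{i+1}/c_i), default weight 1.0. The hazard
  c_i is the instantaneous coalescence rate, so for pairwise data
  Ne(t) = 1/(4μ·c_i) at t = τ/(2μ) TMRCA-generations.

Both families are evaluated with complex-step-differentiable code, so
transform derivatives (needed for IBD block lengths and means) are exact
to machine precision.

The two forms fitted to the same curve give similar CDFs where the data
constrain them; the piecewise form is better behaved in the tails and is
the default. Both, like any regularized estimator here, smooth sharp
demographic transitions.

### Derived quantities

- **IBD block lengths.** Under neutral coalescence with crossover
  recombination, P(r_block > r) = p̃_T′(r)/p̃_T′(0) with r in Morgans. An
  optional flag rescales the map rate by 2/3, the Kingman-pairwise
  fraction of recombination events that change the tree (ghost events do
  not end blocks); it is off by default since outside that idealized case
  ghost events must be kept.
- **Relative recombination rates.** Chromosomes sharing a coalescent
  history but differing in crossover rate have horizontally shifted
  transform-versus-window-length curves. The comparable location is the
  sigmoid's midpoint length L_mid = Lx·(2^ν−1)^{−1/c} (invariant to the
  c–ν shape degeneracy, unlike raw Lx). Ratios are averaged over the
  (at most 4) smallest shared z whose transition amplitude exceeds 0.1 —
  small z pin the curve over the widest range of lengths and showed the
  least location bias — with inverse-variance weights. Identifiability
  filters require the midpoint to lie inside the fitted length range.
- **Shape outliers.** Per-fit errors cannot calibrate intrinsic
  per-chromosome coalescent variability, so chromosomes are compared
  robustly: asymptote curves interpolated to a matched π̂·z grid, deviation
  from the cross-chromosome median scaled by the MAD (floored by the fit
  errors), flagged above 5. Requires ≥ 4 chromosomes.
- **Residual-variation (IQR) test.** The observed interquartile range of
  per-chromosome transform values is compared with a null built by
  simulating chromosomes from the genome-wide fitted distribution
  (simulator injected; a Monte-Carlo per-chromosome-mean simulator is
  provided); exceedance above the 97.5th null percentile flags
  more cross-chromosome variation than coalescent chance allows.

## Windowing and coverage

Windows are half-open [kL, (k+1)L) in 0-based coordinates from position 0
of each chromosome; trailing partial windows are dropped. Merging sums
adjacent pairs; a merged window is valid only if both halves are, which
preserves the coverage guarantee at every scale. Scales are powers of two
of L₀ = 80 bp (the human-appropriate default) and stop when fewer than 100
valid windows remain genome-wide.

The multihetsep format records only how many sites since the previous
variant were called, not which; per-window coverage is reconstructed by
spreading those called sites uniformly over the gap. Windows below the
coverage floor (default 80%) are dropped; windows above it have their SNP
counts binomially thinned (seeded) so effective coverage is exactly the
floor — thinning counts is the count-level equivalent of masking sites,
and whether downsampling acts at site or SNP level is configuration-visible.
Note that thinning rescales the effective mutation rate by the floor, so
on fully-called simulated data the analyses here use a floor of 1.
Intermediate results are recomputed rather than cached (they take seconds
at these problem sizes); every output file carries the configuration hash.

## Synthetic data

Demographies are ms-style: piecewise-exponential size trajectories (times
in 4N₀ units, growth rates per 4N₀) plus an optional split/join admixture
event. Three presets encode the benchmark scenarios: a bottleneck (growth
+10 from t=0.3, −10 from 0.4, 0 from 0.6), repeated bottlenecks
(alternating ∓10 at 0.1…1.1), and admixture (50/50 split at 0.1, join at
2). The default rates are 4N₀μ = 10⁻³ with crossovers at ρ = μ/5 and gene
conversion, when enabled, at g = μ/20 with mean tract length 200 bp.

The single-locus sampler is native: a structured Kingman event loop with
closed-form inversion of the pair-coalescence intensity per epoch
(vectorized for pairwise samples without admixture). All populations share
the size trajectory — true for every preset; a structured demography with
per-population sizes is out of scope. Along-genome simulation delegates to
msprime (exact coalescent with recombination, gene conversion, and the
demography mapped to generations), returning the multihetsep stream, the
ground-truth statistic track per tree, and the number of tree-changing
breakpoints; the expected number of on-tree recombination events
ρ·Σ span·T is exposed so the 2/3 tree-changing fraction is testable.
A `coverage` knob emulates missing data by dropping sites and thinning the
called-site counts.

What the generator does *not* emulate: sequencing or SNP-calling error,
mutation-rate and recombination-rate heterogeneity along the genome,
linked selection, and realistic coverage masks (missingness is uniform,
not clustered). Passing tests therefore demonstrate correctness of the
inference machinery under the stated coalescent models, not robustness to
real-data artifacts.

## Problem sizes and numerical choices

The end-to-end recovery check uses 10 chromosomes × 10⁷ bases (10⁸ total,
a scale at which transform inference is reliably stable; single 10⁷-base
runs succeed only sometimes), with KS distance to the ground-truth track
≤ 0.11. The heterozygosity check uses 10⁵ single-locus replicates; the
recombination-rescaling check pairs two 10⁸-base genomes with ρ and 2ρ and
requires the two-fold ratio within 20%. Monte-Carlo unit tests assert
within 3 standard-error bands at fixed seeds. Degenerate inputs are
defined errors: empty histograms, zero polymorphism, fewer than 4 usable
points per sigmoid, all-rejected asymptotes ("no trusted asymptotes"), and
optimizer failure across all restarts raise `ConvergenceError` (CLI exit
code 3); malformed inputs raise `ValueError` (exit code 2).

## Limitations

- The transform is resolvable only for z between roughly 1/π̂·10⁻² and the
  largest usable window scale; very recent coalescence (large z) is
  unreachable when recombination outpaces mutation (ρ ≳ μ), exactly the
  regime where windows mix histories faster than mutations accumulate.
- Inversion is regularized and parametric: sharp Ne(t) transitions are
  smoothed, and tails beyond the constrained z range follow the chosen
  family.
- The gamma-mixture and piecewise forms can differ visibly in weakly
  constrained regions even when both fit the curve; differences there
  should not be over-interpreted.
- Relative-recombination estimates are rough (the sigmoid transition is
  broad) and systematically compressed toward 1 at large z; the
  small-z restriction mitigates but does not remove this.
- Unphased, unpolarized data only; branch classes are folded. Joint
  distributions across branch classes are not inferred.
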