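# wincoal

Coalescence-time distributions from windowed genomic diversity, without an
explicit model of recombination or demography.

## The problem

A sample of genomes is a mosaic of segments with different coalescent
histories. The local coalescence time T(x) (for a diploid pair, twice the
TMRCA at position x) controls the local SNP density, so the genome-wide
*distribution* of coalescence times — the quantity demographic inference
methods ultimately work with — is encoded in how polymorphism density varies
along the genome. Hidden-Markov approaches (PSMC/MSMC-style) decode that
signal with an explicit coalescent-with-recombination model and become
impractical for large samples. `wincoal` instead works directly with SNP
counts in genomic windows across a hierarchy of window lengths:

1. Count selected SNPs in windows of length L₀ (default 80 bp), then merge
   windows pairwise to get counts at L₀, 2L₀, 4L₀, …
2. Under infinite sites, the count in a window is Poisson with mean
   τ_L = μ·L·T_L, where T_L is the window-averaged coalescence time. The
   Laplace transform of τ_L has the plug-in estimator
   p̃̂(z) = Σₙ (Kₙ/K)(1−z)ⁿ over the count histogram {Kₙ}, with an analytic
   standard error.
3. At fixed z, the quantity p̃_{τL}(z/L) = ⟨e^{−zμT_L}⟩ interpolates between
   the single-locus transform (small L) and e^{−π̂z} (large L, windows
   average over many blocks). A Richards sigmoid in log L is fitted at each
   z, and its left asymptote estimates the single-locus transform p̃_τ(z).
4. The retained transform curve is inverted by fitting a parametric family
   with a closed-form transform: a gamma mixture or a piecewise-exponential
   density whose piecewise-constant hazard is the instantaneous coalescence
   rate, i.e. 1/Ne(t) for pairwise data.

Downstream, the fitted distribution yields the IBD block map-length
survival P(r_block > r) = p̃_T′(r)/p̃_T′(0), the Ne(t) trajectory, relative
recombination rates across chromosomes (from the horizontal rescaling of
the sigmoid transitions), and a residual-variation test for coalescence
differences that recombination cannot explain.

For samples larger than a pair, sites are first filtered to a branch class
(all sites, singletons on a haplotype, a folded frequency class) and the
same machinery estimates the distribution of the corresponding tree-branch
lengths.

## Worked example

```python
import wincoal as wc

N0 = 1e4
mu = 1e-3 / (4 * N0)                      # 4*N0*mu = 1e-3
dem = wc.preset_demographies(N0=N0)["bottleneck"]
cfg = wc.SimConfig(mu=mu, rho=mu / 5, chrom_len=10_000_000, n_chrom=10, seed=7)
sim = wc.simulate_genome(dem, cfg)        # multihetsep stream + truth track

model = wc.CoalescentWindowModel.from_variant_stream(sim.stream, coverage_floor=1.0)
res = model.fit(seed=0)
print(res.summary())

tau, w = sim.truth_times_weights(mu=mu)
print("KS distance to truth:", res.ks_distance(tau, weights=w))
```

This prints (abbreviated):

```
Coalescence-time distribution from windowed diversity
========================================================
statistic:            pairwise
window scales:        80 .. 655360 bp (14 scales)
SNP density pi_hat:   0.001324 per base
retained z points:    J = 22  (z in [7.55, 1.67e+04])
inversion form:       piecewise_exponential
scaled squared error: 6.246
mean tau (= mu*T):    0.001325
...
KS distance to truth: 0.0429
```

`pi_hat` is the realized heterozygosity (the bottleneck demography gives
≈1.3×10⁻³ at these rates); `J` is the number of trusted transform points;
the KS distance of 0.043 says the inferred cumulative distribution of
mutation-scaled coalescence times tracks the simulated ground truth to
within about 4%.

The same pipeline is scriptable from a shell:

```
wincoal simulate --preset bottleneck --n-chrom 10 --chrom-len 10000000 -o sim/
wincoal run sim/multihetsep.txt -o results/ --mu 2.5e-8
```

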