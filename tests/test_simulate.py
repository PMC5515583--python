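import numpy as np
import pytest

import wincoal as wc
from wincoal.branches import BranchClassSpec as B
from wincoal.simulate import expected_pair_tmrca


def mc_band(x, k=3):
    return k * np.std(x) / np.sqrt(len(x))


def test_preset_demographies_encode_stated_parameters():
    d = wc.preset_demographies()
    bn = d["bottleneck"].epochs
    assert [(e.start, e.growth) for e in bn] == [(0.0, 0.0), (0.3, 10.0), (0.4, -10.0), (0.6, 0.0)]
    rb = d["repeated_bottlenecks"].epochs
    assert [(e.start, e.growth) for e in rb[1:]] == [
        (0.1, -10.0), (0.3, 10.0), (0.5, -10.0), (0.7, 10.0), (0.9, -10.0), (1.1, 10.0)
    ]
    ad = d["admixture"].admixture
    assert (ad.time, ad.fraction, ad.join_time) == (0.1, 0.5, 2.0)


def test_demography_validation():
    with pytest.raises(ValueError, match="increasing"):
        wc.Demography(epochs=[wc.Epoch(0.3), wc.Epoch(0.2)])
    with pytest.raises(ValueError, match="final epoch"):
        wc.Demography(epochs=[wc.Epoch(0.5, -1.0)])
    with pytest.raises(ValueError, match="fraction"):
        wc.Demography(admixture=wc.Admixture(0.1, 1.5, 2.0))


def test_constant_size_kingman_means():
    t = wc.sample_coalescence_times(wc.Demography(), B.pairwise(), n_reps=20_000, seed=1)
    # pairwise statistic is the total branch length 2*TMRCA: mean 1 in 4N0 units
    assert abs(t.mean() - 1.0) < mc_band(t)
    assert abs(t.mean() / 2 - 0.5) < mc_band(t / 2)


def test_constant_size_transform_matches_closed_form():
    theta = 1e-3
    tau = wc.sample_coalescence_times(wc.Demography(), B.pairwise(), n_reps=40_000, seed=2, theta=theta)
    for z in [100.0, 1000.0, 5000.0]:
        vals = np.exp(-z * tau)
        assert abs(vals.mean() - wc.constant_N_transform(theta, z)) < mc_band(vals)


def test_constant_N_transform_values():
    assert wc.constant_N_transform(1.0, 1.0) == pytest.approx(0.5)
    assert wc.constant_N_transform(0.37, 0.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        wc.constant_N_transform(0.0, 1.0)


def test_bottleneck_sampler_matches_quadrature():
    dem = wc.preset_demographies()["bottleneck"]
    truth = expected_pair_tmrca(dem)
    t = wc.sample_coalescence_times(dem, B.pairwise(), n_reps=30_000, seed=3) / 2
    assert abs(t.mean() - truth) < mc_band(t)


def test_admixture_sampler_matches_hand_calculation():
    # E[min(T, 0.1)] plus, for pairs surviving the split: 1/2 same
    # population (extra mean 0.5), 1/2 split until the join at 2 (1.9 + 0.5)
    expected = (1 - np.exp(-0.2)) / 2 + np.exp(-0.2) * (0.5 * 0.5 + 0.5 * 2.4)
    dem = wc.preset_demographies()["admixture"]
    t = wc.sample_coalescence_times(dem, B.pairwise(), n_reps=20_000, seed=4) / 2
    assert abs(t.mean() - expected) < mc_band(t)


def test_larger_sample_branch_statistics():
    dem = wc.Demography()
    tot = wc.sample_coalescence_times(dem, B.total(), n_reps=4_000, seed=5, sample_size=4)
    assert abs(tot.mean() - (1 + 1 / 2 + 1 / 3)) < mc_band(tot)  # harmonic sum
    tip = wc.sample_coalescence_times(dem, B.tip(2), n_reps=4_000, seed=6, sample_size=4)
    assert abs(tip.mean() - 0.25) < mc_band(tip)  # total external length is 1
    c1 = wc.sample_coalescence_times(dem, B.frequency_class(1, 4), n_reps=4_000, seed=7)
    assert abs(c1.mean() - 4 / 3) < mc_band(c1)  # folded: doubletons of 1 and 3
    c2 = wc.sample_coalescence_times(dem, B.frequency_class(2, 4), n_reps=4_000, seed=8)
    assert abs(c2.mean() - 0.5) < mc_band(c2)


def test_sampler_reproducible():
    a = wc.sample_coalescence_times(wc.Demography(), B.pairwise(), n_reps=100, seed=11)
    b = wc.sample_coalescence_times(wc.Demography(), B.pairwise(), n_reps=100, seed=11)
    assert np.array_equal(a, b)


def test_simconfig_validation():
    with pytest.raises(ValueError):
        wc.SimConfig(mu=-1e-8)
    with pytest.raises(ValueError):
        wc.SimConfig(mu=1e-8, g=1e-9, lam=0.0)


def test_no_recombination_single_tree_poisson_counts():
    mu = 2.5e-8
    cfg = wc.SimConfig(mu=mu, rho=0.0, chrom_len=1_000_000, n_chrom=3, seed=21)
    sim = wc.simulate_genome(wc.Demography(), cfg)
    for name, tr in sim.truth.items():
        assert len(tr.value) == 1
        lam = mu * cfg.chrom_len * tr.value[0]
        n = int(np.sum(sim.stream.chrom == name))
        assert abs(n - lam) < 4 * np.sqrt(lam) + 4


def test_realized_heterozygosity_matches_demography(bottleneck_sim):
    cfg = bottleneck_sim.config
    dem = bottleneck_sim.demography
    het = []
    for name, tr in bottleneck_sim.truth.items():
        n = int(np.sum(bottleneck_sim.stream.chrom == name))
        het.append(n / cfg.chrom_len)
    expected = 2 * cfg.mu * expected_pair_tmrca(dem) * 4 * dem.N0
    se = np.std(het) / np.sqrt(len(het))
    assert abs(np.mean(het) - expected) < 3 * se + 1e-5


def test_genome_simulation_reproducible():
    cfg = wc.SimConfig(mu=2.5e-8, rho=5e-9, chrom_len=300_000, n_chrom=2, seed=5)
    a = wc.simulate_genome(wc.Demography(), cfg)
    b = wc.simulate_genome(wc.Demography(), cfg)
    assert np.array_equal(a.stream.pos, b.stream.pos)
    assert list(a.stream.alleles) == list(b.stream.alleles)
    for c in a.truth:
        assert np.array_equal(a.truth[c].value, b.truth[c].value)


def test_gene_conversion_adds_breakpoints():
    base = dict(mu=2.5e-8, chrom_len=2_000_000, n_chrom=2, seed=31)
    plain = wc.simulate_genome(wc.Demography(), wc.SimConfig(rho=5e-9, **base))
    gc = wc.simulate_genome(
        wc.Demography(), wc.SimConfig(rho=5e-9, g=5e-9, lam=200.0, **base)
    )
    assert gc.n_tree_changes > plain.n_tree_changes


def test_ghost_recombination_two_thirds_scaling():
    """About 2/3 of on-tree recombination events change a Kingman pair tree."""
    cfg = wc.SimConfig(mu=2.5e-8, rho=5e-9, chrom_len=10_000_000, n_chrom=4, seed=11)
    sim = wc.simulate_genome(wc.Demography(), cfg)
    ratio = sim.n_tree_changes / sim.expected_tree_recombination_events()
    assert ratio == pytest.approx(2 / 3, abs=0.06)


def test_coverage_masking_thins_stream():
    cfg_full = wc.SimConfig(mu=2.5e-8, rho=5e-9, chrom_len=1_000_000, n_chrom=1, seed=41)
    cfg_half = wc.SimConfig(mu=2.5e-8, rho=5e-9, chrom_len=1_000_000, n_chrom=1, seed=41, coverage=0.5)
    full = wc.simulate_genome(wc.Demography(), cfg_full)
    half = wc.simulate_genome(wc.Demography(), cfg_half)
    assert len(half.stream) < 0.75 * len(full.stream)
    gaps = np.diff(np.concatenate(([0], half.stream.pos)))
    assert np.all(half.stream.called <= gaps)
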