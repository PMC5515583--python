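import numpy as np
import pytest
from scipy.integrate import quad

import wincoal as wc
from wincoal.derived import (
    IBDSurvival,
    ibd_survival,
    ks_distance,
    make_mc_asymptote_simulator,
    ne_trajectory,
    relative_recombination,
    residual_iqr_test,
)
from wincoal.distributions import GammaMixture, PiecewiseExponential
from wincoal.richards import RichardsFit
from wincoal.transform import TransformPoint


# --------------------------------------------------------------- IBD survival


def test_ibd_survival_at_zero_and_monotone():
    pe = PiecewiseExponential(times=[0.0, 2e-3], rates=[500.0, 100.0])
    surv = IBDSurvival(pe, mu=1e-8)
    r = np.geomspace(1e-9, 1e-4, 50)
    v = surv(r)
    assert surv(0.0) == pytest.approx(1.0)
    assert np.all(v >= 0) and np.all(v <= 1)
    assert np.all(np.diff(v) <= 1e-12)


def test_ibd_survival_exponential_closed_form():
    # T exponential with mean m: survival (1 + m*r)^-2
    mu = 1.0  # tau = T so the transform argument is already in T units
    m = 0.004
    pe = PiecewiseExponential(times=[0.0], rates=[1.0 / m])
    surv = IBDSurvival(pe, mu=mu)
    r = np.geomspace(1.0, 1e4, 20)
    assert np.allclose(surv(r), (1 + m * r) ** -2, rtol=1e-8)
    assert surv.mean_T == pytest.approx(m)


def test_ibd_mean_block_length_consistency():
    # integral of the survival equals E[r_block] = 1/(2? no: 1/m) for exponential T
    m = 0.01
    pe = PiecewiseExponential(times=[0.0], rates=[1.0 / m])
    surv = IBDSurvival(pe, mu=1.0)
    val, _ = quad(lambda r: float(surv(r)), 0, np.inf, limit=400)
    assert val == pytest.approx(1.0 / m, rel=1e-6)


def test_ibd_ghost_correction_rescales_map_rate():
    pe = PiecewiseExponential(times=[0.0], rates=[100.0])
    plain = IBDSurvival(pe, mu=1.0)
    corr = IBDSurvival(pe, mu=1.0, ghost_correction=True)
    r = 50.0
    assert corr(r) == pytest.approx(plain(r * 2 / 3), rel=1e-10)
    assert ibd_survival(pe, r, mu=1.0) == pytest.approx(plain(r))


# ------------------------------------------------------------------- Ne(t)


def test_ne_trajectory_steps():
    pe = PiecewiseExponential(times=[0.0, 1.0], rates=[2.0, 1.0])
    t, ne = ne_trajectory(pe)
    assert t.tolist() == [0.0, 1.0]
    assert ne.tolist() == [0.5, 1.0]


def test_ne_trajectory_units_with_mu():
    # constant rate 1/theta in tau units is N0 diploids at mu per generation
    theta, mu = 1e-3, 2.5e-8
    pe = PiecewiseExponential(times=[0.0], rates=[1.0 / theta])
    t, ne = ne_trajectory(pe, mu=mu)
    assert ne[0] == pytest.approx(theta / (4 * mu))  # = N0 = 1e4


def test_ne_trajectory_rejects_gamma_form():
    gm = GammaMixture(weights=[1.0], shapes=[1.0], scales=[1e-3])
    with pytest.raises(TypeError):
        ne_trajectory(gm)


def test_ne_recovery_constant_size(constant_results):
    """Fitted hazard near the bulk of the distribution recovers 1/theta within 10%."""
    t, ne = constant_results.ne_trajectory()
    mt = constant_results.mean_tau
    theta = 1e-3
    # evaluate at the distribution's center of mass
    idx = np.searchsorted(t, mt, side="right") - 1
    assert ne[idx] == pytest.approx(theta, rel=0.10)


# ------------------------------------------------- cross-chromosome comparisons


def synthetic_fit(z, a, Lx, a_err=1e-3, lx_err_frac=0.1, b=None, L0=80, Lmax=10**6):
    f = RichardsFit(z=z, a=a, b=b if b is not None else a * 0.5, c=1.0, nu=1.0,
                    Lx=Lx, a_err=a_err, Lx_err=Lx * lx_err_frac, converged=True)
    f.lowest_point = TransformPoint(L=L0, z=z / L0, value=a, stderr=a_err)
    f.L_range = (L0, Lmax)
    return f


def test_identical_chromosomes_unit_ratios():
    zs = np.geomspace(100, 1e4, 6)
    fits = {c: [synthetic_fit(z, a=0.5, Lx=1e4) for z in zs] for c in "abcd"}
    comp = relative_recombination(fits, "a")
    assert np.allclose(comp.table["relative_rate"].values, 1.0)
    assert not comp.table["shape_outlier"].any()


def test_halved_transition_length_doubles_rate():
    zs = np.geomspace(100, 1e4, 6)
    fits = {
        "ref": [synthetic_fit(z, a=0.5, Lx=2e4) for z in zs],
        "fast": [synthetic_fit(z, a=0.5, Lx=1e4) for z in zs],
    }
    comp = relative_recombination(fits, "ref")
    assert comp.table.loc["fast", "relative_rate"] == pytest.approx(2.0, rel=1e-6)


def test_shape_outlier_flagging():
    zs = np.geomspace(100, 1e4, 8)
    fits = {c: [synthetic_fit(z, a=float(np.exp(-1e-3 * z) * 0.9 + 0.05), Lx=1e4)
                for z in zs] for c in "abcde"}
    fits["weird"] = [synthetic_fit(z, a=float(np.exp(-3e-4 * z) * 0.9 + 0.05), Lx=1e4)
                     for z in zs]
    comp = relative_recombination(fits, "a", pi_by_chrom={c: 1e-3 for c in fits})
    assert comp.table.loc["weird", "shape_outlier"]
    assert not comp.table.drop("weird")["shape_outlier"].any()


def test_missing_reference_errors():
    with pytest.raises(ValueError):
        relative_recombination({"a": []}, "zz")


def test_rho_rescaling_recovered_from_simulation():
    """Paired genomes with rho and 2*rho: midpoint lengths differ two-fold."""
    N0, mu = 1e4, 2.5e-8
    rho = mu / 5

    def fits_for(rho_, seed, z_grid):
        cfg = wc.SimConfig(mu=mu, rho=rho_, chrom_len=8_000_000, n_chrom=6, seed=seed)
        sim = wc.simulate_genome(wc.Demography(N0=N0), cfg)
        m = wc.CoalescentWindowModel.from_variant_stream(sim.stream, coverage_floor=1.0)
        _, fits = m.estimate_curve(z_grid=z_grid)
        return fits

    z_grid = np.geomspace(10, 2e4, 16)
    f_slow = fits_for(rho, 101, z_grid)
    f_fast = fits_for(2 * rho, 102, z_grid)
    comp = relative_recombination({"slow": f_slow, "fast": f_fast}, "slow")
    rate = comp.table.loc["fast", "relative_rate"]
    assert rate == pytest.approx(2.0, rel=0.35)


# ------------------------------------------------------------------ IQR test


def test_iqr_zero_for_identical_asymptotes():
    pe = PiecewiseExponential(times=[0.0], rates=[1000.0])
    sim = make_mc_asymptote_simulator(1000.0, 500)
    r = residual_iqr_test([0.5, 0.5, 0.5, 0.5], pe, sim, n_null=50, seed=0)
    assert r.observed_iqr == 0.0
    assert not r.exceeds


def test_iqr_calibrated_under_null():
    pe = PiecewiseExponential(times=[0.0], rates=[1000.0])
    sim = make_mc_asymptote_simulator(1000.0, 800)
    flags = []
    for i in range(24):
        obs = sim(pe, 5, np.random.default_rng(1000 + i))
        flags.append(residual_iqr_test(obs, pe, sim, n_null=120, seed=i).exceeds)
    assert np.mean(flags) <= 0.15  # nominal 2.5% exceedance


def test_iqr_detects_divergent_chromosome():
    pe = PiecewiseExponential(times=[0.0], rates=[1000.0])
    pe_fast = PiecewiseExponential(times=[0.0], rates=[2000.0])
    sim = make_mc_asymptote_simulator(1000.0, 2000)
    rng = np.random.default_rng(5)
    obs = sim(pe, 4, rng)
    obs[0] = sim(pe_fast, 1, rng)[0]  # one chromosome coalesces twice as fast
    r = residual_iqr_test(obs, pe, sim, n_null=200, seed=1)
    assert r.exceeds


def test_iqr_requires_enough_chromosomes():
    pe = PiecewiseExponential(times=[0.0], rates=[1.0])
    with pytest.raises(ValueError):
        residual_iqr_test([0.1, 0.2], pe, lambda d, n, r: np.zeros(n), seed=0)


# ----------------------------------------------------------------- KS distance


def test_ks_point_mass_vs_exponential():
    m = 2.0
    cdf = lambda t: 1 - np.exp(-np.asarray(t) / m)
    # the whole sample sits at t = m: sup deviation is 1 - exp(-1)
    assert ks_distance(cdf, [m]) == pytest.approx(1 - np.exp(-1))


def test_ks_identical_distribution_is_small():
    pe = PiecewiseExponential(times=[0.0, 1.0], rates=[0.5, 2.0])
    x = pe.rvs(100_000, np.random.default_rng(3))
    assert ks_distance(pe.cdf, x) < 0.01


def test_ks_root_n_convergence():
    pe = PiecewiseExponential(times=[0.0], rates=[1.0])
    rng = np.random.default_rng(9)
    prev = None
    for n in [100, 10_000]:
        d = ks_distance(pe.cdf, pe.rvs(n, rng))
        assert d * np.sqrt(n) < 2.5  # K-S statistic scale
        if prev is not None:
            assert d < prev
        prev = d


def test_ks_weighted_sample():
    cdf = lambda t: np.clip(np.asarray(t, dtype=float), 0, 1)  # uniform
    times = np.array([0.25, 0.75])
    assert ks_distance(cdf, times, weights=[1.0, 1.0]) == pytest.approx(0.25)
    assert ks_distance(cdf, times, weights=[3.0, 1.0]) == pytest.approx(0.5)


def test_ks_requires_data():
    with pytest.raises(ValueError):
        ks_distance(lambda t: t, [])
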