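import numpy as np
import pytest

import wincoal as wc

# human-like study conditions used throughout: 4*N0*mu = 1e-3, crossovers at mu/5
N0 = 1e4
MU = 1e-3 / (4 * N0)
RHO = MU / 5


@pytest.fixture(scope="session")
def constant_sim():
    """Constant-size pairwise genome: 5 chromosomes x 4 Mb."""
    cfg = wc.SimConfig(mu=MU, rho=RHO, chrom_len=4_000_000, n_chrom=5, seed=9)
    return wc.simulate_genome(wc.Demography(N0=N0), cfg)


@pytest.fixture(scope="session")
def constant_model(constant_sim):
    return wc.CoalescentWindowModel.from_variant_stream(constant_sim.stream, coverage_floor=1.0)


@pytest.fixture(scope="session")
def constant_results(constant_model):
    return constant_model.fit(seed=0)


@pytest.fixture(scope="session")
def bottleneck_sim():
    """Bottleneck pairwise genome: 4 chromosomes x 5 Mb."""
    dem = wc.preset_demographies(N0=N0)["bottleneck"]
    cfg = wc.SimConfig(mu=MU, rho=RHO, chrom_len=5_000_000, n_chrom=4, seed=7)
    return wc.simulate_genome(dem, cfg)


@pytest.fixture(scope="session")
def bottleneck_model(bottleneck_sim):
    return wc.CoalescentWindowModel.from_variant_stream(bottleneck_sim.stream, coverage_floor=1.0)


@pytest.fixture
def tiny_stream():
    """Three SNPs on one chromosome, fully called."""
    return wc.VariantStream(
        chrom=np.array(["1", "1", "1"], dtype=object),
        pos=np.array([10, 90, 170]),
        called=np.array([10, 80, 80]),
        alleles=np.array(["TC", "AG", "CA"], dtype=object),
    )
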