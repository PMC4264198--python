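import numpy as np
import pandas as pd
import pytest

from hybrase import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=60,
        frac_ase=0.2,
        frac_imprinted_maternal=0.1,
        mean_snp_depth=150.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def nb_draw(rng, mu, dispersion, size=None):
    """Gamma-Poisson sampler used as an independent oracle for NB counts."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), np.shape(mu) if size is None else size)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam)


@pytest.fixture(scope="session")
def table1():
    """Published alignment statistics used as worked-example inputs."""
    return pd.DataFrame(
        dict(
            sample=["NPB", "9311", "NPBx9311", "9311xNPB"],
            n_reads=[77_019_774, 74_384_043, 81_735_674, 78_026_146],
            read_length=[50, 50, 50, 50],
            n_unique=[55_413_403, 58_116_517, 68_473_811, 66_122_696],
        )
    )
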