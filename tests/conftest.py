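import numpy as np
import pytest

from gametoco.bf_sim import BFParams, simulate_bivalents
from gametoco.presets import ZS_FEMALE, ZS_MALE
from gametoco.synthetic_data import GenomeConfig, make_genome_model


@pytest.fixture(scope="session")
def female_like():
    """Fitted female-like Beam-Film parameters (long L, low T2prob)."""
    return ZS_FEMALE


@pytest.fixture(scope="session")
def male_like():
    """Fitted male-like Beam-Film parameters (short L, high T2prob)."""
    return ZS_MALE


@pytest.fixture(scope="session")
def female_bivalents(female_like):
    return simulate_bivalents(female_like, 5000, 1234)


@pytest.fixture(scope="session")
def male_bivalents(male_like):
    return simulate_bivalents(male_like, 5000, 4321)


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome, sparse-SNP genome model for fast pipeline tests."""
    cfg = GenomeConfig(
        n_chromosomes=2,
        total_bp=8_000_000,
        snp_median_spacing=800,
        genes_per_mb=30,
    )
    return make_genome_model(cfg, seed=11)


@pytest.fixture
def poisson_positions():
    """5000 samples of homogeneous-Poisson CO positions on [0, 1]."""
    rng = np.random.default_rng(77)
    return [np.sort(rng.uniform(0, 1, rng.poisson(3.0))) for _ in range(5000)]
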