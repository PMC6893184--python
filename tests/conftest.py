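import numpy as np
import pytest

from recgain.synth import SyntheticGenomeConfig, build_trait, gen_genome


@pytest.fixture(scope="session")
def small_genome():
    """Two short chromosomes; fast enough for per-test simulation."""
    cfg = SyntheticGenomeConfig(
        chrom_ids=("c1", "c2"),
        GL_normal=(80.0, 60.0),
        GL_increased=(240.0, 180.0),
        genes_per_chrom=500,
        seed=3,
    )
    return gen_genome(cfg)


@pytest.fixture(scope="session")
def brapa_genome():
    return gen_genome(SyntheticGenomeConfig.brapa(seed=11))


@pytest.fixture(scope="session")
def osativa_genome():
    return gen_genome(SyntheticGenomeConfig.osativa(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_trait(small_genome):
    return build_trait(small_genome, 20, np.random.default_rng(5))
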