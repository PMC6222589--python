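import numpy as np
import pytest

from wgblup import grm, popsim


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 10 Mbp each, 60+40 SNPs, 1 cM/Mbp."""
    return popsim.default_map(n_snps=100, chrom_mbp=(10, 10))


@pytest.fixture(scope="session")
def small_panel(small_map):
    return popsim.generate_base_panel(80, small_map, maf_floor=0.01, seed=42,
                                      n_males=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hwe_genotypes():
    """Random-mating genotypes (200 x 400) drawn at Hardy-Weinberg."""
    r = np.random.default_rng(99)
    p = r.uniform(0.05, 0.95, 400)
    D = ((r.random((200, 400)) < p).astype(np.int8)
         + (r.random((200, 400)) < p).astype(np.int8))
    return grm.center_genotypes(D)
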