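import numpy as np
import pytest

from epinet import GenomeAssembly, make_bins
from epinet.simulate import FeatureDef, SyntheticConfig


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly(("chrT", "chrU"), (5000, 3000))


@pytest.fixture
def tiny_bins(tiny_assembly):
    return make_bins(tiny_assembly, 1000)


@pytest.fixture
def small_cfg():
    """Small single-causal-feature dataset: 3 chromosomes, 900 bins."""
    return SyntheticConfig(
        chrom_sizes=(("chr1", 300_000), ("chr2", 300_000), ("chr3", 300_000)),
        bin_size=1000,
        features=(FeatureDef("featA", rho=0.8), FeatureDef("featB", rho=0.6)),
        alpha=(("featA", 1.0),),
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
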