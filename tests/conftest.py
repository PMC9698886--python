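import numpy as np
import pytest

from atacdiff.synthio import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic run under the default study conditions."""
    return simulate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast synthetic run for plumbing tests."""
    cfg = SimConfig(seed=7, n_chroms=1, chrom_length=200_000, n_genes=30,
                    n_regions=50, depth=10_000.0)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
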