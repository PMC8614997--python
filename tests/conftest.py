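import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from phagemosaic import simulate_ancestor_panel
from phagemosaic.scenarios import build_chimeric_gene_scenario, build_mosaic_region_scenario

DIVERGENCE_3 = [
    [0.000, 0.005, 0.050],
    [0.005, 0.000, 0.050],
    [0.050, 0.050, 0.000],
]


@pytest.fixture(scope="session")
def small_panel():
    """3-ancestor panel: A/B near-identical, C divergent; 5 genes, 6 kb."""
    return simulate_ancestor_panel(3, 6000, 5, DIVERGENCE_3, seed=7)


@pytest.fixture(scope="session")
def chimeric_gene_scenario():
    return build_chimeric_gene_scenario(seed=3)


@pytest.fixture(scope="session")
def mosaic_region_scenario():
    return build_mosaic_region_scenario(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
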