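import numpy as np
import pytest

from mirevol import SimulationConfig, default_tree
from mirevol.tree import DatedTree


@pytest.fixture(scope="session")
def five_leaf_tree() -> DatedTree:
    return default_tree()


@pytest.fixture(scope="session")
def toy_tree() -> DatedTree:
    """The (((A,B),(C,D)),E) shape used for hand-checked reconstructions."""
    return DatedTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig(rng_seed=42)
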