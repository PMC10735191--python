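import numpy as np
import pytest
from hypothesis import settings

from mgc_ecoscreen import parse_newick, sim_tree

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return parse_newick("(A:1,B:1,C:1);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def small_trees():
    """Fixture trees of <= 6 tips for oracle-equivalence checks."""
    newicks = [
        "((A:1,B:1):1,C:2);",
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:0.5,B:0.5):0.5,C:1):1,(D:1.2,E:0.8):0.8);",
        "((A:2,(B:1,C:1):1):1,(D:1,(E:0.5,F:0.5):0.5):2);",
    ]
    return [parse_newick(nwk) for nwk in newicks]


@pytest.fixture(scope="session")
def yule_tree_64():
    return sim_tree(64, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
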