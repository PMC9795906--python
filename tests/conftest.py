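import numpy as np
import pytest

from areaevo.io_core import parse_newick
from areaevo.synthetic_data import SimConfig, sim_bd_tree


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return parse_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def balanced_unit_tree():
    return parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_unit_tree(rng, n_tips, prefix=None):
    """A random ultrametric tree with unit root age; tips optionally relabeled."""
    cfg = SimConfig(
        n_tips=n_tips, birth_rate=1.0, death_rate=0.0, rng_seed=int(rng.integers(2**31))
    )
    tree, _ = sim_bd_tree(cfg)
    tree = tree.scale(1.0 / tree.root_age)
    if prefix is not None:
        for i, tip in enumerate(tree.tips):
            tip.name = f"{prefix}{i}"
        tree.reindex()
    return tree
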