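import warnings

import numpy as np
import pytest

from phylostruct.synth import make_fixture, simulate_tree
from phylostruct.tree import Phylogeny


TOY_NEWICK = "((A:1.0,B:1.0):1.0,C:2.0);"


@pytest.fixture(scope="session")
def toy_tree() -> Phylogeny:
    """3-tip tree with d(A,B)=2, d(A,C)=d(B,C)=4 used for hand-checked
    expectations throughout."""
    return Phylogeny.from_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def tree47() -> Phylogeny:
    """47-tip ultrametric birth-death tree at unit depth (survey scale)."""
    return simulate_tree(47, seed=2)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Full synthetic survey written once per session."""
    out = tmp_path_factory.mktemp("survey")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture(out, seed=7)


def random_trees(n_trees: int, max_tips: int, seed: int):
    """Stream of small random trees for oracle comparisons."""
    rng = np.random.default_rng(seed)
    for i in range(n_trees):
        n = int(rng.integers(2, max_tips + 1))
        yield simulate_tree(n, seed=int(rng.integers(2**31)))
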