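import numpy as np
import pytest

from climniche import Phylo, simulate_tree


@pytest.fixture
def cherry():
    """Two tips, equal branches."""
    return Phylo.from_newick("(a:1.0,b:1.0);")


@pytest.fixture
def quartet():
    """Balanced 4-tip tree with unequal branches."""
    return Phylo.from_newick("((a:0.5,b:1.2):0.8,(c:0.3,d:0.9):0.4);")


@pytest.fixture
def five_tip():
    """Ladder tree used for hand-enumeration of paintings."""
    return Phylo.from_newick("(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5);")


def random_small_tree(rng: np.random.Generator, max_tips: int = 6) -> Phylo:
    n = int(rng.integers(3, max_tips + 1))
    return simulate_tree(n, 1.0, 0.0, seed=int(rng.integers(2**31 - 1)))
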