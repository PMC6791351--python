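import numpy as np
import pytest

import misstaxa as mt


@pytest.fixture
def three_tip_tree():
    """((A:0.5,B:0.5):0.5,C:1); — unit-height, hand-checkable geometry."""
    return mt.read_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def cherry_pair_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — balanced four-tip tree of height 2."""
    return mt.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def two_tip_tree():
    return mt.read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def yule50():
    return mt.simulate_yule_tree(50, seed=1234)


@pytest.fixture(scope="session")
def yule300():
    return mt.simulate_yule_tree(300, seed=4321)


def cherry_painting(tree, hot_cherry=("A", "B")):
    """Painting with one cherry's parent (and so its tip edges) in regime 1."""
    state = np.zeros(tree.n_nodes, dtype=np.int8)
    a, b = (tree.tip_id(t) for t in hot_cherry)
    parent = tree.parent[a]
    assert parent == tree.parent[b]
    state[parent] = 1
    state[a] = state[b] = 1
    return mt.RegimePainting(state)
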