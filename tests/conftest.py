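import numpy as np
import pytest

from sefrisk import read_newick, simulate_tree


@pytest.fixture
def tree3():
    """((A,B),C) with A/B sharing a length-1 stem."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    """Balanced 4-tip tree with two cherries."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star5():
    return read_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def yule32():
    return simulate_tree(32, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
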