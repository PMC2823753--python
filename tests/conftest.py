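import numpy as np
import pytest

from phyloreg import EvoParams, random_binary_tree, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def cherry():
    return read_newick("(A:2,B:3);")


@pytest.fixture
def quartet():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree10():
    return random_binary_tree(10, seed=7)


@pytest.fixture
def params():
    return EvoParams()
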