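import numpy as np
import pytest

from orthoclock import phylo, synthetic


@pytest.fixture(scope="session")
def wag():
    return phylo.load_model("WAG")


@pytest.fixture(scope="session")
def small_tree5():
    """5-taxon ultrametric tree of height 0.5 used across simulations."""
    tree = synthetic.sample_tree(5, 1.0, seed=2)
    synthetic.rescale_tree(tree, 0.5)
    return tree


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
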