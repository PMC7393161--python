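import numpy as np
import pytest

from eyemorph import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_group_landmarks():
    """Small landmark sample with planted group difference and nuisance axes."""
    cfg = synthetic.SimConfig(seed=1, groups=(("a", 30, 0.05), ("b", 30, 0.05)))
    return synthetic.gen_landmarks(cfg)


@pytest.fixture
def trait_tree_5tip():
    from eyemorph.phylo import TraitTree

    nwk = "((A:1.0,B:2.0):0.5,(C:0.7,(D:0.3,E:0.9):0.4):1.2);"
    traits = {"A": 1.0, "B": -0.5, "C": 2.0, "D": 0.3, "E": 1.7}
    return TraitTree.from_newick(nwk, traits)
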