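import numpy as np
import pandas as pd
import pytest

from pvrda import PhyloTree, read_newick


@pytest.fixture
def quartet():
    """Balanced 4-tip tree ((A,B),(C,D)) with unit-ish branch lengths."""
    return read_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:2):0.5,C:3);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240221)


@pytest.fixture
def study_dataset():
    """One cached study-scale synthetic dataset (39 x 49)."""
    from pvrda import make_study_scale_dataset
    return make_study_scale_dataset(master_seed=7)


def series(**kv):
    return pd.Series(kv, dtype=float)
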