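import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import CommunityTable, SimulationConfig, simulate_dataset


def make_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


@pytest.fixture
def basic_tree():
    return make_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    return make_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        {"s1": [6, 2, 0], "s2": [2, 2, 4], "s3": [1, 5, 2]},
        index=["A", "B", "C"],
    )
    tax = pd.Series({"A": "Chloroflexi", "B": "Chloroflexi", "C": "Acidobacteria"})
    return CommunityTable(counts, tax)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but structured synthetic dataset for integration tests."""
    cfg = SimulationConfig(n_taxa=80, samples_per_layer=4, reads_per_sample=400,
                           seed=11)
    return simulate_dataset(cfg)
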