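import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from nemacore.data_model import FeatureTable, SampleMetadata, TaxonomyMap
from nemacore.synthetic import GeneratorConfig, simulate_dataset


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 samples x 4 ASVs with hand-chosen counts."""
    return FeatureTable(pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 5], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"]))


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "a1": ("d__Bacteria", "p__P1", "g__GenA"),
        "a2": ("d__Bacteria", "p__P1", "g__GenA"),
        "a3": ("d__Bacteria", "p__P2", "g__GenB"),
        "a4": ("d__Bacteria", "p__P2", ""),
    })


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame(
        {"niche": ["gall", "gall", "root"],
         "time_point": [2, 2, 2],
         "plant_id": ["p1", "p2", "p1"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id")))


@pytest.fixture
def cherry_tree() -> TreeNode:
    """((a1:0.1,a2:0.2):0.3,(a3:0.4,a4:0.5):0.6);"""
    return TreeNode.read(["((a1:0.1,a2:0.2):0.3,(a3:0.4,a4:0.5):0.6):0.0;"])


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study (all four niches, 4 time points)."""
    cfg = GeneratorConfig(n_genera=8, strains_per_genus=4, samples_per_group=5,
                          n_time_points=4, depth=9000, missing_groups=(),
                          seed=42)
    return simulate_dataset(cfg)


def random_tree(rng: np.random.Generator, n_leaves: int,
                scale: float = 0.3) -> TreeNode:
    """Random binary tree with exponential branch lengths (test helper)."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.exponential(scale)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.exponential(scale)),
                              children=[a, b]))
    nodes[0].length = 0.0
    return nodes[0]
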