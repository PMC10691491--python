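import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizoassembly import CountTable, SimulationConfig, simulate_dataset

try:  # derandomized hypothesis for reproducible CI-free runs
    from hypothesis import settings

    settings.register_profile("det", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("det")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def toy_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def two_clade_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(["(A:1.5,B:1.5,C:1.5,D:1.5);"])


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[5, 0, 3], [2, 2, 2], [0, 7, 1]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture(scope="session")
def drift_dataset():
    """Small drift-regime data set shared by read-only tests."""
    cfg = SimulationConfig(
        n_taxa=120,
        n_samples_per_group=6,
        groups=[("P1", "BS"), ("P1", "RS")],
        regime="drift",
        depth=1500,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
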