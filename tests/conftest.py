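import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from skbio import TreeNode

from turbicom.datamodel import OtuTable

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def tiny_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — total branch length 5, d(A,C)=4."""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(["(A:1,B:1,C:1,D:1);"])


@pytest.fixture
def small_table() -> OtuTable:
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(6, 12)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"otu{j:02d}" for j in range(12)],
    )
    counts.iloc[:, 0] += 1  # keep at least one column certain non-zero
    meta = pd.DataFrame(
        {
            "lake": ["L1", "L1", "L1", "L2", "L2", "L2"],
            "replicate": [1, 2, 3, 1, 2, 3],
            "turbidity": [1.0, 1.0, 1.0, 30.0, 30.0, 30.0],
        },
        index=counts.index,
    )
    return OtuTable(counts, fraction="rDNA", metadata=meta)


def make_table(counts, sample_ids=None, otu_ids=None, **kw):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"o{j}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids), **kw)
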