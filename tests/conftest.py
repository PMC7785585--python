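import io

import numpy as np
import pytest
from skbio import TreeNode

from bentheco.data_model import OtuTable


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """Balanced 4-tip tree, all branch lengths 1 (total length 6)."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def small_table() -> OtuTable:
    return OtuTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C", "D"],
        np.array([[5, 5, 0, 0], [0, 0, 3, 7], [2, 2, 2, 2]]),
    )


def random_table(rng: np.random.Generator, n_samples: int, n_otus: int,
                 depth: int = 500) -> OtuTable:
    """Random multinomial table with lognormal expected profiles."""
    counts = np.vstack([
        rng.multinomial(depth, (lambda w: w / w.sum())(rng.lognormal(0, 1, n_otus)))
        for _ in range(n_samples)
    ])
    return OtuTable(
        [f"s{i}" for i in range(n_samples)],
        [f"o{j}" for j in range(n_otus)],
        counts,
    )
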