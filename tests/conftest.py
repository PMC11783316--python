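import numpy as np
import pytest

from mcia import Block, MultiBlock, validate_multiblock


def random_multiblock(n, feature_counts, seed, scale=1.0):
    """Dense Gaussian blocks with aligned samples."""
    rng = np.random.default_rng(seed)
    blocks = [
        Block(
            name=f"b{k}",
            values=scale * rng.standard_normal((n, p)),
            sample_ids=[f"s{i}" for i in range(n)],
            feature_ids=[f"b{k}_f{j}" for j in range(p)],
        )
        for k, p in enumerate(feature_counts)
    ]
    return validate_multiblock(blocks)


@pytest.fixture
def single_feature_mb():
    """One block, one feature x = (1, -1)^T: top eigenvalue of XX^T is 2."""
    b = Block("a", np.array([[1.0], [-1.0]]), ["s1", "s2"], ["f1"])
    return validate_multiblock([b])


@pytest.fixture
def identical_blocks_mb():
    """Two identical single-feature blocks: eigenvalue 4, equal weights."""
    x = np.array([[1.0], [-1.0]])
    blocks = [
        Block("a", x, ["s1", "s2"], ["f1"]),
        Block("b", x.copy(), ["s1", "s2"], ["f1"]),
    ]
    return validate_multiblock(blocks)


@pytest.fixture
def small_random_mb():
    return random_multiblock(8, (3, 4, 5), seed=42)
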