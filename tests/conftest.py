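import numpy as np
import pytest

from crocbmi import FeatureMatrix, GoldSolution
from crocbmi.metrics import Partition


@pytest.fixture
def tiny_matrix() -> FeatureMatrix:
    """3 items x 2 features with simple geometry."""
    return FeatureMatrix(
        item_ids=("a", "b", "c"),
        feature_names=("f1", "f2"),
        values=np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]]),
    )


@pytest.fixture
def four_item_gold() -> GoldSolution:
    return GoldSolution({"1": "A", "2": "A", "3": "B", "4": "B"})


@pytest.fixture
def four_item_pred() -> Partition:
    return Partition({"1": "1", "2": "2", "3": "2", "4": "2"})


def random_feature_matrix(rng: np.random.Generator, n: int, m: int) -> FeatureMatrix:
    return FeatureMatrix(
        item_ids=tuple(f"i{k}" for k in range(n)),
        feature_names=tuple(f"f{j}" for j in range(m)),
        values=rng.standard_normal((n, m)),
    )


def random_gold(rng: np.random.Generator, item_ids, r: int) -> GoldSolution:
    """Random labeling guaranteed to use all r classes."""
    n = len(item_ids)
    labels = np.concatenate([np.arange(r), rng.integers(0, r, size=n - r)])
    rng.shuffle(labels)
    return GoldSolution({i: str(l) for i, l in zip(item_ids, labels)})


def all_set_partitions(items: tuple):
    """Every partition of a small item tuple, as label dicts."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller
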