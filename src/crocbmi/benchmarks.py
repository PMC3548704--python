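"""Benchmark computations on the synthetic generators.

These functions run the full pipeline — generate data, compute a distance
matrix, build the CROC, take the best point — under the study conditions
wired into the generators, and are shared by the validation suite and the
reproduction script.  All randomness flows from a single integer seed
through ``numpy.random.default_rng``.
"""
from __future__ import annotations

import numpy as np

from .croc import best_point, croc_curve
from .distances import MI_MIN_FEATURES, pairwise_distance_matrix
from .io import FeatureMatrix, GoldSolution
from .simulate import gen_gaussian3, gen_gaussian5

__all__ = [
    "random_dataset_auc",
    "mean_random_auc",
    "gaussian3_pearson_best_bmi",
    "gaussian5_pearson_best_bmi",
    "max_best_bmi_over_random_datasets",
]


def _subseeds(seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31, size=count)


def random_dataset_auc(seed: int, n: int = 50, m: int = 10) -> float:
    """Euclidean CROC AUC on structureless data with random two-class labels.

    Features are i.i.d. standard normal and the gold labels are a random
    balanced two-class assignment, so the distance has nothing to find and
    the AUC calibrates at 0.5 in expectation.
    """
    rng = np.random.default_rng(seed)
    ids = tuple(f"i{k}" for k in range(n))
    X = FeatureMatrix(
        ids, tuple(f"f{j}" for j in range(m)), rng.standard_normal((n, m))
    )
    labels = rng.permutation([0] * (n // 2) + [1] * (n - n // 2))
    gold = GoldSolution({i: str(l) for i, l in zip(ids, labels)})
    return croc_curve(pairwise_distance_matrix(X, "euclidean"), gold).auc


def mean_random_auc(seed: int, n_seeds: int = 100, n: int = 50, m: int = 10) -> float:
    return float(
        np.mean([random_dataset_auc(int(s), n, m) for s in _subseeds(seed, n_seeds)])
    )


def gaussian3_pearson_best_bmi(seed: int) -> float:
    """Best-point BMI of the Pearson CROC on a Gaussian3 simulation."""
    ds = gen_gaussian3(seed=seed)
    curve = croc_curve(pairwise_distance_matrix(ds.matrix, "pearson"), ds.gold)
    return best_point(curve)[2]


def gaussian5_pearson_best_bmi(seed: int, n_seeds: int = 20, lam: float = 3.0) -> float:
    """Mean best-point BMI of the Pearson CROC on Gaussian5 simulations."""
    vals = []
    for s in _subseeds(seed, n_seeds):
        ds = gen_gaussian5(seed=int(s), lam=lam)
        curve = croc_curve(pairwise_distance_matrix(ds.matrix, "pearson"), ds.gold)
        vals.append(best_point(curve)[2])
    return float(np.mean(vals))


def max_best_bmi_over_random_datasets(seed: int, n_datasets: int = 200) -> float:
    """Maximum best-point BMI over randomized mixture datasets and distances.

    Draws datasets with 10-60 items, 2-50 features and 1-5 Gaussian classes
    at random separations, picks one of the three distances at random
    (skipping mutual information when the feature count is below its
    minimum), and tracks the largest best-point BMI seen.  The all-in-one
    partition is always a CROC solution at (0, 0) with BMI 1 at
    alpha = beta = 0.5, so the maximum is analytically bounded by 1.
    """
    worst = 0.0
    for s in _subseeds(seed, n_datasets):
        rng = np.random.default_rng(int(s))
        n = int(rng.integers(10, 61))
        m = int(rng.integers(2, 51))
        r = int(rng.integers(1, 6))
        centers = rng.uniform(-3, 3, size=(r, m)) * rng.uniform(0, 2)
        assign = np.concatenate([np.arange(r), rng.integers(0, r, size=n - r)])
        rng.shuffle(assign)
        vals = centers[assign] + rng.standard_normal((n, m))
        ids = tuple(f"i{k}" for k in range(n))
        X = FeatureMatrix(ids, tuple(f"f{j}" for j in range(m)), vals)
        # gold: the generating mixture components, with singleton-only or
        # one-class labelings redrawn as balanced two-class labels
        labels = assign
        sizes = np.bincount(labels, minlength=r)
        if r < 2 or sizes.max() < 2:
            labels = rng.permutation([0] * (n // 2) + [1] * (n - n // 2))
        gold = GoldSolution({i: str(l) for i, l in zip(ids, labels)})
        choices = ["euclidean", "pearson"]
        if m >= MI_MIN_FEATURES:
            choices.append("mutual_information")
        name = choices[int(rng.integers(0, len(choices)))]
        curve = croc_curve(pairwise_distance_matrix(X, name), gold)
        worst = max(worst, best_point(curve)[2])
    return worst
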