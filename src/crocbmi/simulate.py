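"""Seeded generators for the three simulated benchmark datasets.

Each generator returns a :class:`SyntheticDataset` bundling a
:class:`~crocbmi.io.FeatureMatrix`, the gold solution used as ground truth,
and the full parameterization (seed included), so that any dataset can be
regenerated bit-identically from its parameter record.

* ``gen_gaussian3`` — 60 samples x 600 features in 3 balanced classes; each
  class owns a block of 200 marker features drawn N(+1, 1) within the class
  and N(-1, 1) outside (a set of genes up-regulated in one cluster and
  down-regulated in the other two).  Strong, high-dimensional separation.
* ``gen_gaussian5`` — 250 planar points, 50 per class, from five bivariate
  Gaussians with unit isotropic variance: four centered at the corners of a
  square of side lambda and one at its center.  lambda tunes the overlap
  (2 and 3 are the conventional settings; 3 is the default).
* ``gen_simulated6`` — 60 samples x 600 genes in 6 classes of sizes
  8/12/10/15/5/10; each class has 50 marker genes drawn N(+1, 1) in the
  class and N(0, 1) outside, plus 300 noise genes in six blocks of 50 with
  linearly decaying residual class effect (block b: +1*(1 - b/6), reaching 0)
  and linearly growing spread (sd 1 + b/6).  Partial, unbalanced separation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ParameterError
from .io import FeatureMatrix, GoldSolution

__all__ = [
    "SyntheticDataset",
    "GENERATORS",
    "gen_gaussian3",
    "gen_gaussian5",
    "gen_simulated6",
    "generate",
]


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: FeatureMatrix
    gold: GoldSolution
    params: Mapping[str, object]


def gen_gaussian3(
    seed: int,
    n_per_class: int = 20,
    n_features: int = 600,
    markers_per_class: int = 200,
    up_mean: float = 1.0,
    down_mean: float = -1.0,
    sd: float = 1.0,
) -> SyntheticDataset:
    """Three classes, each with an exclusive block of up-regulated markers."""
    if 3 * markers_per_class != n_features:
        raise ParameterError(
            f"need 3 * markers_per_class == n_features, got "
            f"3*{markers_per_class} != {n_features}"
        )
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    means = np.full((n, n_features), down_mean)
    for c in range(3):
        rows = slice(c * n_per_class, (c + 1) * n_per_class)
        cols = slice(c * markers_per_class, (c + 1) * markers_per_class)
        means[rows, cols] = up_mean
    values = means + sd * rng.standard_normal((n, n_features))
    item_ids = tuple(f"s{i+1}" for i in range(n))
    labels = {item_ids[i]: f"c{i // n_per_class + 1}" for i in range(n)}
    params = dict(
        generator="gaussian3",
        seed=seed,
        n_per_class=n_per_class,
        n_features=n_features,
        markers_per_class=markers_per_class,
        up_mean=up_mean,
        down_mean=down_mean,
        sd=sd,
    )
    return SyntheticDataset(
        matrix=FeatureMatrix(
            item_ids=item_ids,
            feature_names=tuple(f"g{j+1}" for j in range(n_features)),
            values=values,
        ),
        gold=GoldSolution(labels),
        params=params,
    )


def gen_gaussian5(
    seed: int,
    lam: float = 3.0,
    n_per_class: int = 50,
    sd: float = 1.0,
) -> SyntheticDataset:
    """Five bivariate Gaussians: square corners of side lam plus the center."""
    if lam < 0:
        raise ParameterError(f"side length must be non-negative, got {lam}")
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0.0, 0.0], [lam, 0.0], [0.0, lam], [lam, lam], [lam / 2.0, lam / 2.0]]
    )
    n = 5 * n_per_class
    values = np.repeat(centers, n_per_class, axis=0) + sd * rng.standard_normal((n, 2))
    item_ids = tuple(f"s{i+1}" for i in range(n))
    labels = {item_ids[i]: f"c{i // n_per_class + 1}" for i in range(n)}
    params = dict(
        generator="gaussian5", seed=seed, lam=lam, n_per_class=n_per_class, sd=sd
    )
    return SyntheticDataset(
        matrix=FeatureMatrix(
            item_ids=item_ids, feature_names=("x", "y"), values=values
        ),
        gold=GoldSolution(labels),
        params=params,
    )


def gen_simulated6(
    seed: int,
    class_sizes: Sequence[int] = (8, 12, 10, 15, 5, 10),
    markers_per_class: int = 50,
    n_noise: int = 300,
    up_mean: float = 1.0,
    base_mean: float = 0.0,
    sd: float = 1.0,
) -> SyntheticDataset:
    """Six unbalanced sample classes, 50 unique markers each, 300 noise genes.

    Noise genes come in six blocks of ``markers_per_class`` assigned to the
    classes in order; block b (1-based) carries a residual effect
    ``up_mean * (1 - b/6)`` in its class — decaying to zero — with spread
    ``sd * (1 + b/6)`` everywhere, so later blocks are pure, noisier noise.
    """
    class_sizes = tuple(int(s) for s in class_sizes)
    n_classes = len(class_sizes)
    n_genes = n_classes * markers_per_class + n_noise
    if n_noise % markers_per_class != 0:
        raise ParameterError(
            f"n_noise ({n_noise}) must be a multiple of markers_per_class "
            f"({markers_per_class})"
        )
    if min(class_sizes, default=0) < 1:
        raise ParameterError(f"class sizes must be positive, got {class_sizes}")
    rng = np.random.default_rng(seed)
    n = sum(class_sizes)
    starts = np.concatenate([[0], np.cumsum(class_sizes)])
    means = np.full((n, n_genes), base_mean)
    sds = np.full((n, n_genes), sd)
    for c in range(n_classes):
        rows = slice(starts[c], starts[c + 1])
        cols = slice(c * markers_per_class, (c + 1) * markers_per_class)
        means[rows, cols] = up_mean
    n_noise_blocks = n_noise // markers_per_class
    for b in range(1, n_noise_blocks + 1):
        cols = slice(
            n_classes * markers_per_class + (b - 1) * markers_per_class,
            n_classes * markers_per_class + b * markers_per_class,
        )
        sds[:, cols] = sd * (1.0 + b / 6.0)
        c = (b - 1) % n_classes  # block b is assigned to class b
        rows = slice(starts[c], starts[c + 1])
        means[rows, cols] = base_mean + up_mean * (1.0 - b / 6.0)
    values = means + sds * rng.standard_normal((n, n_genes))
    item_ids = tuple(f"s{i+1}" for i in range(n))
    labels = {}
    for c in range(n_classes):
        for i in range(starts[c], starts[c + 1]):
            labels[item_ids[i]] = f"c{c+1}"
    params = dict(
        generator="simulated6",
        seed=seed,
        class_sizes=class_sizes,
        markers_per_class=markers_per_class,
        n_noise=n_noise,
        up_mean=up_mean,
        base_mean=base_mean,
        sd=sd,
    )
    return SyntheticDataset(
        matrix=FeatureMatrix(
            item_ids=item_ids,
            feature_names=tuple(f"g{j+1}" for j in range(n_genes)),
            values=values,
        ),
        gold=GoldSolution(labels),
        params=params,
    )


GENERATORS = {
    "gaussian3": gen_gaussian3,
    "gaussian5": gen_gaussian5,
    "simulated6": gen_simulated6,
}


def generate(name: str, seed: int, **params) -> SyntheticDataset:
    """Dispatch to a named generator."""
    if name not in GENERATORS:
        raise ParameterError(
            f"unknown generator {name!r}; choose from {sorted(GENERATORS)}"
        )
    return GENERATORS[name](seed=seed, **params)
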