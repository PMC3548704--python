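"""Distance functions and pairwise distance-matrix construction.

Three representatives of the classical families are provided:

* ``euclidean`` — geometric: d2(x, y) = sqrt(sum_i (x_i - y_i)^2).
* ``pearson`` — correlation-based: d_r(x, y) = 1 - r(x, y) in [0, 2].
* ``mutual_information`` — information-based:
  d_MI(x, y) = 1 - MI(X; Y) / max(H(X), H(Y)),
  with the probability mass functions estimated by equal-width histogram
  binning of each vector over its own range (B = ceil(sqrt(m)) bins).

All three satisfy the dissimilarity axioms: non-negativity, symmetry and
d(x, x) = 0.  Pearson and MI are undefined on constant vectors and raise
rather than impute, since a silently substituted value would corrupt every
downstream threshold sweep.  Because threshold analysis operates on [0, 1],
matrices can be normalized by their maximum off-diagonal entry — a strictly
monotone rescaling, so the ranking of pairs (all that the threshold sweep
sees) is untouched.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    DegenerateInputError,
    DegenerateMatrixError,
    DimensionError,
    InsufficientFeaturesError,
)
from .io import FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "JointHistogram",
    "DISTANCE_NAMES",
    "MI_MIN_FEATURES",
    "euclidean_distance",
    "pearson_distance",
    "joint_histogram",
    "mutual_information_distance",
    "pairwise_distance_matrix",
    "normalize_distance_matrix",
]

DISTANCE_NAMES = ("euclidean", "pearson", "mutual_information")

#: Minimum number of features for the histogram MI estimate.  Below this the
#: joint histogram is almost empty and the estimate meaningless; 2-feature
#: data (e.g. planar point clouds) are rejected outright.
MI_MIN_FEATURES = 8


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray
    distance_name: str
    item_ids: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = values.shape[0]
        if values.shape != (n, n):
            raise DimensionError(f"distance matrix must be square, got {values.shape}")
        if len(self.item_ids) != n:
            raise DimensionError("item_ids length does not match matrix size")
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError("non-finite distance entries")
        if (values < 0).any():
            raise DegenerateInputError("negative distance entries")
        if not np.allclose(values, values.T, atol=1e-12):
            raise DegenerateInputError("distance matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise DegenerateInputError("distance matrix diagonal not zero")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i<j) entries as a flat vector."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class JointHistogram:
    """Joint and marginal pmfs of two vectors binned on a common B x B grid."""

    bin_count: int
    edges_x: np.ndarray
    edges_y: np.ndarray
    joint_pmf: np.ndarray
    marginal_x: np.ndarray
    marginal_y: np.ndarray


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"vector length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sample correlation; 0 for perfect positive linear relation, 2 for
    perfect negative."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise DimensionError("pearson distance needs at least 2 features")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / (sx * sy))
    return 1.0 - max(-1.0, min(1.0, r))


def _bin_codes(v: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin assignment of v over its own range; right edge closed."""
    edges = np.linspace(v.min(), v.max(), bins + 1)
    codes = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, bins - 1)
    return codes, edges


def joint_histogram(
    x: np.ndarray, y: np.ndarray, bin_count: int | None = None
) -> JointHistogram:
    """Histogram estimate of the joint and marginal pmfs of two vectors.

    Each vector is discretized into ``bin_count`` equal-width bins over its own
    range (default ceil(sqrt(m))); the joint pmf is the normalized 2-D count
    matrix and the marginals its row/column sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"vector length mismatch: {x.shape} vs {y.shape}")
    m = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("binning undefined for a constant vector")
    bins = bin_count if bin_count is not None else math.ceil(math.sqrt(m))
    if bins < 2:
        raise DimensionError("bin_count must be at least 2")
    cx, ex = _bin_codes(x, bins)
    cy, ey = _bin_codes(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (cx, cy), 1.0)
    joint /= m
    return JointHistogram(
        bin_count=bins,
        edges_x=ex,
        edges_y=ey,
        joint_pmf=joint,
        marginal_x=joint.sum(axis=1),
        marginal_y=joint.sum(axis=0),
    )


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information_distance(
    x: np.ndarray, y: np.ndarray, bin_count: int | None = None
) -> float:
    """1 - MI(X;Y)/max(H(X), H(Y)) from a binned joint histogram.

    Returns 0 when x and y carry the same binned information, 1 when the
    binned variables are independent.  Requires at least
    :data:`MI_MIN_FEATURES` features.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if x.size < MI_MIN_FEATURES:
        raise InsufficientFeaturesError(
            f"mutual-information distance needs at least {MI_MIN_FEATURES} "
            f"features, got {x.size}"
        )
    h = joint_histogram(x, y, bin_count)
    hx = _entropy(h.marginal_x)
    hy = _entropy(h.marginal_y)
    hxy = _entropy(h.joint_pmf.ravel())
    mi = max(0.0, hx + hy - hxy)
    hmax = max(hx, hy)
    if hmax == 0:
        raise DegenerateInputError("zero entropy after binning (constant vector)")
    return float(np.clip(1.0 - mi / hmax, 0.0, 1.0))


_SCALAR: dict[str, Callable[..., float]] = {
    "euclidean": euclidean_distance,
    "pearson": pearson_distance,
    "mutual_information": mutual_information_distance,
}


def pairwise_distance_matrix(
    X: FeatureMatrix, distance_name: str, bin_count: int | None = None
) -> DistanceMatrix:
    """Apply the named scalar distance to every unordered pair of rows."""
    if distance_name not in DISTANCE_NAMES:
        raise DimensionError(
            f"unknown distance {distance_name!r}; choose from {DISTANCE_NAMES}"
        )
    V = X.values
    if distance_name == "mutual_information" and X.n_features < MI_MIN_FEATURES:
        raise InsufficientFeaturesError(
            f"mutual-information distance needs at least {MI_MIN_FEATURES} "
            f"features, got {X.n_features}"
        )
    if distance_name == "euclidean":
        mat = squareform(pdist(V, metric="euclidean"))
    elif distance_name == "pearson":
        const = np.ptp(V, axis=1) == 0
        if const.any():
            bad = X.item_ids[int(np.flatnonzero(const)[0])]
            raise DegenerateInputError(
                f"item {bad!r}: correlation undefined for a constant vector"
            )
        r = np.clip(np.corrcoef(V), -1.0, 1.0)
        mat = 1.0 - r
        np.fill_diagonal(mat, 0.0)
        mat = np.clip((mat + mat.T) / 2.0, 0.0, 2.0)
    else:
        fn = _SCALAR[distance_name]
        kwargs = {"bin_count": bin_count} if distance_name == "mutual_information" else {}
        n = X.n_items
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    mat[i, j] = mat[j, i] = fn(V[i], V[j], **kwargs)
                except DegenerateInputError as exc:
                    raise DegenerateInputError(
                        f"items {X.item_ids[i]!r} / {X.item_ids[j]!r}: {exc}"
                    ) from exc
    return DistanceMatrix(
        values=mat, distance_name=distance_name, item_ids=X.item_ids
    )


def normalize_distance_matrix(D: DistanceMatrix) -> DistanceMatrix:
    """Scale entries into [0, 1] by the maximum off-diagonal entry.

    A strictly monotone transform: the rank order of all entries is preserved,
    and applying it twice is a no-op.
    """
    if D.normalized:
        return D
    top = float(D.offdiag().max(initial=0.0))
    if top == 0:
        raise DegenerateMatrixError("all off-diagonal distances are zero")
    return DistanceMatrix(
        values=D.values / top,
        distance_name=D.distance_name,
        item_ids=D.item_ids,
        normalized=True,
    )


def write_distance_matrix(D: DistanceMatrix, path, delimiter: str = "\t") -> None:
    """Square delimited text with item-id header row and column."""
    import pandas as pd

    pd.DataFrame(D.values, index=list(D.item_ids), columns=list(D.item_ids)).to_csv(
        path, sep=delimiter, index_label="item_id"
    )
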