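"""Partition comparison on the ROC plane and classical external indices.

A partition of n items induces a binary *connectivity matrix* J with
J(i, j) = 1 iff items i and j share a cluster; J is transitive by
construction.  Comparing a predicted partition against the gold solution at
the level of unordered item pairs yields a 2x2 confusion matrix in which the
*positive* class is "the pair belongs to different clusters":

* T0 — pairs separated in gold and in the prediction,
* F1 — pairs separated in gold but co-clustered in the prediction,
* T1 — pairs co-clustered in both,
* F0 — pairs co-clustered in gold but separated in the prediction.

TPR = T0/(T0+F1) and FPR = F0/(T1+F0) map the partition to a point on the
ROC plane; the gold solution itself maps to (0, 1), the all-in-one partition
to (0, 0) and all-singletons to (1, 1).

The Balanced Misclassification Index combines the misclassification error
E_m = FPR + FNR and the balancing error E_b = |FPR - FNR|:

    BMI = sqrt(alpha * E_m^2 + beta * E_b^2),    alpha + beta = 1.

At alpha = beta = 0.5 this is exactly the Euclidean distance from the
partition's ROC point to (0, 1), so any point on or above the chance
diagonal has BMI <= 1.  Lower is better, in contrast to the adjusted Rand,
Fowlkes-Mallows and F indices (also provided here), which are maximized.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    DimensionError,
    ParameterError,
    UndefinedIndexError,
    UndefinedRateError,
)
from .io import GoldSolution

__all__ = [
    "Partition",
    "ConnectivityMatrix",
    "PairConfusion",
    "ROCPoint",
    "ContingencyTable",
    "connectivity_matrix",
    "pair_confusion",
    "roc_point",
    "misclassification_error",
    "balancing_error",
    "bmi",
    "contingency",
    "adjusted_rand",
    "fowlkes_mallows",
    "f_measure",
]


@dataclass(frozen=True)
class Partition:
    """An item -> cluster assignment with free-text provenance."""

    labels: Mapping[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = {str(k): str(v) for k, v in dict(self.labels).items()}
        if not labels:
            raise ParameterError("partition is empty")
        object.__setattr__(self, "labels", labels)

    @property
    def t(self) -> int:
        """Number of clusters."""
        return len(set(self.labels.values()))

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.labels)

    def label_array(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.item_ids if item_ids is None else item_ids
        labs = [self.labels[i] for i in ids]
        _, codes = np.unique(labs, return_inverse=True)
        return codes

    @classmethod
    def from_codes(
        cls, item_ids: Sequence[str], codes: Sequence[int], provenance: str = ""
    ) -> "Partition":
        return cls(
            {str(i): str(int(c)) for i, c in zip(item_ids, codes)}, provenance
        )

    @classmethod
    def from_gold(cls, gold: GoldSolution) -> "Partition":
        return cls(dict(gold.labels), provenance="gold")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric binary matrix, diagonal 1, transitive (a true partition)."""

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", values)
        n = values.shape[0]
        if values.shape != (n, n):
            raise DimensionError("connectivity matrix must be square")
        if len(self.item_ids) != n:
            raise DimensionError("item_ids length does not match matrix size")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PairConfusion:
    """Counts over the n(n-1)/2 unordered item pairs."""

    T0: int  # separated in gold, separated in prediction
    F1: int  # separated in gold, co-clustered in prediction
    T1: int  # co-clustered in both
    F0: int  # co-clustered in gold, separated in prediction

    @property
    def total(self) -> int:
        return self.T0 + self.F1 + self.T1 + self.F0


@dataclass(frozen=True)
class ROCPoint:
    """(FPR, TPR) coordinates of a partition in the ROC plane."""

    fpr: float
    tpr: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.fpr <= 1.0 and 0.0 <= self.tpr <= 1.0):
            raise ParameterError(
                f"ROC coordinates out of [0,1]: ({self.fpr}, {self.tpr})"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """r x t cross-tabulation of gold classes against predicted clusters."""

    counts: np.ndarray
    gold_classes: tuple[str, ...]
    pred_clusters: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def connectivity_matrix(p: Partition) -> ConnectivityMatrix:
    """J(i, j) = 1 iff items i and j share a cluster (Boolean outer equality)."""
    codes = p.label_array()
    return ConnectivityMatrix(
        values=codes[:, None] == codes[None, :], item_ids=p.item_ids
    )


def pair_confusion(pred: ConnectivityMatrix, gold: ConnectivityMatrix) -> PairConfusion:
    """2x2 pair-level confusion counts; positive class = separated pair."""
    if pred.n_items != gold.n_items or pred.item_ids != gold.item_ids:
        raise DimensionError("connectivity matrices are over different item sets")
    iu = np.triu_indices(pred.n_items, k=1)
    p_co = pred.values[iu]
    g_co = gold.values[iu]
    return PairConfusion(
        T0=int(np.sum(~g_co & ~p_co)),
        F1=int(np.sum(~g_co & p_co)),
        T1=int(np.sum(g_co & p_co)),
        F0=int(np.sum(g_co & ~p_co)),
    )


def roc_point(c: PairConfusion, provenance: str = "") -> ROCPoint:
    """Map pair confusion counts to (FPR, TPR).

    Requires a non-degenerate gold: at least one separated pair (>= 2 classes)
    and at least one co-clustered pair (>= 1 class of size >= 2).
    """
    sep_gold = c.T0 + c.F1
    co_gold = c.T1 + c.F0
    if sep_gold == 0 or co_gold == 0:
        raise UndefinedRateError(
            "TPR/FPR undefined: gold solution has a single class or only "
            "singleton classes"
        )
    return ROCPoint(fpr=c.F0 / co_gold, tpr=c.T0 / sep_gold, provenance=provenance)


def misclassification_error(p: ROCPoint) -> float:
    """E_m = FPR + FNR, the L1 distance from the point to (0, 1)."""
    return p.fpr + (1.0 - p.tpr)


def balancing_error(p: ROCPoint) -> float:
    """E_b = |FPR - FNR|, how unbalanced the two error rates are."""
    return abs(p.fpr - (1.0 - p.tpr))


def bmi(p: ROCPoint, alpha: float = 0.5, beta: float = 0.5) -> float:
    """Balanced Misclassification Index sqrt(alpha*E_m^2 + beta*E_b^2).

    At alpha = beta = 0.5 equals the Euclidean distance from (fpr, tpr) to the
    gold point (0, 1).  Weights must be non-negative and sum to 1.
    """
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-12:
        raise ParameterError(
            f"weights must be non-negative and sum to 1, got alpha={alpha}, beta={beta}"
        )
    em = misclassification_error(p)
    eb = balancing_error(p)
    return float(np.sqrt(alpha * em**2 + beta * eb**2))


def contingency(gold: GoldSolution, p: Partition) -> ContingencyTable:
    """r x t table T with T_ij = number of items in gold class i and cluster j."""
    if set(gold.item_ids) != set(p.item_ids):
        raise DimensionError("gold and partition are over different item sets")
    ids = gold.item_ids
    g_labs = [gold.labels[i] for i in ids]
    p_labs = [p.labels[i] for i in ids]
    g_classes, g_codes = np.unique(g_labs, return_inverse=True)
    p_clusters, p_codes = np.unique(p_labs, return_inverse=True)
    counts = np.zeros((len(g_classes), len(p_clusters)), dtype=np.int64)
    np.add.at(counts, (g_codes, p_codes), 1)
    return ContingencyTable(
        counts=counts,
        gold_classes=tuple(g_classes),
        pred_clusters=tuple(p_clusters),
    )


def adjusted_rand(ct: ContingencyTable) -> float:
    """Adjusted Rand index R_A: chance-corrected pair agreement, 1 for
    identical partitions, possibly negative."""
    n = ct.N
    if n < 2:
        raise UndefinedIndexError("adjusted Rand needs at least 2 items")
    comb2 = lambda a: a * (a - 1) / 2.0
    index = comb2(ct.counts).sum()
    sum_rows = comb2(ct.row_margins).sum()
    sum_cols = comb2(ct.col_margins).sum()
    expected = sum_rows * sum_cols / comb2(n)
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if denom == 0:
        raise UndefinedIndexError(
            "adjusted Rand undefined: both partitions are trivial"
        )
    return float((index - expected) / denom)


def fowlkes_mallows(ct: ContingencyTable) -> float:
    """Fowlkes-Mallows index (sum T_ij^2 - N) / sqrt((sum T_i.^2 - N)(sum T_.j^2 - N)).

    Equals sqrt(pair-precision x pair-recall); undefined when either partition
    has no co-clustered pair (all singletons).
    """
    n = ct.N
    tk = float((ct.counts.astype(float) ** 2).sum() - n)
    pk = float((ct.row_margins.astype(float) ** 2).sum() - n)
    qk = float((ct.col_margins.astype(float) ** 2).sum() - n)
    if pk == 0 or qk == 0:
        raise UndefinedIndexError(
            "Fowlkes-Mallows undefined: a partition has only singleton clusters"
        )
    return float(tk / np.sqrt(pk * qk))


def f_measure(ct: ContingencyTable) -> float:
    """Clustering F-measure: for each gold class, the best harmonic mean of
    precision (T_ij/T_.j) and recall (T_ij/T_i.) over clusters, weighted by
    class size.  1 for identical partitions."""
    n = ct.N
    if n < 2:
        raise UndefinedIndexError("F-measure needs at least 2 items")
    T = ct.counts.astype(float)
    prec = np.divide(
        T,
        ct.col_margins[None, :],
        out=np.zeros_like(T),
        where=ct.col_margins[None, :] > 0,
    )
    rec = np.divide(
        T,
        ct.row_margins[:, None],
        out=np.zeros_like(T),
        where=ct.row_margins[:, None] > 0,
    )
    denom = prec + rec
    f = np.where(denom > 0, 2.0 * prec * rec / np.where(denom > 0, denom, 1.0), 0.0)
    best = f.max(axis=1)
    weights = ct.row_margins / n
    return float(np.sum(weights * best))
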