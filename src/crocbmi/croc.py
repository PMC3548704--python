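"""The CROC curve: threshold sweep of a distance matrix corrected into
proper partitions.

Thresholding a normalized distance matrix D at phi in [0, 1] gives the
indicator matrix I_phi(i, j) = 1 iff D(i, j) <= phi.  I_phi is generally NOT
a connectivity matrix: three roughly collinear items with
D(1,2) = D(2,3) = phi but D(1,3) > phi break transitivity.  Each threshold
graph is therefore *closed* into a genuine partition by taking connected
components — overlapping would-be clusters are merged.  The resulting curve
of (FPR, TPR) points, one per distinct closed partition, is the CROC
(Corrected ROC) of the distance: every point on it is a clustering solution
the distance alone can produce.  This closure is exactly single-linkage
agglomeration, so the sweep is computed with an incremental union-find over
edges sorted by distance.

The sweep runs over the sorted distinct off-diagonal values of the
normalized matrix (between consecutive values the indicator is constant, so
this finite sweep is exhaustive).  The all-singletons configuration is never
a solution — it would need phi < 0 — while the all-in-one partition always
is (phi = 1).  The points (1, 1) and (0, 0) enter the trapezoidal AUC only
as geometric anchors.  AUC calibrates at 0.5 for a distance with no
discriminative ability and approaches 1 as the best solution approaches the
gold point (0, 1); the *best point* of the curve is the solution minimizing
the BMI, and its BMI value summarizes the intrinsic discriminative ability
of the distance on that dataset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, normalize_distance_matrix
from .exceptions import ParameterError, UndefinedRateError
from .io import GoldSolution
from .metrics import (
    Partition,
    ROCPoint,
    bmi,
    connectivity_matrix,
    pair_confusion,
    roc_point,
)

__all__ = [
    "ThresholdIndicator",
    "CROCSolution",
    "CROCCurve",
    "threshold_indicator",
    "component_closure",
    "croc_curve",
    "croc_auc",
    "best_point",
    "gray_region_contains",
]


@dataclass(frozen=True)
class ThresholdIndicator:
    """Binary threshold graph I_phi; symmetric, diagonal 1, NOT transitive."""

    phi: float
    values: np.ndarray
    item_ids: tuple[str, ...]


@dataclass(frozen=True)
class CROCSolution:
    """One point of the CROC: a closed partition and its ROC coordinates."""

    phi: float
    partition: Partition
    point: ROCPoint

    @property
    def n_clusters(self) -> int:
        return self.partition.t


@dataclass(frozen=True)
class CROCCurve:
    """Ordered CROC solutions plus the geometric anchors and the AUC."""

    solutions: tuple[CROCSolution, ...]
    auc: float
    distance_name: str
    anchors: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 1.0))


def threshold_indicator(D: DistanceMatrix, phi: float) -> ThresholdIndicator:
    """I_phi(i, j) = 1 iff D(i, j) <= phi, for a normalized matrix."""
    if not D.normalized:
        raise ParameterError("threshold_indicator requires a normalized matrix")
    if not (0.0 <= phi <= 1.0):
        raise ParameterError(f"threshold must lie in [0, 1], got {phi}")
    return ThresholdIndicator(
        phi=float(phi), values=D.values <= phi, item_ids=D.item_ids
    )


def component_closure(I: ThresholdIndicator) -> Partition:
    """Close a threshold graph into a partition via connected components.

    Clusters are the connected components of the graph whose edges are the
    1-entries of I; the closure's connectivity matrix is transitive and
    entrywise >= I.
    """
    _, labels = connected_components(
        csr_matrix(I.values), directed=False, return_labels=True
    )
    return Partition.from_codes(
        I.item_ids, labels, provenance=f"threshold phi={I.phi:g}"
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def croc_curve(D: DistanceMatrix, gold: GoldSolution) -> CROCCurve:
    """Build the CROC of a distance matrix against a gold solution.

    Normalizes D, sweeps phi over the sorted distinct off-diagonal values,
    closes each threshold graph into a partition (incrementally, via
    union-find over distance-sorted edges — equal distances merge at the same
    threshold), keeps each distinct partition once, maps it to the ROC plane
    and integrates the trapezoidal AUC with the anchors (0, 0) and (1, 1).
    """
    if gold.r < 2 or max(gold.class_sizes().values()) < 2:
        raise UndefinedRateError(
            "CROC needs a gold solution with >= 2 classes and >= 1 class of size >= 2"
        )
    D = normalize_distance_matrix(D)
    if tuple(gold.item_ids) != D.item_ids and set(gold.item_ids) != set(D.item_ids):
        raise UndefinedRateError("gold solution does not cover the distance matrix")
    n = D.n_items
    iu = np.triu_indices(n, k=1)
    dvals = D.values[iu]
    order = np.argsort(dvals, kind="stable")
    ii, jj = iu[0][order], iu[1][order]
    dsorted = dvals[order]

    gold_conn = connectivity_matrix(Partition.from_gold(gold))
    # align gold connectivity to the distance matrix's item order
    if gold_conn.item_ids != D.item_ids:
        idx = [gold_conn.item_ids.index(i) for i in D.item_ids]
        gold_conn = type(gold_conn)(
            values=gold_conn.values[np.ix_(idx, idx)], item_ids=D.item_ids
        )

    uf = _UnionFind(n)
    solutions: list[CROCSolution] = []
    k = 0
    n_edges = len(dsorted)
    while k < n_edges:
        phi = dsorted[k]
        changed = False
        # merge every edge at this distance value before snapshotting
        while k < n_edges and dsorted[k] == phi:
            changed |= uf.union(int(ii[k]), int(jj[k]))
            k += 1
        if not changed:
            continue
        roots = np.fromiter((uf.find(i) for i in range(n)), dtype=np.int64, count=n)
        part = Partition.from_codes(
            D.item_ids, roots, provenance=f"threshold phi={phi:g}"
        )
        conf = pair_confusion(connectivity_matrix(part), gold_conn)
        pt = roc_point(conf, provenance=f"phi={phi:g}")
        solutions.append(CROCSolution(phi=float(phi), partition=part, point=pt))

    curve = CROCCurve(
        solutions=tuple(solutions), auc=0.0, distance_name=D.distance_name
    )
    return CROCCurve(
        solutions=curve.solutions,
        auc=croc_auc(curve),
        distance_name=D.distance_name,
    )


def croc_auc(curve: CROCCurve) -> float:
    """Trapezoidal area under the CROC points plus the (0,0)/(1,1) anchors."""
    pts = [(s.point.fpr, s.point.tpr) for s in curve.solutions]
    pts.extend(curve.anchors)
    pts.sort()
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def best_point(
    curve: CROCCurve, alpha: float = 0.5, beta: float = 0.5
) -> tuple[ROCPoint, Partition, float]:
    """The CROC solution minimizing the BMI, with ties broken toward the
    smaller FPR and then the fewer clusters (the more conservative split)."""
    if not curve.solutions:
        raise ParameterError("CROC curve has no solutions")
    best = min(
        curve.solutions,
        key=lambda s: (bmi(s.point, alpha, beta), s.point.fpr, s.n_clusters),
    )
    return best.point, best.partition, bmi(best.point, alpha, beta)


def gray_region_contains(
    p: ROCPoint, bmi_star: float, alpha: float = 0.5, beta: float = 0.5
) -> bool:
    """True iff the point strictly outperforms the distance's best solution.

    The gray region is the set of ROC points with BMI strictly below
    ``bmi_star``; the iso-BMI boundary itself is outside.
    """
    if bmi_star < 0:
        raise ParameterError("bmi_star must be non-negative")
    return bmi(p, alpha, beta) < bmi_star
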