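"""Clustering algorithms on the ROC plane and the distance-vs-algorithm
comparison procedure.

The comparison runs in five steps per distance: (1) threshold the distance
matrix into its ROC curve, (2) correct it into the CROC, (3) mark the CROC's
best point (lowest BMI) — this summarizes what the distance alone can do,
(4) map each clustering solution produced by an algorithm into the ROC
plane, (5) rank all marked points by BMI.  An algorithm whose point falls
strictly inside the *gray region* (BMI below the distance's best-point BMI)
improves on the intrinsic separation ability of the distance; a point's
position also reveals the algorithm's bias — high FPR means over-splitting
(divisive), high FNR means over-merging (agglomerative).

Four standard algorithms are provided: single, complete and average linkage
(on the precomputed dissimilarity matrix, so Pearson and mutual-information
distances are honored) and a generalized Lloyd K-means whose assignment step
uses the chosen distance to the coordinate-wise mean centroids.

Finally, to validate BMI as an external index in its own right, the Pearson
correlation between the BMI series and each classical index series (adjusted
Rand, Fowlkes-Mallows, F) is computed over the full CROC solution set,
ordered by cluster count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .croc import CROCCurve, best_point, croc_curve, gray_region_contains
from .distances import (
    DISTANCE_NAMES,
    DistanceMatrix,
    pairwise_distance_matrix,
)
from .exceptions import (
    CrocBmiError,
    InsufficientFeaturesError,
    ParameterError,
    UndefinedCorrelationError,
    UndefinedIndexError,
)
from .io import FeatureMatrix, GoldSolution
from .metrics import (
    Partition,
    ROCPoint,
    adjusted_rand,
    bmi,
    connectivity_matrix,
    contingency,
    f_measure,
    fowlkes_mallows,
    pair_confusion,
    roc_point,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "INDEX_NAMES",
    "ClusteringRun",
    "SolutionRecord",
    "DistanceSummary",
    "EvaluationReport",
    "run_clustering",
    "map_solution_to_roc",
    "bias_label",
    "index_correlation",
    "evaluate",
]

ALGORITHMS = ("kmeans", "single_link", "complete_link", "average_link")
INDEX_NAMES = ("adjusted_rand", "fowlkes_mallows", "f_measure")

_INDEX_FN = {
    "adjusted_rand": adjusted_rand,
    "fowlkes_mallows": fowlkes_mallows,
    "f_measure": f_measure,
}

_LINKAGE_METHOD = {
    "single_link": "single",
    "complete_link": "complete",
    "average_link": "average",
}

#: |FPR - FNR| margin beyond which a solution is called divisive or
#: agglomerative rather than balanced.
DEFAULT_BIAS_MARGIN = 0.2


@dataclass(frozen=True)
class ClusteringRun:
    algorithm: str
    distance_name: str
    k: int
    partition: Partition
    seed: int | None = None


@dataclass(frozen=True)
class SolutionRecord:
    """One clustering solution scored against the gold solution."""

    algorithm: str
    distance_name: str
    k: int
    point: ROCPoint
    bmi: float
    adjusted_rand: float | None
    fowlkes_mallows: float | None
    f_measure: float | None
    in_gray: bool
    bias: str


@dataclass(frozen=True)
class DistanceSummary:
    distance_name: str
    bmi_star: float
    auc: float
    best_fpr: float
    best_tpr: float
    best_n_clusters: int
    correlations: Mapping[str, float | None]


@dataclass(frozen=True)
class EvaluationReport:
    summaries: tuple[DistanceSummary, ...]
    records: tuple[SolutionRecord, ...]
    missing: tuple[tuple[str, str], ...]  # (distance_name, reason)
    gray_tallies: Mapping[str, tuple[int, int]] = field(default_factory=dict)


def _kmeans_generalized(
    X: FeatureMatrix,
    distance_name: str,
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd iteration with assignment under the chosen distance.

    Centroids are coordinate-wise means; the assignment step measures each
    item against each centroid with the selected distance, which makes the
    procedure applicable beyond the Euclidean case.  Seeded restarts keep the
    result deterministic; the restart minimizing the within-cluster sum of
    distances wins.
    """
    from .distances import _SCALAR  # scalar distance dispatch

    fn = _SCALAR[distance_name]
    V = X.values
    n = V.shape[0]
    rng = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_cost = np.inf
    for _ in range(n_restarts):
        centroids = V[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=np.int64)
        for _it in range(max_iter):
            dists = np.empty((n, k))
            for j in range(k):
                if distance_name == "euclidean":
                    dists[:, j] = np.sqrt(((V - centroids[j]) ** 2).sum(axis=1))
                else:
                    for i in range(n):
                        try:
                            dists[i, j] = fn(V[i], centroids[j])
                        except CrocBmiError:
                            dists[i, j] = np.inf
            new_labels = dists.argmin(axis=1)
            if np.array_equal(new_labels, labels) and _it > 0:
                break
            labels = new_labels
            for j in range(k):
                members = V[labels == j]
                if len(members):
                    centroids[j] = members.mean(axis=0)
        cost = float(dists[np.arange(n), labels][np.isfinite(dists[np.arange(n), labels])].sum())
        if cost < best_cost:
            best_cost = cost
            best_labels = labels
    assert best_labels is not None
    return best_labels


def run_clustering(
    X: FeatureMatrix,
    D: DistanceMatrix,
    algorithm: str,
    k: int,
    seed: int = 0,
) -> ClusteringRun:
    """Run one algorithm at one cluster count.

    Hierarchical methods consume the precomputed distance matrix D; K-means
    consumes the feature matrix X with D's distance used in the assignment
    step.  Deterministic given the seed.
    """
    if algorithm not in ALGORITHMS:
        raise ParameterError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    n = D.n_items
    if not (2 <= k <= n - 1):
        raise ParameterError(f"k must lie in [2, {n - 1}], got {k}")
    if algorithm == "kmeans":
        codes = _kmeans_generalized(X, D.distance_name, k, seed)
    else:
        condensed = squareform(D.values, checks=False)
        Z = linkage(condensed, method=_LINKAGE_METHOD[algorithm])
        codes = fcluster(Z, t=k, criterion="maxclust")
    provenance = f"{algorithm} k={k} distance={D.distance_name}"
    if algorithm == "kmeans":
        provenance += f" seed={seed}"
    return ClusteringRun(
        algorithm=algorithm,
        distance_name=D.distance_name,
        k=k,
        partition=Partition.from_codes(D.item_ids, codes, provenance=provenance),
        seed=seed if algorithm == "kmeans" else None,
    )


def map_solution_to_roc(
    p: Partition, gold: GoldSolution, alpha: float = 0.5, beta: float = 0.5
) -> tuple[ROCPoint, float]:
    """Connectivity matrix -> pair confusion -> (FPR, TPR) -> BMI."""
    # gold connectivity aligned to the partition's item order
    gold_conn = connectivity_matrix(
        Partition({i: gold.labels[i] for i in p.item_ids}, provenance="gold")
    )
    pred_conn = connectivity_matrix(p)
    pt = roc_point(pair_confusion(pred_conn, gold_conn), provenance=p.provenance)
    return pt, bmi(pt, alpha, beta)


def bias_label(p: ROCPoint, margin: float = DEFAULT_BIAS_MARGIN) -> str:
    """Read the over-splitting / over-merging tendency off the ROC point.

    ``divisive`` when FPR exceeds FNR by more than ``margin`` (too many pairs
    split), ``agglomerative`` when FNR exceeds FPR by more than ``margin``
    (too many pairs merged), else ``balanced``.
    """
    fnr = 1.0 - p.tpr
    if p.fpr - fnr > margin:
        return "divisive"
    if fnr - p.fpr > margin:
        return "agglomerative"
    return "balanced"


def index_correlation(
    curve: CROCCurve,
    gold: GoldSolution,
    index_name: str,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> float:
    """Pearson correlation between the BMI series and an index series over
    the CROC solution set, ordered by cluster count.

    Solutions on which the index is undefined are dropped pairwise (and
    logged).  Raises :class:`UndefinedCorrelationError` when fewer than two
    valid solutions remain or a series is constant.
    """
    if index_name not in _INDEX_FN:
        raise ParameterError(
            f"unknown index {index_name!r}; choose from {INDEX_NAMES}"
        )
    fn = _INDEX_FN[index_name]
    sols = sorted(curve.solutions, key=lambda s: s.n_clusters)
    bmis, vals = [], []
    for s in sols:
        try:
            v = fn(contingency(gold, s.partition))
        except UndefinedIndexError:
            logger.info(
                "dropping CROC solution with %d clusters: %s undefined",
                s.n_clusters,
                index_name,
            )
            continue
        bmis.append(bmi(s.point, alpha, beta))
        vals.append(v)
    if len(bmis) < 2:
        raise UndefinedCorrelationError(
            f"fewer than 2 CROC solutions with {index_name} defined"
        )
    b = np.asarray(bmis)
    v = np.asarray(vals)
    if np.ptp(b) == 0 or np.ptp(v) == 0:
        raise UndefinedCorrelationError(
            f"constant series: correlation with {index_name} undefined"
        )
    return float(np.corrcoef(b, v)[0, 1])


def default_k_range(gold: GoldSolution, n: int) -> tuple[int, ...]:
    """2 .. min(n-1, 2r+2): brackets the gold class count r."""
    return tuple(range(2, min(n - 1, 2 * gold.r + 2) + 1))


def evaluate(
    X: FeatureMatrix,
    gold: GoldSolution,
    distance_names: Sequence[str] = DISTANCE_NAMES,
    algorithms: Sequence[str] = ALGORITHMS,
    k_range: Sequence[int] | None = None,
    alpha: float = 0.5,
    beta: float = 0.5,
    seed: int = 0,
    bias_margin: float = DEFAULT_BIAS_MARGIN,
) -> EvaluationReport:
    """Full distance-vs-algorithm comparison on one dataset.

    Per distance: the CROC, its AUC and best-point BMI, and the BMI-vs-index
    correlations.  Per algorithm x k: the ROC point, BMI, external indices,
    gray-region membership and bias call.  Distances inapplicable to the data
    (e.g. mutual information on 2-feature data) become missing cells, not
    failures.
    """
    auto_k = k_range is None
    if auto_k:
        k_range = default_k_range(gold, X.n_items)
    summaries: list[DistanceSummary] = []
    records: list[SolutionRecord] = []
    missing: list[tuple[str, str]] = []
    gray_hits: dict[str, int] = {a: 0 for a in algorithms}
    gray_total: dict[str, int] = {a: 0 for a in algorithms}

    for dist_name in distance_names:
        try:
            D = pairwise_distance_matrix(X, dist_name)
        except (InsufficientFeaturesError, CrocBmiError) as exc:
            logger.warning("distance %s inapplicable: %s", dist_name, exc)
            missing.append((dist_name, str(exc)))
            continue
        curve = croc_curve(D, gold)
        pt_star, _, bmi_star = best_point(curve, alpha, beta)
        correlations: dict[str, float | None] = {}
        for index_name in INDEX_NAMES:
            try:
                correlations[index_name] = index_correlation(
                    curve, gold, index_name, alpha, beta
                )
            except UndefinedCorrelationError as exc:
                logger.info("correlation %s/%s: %s", dist_name, index_name, exc)
                correlations[index_name] = None
        _, best_part, _ = best_point(curve, alpha, beta)
        summaries.append(
            DistanceSummary(
                distance_name=dist_name,
                bmi_star=bmi_star,
                auc=curve.auc,
                best_fpr=pt_star.fpr,
                best_tpr=pt_star.tpr,
                best_n_clusters=best_part.t,
                correlations=correlations,
            )
        )
        # when the grid is automatic, add the cluster counts realized on the
        # CROC so algorithm points are comparable to curve points
        ks = list(k_range)
        if auto_k:
            croc_ks = {
                s.n_clusters
                for s in curve.solutions
                if 2 <= s.n_clusters <= X.n_items - 1
            }
            ks = sorted(set(ks) | croc_ks)
        for algorithm in algorithms:
            for k in ks:
                run = run_clustering(X, D, algorithm, k, seed=seed)
                pt, b = map_solution_to_roc(run.partition, gold, alpha, beta)
                ct = contingency(gold, run.partition)
                idx_vals: dict[str, float | None] = {}
                for index_name in INDEX_NAMES:
                    try:
                        idx_vals[index_name] = _INDEX_FN[index_name](ct)
                    except UndefinedIndexError:
                        idx_vals[index_name] = None
                in_gray = gray_region_contains(pt, bmi_star, alpha, beta)
                gray_total[algorithm] += 1
                gray_hits[algorithm] += int(in_gray)
                records.append(
                    SolutionRecord(
                        algorithm=algorithm,
                        distance_name=dist_name,
                        k=k,
                        point=pt,
                        bmi=b,
                        adjusted_rand=idx_vals["adjusted_rand"],
                        fowlkes_mallows=idx_vals["fowlkes_mallows"],
                        f_measure=idx_vals["f_measure"],
                        in_gray=in_gray,
                        bias=bias_label(pt, bias_margin),
                    )
                )
    return EvaluationReport(
        summaries=tuple(summaries),
        records=tuple(records),
        missing=tuple(missing),
        gray_tallies={a: (gray_hits[a], gray_total[a]) for a in algorithms},
    )
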