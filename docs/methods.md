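# Methods

## Pair-level ROC mapping of partitions

All comparisons between a partition and the gold solution are made over the
n(n−1)/2 unordered item pairs (i < j, diagonal excluded; the diagonal of a
connectivity matrix is constitutively 1 and ordered pairs carry no extra
information — and since TPR/FPR are ratios, the ordered/unordered choice
does not move any ROC coordinate). The positive class is the *separated*
pair: TPR is the fraction of gold-separated pairs the prediction separates,
FPR the fraction of gold-co-clustered pairs it separates. Consequences
worth keeping in mind: the gold solution maps to (0, 1), the all-in-one
partition to (0, 0), all-singletons to (1, 1). The mapping is undefined —
and raises — when the gold has a single class or only singleton classes.

## The BMI

BMI = √(α·E_m² + β·E_b²) with E_m = FPR + FNR and E_b = |FPR − FNR|,
weights non-negative and summing to 1, default α = β = ½. The square root
is structural, not cosmetic: with it, the α = β = ½ case satisfies the
identity ½(a+b)² + ½(a−b)² = a² + b², i.e. BMI equals the Euclidean
distance from the partition's ROC point to (0, 1), which is what makes BMI
values of distances and of algorithms directly comparable and bounds BMI by
1 for any solution on or above the chance diagonal. The identity is
asserted in the test suite at 1e−12 over 10⁴ random points. E_b is the
unique symmetric unbalance measure consistent with that identity; it reads
out algorithm bias (FPR ≫ FNR: divisive; FNR ≫ FPR: agglomerative).

## Distances

* **Euclidean** — √Σ(x_i−y_i)²; delegated to `scipy.spatial.distance.pdist`.
* **Pearson** — 1 − r with r the sample correlation, range [0, 2]. On
  2-feature vectors r is exactly ±1, so the distance is exactly 0 or 2;
  planar datasets therefore yield a two-solution CROC (the sign-split
  2-clustering and all-in-one). This degeneracy is exploited as an exact
  regression case in the tests.
* **Mutual information** — 1 − MI(X;Y)/max(H(X), H(Y)). The pmfs are
  estimated by equal-width histogram binning of each vector over its own
  range with B = ⌈√m⌉ bins per variable (a standard histogram estimator
  whose resolution grows with the feature count); entropies in bits
  (the base cancels in the ratio; bits are convenient for reporting), with
  0·log 0 := 0. Below **8 features** the estimate is refused outright
  (`InsufficientFeaturesError`): a B×B joint histogram with m < 8 samples
  is essentially empty. Pipelines surface this as a missing cell rather
  than a failure.

Constant vectors make Pearson and MI undefined; both raise rather than
impute, because a silently substituted value would corrupt every CROC
built downstream. Constant rows are still *loaded* (they are legal
geometry for the Euclidean distance) but flagged in the log.

Distance matrices are normalized by the **maximum off-diagonal entry**
rather than a theoretical range, guaranteeing the [0, 1] threshold sweep
reaches every partition the matrix can induce. The transform is strictly
monotone, hence rank-preserving and idempotent, and the CROC is invariant
under it (only the ranking of distances matters — a property the tests
check under arbitrary monotone rescalings).

## The CROC

The threshold graph I_φ (edges where D ≤ φ) is closed into a partition by
connected components. The sweep runs over the sorted distinct off-diagonal
values of the normalized matrix: between consecutive values the indicator
is constant, so this finite sweep is exhaustive, and it dominates any
evenly spaced grid (its solution set is a superset). Equal distances merge
at the same threshold — no arbitrary tie order — so zero-distance pairs are
co-clustered in every solution. All-singletons is never a solution (it
would need φ < 0); the all-in-one partition always is (φ = 1). The points
(1, 1) and (0, 0) enter only as geometric anchors of the trapezoidal AUC,
which is computed over solution points plus anchors sorted by (FPR, TPR) —
exact for the step-free curves produced here, and 0.5 when the curve holds
no information.

Implementation: closure is incremental union-find over edges sorted by
distance (near-linear in the number of pairs), snapshotting a solution
after each distinct value that causes a merge; this is exactly
single-linkage agglomeration, and the tests pin both the equivalence to
per-threshold component extraction (reachability oracle) and to
`scipy` single-link tree cuts at matching cluster counts. Partitions along
the sweep are nested with non-increasing TPR and FPR.

Best point: the solution minimizing BMI, ties broken toward smaller FPR and
then fewer clusters (the more conservative separation). The gray region is
the open set {P : BMI(P) < BMI*}; points exactly on the iso-BMI boundary
are outside.

## External indices and correlation curves

Adjusted Rand, Fowlkes–Mallows and the clustering F-measure are computed
from the r×t contingency table. The F-measure is the standard form:
per gold class, the maximum over clusters of the harmonic mean of precision
T_ij/T_.j and recall T_ij/T_i., weighted by class size — with 0 where
T_ij = 0. Undefined cases (FM when a partition is all singletons, R_A when
both partitions are trivial) raise and are dropped pairwise — and logged —
from correlation series, never imputed. The BMI-vs-index correlation is the
Pearson correlation between the BMI series and the index series over all
CROC solutions (ordered by cluster count, the x-axis of the index-curve
figures); it requires at least two valid solutions and non-constant series.

## Clustering algorithms

Single/complete/average linkage consume the precomputed distance matrix
(`scipy.cluster.hierarchy`), so Pearson and MI distances are honored.
K-means is a generalized Lloyd iteration: assignment by the chosen distance
to the centroids, centroid update by coordinate-wise mean, 10 seeded
restarts, 300-iteration cap; the restart with the lowest within-cluster
distance sum wins. This is the common adaptation for non-Euclidean
distances in expression analysis and is fully reproducible given the seed.
The default cluster-count grid is 2 … min(n−1, 2r+2), bracketing the gold
class count r. The divisive/agglomerative call uses a margin of 0.2 on
|FPR − FNR| (configurable): bias is intrinsically a qualitative read off
the plane, and the margin makes the encoding explicit.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` and are
bit-reproducible from their parameter record.

* **Gaussian3** (60×600, 3 balanced classes): class i's block of 200 marker
  features is N(+1, 1) within the class and N(−1, 1) outside. The ±1/unit-sd
  defaults realize the strong-separation regime this benchmark is meant to
  occupy (the distributional parameters are exposed, not hard-coded).
* **Gaussian5** (250×2, five classes of 50): unit-variance isotropic
  Gaussians at the corners of a square of side λ plus its center. λ = 3 by
  default; λ = 2 gives heavier overlap, and `n_per_class=100` reproduces
  the 500-row variant of this design.
* **Simulated6** (60×600, classes 8/12/10/15/5/10): 50 markers per class at
  N(+1, 1) in-class vs N(0, 1) outside, plus 300 noise genes in six blocks
  of 50 assigned to the classes in order, block b carrying a residual
  effect 1·(1−b/6) — decaying to exactly 0 in the last block — with sd
  1 + b/6. The schedule encodes "decreasing differential expression and
  increasing variation" linearly; the last block is the clean null used by
  the across-class indistinguishability test.

What the generators emulate is cluster *geometry* under Gaussian noise:
they do not model heavy-tailed expression noise, feature correlation,
batch effects or missing values. Green tests on them demonstrate the
correctness and calibration of the machinery (AUC 0.5 on structureless
data, BMI ≤ 1, exact degeneracies), not performance claims on real
microarray or single-cell data.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) uses 100 replicates of
n = 50, m = 10 for the chance calibration, single 60×600 Gaussian3 and
20-replicate 250×2 Gaussian5 runs for the intrinsic-BMI values, and 200
randomized datasets (n ∈ [10, 60], m ∈ [2, 50], 1–5 classes) for the BMI
bound — sizes at which every quantity is stable to well within its
tolerance while the full run stays in the seconds-to-a-minute range.

## Known limitations

* The MI estimator is the plain equal-width histogram; no
  kernel/adaptive-bandwidth estimators, and no additional distances
  (Spearman, Manhattan, cosine) — deliberately out of scope.
* Closure of the intransitive threshold graph is the connected-component
  rule only; clique-based alternatives would give different (finer) CROCs.
* Only external validation is provided; internal indices
  (homogeneity/separation) are a non-goal, as BMI is positioned precisely
  as an external index.
* `evaluate` is O(n²) per solution in the pair-level scoring; fine for the
  hundreds-of-items scale these benchmarks target, not for 10⁵-cell
  atlases.
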