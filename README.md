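# crocbmi

Benchmarking toolkit for the first — and least examined — choice in any
clustering pipeline: the **distance function**. Given a feature matrix
(items × features: expression profiles, coordinates, …) and a gold solution
(the true partition of the items into classes), `crocbmi` measures how much
class structure a distance function can recover *on its own*, before any
clustering algorithm touches it, and then compares that intrinsic ability
against the solutions of actual clustering algorithms on a common scale.

## The method

Every partition *s* of the items is compared to the gold solution GS at the
level of unordered item pairs. Taking "the pair is in different clusters"
as the positive class, the pair-level confusion counts give

- TPR = fraction of gold-separated pairs the partition separates,
- FPR = fraction of gold-co-clustered pairs the partition separates,

so *s* becomes a point P_s = (FPR, TPR) on the ROC plane, with GS at
P_GS = (0, 1). Its quality is the **Balanced Misclassification Index**

    BMI = sqrt(α·E_m² + β·E_b²),   E_m = FPR + FNR,  E_b = |FPR − FNR|,

with α + β = 1. At the default α = β = ½ the BMI is exactly the Euclidean
distance from P_s to (0, 1): 0 means perfect agreement, and any solution
above the chance diagonal scores ≤ 1. E_m measures how much is
misclassified; E_b whether the errors are skewed toward over-splitting
(divisive bias, high FPR) or over-merging (agglomerative bias, high FNR).

A distance matrix D is mapped into the same plane by thresholding:
I_φ(i,j) = 1 iff D(i,j) ≤ φ. Threshold graphs are generally not
transitive, so each is closed into a proper partition by connected
components (equivalently: single-linkage agglomeration). Sweeping φ over
the distinct values of the normalized matrix yields the **CROC curve**
(Corrected ROC) — a curve on which *every* point is a genuine clustering
solution. Its area (AUC, 0.5 = no discriminative ability) and the BMI of
its best point summarize what the distance alone can do; a clustering
algorithm whose point falls in the **gray region** (BMI strictly below the
distance's best) improves on the raw distance.

Three distances are built in — Euclidean, Pearson correlation
(d = 1 − r), and a histogram-estimated mutual-information distance
(d = 1 − MI/max(H)) — plus four algorithms: K-means (generalized Lloyd, so
non-Euclidean distances are honored) and single/complete/average linkage on
the precomputed distance matrix. The classical external indices (adjusted
Rand, Fowlkes–Mallows, F) are included for cross-validation of the BMI.

## Worked example

Five planar Gaussian clusters (four on the corners of a square of side 3,
one in the center, 50 points each, unit variance):

```python
import crocbmi as cb

ds = cb.gen_gaussian5(seed=1, lam=3.0)
D = cb.pairwise_distance_matrix(ds.matrix, "euclidean")
curve = cb.croc_curve(D, ds.gold)
point, partition, bmi_star = cb.best_point(curve)
print(f"AUC = {curve.auc:.4f}")
print(f"best point: FPR={point.fpr:.3f}  TPR={point.tpr:.3f}  "
      f"clusters={partition.t}  BMI* = {bmi_star:.4f}")

report = cb.evaluate(ds.matrix, ds.gold, distance_names=["euclidean"],
                     algorithms=["kmeans", "complete_link", "average_link",
                                 "single_link"],
                     k_range=[5], seed=0)
for rec in report.records:
    print(f"{rec.algorithm:13s} k={rec.k}: FPR={rec.point.fpr:.3f} "
          f"TPR={rec.point.tpr:.3f} BMI={rec.bmi:.4f} "
          f"in_gray={rec.in_gray} bias={rec.bias}")
```

prints

```
AUC = 0.5747
best point: FPR=0.561  TPR=0.740  clusters=42  BMI* = 0.6184
kmeans        k=5: FPR=0.328 TPR=0.917 BMI=0.3383 in_gray=True bias=divisive
complete_link k=5: FPR=0.306 TPR=0.858 BMI=0.3373 in_gray=True bias=balanced
average_link  k=5: FPR=0.183 TPR=0.689 BMI=0.3606 in_gray=True bias=balanced
single_link   k=5: FPR=0.032 TPR=0.032 BMI=0.9687 in_gray=False bias=agglomerative
```

On these overlapping clusters the Euclidean distance alone barely beats
chance (AUC 0.57; its best solution sits at BMI 0.62, an over-fragmented
42-cluster partition). K-means, complete link and average link all land
inside the gray region — they genuinely improve on the raw distance —
while single link collapses almost everything into one cluster (TPR ≈ FPR
≈ 0.03, strongly agglomerative) and does not.

The same analysis is scriptable from the shell:

```sh
crocbmi simulate --generator gaussian5 --seed 1 --out data/
crocbmi evaluate --in data/matrix.tsv --labels data/labels.tsv \
        --metrics euclidean,pearson --out results/
```

which writes per-distance summary tables (BMI*, AUC), BMI-vs-index
correlation tables, a per-solution table with gray-region membership and
bias calls, and SVG figures of each CROC with the gray disc and the
algorithm markers.

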