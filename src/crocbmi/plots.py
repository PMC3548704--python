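"""Headless, deterministic figures for the CROC analysis.

Two layouts are provided: the ROC-plane view (CROC curve with solution
markers, the gray disc of points outperforming the distance's best solution
and the dotted iso-BMI boundary) and the index-curve view (BMI, adjusted
Rand, Fowlkes-Mallows and F along the CROC, against the number of clusters).
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .croc import CROCCurve, best_point
from .evaluation import INDEX_NAMES, EvaluationReport, index_correlation
from .io import GoldSolution
from .metrics import bmi, contingency
from .exceptions import UndefinedIndexError

__all__ = ["plot_croc", "plot_index_curves"]

_MARKERS = {"kmeans": "o", "single_link": "v", "complete_link": "s", "average_link": "D"}


def _iso_bmi_boundary(bmi_star: float, alpha: float, beta: float, steps: int = 400):
    """Points (fpr, tpr) in the unit square with BMI == bmi_star."""
    # at alpha=beta=0.5 the boundary is the circle of radius bmi_star around
    # (0, 1); for general weights sample the implicit curve on a grid
    f = np.linspace(0, 1, steps)
    t = np.linspace(0, 1, steps)
    F, T = np.meshgrid(f, t)
    em = F + (1 - T)
    eb = np.abs(F - (1 - T))
    return F, T, np.sqrt(alpha * em**2 + beta * eb**2) - bmi_star


def plot_croc(
    curve: CROCCurve,
    report: EvaluationReport | None = None,
    path: str | Path | None = None,
    alpha: float = 0.5,
    beta: float = 0.5,
    title: str | None = None,
):
    """ROC-plane figure: CROC curve, best point, gray region, algorithm marks."""
    fig, ax = plt.subplots(figsize=(5, 5))
    pts = sorted(
        [(s.point.fpr, s.point.tpr) for s in curve.solutions] + list(curve.anchors)
    )
    xs, ys = zip(*pts)
    _, _, bmi_star = best_point(curve, alpha, beta)
    F, T, level = _iso_bmi_boundary(bmi_star, alpha, beta)
    ax.contourf(F, T, level, levels=[-np.inf, 0], colors=["0.85"])
    ax.contour(F, T, level, levels=[0], colors="k", linestyles="dotted")
    ax.plot(xs, ys, "-", color="tab:blue", lw=1.5, label="CROC")
    ax.plot(
        [s.point.fpr for s in curve.solutions],
        [s.point.tpr for s in curve.solutions],
        ".",
        color="tab:blue",
    )
    bp, _, _ = best_point(curve, alpha, beta)
    ax.plot(bp.fpr, bp.tpr, "o", color="tab:green", ms=9, label="best point")
    if report is not None:
        for rec in report.records:
            if rec.distance_name != curve.distance_name:
                continue
            ax.plot(
                rec.point.fpr,
                rec.point.tpr,
                _MARKERS.get(rec.algorithm, "x"),
                ms=5,
                alpha=0.7,
                label=rec.algorithm,
            )
        # deduplicate legend entries
        handles, labels = ax.get_legend_handles_labels()
        seen: dict[str, object] = {}
        for h, l in zip(handles, labels):
            seen.setdefault(l, h)
        ax.legend(seen.values(), seen.keys(), loc="lower right", fontsize=8)
    else:
        ax.legend(loc="lower right", fontsize=8)
    ax.plot([0, 1], [0, 1], "--", color="0.6", lw=0.8)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_title(title or f"CROC — {curve.distance_name} (AUC={curve.auc:.3f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata=_no_timestamp_metadata(path))
        plt.close(fig)
    return fig


def plot_index_curves(
    curve: CROCCurve,
    gold: GoldSolution,
    path: str | Path | None = None,
    alpha: float = 0.5,
    beta: float = 0.5,
    title: str | None = None,
):
    """BMI and the classical external indices along the CROC solutions."""
    from .metrics import adjusted_rand, f_measure, fowlkes_mallows

    fns = {
        "adjusted_rand": adjusted_rand,
        "fowlkes_mallows": fowlkes_mallows,
        "f_measure": f_measure,
    }
    sols = sorted(curve.solutions, key=lambda s: s.n_clusters)
    ks = [s.n_clusters for s in sols]
    bmis = [bmi(s.point, alpha, beta) for s in sols]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ks, bmis, "o-", label="BMI")
    for name in INDEX_NAMES:
        vals = []
        for s in sols:
            try:
                vals.append(fns[name](contingency(gold, s.partition)))
            except UndefinedIndexError:
                vals.append(np.nan)
        ax.plot(ks, vals, ".-", label=name)
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("index value")
    ax.set_title(title or f"BMI vs external indices — {curve.distance_name}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata=_no_timestamp_metadata(path))
        plt.close(fig)
    return fig


def _no_timestamp_metadata(path: str | Path) -> dict | None:
    """Strip creation-date metadata so repeated runs are byte-identical."""
    suffix = Path(path).suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None
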