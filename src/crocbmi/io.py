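"""Core data containers and delimited-text readers/writers.

A dataset is a *feature matrix*: one row per item to be clustered (gene,
sample, cell line, ...), one column per feature (experimental condition,
coordinate, ...).  External knowledge about the true classes is a *gold
solution*: a partition of the items into r classes known a priori, against
which distances and clustering algorithms are scored.

Files are plain delimited text.  The feature matrix has a header row of
feature names and a leading identifier column; the gold solution is a
two-column (item_id, class label) table.  Tab and comma delimiters are
auto-detected from the header line.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "GoldSolution",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_gold_solution",
    "write_gold_solution",
    "write_report_table",
    "write_json_report",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """items x features matrix of finite reals with unique row identifiers."""

    item_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # shape (n, m), float64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        object.__setattr__(
            self, "feature_names", tuple(str(f) for f in self.feature_names)
        )
        n, m = values.shape
        if n < 2:
            raise FormatError(f"need at least 2 items, got {n}")
        if m < 1:
            raise FormatError(f"need at least 1 feature, got {m}")
        if len(self.item_ids) != n or len(self.feature_names) != m:
            raise FormatError("identifier counts do not match matrix shape")
        if len(set(self.item_ids)) != n:
            dupes = sorted({i for i in self.item_ids if self.item_ids.count(i) > 1})
            raise FormatError(f"duplicate item ids: {dupes}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at row {self.item_ids[bad[0]]!r}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        # constant rows are legal geometry but break Pearson/MI downstream
        const = np.ptp(values, axis=1) == 0
        if const.any():
            ids = [self.item_ids[i] for i in np.flatnonzero(const)]
            logger.warning(
                "constant-valued rows (Pearson/MI distances will reject them): %s",
                ids,
            )

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.item_ids), columns=list(self.feature_names)
        )


@dataclass(frozen=True)
class GoldSolution:
    """A priori partition of the items into r non-empty classes."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = {str(k): str(v) for k, v in dict(self.labels).items()}
        if not labels:
            raise CoverageError("gold solution is empty")
        object.__setattr__(self, "labels", labels)

    @property
    def r(self) -> int:
        """Number of distinct classes."""
        return len(set(self.labels.values()))

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.labels)

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def label_array(self, item_ids: Sequence[str]) -> np.ndarray:
        """Integer-coded labels aligned to ``item_ids`` order."""
        labs = [self.labels[i] for i in item_ids]
        _, codes = np.unique(labs, return_inverse=True)
        return codes


def _sniff_delimiter(header: str) -> str:
    """Tab wins if present; otherwise comma; otherwise whitespace run."""
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_feature_matrix(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Load an items x features matrix from delimited text.

    The first line is a header of feature names; the first column holds the
    item identifiers.  Raises :class:`FormatError` naming the offending
    row/column on ragged rows, duplicate ids or non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = delimiter or _sniff_delimiter(header)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no feature columns found")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().astype(str))
        raise FormatError(f"{path}: duplicate item ids: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().argmax()]
            raise FormatError(f"{path}: missing value at row {row!r}, column {col!r}")
        values[:, j] = numeric.to_numpy()
    return FeatureMatrix(
        item_ids=tuple(df.index.astype(str)),
        feature_names=tuple(df.columns.astype(str)),
        values=values,
    )


def write_feature_matrix(
    matrix: FeatureMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="item_id")


def read_gold_solution(path: str | Path, matrix: FeatureMatrix) -> GoldSolution:
    """Load a two-column (item_id, class label) file covering ``matrix``.

    Raises :class:`CoverageError` listing missing/extra item ids.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (item_id, label)")
    labels = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    have, want = set(labels), set(matrix.item_ids)
    missing, extra = sorted(want - have), sorted(have - want)
    if missing or extra:
        raise CoverageError(
            f"{path}: label file does not cover the matrix "
            f"(missing={missing}, extra={extra})"
        )
    # preserve the matrix's item order
    return GoldSolution({i: labels[i] for i in matrix.item_ids})


def write_gold_solution(gold: GoldSolution, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"item_id{delimiter}label\n")
        for item, lab in gold.labels.items():
            fh.write(f"{item}{delimiter}{lab}\n")


def write_report_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write homogeneous records as delimited text with a deterministic header.

    Column order is the order of ``columns`` if given, else the key order of
    the first record; an empty row list yields a header-only file (``columns``
    then required).
    """
    if columns is None:
        if not rows:
            raise ValueError("columns must be given when rows is empty")
        columns = list(rows[0].keys())
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep=delimiter, index=False)


def write_json_report(payload: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
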