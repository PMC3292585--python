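"""Labelled expression matrices and their plain-text I/O.

The central container is :class:`ExpressionDataset`: an ``N x K`` real matrix
of intensities (mass-spectral peaks or gene expression levels), one row per
sample, with feature identifiers (m/z ratios or gene ids, carried as opaque
strings in file order) and binary labels ``y in {1, -1}`` (1 = disease/case,
-1 = control). Intensities may be negative: baseline-corrected spectra
routinely dip below zero and are accepted as-is. Missing values are a hard
error -- the decomposition has no missing-data mechanism.

Files are plain TSV/CSV with one header row of feature ids; labels come
either from a designated column of the matrix file or from a separate
two-column (sample_id, label) file. Label aliases ``{1, -1}``, ``{1, 0}``
and ``{case, control}`` are accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, LabelError

__all__ = [
    "ExpressionDataset",
    "read_expression_matrix",
    "write_expression_matrix",
]

#: accepted spellings for the two classes (case-insensitive for strings)
_LABEL_ALIASES = {
    "1": 1, "+1": 1, "case": 1, "disease": 1, "cancer": 1,
    "-1": -1, "0": -1, "control": -1, "normal": -1,
}


@dataclass
class ExpressionDataset:
    """``N x K`` labelled feature matrix.

    Parameters
    ----------
    values
        Real matrix, rows are samples. May contain negative intensities.
    feature_ids
        K identifier strings (m/z values or gene ids), in file order.
    sample_ids
        N sample identifier strings.
    labels
        N values in {1, -1}; 1 = disease, -1 = control.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise DimensionError(f"need N >= 2 and K >= 2, got N={n}, K={k}")
        if len(self.feature_ids) != k:
            raise DimensionError(
                f"{len(self.feature_ids)} feature ids for {k} columns")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DimensionError("sample_ids/labels length must equal N")
        if not np.isfinite(self.values).all():
            raise FormatError("values contain NaN/Inf; missing data is not supported")
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise LabelError(f"labels must be in {{1, -1}}, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def require_both_classes(self) -> None:
        if not (np.any(self.labels == 1) and np.any(self.labels == -1)):
            raise LabelError("both classes (1 and -1) must be present")


def _normalize_labels(raw, context: str) -> np.ndarray:
    values = list(raw)
    distinct = sorted({str(v).strip().lower() for v in values})
    if len(distinct) != 2:
        raise LabelError(
            f"{context}: expected exactly 2 distinct label values, "
            f"found {len(distinct)}: {distinct}")
    mapped = []
    for v in values:
        key = str(v).strip().lower()
        if key.endswith(".0"):  # numeric labels read back as floats
            key = key[:-2]
        if key not in _LABEL_ALIASES:
            raise LabelError(
                f"{context}: unrecognised label {v!r}; accepted values are "
                f"{{1, -1}}, {{1, 0}} or {{case, control}}")
        mapped.append(_LABEL_ALIASES[key])
    out = np.asarray(mapped, dtype=int)
    if len(set(out.tolist())) != 2:
        raise LabelError(f"{context}: labels {distinct} map onto a single class")
    return out


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(
    path,
    label_column_or_file: str = "label",
    orientation: str = "rows-are-samples",
) -> ExpressionDataset:
    """Read a delimited labelled feature matrix.

    ``label_column_or_file`` is resolved first as a column name of the matrix
    file and, failing that, as a path to a two-column (sample_id, label)
    file. ``orientation`` is ``rows-are-samples`` (default) or
    ``columns-are-samples``; the returned dataset is always rows-are-samples.
    """
    if orientation not in ("rows-are-samples", "columns-are-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    frame.index = frame.index.astype(str)
    if orientation == "columns-are-samples":
        frame = frame.T

    labels = None
    if label_column_or_file in frame.columns:
        labels = _normalize_labels(frame[label_column_or_file], str(path))
        frame = frame.drop(columns=[label_column_or_file])
    elif os.path.exists(label_column_or_file):
        lab = pd.read_csv(label_column_or_file, sep=_sniff_sep(label_column_or_file),
                          index_col=0, dtype=str)
        lab.index = lab.index.astype(str)
        try:
            aligned = lab.iloc[:, 0].loc[frame.index]
        except KeyError as exc:
            raise LabelError(
                f"{label_column_or_file}: missing label for sample {exc}") from exc
        labels = _normalize_labels(aligned, label_column_or_file)
    else:
        raise LabelError(
            f"{label_column_or_file!r} is neither a column of {path} nor an "
            f"existing label file")

    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            # numpy's strtod round-trips exactly; pandas' fast parser does not
            values[:, j] = frame[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}")
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}")

    return ExpressionDataset(
        values=values,
        feature_ids=[str(c) for c in frame.columns],
        sample_ids=list(frame.index),
        labels=labels,
    )


def write_expression_matrix(dataset: ExpressionDataset, path,
                            label_column: str = "label") -> None:
    """Write a dataset as TSV with the label as a designated column."""
    frame = pd.DataFrame(dataset.values, index=pd.Index(dataset.sample_ids, name="sample_id"),
                         columns=dataset.feature_ids)
    frame.insert(0, label_column, dataset.labels)
    frame.to_csv(path, sep="\t")
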