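"""Ingestion of delimited expression matrices and two-class label files.

The internal model is :class:`ExpressionDataset`: a dense ``n_features x
m_samples`` matrix, unique feature identifiers, and a boolean per-sample
label vector (``True`` = positive class).  Features carrying any missing
value are dropped before analysis (see :func:`drop_missing_features`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "DatasetError",
    "ParseError",
    "LabelError",
    "AlignmentError",
    "EmptyDatasetError",
    "load_dataset",
    "drop_missing_features",
    "save_dataset",
]

#: tokens recognised as missing, compared case-insensitively
MISSING_TOKENS = {"", "na", "nan"}


class DatasetError(ValueError):
    """Base class for ingestion failures."""


class ParseError(DatasetError):
    """Matrix file is not rectangular numeric."""


class LabelError(DatasetError):
    """Label file does not define exactly two classes."""


class AlignmentError(DatasetError):
    """Sample identifiers of matrix and label files do not match."""


class EmptyDatasetError(DatasetError):
    """Every feature was removed by the missing-data filter."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A numeric feature matrix with binary sample labels.

    Attributes
    ----------
    matrix:
        Array of shape ``(n_features, m_samples)``.
    feature_ids:
        Unique identifier per feature (length ``n_features``).
    labels:
        Boolean array of length ``m_samples``; ``True`` marks the
        positive class.
    sample_ids:
        Optional sample identifiers (length ``m_samples``).
    """

    matrix: np.ndarray
    feature_ids: tuple[str, ...]
    labels: np.ndarray
    sample_ids: tuple[str, ...] | None = None
    positive_name: str = "positive"
    negative_name: str = "negative"
    allow_missing: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_ids", tuple(map(str, self.feature_ids)))
        if matrix.ndim != 2:
            raise ParseError(f"matrix must be 2-D, got shape {matrix.shape}")
        n, m = matrix.shape
        if n < 1:
            raise EmptyDatasetError("dataset has no features")
        if len(self.feature_ids) != n:
            raise ParseError(
                f"{len(self.feature_ids)} feature ids for {n} matrix rows"
            )
        if len(set(self.feature_ids)) != n:
            raise ParseError("feature ids are not unique")
        if labels.shape != (m,):
            raise LabelError(f"{labels.size} labels for {m} samples")
        if self.P < 1 or self.N < 1:
            raise LabelError("both classes must be non-empty")
        if self.sample_ids is not None:
            object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
            if len(self.sample_ids) != m:
                raise ParseError("sample_ids length mismatch")
        if not self.allow_missing and np.isnan(matrix).any():
            raise ParseError(
                "matrix contains missing values; run drop_missing_features first"
            )

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def m_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def P(self) -> int:
        """Number of positive samples."""
        return int(self.labels.sum())

    @property
    def N(self) -> int:
        """Number of negative samples."""
        return int((~self.labels).sum())

    def subset(self, feature_indices: Sequence[int]) -> np.ndarray:
        """Return the ``len(indices) x m_samples`` view for a feature subset."""
        idx = np.asarray(feature_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("feature subset must be non-empty")
        if idx.min() < 0 or idx.max() >= self.n_features:
            raise IndexError("feature index out of range")
        return self.matrix[idx, :]


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            header=0,
            keep_default_na=False,
            dtype=str,
        )
        # case-insensitive missing tokens, applied to cells only
        mask = df.apply(
            lambda col: col.str.strip().str.lower().isin(MISSING_TOKENS)
        )
        df = df.mask(mask)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns parsed (wrong delimiter?)")
    return df


def load_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    positive_label: str,
    *,
    orientation: str = "features_as_rows",
    delimiter: str = ",",
) -> ExpressionDataset:
    """Load a delimited matrix plus a two-column label file.

    Parameters
    ----------
    matrix_path:
        Delimited file with a header of identifiers and an identifier
        column; numeric elsewhere.  Empty cells, ``NA`` and ``NaN``
        (case-insensitive) are read as missing.
    labels_path:
        Two-column delimited file ``sample_id, label`` with exactly two
        distinct label values.
    positive_label:
        Which of the two label values is the positive class.  There is
        deliberately no default: sensitivity/specificity are asymmetric.
    orientation:
        ``"features_as_rows"`` (default) or ``"samples_as_rows"``.

    Returns
    -------
    ExpressionDataset
        Samples ordered as in the matrix file; labels aligned by
        sample identifier.  May contain missing values — call
        :func:`drop_missing_features` before analysis.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")

    df = _read_table(matrix_path, delimiter)
    if orientation == "samples_as_rows":
        df = df.T
    try:
        # per-cell float() conversion: correctly rounded, exact round-trip
        values = df.to_numpy(dtype=object).astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{matrix_path}: non-numeric matrix entry ({exc})") from exc

    feature_ids = [str(x) for x in df.index]
    sample_ids = [str(x) for x in df.columns]

    lab = _read_table(labels_path, delimiter)
    label_of = {str(k): str(v) for k, v in lab.iloc[:, 0].items()}
    classes = sorted(set(label_of.values()))
    if len(classes) != 2:
        raise LabelError(
            f"{labels_path}: expected exactly 2 label values, got {classes}"
        )
    if str(positive_label) not in classes:
        raise LabelError(
            f"positive label {positive_label!r} not among {classes}"
        )
    missing = [s for s in sample_ids if s not in label_of]
    extra = [s for s in label_of if s not in set(sample_ids)]
    if missing or extra:
        raise AlignmentError(
            f"sample identifiers disagree between matrix and labels "
            f"(unlabelled: {missing[:5]}, unmatched: {extra[:5]})"
        )
    labels = np.array([label_of[s] == str(positive_label) for s in sample_ids])
    negative_name = next(c for c in classes if c != str(positive_label))
    return ExpressionDataset(
        matrix=values,
        feature_ids=feature_ids,
        labels=labels,
        sample_ids=sample_ids,
        positive_name=str(positive_label),
        negative_name=negative_name,
        allow_missing=True,
    )


def drop_missing_features(ds: ExpressionDataset) -> ExpressionDataset:
    """Remove every feature with at least one missing value.

    Idempotent; the sample set is unchanged.  Raises
    :class:`EmptyDatasetError` if nothing survives.
    """
    bad = np.isnan(ds.matrix).any(axis=1)
    if not bad.any():
        return ExpressionDataset(
            matrix=ds.matrix,
            feature_ids=ds.feature_ids,
            labels=ds.labels,
            sample_ids=ds.sample_ids,
            positive_name=ds.positive_name,
            negative_name=ds.negative_name,
        )
    if bad.all():
        raise EmptyDatasetError("all features contain missing data")
    dropped = [ds.feature_ids[i] for i in np.flatnonzero(bad)]
    logger.info("dropping %d feature(s) with missing data: %s",
                len(dropped), ", ".join(dropped[:10]))
    keep = ~bad
    return ExpressionDataset(
        matrix=ds.matrix[keep, :],
        feature_ids=tuple(f for f, k in zip(ds.feature_ids, keep) if k),
        labels=ds.labels,
        sample_ids=ds.sample_ids,
        positive_name=ds.positive_name,
        negative_name=ds.negative_name,
    )


def save_dataset(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write ``ds`` back out in the format :func:`load_dataset` reads."""
    sample_ids = ds.sample_ids or tuple(f"s{i}" for i in range(ds.m_samples))
    pd.DataFrame(ds.matrix, index=list(ds.feature_ids),
                 columns=list(sample_ids)).to_csv(
        matrix_path, sep=delimiter, float_format="%.17g")
    lab = pd.DataFrame(
        {"label": [ds.positive_name if l else ds.negative_name for l in ds.labels]},
        index=list(sample_ids),
    )
    lab.index.name = "sample_id"
    lab.to_csv(labels_path, sep=delimiter)
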