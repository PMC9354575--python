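"""Data model and shared preprocessing for paired microarray studies.

The central container is :class:`ExpressionMatrix`, a probes x arrays
intensity table in which probe identifiers may repeat (replicate spots of
the same microRNA probe) while array identifiers are unique.  A
:class:`PairedStudy` bundles two such matrices profiled on the same tumor
samples -- one handled uniformly, one handled in processing order -- with
the sample and array annotations that downstream stages need.

Preprocessing follows the fixed chain

    load (raw intensities) -> log2 transform -> ... -> probe-replicate
    summarization by the median

with normalization slotted between the log2 transform and the replicate
summarization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SampleAnnotation",
    "ArrayAnnotation",
    "PairedStudy",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_sample_annotation",
    "load_array_annotation",
    "log2_transform",
    "summarize_probe_replicates",
]


class Scale(str, enum.Enum):
    """Measurement scale of an expression matrix."""

    RAW = "raw"
    LOG2 = "log2"


def _clean_ids(ids) -> list[str]:
    return [str(i).strip() for i in ids]


@dataclass
class ExpressionMatrix:
    """Probes x arrays intensity matrix.

    Parameters
    ----------
    values : ndarray of shape (n_probes, n_arrays)
        Fluorescence intensities (``scale=raw``, strictly positive) or
        log2 intensities (``scale=log2``).
    probe_ids : list of str
        Row identifiers; duplicated IDs denote probe replicates.
    array_ids : list of str
        Unique column identifiers.
    scale : Scale
    meta : dict
        Free-form provenance (e.g. the array assigned to each simulated
        sample); never consulted by computations.
    """

    values: np.ndarray
    probe_ids: list[str]
    array_ids: list[str]
    scale: Scale = Scale.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = _clean_ids(self.probe_ids)
        self.array_ids = _clean_ids(self.array_ids)
        self.scale = Scale(self.scale)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (probes x arrays)")
        if self.values.shape[0] != len(self.probe_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.probe_ids)} probe IDs"
            )
        if self.values.shape[1] != len(self.array_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.array_ids)} array IDs"
            )
        if len(set(self.array_ids)) != len(self.array_ids):
            dupes = sorted({a for a in self.array_ids if self.array_ids.count(a) > 1})
            raise ValueError(f"duplicate array IDs: {dupes}")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")
        if self.scale is Scale.RAW and not (self.values > 0).all():
            raise ValueError("raw-scale intensities must be strictly positive")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def array_index(self, array_id: str) -> int:
        try:
            return self.array_ids.index(str(array_id).strip())
        except ValueError:
            raise KeyError(f"unknown array ID {array_id!r}") from None

    def column(self, array_id: str) -> np.ndarray:
        return self.values[:, self.array_index(array_id)]

    def select_arrays(self, array_ids: list[str]) -> "ExpressionMatrix":
        """Column subset, in the order requested (lookup by ID, never index)."""
        idx = [self.array_index(a) for a in array_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.probe_ids), list(array_ids), self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.array_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.probe_ids), list(self.array_ids),
            self.scale, dict(self.meta),
        )


@dataclass
class SampleAnnotation:
    """Sample identifiers with a binary class label (e.g. tumor type)."""

    sample_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = _clean_ids(self.sample_ids)
        self.class_labels = _clean_ids(self.class_labels)
        if len(self.sample_ids) != len(self.class_labels):
            raise ValueError("one class label per sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs must be unique")
        if len(set(self.class_labels)) != 2:
            raise ValueError(
                f"exactly two classes required, got {sorted(set(self.class_labels))}"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.class_labels))

    def label_of(self, sample_id: str) -> str:
        return self.class_labels[self.sample_ids.index(str(sample_id).strip())]


@dataclass
class ArrayAnnotation:
    """Array identifiers with 1-based processing order and batch."""

    array_ids: list[str]
    processing_order: list[int]
    batch: list[str]

    def __post_init__(self) -> None:
        self.array_ids = _clean_ids(self.array_ids)
        self.processing_order = [int(o) for o in self.processing_order]
        self.batch = _clean_ids(self.batch)
        n = len(self.array_ids)
        if len(self.processing_order) != n or len(self.batch) != n:
            raise ValueError("processing_order and batch must match array_ids")
        if len(set(self.array_ids)) != n:
            raise ValueError("array IDs must be unique")
        if sorted(self.processing_order) != list(range(1, n + 1)):
            raise ValueError("processing_order must be a permutation of 1..n")

    def order_of(self, array_id: str) -> int:
        return self.processing_order[self.array_ids.index(str(array_id).strip())]


@dataclass
class PairedStudy:
    """Two expression matrices over the same samples plus annotations.

    ``uniform`` columns are labelled by sample ID (each uniformly handled
    array stands for its sample); ``nonuniform`` columns are labelled by
    array ID, and ``sample_to_array`` declares the one-to-one sample-array
    correspondence in the nonuniformly handled dataset.
    """

    uniform: ExpressionMatrix
    nonuniform: ExpressionMatrix
    samples: SampleAnnotation
    arrays: ArrayAnnotation
    sample_to_array: dict[str, str]

    def __post_init__(self) -> None:
        if self.uniform.probe_ids != self.nonuniform.probe_ids:
            raise ValueError("uniform and nonuniform probe IDs must be identical")
        if set(self.uniform.array_ids) != set(self.samples.sample_ids):
            raise ValueError("uniform matrix columns must cover exactly the samples")
        if set(self.nonuniform.array_ids) != set(self.arrays.array_ids):
            raise ValueError("nonuniform matrix columns must cover exactly the arrays")
        mapping = {str(k).strip(): str(v).strip() for k, v in self.sample_to_array.items()}
        if set(mapping) != set(self.samples.sample_ids):
            raise ValueError("sample_to_array must map every sample exactly once")
        if sorted(mapping.values()) != sorted(self.arrays.array_ids):
            raise ValueError("sample_to_array must hit every array exactly once")
        self.sample_to_array = mapping


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def load_expression_matrix(path, delimiter: str | None = None,
                           scale: Scale = Scale.RAW) -> ExpressionMatrix:
    """Read a delimited probes x arrays table.

    First column holds probe IDs, the header row holds array IDs, the body
    is numeric.  Raises on duplicate array IDs, non-numeric cells (naming
    the offending row and column) and nonpositive raw intensities.
    """
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    array_ids = _clean_ids(header[1:])
    if len(set(array_ids)) != len(array_ids):
        dupes = sorted({a for a in array_ids if array_ids.count(a) > 1})
        raise ValueError(f"duplicate array IDs in header: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    probe_ids = _clean_ids(df.index)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at probe {probe_ids[r]!r}, "
            f"array {array_ids[c]!r}"
        )
    # convert via Python's correctly-rounded parser so write -> load is exact
    values = np.array([[float(v) for v in row] for row in df.to_numpy()])
    return ExpressionMatrix(values, probe_ids, array_ids, scale)


def write_expression_matrix(x: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix in the same dialect :func:`load_expression_matrix` reads.

    Values are written with shortest round-tripping float representation so
    a write -> load cycle is an identity on values and identifiers.
    """
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write("probe_id" + sep + sep.join(x.array_ids) + "\n")
        for pid, row in zip(x.probe_ids, x.values):
            fh.write(pid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def load_sample_annotation(path, delimiter: str | None = None) -> SampleAnnotation:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    return SampleAnnotation(list(df["sample_id"]), list(df["class"]))


def load_array_annotation(path, delimiter: str | None = None) -> ArrayAnnotation:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    return ArrayAnnotation(
        list(df["array_id"]), list(df["processing_order"]), list(df["batch"])
    )


def log2_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Base-2 logarithm of every intensity; guards against double transforms."""
    if x.scale is Scale.LOG2:
        raise ValueError("matrix is already on the log2 scale")
    if not (x.values > 0).all():
        raise ValueError("log2 transform requires strictly positive values")
    return ExpressionMatrix(
        np.log2(x.values), list(x.probe_ids), list(x.array_ids), Scale.LOG2,
        dict(x.meta),
    )


def summarize_probe_replicates(x: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate rows (equal probe IDs) to their per-array median.

    Output probe IDs are unique, ordered by first appearance.  Even-sized
    replicate sets take the midpoint of the two central order statistics.
    Idempotent: a probe with a single replicate passes through unchanged.
    """
    if x.scale is not Scale.LOG2:
        raise ValueError("replicate summarization expects log2-scale data")
    df = pd.DataFrame(x.values, index=x.probe_ids)
    med = df.groupby(level=0, sort=False).median()
    return ExpressionMatrix(
        med.to_numpy(), list(med.index), list(x.array_ids), Scale.LOG2, dict(x.meta)
    )
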