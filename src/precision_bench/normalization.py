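"""Training- and test-data normalization for classifier development.

Training data may be median-, quantile- or (simplified) variance-
stabilizing-normalized, or left unnormalized as a reference.  Test data
admit seven named strategies: each of the three methods applied to the
test set alone, each applied *frozen* toward the stored training
reference (every test array normalized one at a time, never pooling test
arrays), and pooled quantile normalization of the train+test
concatenation; "no normalization" is kept as an eighth reference-only
entry so the seven named strategies remain countable as seven.

Frozen normalization maps the empirical distribution of each individual
test array onto the frozen empirical distribution of the normalized
training data, which is what a locked-down classifier sees at deployment
time: test samples arrive one at a time and must not influence each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix

__all__ = [
    "TRAIN_METHODS",
    "TEST_STRATEGIES",
    "NormalizationReference",
    "normalize_train",
    "normalize_test",
    "batch_correct",
    "write_reference",
    "read_reference",
]

#: named training normalization methods ("none" is the reference entry)
TRAIN_METHODS = ("median", "quantile", "vsn")

#: the seven named test-data strategies ("none" is the reference entry)
TEST_STRATEGIES = (
    "median_alone",
    "quantile_alone",
    "vsn_alone",
    "median_frozen",
    "quantile_frozen",
    "vsn_frozen",
    "pooled_quantile",
)

_FROZEN_METHOD = {"median_frozen": "median", "quantile_frozen": "quantile",
                  "vsn_frozen": "vsn"}


@dataclass
class NormalizationReference:
    """Frozen state of a fitted training normalization.

    Exactly the fields of the declared method are populated:
    ``reference_median`` (median), ``reference_quantiles`` (quantile), or
    ``vsn_ref_profile`` + ``vsn_target_quantiles`` (vsn).
    """

    method: str
    reference_median: float | None = None
    reference_quantiles: np.ndarray | None = None
    vsn_ref_profile: np.ndarray | None = None
    vsn_target_quantiles: np.ndarray | None = None
    vsn_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("none",) + TRAIN_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "median" and self.reference_median is None:
            raise ValueError("median reference requires reference_median")
        if self.method == "quantile":
            if self.reference_quantiles is None:
                raise ValueError("quantile reference requires reference_quantiles")
            q = np.asarray(self.reference_quantiles, dtype=float)
            if np.any(np.diff(q) < 0):
                raise ValueError("reference_quantiles must be nondecreasing")
            self.reference_quantiles = q
        if self.method == "vsn" and (
            self.vsn_ref_profile is None or self.vsn_target_quantiles is None
        ):
            raise ValueError("vsn reference requires profile and target quantiles")


def _map_to_sorted_reference(col: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Replace a column's order statistics by a sorted reference vector.

    Ties share the mean of the reference values at their tied ranks, so
    tied inputs stay tied.
    """
    order = np.argsort(col, kind="mergesort")
    out = np.empty_like(ref_sorted, dtype=float)
    out[order] = ref_sorted
    s = pd.Series(out)
    return s.groupby(pd.Series(col)).transform("mean").to_numpy()


def _quantile_normalize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.column_stack(
        [_map_to_sorted_reference(values[:, j], ref) for j in range(values.shape[1])]
    )
    return out, ref


def _vsn_calibrate(col: np.ndarray, ref_profile: np.ndarray) -> np.ndarray:
    """Affine-calibrate one array against the reference profile, then arcsinh."""
    b = np.cov(col, ref_profile)[0, 1] / max(np.var(ref_profile), 1e-12)
    if b <= 0:
        b = 1.0
    a = col.mean() - b * ref_profile.mean()
    return np.arcsinh((col - a) / b)


def normalize_train(x: ExpressionMatrix, method: str
                    ) -> tuple[ExpressionMatrix, NormalizationReference]:
    """Normalize the training arrays and freeze the reference for test use.

    median
        Shift every array so its median equals the across-array median of
        per-array medians (stored as the frozen scalar).
    quantile
        Replace each array's sorted values by the across-array mean of order
        statistics (stored as the frozen quantile vector).
    vsn
        Affine-calibrated arcsinh per array against the per-probe median
        profile, then mapping onto pooled target quantiles (profile and
        target stored).
    """
    if method == "none":
        return x.copy(), NormalizationReference("none")
    if method not in TRAIN_METHODS:
        raise ValueError(f"unknown training method {method!r}")
    if method in ("quantile", "vsn") and x.n_arrays < 2:
        raise ValueError(f"{method} normalization requires at least 2 arrays")
    v = x.values
    if method == "median":
        med = np.median(v, axis=0)
        target = float(np.median(med))
        out = v + (target - med)[None, :]
        ref = NormalizationReference("median", reference_median=target)
    elif method == "quantile":
        out, ref_q = _quantile_normalize(v)
        ref = NormalizationReference("quantile", reference_quantiles=ref_q)
    else:  # vsn
        profile = np.median(v, axis=1)
        trans = np.column_stack(
            [_vsn_calibrate(v[:, j], profile) for j in range(v.shape[1])]
        )
        target = np.sort(trans, axis=0).mean(axis=1)
        out = np.column_stack(
            [_map_to_sorted_reference(trans[:, j], target) for j in range(v.shape[1])]
        )
        ref = NormalizationReference(
            "vsn", vsn_ref_profile=profile, vsn_target_quantiles=target
        )
    return (
        ExpressionMatrix(out, list(x.probe_ids), list(x.array_ids), x.scale,
                         dict(x.meta)),
        ref,
    )


def normalize_test(x_test: ExpressionMatrix, strategy: str,
                   reference: NormalizationReference | None = None,
                   x_train: ExpressionMatrix | None = None) -> ExpressionMatrix:
    """Apply one of the seven test-data strategies (or ``none``).

    Frozen strategies require a matching-method reference and normalize
    each test array in isolation; ``pooled_quantile`` requires the
    normalized training matrix and quantile-normalizes the concatenation.
    """
    if strategy == "none":
        return x_test.copy()
    if strategy in ("median_alone", "quantile_alone", "vsn_alone"):
        out, _ = normalize_train(x_test, strategy.removesuffix("_alone"))
        return out
    if strategy in _FROZEN_METHOD:
        want = _FROZEN_METHOD[strategy]
        if reference is None or reference.method != want:
            have = None if reference is None else reference.method
            raise ValueError(
                f"{strategy} requires a {want!r} training reference, got {have!r}"
            )
        v = x_test.values
        if strategy == "median_frozen":
            med = np.median(v, axis=0)
            out = v + (reference.reference_median - med)[None, :]
        elif strategy == "quantile_frozen":
            rq = reference.reference_quantiles
            if len(rq) != v.shape[0]:
                raise ValueError("reference quantile length must equal probe count")
            out = np.column_stack(
                [_map_to_sorted_reference(v[:, j], rq) for j in range(v.shape[1])]
            )
        else:  # vsn_frozen
            profile = reference.vsn_ref_profile
            target = reference.vsn_target_quantiles
            if len(profile) != v.shape[0]:
                raise ValueError("reference profile length must equal probe count")
            out = np.column_stack(
                [_map_to_sorted_reference(_vsn_calibrate(v[:, j], profile), target)
                 for j in range(v.shape[1])]
            )
        return ExpressionMatrix(out, list(x_test.probe_ids), list(x_test.array_ids),
                                x_test.scale, dict(x_test.meta))
    if strategy == "pooled_quantile":
        if x_train is None:
            raise ValueError("pooled_quantile requires the training matrix")
        if x_train.probe_ids != x_test.probe_ids:
            raise ValueError("train and test probe IDs must be identical")
        pooled = np.column_stack([x_train.values, x_test.values])
        out, _ = _quantile_normalize(pooled)
        return ExpressionMatrix(out[:, x_train.n_arrays:], list(x_test.probe_ids),
                                list(x_test.array_ids), x_test.scale,
                                dict(x_test.meta))
    raise ValueError(
        f"unknown test strategy {strategy!r}; choose from {('none',) + TEST_STRATEGIES}"
    )


def batch_correct(x: ExpressionMatrix, batches: list[str]) -> ExpressionMatrix:
    """Location-only batch adjustment: per probe, per batch, remove the batch
    mean and restore the grand mean.  Requires >= 2 arrays per batch."""
    batches = [str(b) for b in batches]
    if len(batches) != x.n_arrays:
        raise ValueError("one batch label per array required")
    labels = np.asarray(batches)
    out = x.values.copy()
    grand = x.values.mean(axis=1)
    for b in sorted(set(batches)):
        cols = labels == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 arrays")
        out[:, cols] += (grand - x.values[:, cols].mean(axis=1))[:, None]
    return ExpressionMatrix(out, list(x.probe_ids), list(x.array_ids), x.scale,
                            dict(x.meta))


def write_reference(ref: NormalizationReference, path) -> None:
    """Serialize a frozen reference to a key-value text file."""
    with open(path, "w") as fh:
        fh.write(f"method\t{ref.method}\n")
        if ref.reference_median is not None:
            fh.write(f"reference_median\t{ref.reference_median!r}\n")
        for name, vec in (("reference_quantiles", ref.reference_quantiles),
                          ("vsn_ref_profile", ref.vsn_ref_profile),
                          ("vsn_target_quantiles", ref.vsn_target_quantiles)):
            if vec is not None:
                fh.write(name + "\t" + ",".join(repr(float(v)) for v in vec) + "\n")


def read_reference(path) -> NormalizationReference:
    kv = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition("\t")
            kv[key] = val
    vec = lambda k: (np.array([float(t) for t in kv[k].split(",")])
                     if k in kv else None)
    return NormalizationReference(
        kv["method"],
        reference_median=float(kv["reference_median"]) if "reference_median" in kv else None,
        reference_quantiles=vec("reference_quantiles"),
        vsn_ref_profile=vec("vsn_ref_profile"),
        vsn_target_quantiles=vec("vsn_target_quantiles"),
    )
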