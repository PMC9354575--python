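"""Biological and handling-effect decomposition of a paired study.

The uniformly handled dataset supplies each sample's biological effect
(the "virtual sample"); the per-sample difference between the
nonuniformly and uniformly handled arrays supplies each array's handling
effect (the "virtual array").  The decomposition is additive and
lossless: uniform + handling reconstructs the nonuniform matrix exactly.

Two dials rescale the decomposition for signal-to-noise experiments:
``reduce_signal`` shrinks the between-class contrast, and
``amplify_handling_effects`` scales the handling columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import PairedStudy, Scale

__all__ = [
    "BiologicalEffects",
    "HandlingEffects",
    "estimate_biological_effects",
    "estimate_handling_effects",
    "reduce_signal",
    "amplify_handling_effects",
]


@dataclass
class BiologicalEffects:
    """Per-sample biological profiles (probes x samples, log2 scale)."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape must be (n_probes, n_samples)")
        if len(self.class_labels) != len(self.sample_ids):
            raise ValueError("one class label per sample required")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.class_labels))

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select_samples(self, sample_ids: list[str]) -> "BiologicalEffects":
        idx = [self.sample_index(s) for s in sample_ids]
        return BiologicalEffects(
            self.values[:, idx], list(self.probe_ids), list(sample_ids),
            [self.class_labels[i] for i in idx],
        )


@dataclass
class HandlingEffects:
    """Per-array handling profiles (probes x arrays, log2-difference scale)."""

    values: np.ndarray
    probe_ids: list[str]
    array_ids: list[str]
    processing_order: list[int]
    batch: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValueError("values shape must be (n_probes, n_arrays)")
        if len(self.processing_order) != len(self.array_ids):
            raise ValueError("processing_order must cover every array")
        if len(self.batch) != len(self.array_ids):
            raise ValueError("batch must cover every array")

    def array_index(self, array_id: str) -> int:
        return self.array_ids.index(array_id)

    def column(self, array_id: str) -> np.ndarray:
        return self.values[:, self.array_index(array_id)]


def estimate_biological_effects(study: PairedStudy) -> BiologicalEffects:
    """Take the uniformly handled profiles as the virtual samples.

    Columns are returned in annotation order and carry the class label of
    each sample.
    """
    if study.uniform.scale is not Scale.LOG2:
        raise ValueError("uniform matrix must be log2-transformed first")
    missing = [s for s in study.samples.sample_ids if s not in study.uniform.array_ids]
    if missing:
        raise ValueError(f"samples missing from the uniform matrix: {missing}")
    sub = study.uniform.select_arrays(study.samples.sample_ids)
    return BiologicalEffects(
        sub.values, list(sub.probe_ids), list(study.samples.sample_ids),
        list(study.samples.class_labels),
    )


def estimate_handling_effects(study: PairedStudy) -> HandlingEffects:
    """Per-array handling effect: nonuniform profile minus uniform profile.

    For each sample's matched array pair the output column is the raw
    paired difference, so uniform + handling reconstructs the nonuniform
    matrix exactly.  Columns follow the array-annotation order.
    """
    if study.uniform.scale is not Scale.LOG2 or study.nonuniform.scale is not Scale.LOG2:
        raise ValueError("both matrices must be log2-transformed first")
    array_to_sample = {a: s for s, a in study.sample_to_array.items()}
    offenders = [a for a in study.arrays.array_ids if a not in array_to_sample]
    if offenders:
        raise ValueError(f"arrays without a matched sample: {offenders}")
    cols = []
    for a in study.arrays.array_ids:
        s = array_to_sample[a]
        cols.append(study.nonuniform.column(a) - study.uniform.column(s))
    return HandlingEffects(
        np.column_stack(cols), list(study.uniform.probe_ids),
        list(study.arrays.array_ids), list(study.arrays.processing_order),
        list(study.arrays.batch),
    )


def reduce_signal(bio: BiologicalEffects, factor: float,
                  probes: list[str] | None = None) -> BiologicalEffects:
    """Shrink the between-class contrast to ``factor`` times its size.

    For each selected probe g and sample j of class c,

        x'_gj = x_gj - (1 - f) * (m_gc - mbar_g)

    where m_gc is the probe's class-c mean and mbar_g the unweighted
    midpoint of the two class means.  The class-mean difference becomes
    f times the original while within-class deviations are preserved.
    Unselected probes pass through unchanged.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError(f"factor must lie in [0, 1], got {factor}")
    if probes is None:
        mask = np.ones(len(bio.probe_ids), dtype=bool)
    else:
        unknown = sorted(set(probes) - set(bio.probe_ids))
        if unknown:
            raise ValueError(f"unknown probe IDs: {unknown}")
        sel = set(probes)
        mask = np.array([p in sel for p in bio.probe_ids])
    labels = np.asarray(bio.class_labels)
    c0, c1 = bio.classes
    m0 = bio.values[:, labels == c0].mean(axis=1)
    m1 = bio.values[:, labels == c1].mean(axis=1)
    mid = 0.5 * (m0 + m1)
    shift = np.where(labels[None, :] == c0, (m0 - mid)[:, None], (m1 - mid)[:, None])
    out = bio.values - (1.0 - factor) * shift * mask[:, None]
    return BiologicalEffects(
        out, list(bio.probe_ids), list(bio.sample_ids), list(bio.class_labels)
    )


def amplify_handling_effects(handling: HandlingEffects, factor: float,
                             arrays: list[str] | None = None) -> HandlingEffects:
    """Multiply the selected handling columns elementwise by ``factor``."""
    if factor < 0:
        raise ValueError(f"factor must be nonnegative, got {factor}")
    if arrays is None:
        idx = np.arange(len(handling.array_ids))
    else:
        unknown = sorted(set(arrays) - set(handling.array_ids))
        if unknown:
            raise ValueError(f"unknown array IDs: {unknown}")
        idx = np.array([handling.array_index(a) for a in arrays])
    out = handling.values.copy()
    out[:, idx] = out[:, idx] * factor
    return HandlingEffects(
        out, list(handling.probe_ids), list(handling.array_ids),
        list(handling.processing_order), list(handling.batch),
    )
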