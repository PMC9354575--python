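"""Synthetic paired-study generator.

Emulates the statistical structure of a paired microRNA-array study: the
same tumor samples profiled twice, once under uniform handling and once
in processing order.  The biological layer is a per-probe baseline plus
a class effect on an informative probe subset plus per-sample noise,
replicated over probe-replicate rows with replicate noise.  The handling
layer is a smooth monotone trend in processing order (a scaled logistic
ramp, so confounded designs provably transfer class-correlated
structure) plus batch offsets plus noise.  The nonuniform matrix is the
exact float sum of the two layers, so the paired-difference estimator
recovers the injected handling layer bit-for-bit.

Processing order follows sample-collection order with one class
collected before the other, mirroring the handling/biology confounding
the framework exists to expose.  Ground-truth layers are returned
alongside the study for oracle tests and never consulted by pipeline
stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .core_data import (
    ArrayAnnotation,
    ExpressionMatrix,
    PairedStudy,
    SampleAnnotation,
    Scale,
)

__all__ = ["FixtureSpec", "GroundTruth", "generate_paired_study",
           "default_fixture", "write_paired_study"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the generator; log2 units throughout.

    The arithmetic constraints (class counts and array total divisible
    by 3) keep the 2:1 sample split and the thirds array split legal.
    """

    n_per_class: int = 24
    n_probes: int = 120
    replicates_per_probe: int = 3
    n_informative: int = 24
    class_effect_delta: float = 1.5
    bio_sd: float = 0.5
    trend_amplitude: float = 1.0
    batch_offsets: tuple[float, ...] = (-0.5, 0.5)
    handling_sd: float = 0.3
    replicate_sd: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    class_names: tuple[str, str] = ("endometrial", "ovarian")
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative must not exceed n_probes")
        for name in ("bio_sd", "handling_sd", "replicate_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_per_class % 3 != 0:
            raise ValueError("n_per_class must be divisible by 3 (2:1 split)")
        if (2 * self.n_per_class) % 3 != 0:
            raise ValueError("total arrays must be divisible by 3 (thirds split)")
        if len(self.batch_offsets) < 1:
            raise ValueError("at least one batch offset required")


@dataclass
class GroundTruth:
    """Generator internals kept as a side channel for oracle tests."""

    biological: np.ndarray       # probes*replicates x samples, log2
    handling: np.ndarray         # probes*replicates x arrays, log2 difference
    informative_probes: list[str]
    class_effect_delta: float


def _logistic_ramp(n: int) -> np.ndarray:
    """Smooth monotone ramp over processing order, centered, unit range."""
    t = np.linspace(-6.0, 6.0, n)
    r = 1.0 / (1.0 + np.exp(-t))
    return (r - r.mean()) / (r.max() - r.min())


def default_fixture() -> FixtureSpec:
    """Desk-scale spec used throughout the test suite (48 samples)."""
    return FixtureSpec()


def generate_paired_study(spec: FixtureSpec
                          ) -> tuple[PairedStudy, GroundTruth]:
    """Generate a paired study (log2 scale) plus its ground-truth layers."""
    rng = np.random.default_rng(spec.seed)
    n_samples = 2 * spec.n_per_class
    probe_names = [f"probe{i:04d}" for i in range(spec.n_probes)]
    probe_ids = [p for p in probe_names for _ in range(spec.replicates_per_probe)]
    n_rows = len(probe_ids)

    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    class_labels = ([spec.class_names[0]] * spec.n_per_class
                    + [spec.class_names[1]] * spec.n_per_class)
    array_ids = [f"a{i:03d}" for i in range(n_samples)]
    # collection order == processing order; one class collected first
    processing_order = list(range(1, n_samples + 1))
    n_batches = len(spec.batch_offsets)
    bounds = np.linspace(0, n_samples, n_batches + 1)
    batch = [f"batch{int(np.searchsorted(bounds, o, side='left'))}"
             for o in processing_order]

    informative = list(rng.choice(probe_names, spec.n_informative, replace=False))
    info_set = set(informative)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_probes)
    baseline_rows = np.repeat(baseline, spec.replicates_per_probe)
    info_rows = np.array([p in info_set for p in probe_ids])
    class_ind = np.array([l == spec.class_names[1] for l in class_labels], float)
    sample_noise = rng.normal(0.0, spec.bio_sd, (spec.n_probes, n_samples))
    sample_noise_rows = np.repeat(sample_noise, spec.replicates_per_probe, axis=0)
    replicate_noise = rng.normal(0.0, spec.replicate_sd, (n_rows, n_samples))
    biological = (
        baseline_rows[:, None]
        + spec.class_effect_delta * info_rows[:, None] * class_ind[None, :]
        + sample_noise_rows
        + replicate_noise
    )

    ramp = _logistic_ramp(n_samples)
    trend = spec.trend_amplitude * ramp  # per array, shared across probes
    offsets = np.array([spec.batch_offsets[int(b[5:]) - 1] for b in batch])
    handling = (
        trend[None, :] + offsets[None, :]
        + rng.normal(0.0, spec.handling_sd, (n_rows, n_samples))
    )

    uniform = ExpressionMatrix(biological, probe_ids, sample_ids, Scale.LOG2)
    nonuniform_values = biological + handling
    # store the realized handling layer (the paired difference) so the
    # additive decomposition is bit-exact despite float rounding
    handling = nonuniform_values - biological
    nonuniform = ExpressionMatrix(nonuniform_values, probe_ids, array_ids,
                                  Scale.LOG2)
    study = PairedStudy(
        uniform=uniform,
        nonuniform=nonuniform,
        samples=SampleAnnotation(sample_ids, class_labels),
        arrays=ArrayAnnotation(array_ids, processing_order, batch),
        sample_to_array=dict(zip(sample_ids, array_ids)),
    )
    truth = GroundTruth(biological, handling, informative,
                        spec.class_effect_delta)
    return study, truth


def write_paired_study(study: PairedStudy, out_dir, truth: GroundTruth | None = None
                       ) -> dict[str, str]:
    """Write the four study TSVs (raw-scale matrices, two annotations).

    log2 matrices are exponentiated so the files exercise the standard
    load -> log2 ingestion chain; the optional ground-truth archive goes
    to a separate subdirectory.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _write_matrix(x: ExpressionMatrix, name: str) -> None:
        path = os.path.join(out_dir, name)
        vals = np.exp2(x.values) if x.scale is Scale.LOG2 else x.values
        with open(path, "w") as fh:
            fh.write("probe_id\t" + "\t".join(x.array_ids) + "\n")
            for pid, row in zip(x.probe_ids, vals):
                fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        paths[name] = path

    _write_matrix(study.uniform, "uniform.tsv")
    _write_matrix(study.nonuniform, "nonuniform.tsv")

    path = os.path.join(out_dir, "samples.tsv")
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\tarray_id\n")
        for s, c in zip(study.samples.sample_ids, study.samples.class_labels):
            fh.write(f"{s}\t{c}\t{study.sample_to_array[s]}\n")
    paths["samples.tsv"] = path

    path = os.path.join(out_dir, "arrays.tsv")
    with open(path, "w") as fh:
        fh.write("array_id\tprocessing_order\tbatch\n")
        for a, o, b in zip(study.arrays.array_ids, study.arrays.processing_order,
                           study.arrays.batch):
            fh.write(f"{a}\t{o}\t{b}\n")
    paths["arrays.tsv"] = path

    if truth is not None:
        tdir = os.path.join(out_dir, "ground_truth")
        os.makedirs(tdir, exist_ok=True)
        np.savetxt(os.path.join(tdir, "handling_layer.tsv"), truth.handling,
                   delimiter="\t")
        with open(os.path.join(tdir, "informative_probes.txt"), "w") as fh:
            fh.write("\n".join(truth.informative_probes) + "\n")
        paths["ground_truth"] = tdir
    return paths
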