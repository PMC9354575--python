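"""Study splitting, array-to-sample assignment designs, and re-hybridization.

The virtual samples are split randomly (class-stratified) in a 2:1 ratio
into training and test sets, while the virtual arrays are split
deterministically by processing order: first and last thirds train,
middle third test.  Arrays are then assigned to samples within each part
under a *confounding*, *balanced* (blocked + randomized + stratified) or
*complete_random* design, and a simulated dataset is produced by summing
each sample's biological effect with its assigned array's handling
effect ("virtual re-hybridization").  The handling-free test profiles
serve as the benchmark against which classifier accuracy is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionMatrix, Scale
from .effects import BiologicalEffects, HandlingEffects

__all__ = [
    "DESIGNS",
    "StudySplit",
    "DesignAssignment",
    "split_samples",
    "split_study",
    "assign_arrays",
    "rehybridize",
    "make_benchmark",
    "default_block_size",
    "write_assignment",
]

DESIGNS = ("confounding", "balanced", "complete_random")


@dataclass
class StudySplit:
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    train_array_ids: list[str]
    test_array_ids: list[str]


@dataclass
class DesignAssignment:
    """Bijective array -> sample mapping within one split part."""

    mapping: dict[str, str]
    design_name: str
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("assignment must be a bijection")
        if self.design_name not in DESIGNS:
            raise ValueError(f"unknown design {self.design_name!r}")

    def sample_for(self, array_id: str) -> str:
        return self.mapping[array_id]

    def array_for(self, sample_id: str) -> str:
        for a, s in self.mapping.items():
            if s == sample_id:
                return a
        raise KeyError(f"sample {sample_id!r} not assigned")


def split_samples(sample_ids: list[str], class_labels: list[str],
                  seed: int) -> tuple[list[str], list[str]]:
    """Seeded class-stratified 2:1 split of samples into train and test.

    Requires the per-class counts to be divisible by 3 so the ratio is
    exact within each class.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(class_labels)
    train: list[str] = []
    test: list[str] = []
    for c in sorted(set(class_labels)):
        ids = [s for s, l in zip(sample_ids, labels) if l == c]
        if len(ids) % 3 != 0:
            raise ValueError(
                f"class {c!r} has {len(ids)} samples; each class count must be "
                "divisible by 3 for an exact 2:1 split"
            )
        perm = rng.permutation(len(ids))
        cut = 2 * len(ids) // 3
        train.extend(ids[i] for i in perm[:cut])
        test.extend(ids[i] for i in perm[cut:])
    # canonical order: as the samples appear in the input list
    order = {s: i for i, s in enumerate(sample_ids)}
    return sorted(train, key=order.get), sorted(test, key=order.get)


def split_study(bio: BiologicalEffects, handling: HandlingEffects,
                seed: int) -> StudySplit:
    """2:1 stratified sample split + deterministic thirds array split.

    Arrays sorted by processing order go first-third and last-third to
    training, middle third to test; the array count must be divisible
    by 3.
    """
    n_arr = len(handling.array_ids)
    if n_arr % 3 != 0:
        raise ValueError(
            f"{n_arr} arrays; the array count must be divisible by 3 for the "
            "first/middle/last thirds split"
        )
    train_s, test_s = split_samples(bio.sample_ids, bio.class_labels, seed)
    by_order = [a for _, a in sorted(zip(handling.processing_order, handling.array_ids))]
    third = n_arr // 3
    train_a = by_order[:third] + by_order[2 * third:]
    test_a = by_order[third:2 * third]
    return StudySplit(train_s, test_s, train_a, test_a)


def default_block_size(n_total_arrays: int) -> int:
    """Balanced-design block size: total/24 rounded to the nearest even >= 2.

    192 arrays at study scale gives blocks of 8.
    """
    return max(2, 2 * round(n_total_arrays / 48))


def assign_arrays(sample_ids: list[str], class_labels: list[str],
                  array_ids: list[str], processing_order: list[int],
                  design: str, seed: int,
                  block_size: int | None = None) -> DesignAssignment:
    """Assign every array of a split part to one sample under a named design.

    confounding
        Arrays in ascending processing order go to all samples of the
        lexicographically first class, then the second; within-class
        sample order is randomized by the seed.
    balanced
        Arrays are partitioned into consecutive processing-order blocks
        of ``block_size``; each block receives an equal number of samples
        from each class, placed randomly within the block.
    complete_random
        Uniformly random bijection.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    if len(sample_ids) != len(array_ids):
        raise ValueError(
            f"{len(sample_ids)} samples but {len(array_ids)} arrays; "
            "assignment requires equal counts"
        )
    rng = np.random.default_rng(seed)
    by_order = [a for _, a in sorted(zip(processing_order, array_ids))]
    classes = sorted(set(class_labels))
    per_class = {
        c: [s for s, l in zip(sample_ids, class_labels) if l == c] for c in classes
    }

    if design == "confounding":
        ordered_samples: list[str] = []
        for c in classes:
            ids = per_class[c]
            ordered_samples.extend(np.asarray(ids)[rng.permutation(len(ids))])
        mapping = dict(zip(by_order, ordered_samples))
    elif design == "balanced":
        counts = {c: len(v) for c, v in per_class.items()}
        if len(set(counts.values())) != 1:
            raise ValueError(
                f"balanced design requires equal class counts, got {counts}"
            )
        n = len(by_order)
        if block_size is None:
            raise ValueError("balanced design requires a block_size")
        if block_size % 2 != 0 or block_size < 2:
            raise ValueError(f"block_size must be even and >= 2, got {block_size}")
        if n % block_size != 0:
            raise ValueError(
                f"block_size {block_size} does not divide the {n} arrays of this part"
            )
        queues = {
            c: list(np.asarray(v)[rng.permutation(len(v))]) for c, v in per_class.items()
        }
        mapping = {}
        half = block_size // len(classes)
        for b in range(n // block_size):
            block_arrays = by_order[b * block_size:(b + 1) * block_size]
            block_samples = [queues[c].pop() for c in classes for _ in range(half)]
            placement = rng.permutation(block_size)
            for a, i in zip(block_arrays, placement):
                mapping[a] = block_samples[i]
    else:  # complete_random
        perm = rng.permutation(len(sample_ids))
        mapping = {a: sample_ids[i] for a, i in zip(by_order, perm)}
    return DesignAssignment(mapping, design, seed)


def rehybridize(bio: BiologicalEffects, handling: HandlingEffects,
                assignment: DesignAssignment) -> ExpressionMatrix:
    """Simulate a dataset: biological effect + assigned array's handling effect.

    Output columns are labelled by sample ID, ordered as the samples
    appear in ``bio``; the array assigned to each sample is retained in
    ``meta['assigned_array']``.
    """
    if bio.probe_ids != handling.probe_ids:
        raise ValueError("bio and handling probe IDs must be identical")
    sample_to_array = {s: a for a, s in assignment.mapping.items()}
    samples = [s for s in bio.sample_ids if s in sample_to_array]
    missing = set(sample_to_array) - set(samples)
    if missing:
        raise ValueError(f"assigned samples missing from bio: {sorted(missing)}")
    cols = []
    for s in samples:
        a = sample_to_array[s]
        cols.append(bio.values[:, bio.sample_index(s)] + handling.column(a))
    return ExpressionMatrix(
        np.column_stack(cols), list(bio.probe_ids), samples, Scale.LOG2,
        meta={"assigned_array": {s: sample_to_array[s] for s in samples},
              "design": assignment.design_name, "seed": assignment.seed},
    )


def make_benchmark(bio: BiologicalEffects, split: StudySplit) -> ExpressionMatrix:
    """Handling-free test-set profiles: the yardstick for classifier accuracy."""
    sub = bio.select_samples(split.test_sample_ids)
    return ExpressionMatrix(
        sub.values, list(sub.probe_ids), list(sub.sample_ids), Scale.LOG2,
        meta={"benchmark": True},
    )


def write_assignment(assignment: DesignAssignment, path) -> None:
    """Serialize as two-column TSV with a header comment (design, seed)."""
    with open(path, "w") as fh:
        fh.write(f"# design={assignment.design_name} seed={assignment.seed}\n")
        fh.write("array_id\tsample_id\n")
        for a, s in assignment.mapping.items():
            fh.write(f"{a}\t{s}\n")
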