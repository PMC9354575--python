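"""The assessment grid: simulate, preprocess, classify, score.

``precision_simulate`` repeats the full experiment: split the virtual
samples 2:1 and the virtual arrays into thirds, assign arrays to samples
under the configured designs, re-hybridize, normalize training data and
test data (every configured strategy), summarize probe replicates, train
every configured classifier, and record misclassification proportions
under three validation targets -- cross-validation on the training set,
external validation on the simulated (handling-affected) test set, and
external validation on the handling-free benchmark test set.
``uni_handled_simulate`` runs the same grid on biological effects alone.

Results come back as a long-format table with one row per grid cell and
repetition.  Cells that are structurally invalid (a frozen test strategy
paired with a different training method) or that fail are kept with a
NaN value and an explanatory status, so the grid is always complete.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import CLASSIFIERS, cross_validate, external_validate, fit_classifier
from .core_data import ExpressionMatrix, Scale, summarize_probe_replicates
from .design import (
    DESIGNS,
    assign_arrays,
    default_block_size,
    make_benchmark,
    rehybridize,
    split_samples,
    split_study,
)
from .effects import (
    BiologicalEffects,
    HandlingEffects,
    amplify_handling_effects,
    reduce_signal,
)
from .normalization import TEST_STRATEGIES, TRAIN_METHODS, normalize_test, normalize_train

__all__ = [
    "VALIDATIONS",
    "SimulationConfig",
    "uni_handled_simulate",
    "precision_simulate",
    "precision_simulate_multiclass",
    "summarize_results",
    "plot_results",
    "write_manifest",
    "config_from_yaml",
]

VALIDATIONS = ("cross_validation", "external_simulated", "external_benchmark")

_KEY_COLS = ["repetition", "train_design", "test_design", "train_norm",
             "test_norm", "classifier", "validation"]


@dataclass
class SimulationConfig:
    """Grid specification for one assessment run."""

    n_repetitions: int = 20
    base_seed: int = 0
    train_design: str = "balanced"
    test_design: str = "balanced"
    signal_factor: float = 1.0
    handling_factor: float = 1.0
    train_norms: tuple = ("none",) + TRAIN_METHODS
    test_norms: tuple = ("none",) + TEST_STRATEGIES
    classifiers: tuple = CLASSIFIERS
    block_size: int | None = None
    folds: int = 5

    def validate(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        for d in (self.train_design, self.test_design):
            if d not in DESIGNS:
                raise ValueError(f"unknown design {d!r}; choose from {DESIGNS}")
        for m in self.train_norms:
            if m not in ("none",) + TRAIN_METHODS:
                raise ValueError(f"unknown training normalization {m!r}")
        for s in self.test_norms:
            if s not in ("none",) + TEST_STRATEGIES:
                raise ValueError(f"unknown test strategy {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _frozen_compatible(train_norm: str, test_norm: str) -> bool:
    frozen = {"median_frozen": "median", "quantile_frozen": "quantile",
              "vsn_frozen": "vsn"}
    return test_norm not in frozen or frozen[test_norm] == train_norm


def _run_grid(config: SimulationConfig, rep: int, seed: int,
              train_em: ExpressionMatrix, test_sim: ExpressionMatrix,
              test_bench: ExpressionMatrix, y_train, y_test) -> list[dict]:
    rows: list[dict] = []
    base = {"repetition": rep, "train_design": config.train_design,
            "test_design": config.test_design, "seed": seed}

    for train_norm in config.train_norms:
        train_n, ref = normalize_train(train_em, train_norm)
        train_s = summarize_probe_replicates(train_n)
        fitted = {}
        cv_value = {}
        for clf_name in config.classifiers:
            clf = fit_classifier(train_s.values, y_train, clf_name,
                                 folds=config.folds, seed=seed,
                                 probe_ids=train_s.probe_ids)
            fitted[clf_name] = clf
            cv_value[clf_name] = cross_validate(
                train_s.values, y_train, clf_name, folds=config.folds, seed=seed
            )
        for test_norm in config.test_norms:
            if not _frozen_compatible(train_norm, test_norm):
                for clf_name in config.classifiers:
                    sel = str(fitted[clf_name].tuning_record.get("selected")
                              or "-")
                    for v, val, st in (
                        ("cross_validation", cv_value[clf_name], "ok"),
                        ("external_simulated", np.nan, "incompatible_reference"),
                        ("external_benchmark", np.nan, "incompatible_reference"),
                    ):
                        rows.append({**base, "train_norm": train_norm,
                                     "test_norm": test_norm,
                                     "classifier": clf_name, "validation": v,
                                     "value": val, "status": st, "selected": sel})
                continue
            sim_n = summarize_probe_replicates(
                normalize_test(test_sim, test_norm, ref, x_train=train_n))
            bench_n = summarize_probe_replicates(
                normalize_test(test_bench, test_norm, ref, x_train=train_n))
            for clf_name in config.classifiers:
                clf = fitted[clf_name]
                sel = str(clf.tuning_record.get("selected") or "-")
                ext_sim = external_validate(clf, sim_n.values, y_test,
                                            probe_ids=sim_n.probe_ids)
                ext_bench = external_validate(clf, bench_n.values, y_test,
                                              probe_ids=bench_n.probe_ids)
                for v, val in (("cross_validation", cv_value[clf_name]),
                               ("external_simulated", ext_sim),
                               ("external_benchmark", ext_bench)):
                    rows.append({**base, "train_norm": train_norm,
                                 "test_norm": test_norm, "classifier": clf_name,
                                 "validation": v, "value": val, "status": "ok",
                                 "selected": sel})
    return rows


def _finalize(frames: list[pd.DataFrame]) -> pd.DataFrame:
    result = pd.concat(frames, ignore_index=True)
    if result.duplicated(subset=_KEY_COLS).any():
        raise ValueError("duplicate grid cells in assessment result")
    ok = result.loc[result["status"] == "ok", "value"]
    if ((ok < 0) | (ok > 1)).any():
        raise ValueError("misclassification proportions must lie in [0, 1]")
    return result


def _checkpoint_path(checkpoint_dir, tag: str, config: SimulationConfig,
                     rep: int) -> str | None:
    if checkpoint_dir is None:
        return None
    os.makedirs(checkpoint_dir, exist_ok=True)
    return os.path.join(checkpoint_dir, f"{tag}_{config.digest()}_rep{rep}.tsv")


def _run_repetitions(config: SimulationConfig, tag: str, one_rep,
                     checkpoint_dir=None) -> pd.DataFrame:
    config.validate()
    frames = []
    for rep in range(config.n_repetitions):
        path = _checkpoint_path(checkpoint_dir, tag, config, rep)
        if path is not None and os.path.exists(path):
            frames.append(pd.read_csv(path, sep="\t"))
            continue
        seed = config.base_seed + rep
        df = pd.DataFrame(one_rep(rep, seed))
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        frames.append(df)
    return _finalize(frames)


def uni_handled_simulate(config: SimulationConfig, bio: BiologicalEffects,
                         checkpoint_dir=None) -> pd.DataFrame:
    """Assessment grid on biological effects only (no handling effects)."""
    bio = reduce_signal(bio, config.signal_factor)
    labels = dict(zip(bio.sample_ids, bio.class_labels))

    def one_rep(rep: int, seed: int) -> list[dict]:
        train_s, test_s = split_samples(bio.sample_ids, bio.class_labels, seed)
        tr = bio.select_samples(train_s)
        te = bio.select_samples(test_s)
        train_em = ExpressionMatrix(tr.values, tr.probe_ids, tr.sample_ids, Scale.LOG2)
        test_em = ExpressionMatrix(te.values, te.probe_ids, te.sample_ids, Scale.LOG2)
        return _run_grid(config, rep, seed, train_em, test_em, test_em,
                         [labels[s] for s in train_s], [labels[s] for s in test_s])

    return _run_repetitions(config, "uni", one_rep, checkpoint_dir)


def precision_simulate(config: SimulationConfig, bio: BiologicalEffects,
                       handling: HandlingEffects,
                       checkpoint_dir=None) -> pd.DataFrame:
    """Full virtual re-hybridization assessment grid."""
    if bio.probe_ids != handling.probe_ids:
        raise ValueError("bio and handling probe IDs must be identical")
    bio = reduce_signal(bio, config.signal_factor)
    handling = amplify_handling_effects(handling, config.handling_factor)
    labels = dict(zip(bio.sample_ids, bio.class_labels))
    order = dict(zip(handling.array_ids, handling.processing_order))
    n_total = len(handling.array_ids)
    block = config.block_size if config.block_size is not None \
        else default_block_size(n_total)

    def one_rep(rep: int, seed: int) -> list[dict]:
        split = split_study(bio, handling, seed)
        parts = {}
        for part, samples, arrays, design in (
            ("train", split.train_sample_ids, split.train_array_ids,
             config.train_design),
            ("test", split.test_sample_ids, split.test_array_ids,
             config.test_design),
        ):
            assignment = assign_arrays(
                samples, [labels[s] for s in samples], arrays,
                [order[a] for a in arrays], design, seed, block_size=block,
            )
            parts[part] = rehybridize(bio, handling, assignment)
        bench = make_benchmark(bio, split)
        return _run_grid(
            config, rep, seed, parts["train"], parts["test"], bench,
            [labels[s] for s in parts["train"].array_ids],
            [labels[s] for s in parts["test"].array_ids],
        )

    return _run_repetitions(config, "precision", one_rep, checkpoint_dir)


def precision_simulate_multiclass(config: SimulationConfig,
                                  bio: BiologicalEffects,
                                  handling: HandlingEffects,
                                  checkpoint_dir=None) -> pd.DataFrame:
    """Wrapper running the grid per configured classifier and merging results."""
    if len(config.classifiers) < 1:
        raise ValueError("at least one classifier required")
    frames = []
    for clf in config.classifiers:
        sub = SimulationConfig(**{**asdict(config), "classifiers": (clf,)})
        frames.append(precision_simulate(sub, bio, handling,
                                         checkpoint_dir=checkpoint_dir))
    return _finalize(frames)


def summarize_results(result: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and IQR of misclassification per grid cell, with the delta
    of each cell's mean against the no-normalization reference cell of the
    same design/classifier/validation."""
    if result.empty:
        raise ValueError("empty assessment result")
    ok = result[result["status"] == "ok"]
    keys = ["train_design", "test_design", "train_norm", "test_norm",
            "classifier", "validation"]
    g = ok.groupby(keys)["value"]
    summary = g.agg(
        mean="mean",
        sd=lambda v: 0.0 if len(v) < 2 else float(np.std(v, ddof=1)),
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
        n_repetitions="size",
    ).reset_index()
    ref = summary[(summary["train_norm"] == "none")
                  & (summary["test_norm"] == "none")]
    ref_keys = ["train_design", "test_design", "classifier", "validation"]
    merged = summary.merge(
        ref[ref_keys + ["mean"]].rename(columns={"mean": "_ref_mean"}),
        on=ref_keys, how="left",
    )
    merged["delta_vs_none"] = merged["mean"] - merged["_ref_mean"]
    return merged.drop(columns="_ref_mean")


def plot_results(summary: pd.DataFrame, out_dir,
                 result: pd.DataFrame | None = None) -> list[str]:
    """Heatmaps of mean misclassification (norm x classifier per validation)
    and, when the raw result table is supplied, per-cell boxplots over
    repetitions.  Every figure is rendered from a TSV written first, so
    plot-backing data are byte-stable and auditable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if summary.empty:
        raise ValueError("empty summary")
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    heat_tsv = os.path.join(out_dir, "heatmap_data.tsv")
    summary.to_csv(heat_tsv, sep="\t", index=False)
    paths.append(heat_tsv)
    backing = pd.read_csv(heat_tsv, sep="\t")
    validations = list(backing["validation"].unique())
    fig, axes = plt.subplots(1, len(validations),
                             figsize=(5 * len(validations) + 2, 5), squeeze=False)
    for ax, v in zip(axes[0], validations):
        sub = backing[backing["validation"] == v]
        pivot = sub.pivot_table(index=["train_norm", "test_norm"],
                                columns="classifier", values="mean")
        sns.heatmap(pivot, ax=ax, cmap="viridis", vmin=0, vmax=max(0.5, pivot.to_numpy().max()),
                    annot=len(pivot) <= 12, fmt=".2f")
        ax.set_title(f"mean misclassification: {v}")
    fig.tight_layout()
    heat_png = os.path.join(out_dir, "heatmap.png")
    fig.savefig(heat_png, dpi=120)
    plt.close(fig)
    paths.append(heat_png)

    if result is not None:
        box_tsv = os.path.join(out_dir, "boxplot_data.tsv")
        ok = result[result["status"] == "ok"].copy()
        ok.to_csv(box_tsv, sep="\t", index=False)
        paths.append(box_tsv)
        data = pd.read_csv(box_tsv, sep="\t")
        data["cell"] = (data["train_norm"] + "/" + data["test_norm"]
                        + "/" + data["classifier"])
        fig, axes = plt.subplots(len(validations), 1,
                                 figsize=(max(8, data["cell"].nunique() * 0.5),
                                          4 * len(validations)), squeeze=False)
        for ax, v in zip(axes[:, 0], validations):
            sub = data[data["validation"] == v]
            sns.boxplot(data=sub, x="cell", y="value", ax=ax)
            ax.set_title(v)
            ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        box_png = os.path.join(out_dir, "boxplots.png")
        fig.savefig(box_png, dpi=120)
        plt.close(fig)
        paths.append(box_png)
    return paths


def write_manifest(config: SimulationConfig, path) -> None:
    """Record the run configuration and package version as YAML."""
    payload = {"package_version": __version__, "config": asdict(config)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw = raw.get("config", raw)
    cfg = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
    cfg.validate()
    return cfg
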