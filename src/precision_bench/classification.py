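"""Binary classifier trainers and the two validation modes.

Seven methods are registered: nearest shrunken centroids (PAM), lasso-
penalized logistic regression, class-specific nearest centroids (ClaNC),
diagonal linear discriminant analysis (DLDA), k-nearest neighbors,
random forest and a linear support vector machine.  PAM, DLDA and ClaNC
are implemented here; the remaining four delegate the core fit to
scikit-learn behind a uniform tuning loop.

All trainers consume a probes x samples matrix of preprocessed (log2,
normalized, replicate-summarized) intensities.  Hyperparameters are
chosen by seeded stratified k-fold cross-validated misclassification
with deterministic tie-breaks toward the least complex setting.
Misclassification proportions are exact counts divided by the number of
samples tested.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIERS",
    "FittedClassifier",
    "train_pam",
    "train_dlda",
    "train_clanc",
    "train_generic",
    "fit_classifier",
    "cross_validate",
    "external_validate",
    "save_classifier",
    "load_classifier",
]

#: the seven registered classifier-building methods
CLASSIFIERS = ("pam", "lasso", "clanc", "dlda", "knn", "rf", "svm")

DEFAULT_CLANC_GRID = (1, 2, 5, 10, 20)


@dataclass
class FittedClassifier:
    """A trained model plus the record of how it was tuned."""

    method: str
    classes: list[str]
    model_state: dict
    tuning_record: dict = field(default_factory=dict)
    probe_ids: list[str] | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict labels for a probes x samples matrix."""
        x = np.asarray(x, dtype=float)
        return _PREDICTORS[self.method](self, x)


def _check_two_classes(y) -> tuple[np.ndarray, list[str]]:
    y = np.asarray([str(v) for v in y])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(classes) > 2:
        raise ValueError(f"binary endpoint required, got classes {classes}")
    return y, classes


# ---------------------------------------------------------------------------
# PAM: nearest shrunken centroids
# ---------------------------------------------------------------------------

def _pam_stats(x: np.ndarray, y: np.ndarray, classes: list[str]):
    """Overall/class centroids, pooled within-class SD, and the standardized
    centroid deviations d_kg = (xbar_kg - xbar_g) / (m_k (s_g + s0))."""
    n = x.shape[1]
    overall = x.mean(axis=1)
    cents, nk, ss = [], [], np.zeros(x.shape[0])
    for c in classes:
        xc = x[:, y == c]
        cents.append(xc.mean(axis=1))
        nk.append(xc.shape[1])
        ss += ((xc - cents[-1][:, None]) ** 2).sum(axis=1)
    cents = np.column_stack(cents)
    nk = np.asarray(nk, dtype=float)
    s = np.sqrt(ss / max(n - len(classes), 1))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk + 1.0 / n)
    d = (cents - overall[:, None]) / (mk[None, :] * (s + s0)[:, None])
    priors = nk / n
    return overall, s, s0, mk, d, priors


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _pam_scores(x, overall, s, s0, mk, d_shrunk, priors):
    cent = overall[:, None] + mk[None, :] * (s + s0)[:, None] * d_shrunk
    denom = (s + s0) ** 2
    # score_k(x) = sum_g (x_g - cent_kg)^2 / (s_g+s0)^2 - 2 log pi_k
    diff = x[:, :, None] - cent[:, None, :]
    return (diff ** 2 / denom[:, None, None]).sum(axis=0) - 2.0 * np.log(priors)[None, :]


def train_pam(x: np.ndarray, y, thresholds=None, folds: int = 5, seed: int = 0,
              probe_ids: list[str] | None = None) -> FittedClassifier:
    """Nearest shrunken centroids with the shrinkage Δ tuned by CV.

    Standardized centroid deviations are soft-thresholded at Δ; Δ is
    chosen from the grid by minimum cross-validated misclassification
    (ties broken toward the smallest Δ).
    """
    x = np.asarray(x, dtype=float)
    y, classes = _check_two_classes(y)
    overall, s, s0, mk, d, priors = _pam_stats(x, y, classes)
    if thresholds is None:
        thresholds = np.linspace(0.0, float(np.abs(d).max()), 30)
    thresholds = np.asarray(thresholds, dtype=float)

    errors = np.zeros(len(thresholds))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(x.T, y):
        ov, sf, s0f, mkf, df, prf = _pam_stats(x[:, tr], y[tr], classes)
        for i, delta in enumerate(thresholds):
            scores = _pam_scores(x[:, te], ov, sf, s0f, mkf,
                                 _soft_threshold(df, delta), prf)
            pred = np.asarray(classes)[np.argmin(scores, axis=1)]
            errors[i] += int((pred != y[te]).sum())
    best = int(np.flatnonzero(errors == errors.min())[0])
    delta = float(thresholds[best])
    return FittedClassifier(
        "pam", classes,
        model_state={
            "overall": overall, "s": s, "s0": s0, "mk": mk,
            "d_shrunk": _soft_threshold(d, delta), "priors": priors,
        },
        tuning_record={"grid": thresholds.tolist(), "folds": folds, "seed": seed,
                       "cv_errors": errors.tolist(), "selected": {"delta": delta}},
        probe_ids=list(probe_ids) if probe_ids is not None else None,
    )


def _predict_pam(clf: FittedClassifier, x: np.ndarray) -> np.ndarray:
    ms = clf.model_state
    scores = _pam_scores(x, ms["overall"], ms["s"], ms["s0"], ms["mk"],
                         ms["d_shrunk"], ms["priors"])
    return np.asarray(clf.classes)[np.argmin(scores, axis=1)]


# ---------------------------------------------------------------------------
# DLDA: diagonal linear discriminant analysis
# ---------------------------------------------------------------------------

def train_dlda(x: np.ndarray, y,
               probe_ids: list[str] | None = None) -> FittedClassifier:
    """Linear discriminant with a diagonal pooled covariance.

    Assigns the class minimizing sum_g (x_g - mu_kg)^2 / s2_g.  Probes
    with zero pooled variance are excluded with a warning.  Score ties
    break to the first class label in sort order.
    """
    x = np.asarray(x, dtype=float)
    y, classes = _check_two_classes(y)
    means = np.column_stack([x[:, y == c].mean(axis=1) for c in classes])
    n = x.shape[1]
    ss = np.zeros(x.shape[0])
    for i, c in enumerate(classes):
        ss += ((x[:, y == c] - means[:, [i]]) ** 2).sum(axis=1)
    s2 = ss / max(n - len(classes), 1)
    keep = s2 > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance probe(s) from DLDA",
            stacklevel=2,
        )
    return FittedClassifier(
        "dlda", classes,
        model_state={"means": means[keep], "s2": s2[keep], "keep": keep},
        probe_ids=list(probe_ids) if probe_ids is not None else None,
    )


def _predict_dlda(clf: FittedClassifier, x: np.ndarray) -> np.ndarray:
    ms = clf.model_state
    xk = x[ms["keep"]]
    diff = xk[:, :, None] - ms["means"][:, None, :]
    scores = (diff ** 2 / ms["s2"][:, None, None]).sum(axis=0)
    return np.asarray(clf.classes)[np.argmin(scores, axis=1)]


# ---------------------------------------------------------------------------
# ClaNC: class-specific nearest centroids
# ---------------------------------------------------------------------------

def clanc_statistic(x: np.ndarray, y, classes=None) -> np.ndarray:
    """Standardized (unshrunken) centroid deviations used for probe selection;
    one column per class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray([str(v) for v in y])
    if classes is None:
        classes = sorted(set(y))
    _, s, s0, mk, d, _ = _pam_stats(x, y, list(classes))
    return d


def train_clanc(x: np.ndarray, y, genes_per_class: int,
                probe_ids: list[str] | None = None) -> FittedClassifier:
    """Nearest centroids on class-specific selected probes, unshrunken.

    Each probe is a candidate for the class in which it is up-regulated
    (positive standardized deviation), so the class-specific sets are
    disjoint by construction; within a class, candidates are ranked by
    the deviation magnitude.  A class whose candidate supply falls short
    of ``genes_per_class`` (possible only for large requests) fills up
    with its strongest remaining probes regardless of sign.  The class
    centroid keeps its own mean on its active probes and falls back to
    the overall mean elsewhere.
    """
    x = np.asarray(x, dtype=float)
    y, classes = _check_two_classes(y)
    p = x.shape[0]
    if not 1 <= genes_per_class <= p:
        raise ValueError(
            f"genes_per_class must be in [1, {p}], got {genes_per_class}"
        )
    overall, s, s0, mk, d, _ = _pam_stats(x, y, classes)
    means = np.column_stack([x[:, y == c].mean(axis=1) for c in classes])
    active = {}
    for k, c in enumerate(classes):
        ranked = np.argsort(-d[:, k], kind="mergesort")
        chosen = [g for g in ranked if d[g, k] > 0][:genes_per_class]
        if len(chosen) < genes_per_class:  # up-regulated supply exhausted
            by_mag = np.argsort(-np.abs(d[:, k]), kind="mergesort")
            extra = [g for g in by_mag if g not in chosen]
            chosen += extra[: genes_per_class - len(chosen)]
        active[c] = sorted(chosen)
    cent = np.tile(overall[:, None], (1, len(classes)))
    for k, c in enumerate(classes):
        cent[active[c], k] = means[active[c], k]
    return FittedClassifier(
        "clanc", classes,
        model_state={"centroids": cent, "s": s, "s0": s0,
                     "active": {c: np.array(v) for c, v in active.items()}},
        tuning_record={"genes_per_class": genes_per_class},
        probe_ids=list(probe_ids) if probe_ids is not None else None,
    )


def _predict_clanc(clf: FittedClassifier, x: np.ndarray) -> np.ndarray:
    ms = clf.model_state
    denom = (ms["s"] + ms["s0"]) ** 2
    diff = x[:, :, None] - ms["centroids"][:, None, :]
    scores = (diff ** 2 / denom[:, None, None]).sum(axis=0)
    return np.asarray(clf.classes)[np.argmin(scores, axis=1)]


# ---------------------------------------------------------------------------
# sklearn-backed methods: lasso, knn, rf, svm
# ---------------------------------------------------------------------------

def _default_grid(method: str) -> list[dict]:
    # ordered least-complex first so argmin tie-breaks prefer simpler models
    if method == "lasso":
        return [{"C": float(c)} for c in np.logspace(-3, 3, 50)]
    if method == "knn":
        return [{"n_neighbors": k} for k in (11, 9, 7, 5, 3, 1)]
    if method == "rf":
        return [{"n_estimators": 500}]
    if method == "svm":
        return [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]
    raise ValueError(f"unknown generic method {method!r}")


def _make_estimator(method: str, params: dict, seed: int):
    if method == "lasso":
        # saga leaves the intercept unpenalized, so the penalty->inf limit
        # is the intercept-only majority-class model
        return LogisticRegression(l1_ratio=1.0, solver="saga",
                                  max_iter=2000, random_state=seed, **params)
    if method == "knn":
        return KNeighborsClassifier(**params)
    if method == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if method == "svm":
        return SVC(kernel="linear", **params)
    raise ValueError(f"unknown generic method {method!r}")


def train_generic(x: np.ndarray, y, method: str, grid=None, folds: int = 5,
                  seed: int = 0,
                  probe_ids: list[str] | None = None) -> FittedClassifier:
    """Tune and fit a delegated classifier (lasso / knn / rf / svm).

    The hyperparameter grid is searched by seeded stratified k-fold
    cross-validated misclassification; ties go to the earliest (least
    complex) grid entry.  Degenerate entries (e.g. k exceeding the fold
    size) are skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y, classes = _check_two_classes(y)
    if method not in ("lasso", "knn", "rf", "svm"):
        raise ValueError(f"unknown generic method {method!r}")
    grid = list(grid) if grid is not None else _default_grid(method)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    xt = x.T

    if len(grid) == 1:
        best_params, errors = grid[0], [float("nan")]
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(xt, y))
        errors = []
        for params in grid:
            try:
                err = 0
                for tr, te in splits:
                    est = _make_estimator(method, params, seed)
                    est.fit(xt[tr], y[tr])
                    err += int((est.predict(xt[te]) != y[te]).sum())
                errors.append(err)
            except Exception as exc:  # degenerate entry (e.g. k > fold size)
                warnings.warn(f"skipping grid entry {params}: {exc}", stacklevel=2)
                errors.append(float("inf"))
        if not np.isfinite(errors).any():
            raise ValueError("every hyperparameter grid entry failed")
        best_params = grid[int(np.argmin(errors))]
    est = _make_estimator(method, best_params, seed)
    est.fit(xt, y)
    return FittedClassifier(
        method, classes,
        model_state={"estimator": est},
        tuning_record={"grid": grid, "folds": folds, "seed": seed,
                       "cv_errors": list(errors), "selected": best_params},
        probe_ids=list(probe_ids) if probe_ids is not None else None,
    )


def _predict_generic(clf: FittedClassifier, x: np.ndarray) -> np.ndarray:
    return np.asarray(clf.model_state["estimator"].predict(x.T))


_PREDICTORS = {
    "pam": _predict_pam,
    "dlda": _predict_dlda,
    "clanc": _predict_clanc,
    "lasso": _predict_generic,
    "knn": _predict_generic,
    "rf": _predict_generic,
    "svm": _predict_generic,
}


# ---------------------------------------------------------------------------
# Uniform fitting entry point and the two validation modes
# ---------------------------------------------------------------------------

def fit_classifier(x: np.ndarray, y, method: str, folds: int = 5, seed: int = 0,
                   grid=None, probe_ids: list[str] | None = None) -> FittedClassifier:
    """Train any registered method with its default tuning protocol."""
    if method not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {method!r}; choose from {CLASSIFIERS}")
    if method == "pam":
        return train_pam(x, y, thresholds=grid, folds=folds, seed=seed,
                         probe_ids=probe_ids)
    if method == "dlda":
        return train_dlda(x, y, probe_ids=probe_ids)
    if method == "clanc":
        x = np.asarray(x, dtype=float)
        y_arr, _ = _check_two_classes(y)
        candidates = [g for g in (grid or DEFAULT_CLANC_GRID) if g <= x.shape[0]]
        if len(candidates) == 1:
            return train_clanc(x, y_arr, candidates[0], probe_ids=probe_ids)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(x.T, y_arr))
        errors = []
        for g in candidates:
            err = 0
            for tr, te in splits:
                sub = train_clanc(x[:, tr], y_arr[tr], g)
                err += int((sub.predict(x[:, te]) != y_arr[te]).sum())
            errors.append(err)
        best = candidates[int(np.argmin(errors))]
        clf = train_clanc(x, y_arr, best, probe_ids=probe_ids)
        clf.tuning_record.update({"grid": list(candidates), "folds": folds,
                                  "seed": seed, "cv_errors": errors})
        return clf
    return train_generic(x, y, method, grid=grid, folds=folds, seed=seed,
                         probe_ids=probe_ids)


def cross_validate(x: np.ndarray, y, method: str, folds: int = 5,
                   seed: int = 0, grid=None) -> float:
    """Pooled misclassification proportion over seeded stratified k-folds.

    Each fold retrains the full tuning protocol on the remaining data
    (nested cross-validation for tuned methods).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.asarray(x, dtype=float)
    y, classes = _check_two_classes(y)
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(
            f"smallest class ({counts}) is too small for {folds}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = 0
    for tr, te in skf.split(x.T, y):
        clf = fit_classifier(x[:, tr], y[tr], method, folds=folds, seed=seed,
                             grid=grid)
        wrong += int((clf.predict(x[:, te]) != y[te]).sum())
    return wrong / len(y)


def external_validate(clf: FittedClassifier, x_test: np.ndarray, y_test,
                      probe_ids: list[str] | None = None) -> float:
    """Proportion of test samples whose predicted label differs from truth."""
    if probe_ids is not None and clf.probe_ids is not None \
            and list(probe_ids) != list(clf.probe_ids):
        raise ValueError("test probe set does not match the training probe set")
    y_test = np.asarray([str(v) for v in y_test])
    pred = clf.predict(np.asarray(x_test, dtype=float))
    return int((pred != y_test).sum()) / len(y_test)


def save_classifier(clf: FittedClassifier, path) -> None:
    """Persist a fitted classifier (self-describing pickle)."""
    with open(path, "wb") as fh:
        pickle.dump(clf, fh)


def load_classifier(path) -> FittedClassifier:
    with open(path, "rb") as fh:
        clf = pickle.load(fh)
    if not isinstance(clf, FittedClassifier):
        raise TypeError("file does not contain a FittedClassifier")
    return clf
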