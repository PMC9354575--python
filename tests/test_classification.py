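"""Classifier trainers, tuning determinism, and the two validation modes."""

import numpy as np
import pytest

from precision_bench.classification import (
    CLASSIFIERS,
    cross_validate,
    external_validate,
    fit_classifier,
    load_classifier,
    save_classifier,
    train_clanc,
    train_dlda,
    train_generic,
    train_pam,
)
from precision_bench.classification import clanc_statistic


def make_gaussian(rng, n_per_class=20, p=20, delta=3.0, informative=None):
    """Two Gaussian classes separated by delta SDs on the informative probes."""
    informative = informative if informative is not None else p
    x = rng.normal(0, 1, (p, 2 * n_per_class))
    x[:informative, n_per_class:] += delta
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return x, y


def nearest_centroid_oracle(x_train, y_train, x_new):
    """Independent standardized nearest-centroid rule, per-sample loop."""
    classes = sorted(set(y_train))
    n = x_train.shape[1]
    cents, ss, nk = {}, np.zeros(x_train.shape[0]), {}
    for c in classes:
        xc = x_train[:, y_train == c]
        cents[c] = xc.mean(axis=1)
        nk[c] = xc.shape[1]
        ss += ((xc - cents[c][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    preds = []
    for j in range(x_new.shape[1]):
        best, best_score = None, None
        for c in classes:
            score = float((((x_new[:, j] - cents[c]) / (s + s0)) ** 2).sum()
                          - 2.0 * np.log(nk[c] / n))
            if best_score is None or score < best_score:
                best, best_score = c, score
        preds.append(best)
    return np.array(preds)


class TestPam:
    def test_delta_zero_matches_independent_nearest_centroid(self, rng):
        x, y = make_gaussian(rng, n_per_class=15, p=20, delta=1.0)
        clf = train_pam(x, y, thresholds=[0.0])
        x_new = rng.normal(0.5, 1.5, (20, 40))
        assert np.array_equal(clf.predict(x_new),
                              nearest_centroid_oracle(x, y, x_new))

    def test_extreme_shrinkage_falls_back_to_class_priors(self, rng):
        x = rng.normal(0, 1, (10, 30))
        y = np.array(["A"] * 10 + ["B"] * 20)  # B is the majority class
        clf = train_pam(x, y, thresholds=[1e6])
        assert (clf.model_state["d_shrunk"] == 0).all()
        assert set(clf.predict(rng.normal(size=(10, 12)))) == {"B"}

    def test_separable_classes_zero_training_error(self, rng):
        x, y = make_gaussian(rng, delta=3.0)
        clf = train_pam(x, y, seed=0)
        assert external_validate(clf, x, y) == 0.0

    def test_threshold_ties_break_to_smallest(self, rng):
        x, y = make_gaussian(rng, delta=3.0)
        clf = train_pam(x, y, thresholds=[0.0, 0.1], seed=0)
        # both thresholds classify perfectly -> smallest wins
        assert clf.tuning_record["selected"]["delta"] == 0.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_pam(rng.normal(size=(5, 8)), ["A"] * 8)


class TestDlda:
    def test_one_probe_symmetric_boundary(self):
        x = np.array([[-1.0, -1.2, -0.8, 1.0, 1.2, 0.8]])
        y = np.array(["A"] * 3 + ["B"] * 3)
        clf = train_dlda(x, y)
        assert clf.predict(np.array([[-0.1]]))[0] == "A"
        assert clf.predict(np.array([[0.1]]))[0] == "B"

    def test_equal_class_means_tie_breaks_to_first_sorted_label(self, rng):
        x = np.array([[1.0, 2.0, 1.0, 2.0]])
        y = np.array(["B", "B", "A", "A"])  # identical class means
        clf = train_dlda(x, y)
        assert clf.predict(np.array([[1.5]]))[0] == "A"

    def test_matches_brute_force_discriminant_formula(self, rng):
        x, y = make_gaussian(rng, n_per_class=12, p=10, delta=1.0)
        clf = train_dlda(x, y)
        x_new = rng.normal(0.5, 1, (10, 25))
        classes = sorted(set(y))
        means = {c: x[:, y == c].mean(axis=1) for c in classes}
        s2 = sum(((x[:, y == c] - means[c][:, None]) ** 2).sum(axis=1)
                 for c in classes) / (x.shape[1] - 2)
        expect = []
        for j in range(x_new.shape[1]):
            scores = {c: (((x_new[:, j] - means[c]) ** 2) / s2).sum()
                      for c in classes}
            expect.append(min(classes, key=lambda c: (scores[c], c)))
        assert np.array_equal(clf.predict(x_new), np.array(expect))

    def test_zero_variance_probe_excluded_with_warning(self, rng):
        x, y = make_gaussian(rng, n_per_class=8, p=5, delta=1.0)
        x[2] = 7.0  # constant probe
        with pytest.warns(UserWarning, match="zero-variance"):
            clf = train_dlda(x, y)
        assert clf.model_state["keep"].sum() == 4


class TestClanc:
    def test_all_probes_reduces_to_standardized_nearest_centroid(self, rng):
        x, y = make_gaussian(rng, n_per_class=15, p=12, delta=1.0)
        clf = train_clanc(x, y, genes_per_class=12)
        x_new = rng.normal(0.5, 1.5, (12, 30))
        assert np.array_equal(clf.predict(x_new),
                              nearest_centroid_oracle(x, y, x_new))

    def test_informative_probes_rank_first_for_their_class(self, rng):
        x, y = make_gaussian(rng, n_per_class=20, p=30, delta=4.0, informative=5)
        d = clanc_statistic(x, y)
        top5 = set(np.argsort(-np.abs(d[:, 1]))[:5])
        assert top5 == {0, 1, 2, 3, 4}

    def test_selection_invariant_to_probe_permutation(self, rng):
        x, y = make_gaussian(rng, n_per_class=10, p=15, delta=2.0, informative=4)
        perm = rng.permutation(15)
        d = clanc_statistic(x, y)
        d_perm = clanc_statistic(x[perm], y)
        assert np.allclose(d_perm, d[perm])

    def test_no_overlap_when_supply_suffices(self, rng):
        x, y = make_gaussian(rng, n_per_class=10, p=20, delta=1.0)
        x[:10, 10:] -= 2.0  # first half up in class A, second half up in B
        clf = train_clanc(x, y, genes_per_class=5)
        active = clf.model_state["active"]
        sets = [set(v.tolist()) for v in active.values()]
        assert not sets[0] & sets[1]

    def test_requesting_more_probes_than_available_rejected(self, rng):
        x, y = make_gaussian(rng, p=10)
        with pytest.raises(ValueError, match="genes_per_class"):
            train_clanc(x, y, genes_per_class=11)


class TestGeneric:
    def test_knn_k1_zero_training_error(self, rng):
        x, y = make_gaussian(rng, n_per_class=10, p=8, delta=0.5)
        clf = train_generic(x, y, "knn", grid=[{"n_neighbors": 1}])
        assert external_validate(clf, x, y) == 0.0

    def test_lasso_infinite_penalty_predicts_majority(self, rng):
        x = rng.normal(0, 1, (10, 30))
        y = np.array(["A"] * 10 + ["B"] * 20)
        clf = train_generic(x, y, "lasso", grid=[{"C": 1e-8}])
        assert set(clf.predict(rng.normal(size=(10, 15)))) == {"B"}

    def test_svm_separable_zero_training_error(self, rng):
        x, y = make_gaussian(rng, delta=3.0)
        clf = train_generic(x, y, "svm", seed=0)
        assert external_validate(clf, x, y) == 0.0

    def test_tie_break_prefers_least_complex_entry(self, rng):
        x, y = make_gaussian(rng, delta=4.0)
        clf = train_generic(x, y, "knn", seed=0)
        # all k classify the well-separated data perfectly; largest k wins
        assert clf.tuning_record["selected"] == {"n_neighbors": 11}

    def test_empty_grid_rejected(self, rng):
        x, y = make_gaussian(rng)
        with pytest.raises(ValueError, match="non-empty"):
            train_generic(x, y, "knn", grid=[])


class TestValidation:
    def test_constant_classifier_on_balanced_labels_scores_half(self, rng):
        x = rng.normal(0, 1, (5, 20))
        y = np.array(["A"] * 10 + ["B"] * 20)[:20]
        clf = train_pam(x[:, :20], np.array(["A"] * 10 + ["B"] * 10),
                        thresholds=[1e9])
        # extreme shrinkage predicts one class everywhere
        balanced_y = np.array(["A"] * 10 + ["B"] * 10)
        assert external_validate(clf, x, balanced_y) == 0.5

    @pytest.mark.parametrize("method", ["dlda", "pam", "knn"])
    def test_separable_fixture_zero_cv_error(self, rng, method):
        x, y = make_gaussian(rng, n_per_class=15, delta=4.0)
        assert cross_validate(x, y, method, folds=3, seed=0) == 0.0

    def test_cross_validation_deterministic_per_seed(self, rng):
        x, y = make_gaussian(rng, n_per_class=12, delta=1.0)
        a = cross_validate(x, y, "dlda", folds=4, seed=9)
        b = cross_validate(x, y, "dlda", folds=4, seed=9)
        assert a == b

    def test_external_validation_counts_disagreements(self, rng):
        x, y = make_gaussian(rng, delta=3.0)
        clf = train_dlda(x, y)
        assert external_validate(clf, x, y) == 0.0
        flipped = np.where(y == "A", "B", "A")
        assert external_validate(clf, x, flipped) == 1.0
        # independent count on a noisy test set
        x_new = rng.normal(1.5, 2.0, (20, 40))
        y_new = np.array(["A"] * 20 + ["B"] * 20)
        pred = clf.predict(x_new)
        expect = sum(p != t for p, t in zip(pred, y_new)) / 40
        assert external_validate(clf, x_new, y_new) == expect

    def test_probe_mismatch_rejected(self, rng):
        x, y = make_gaussian(rng, p=6)
        clf = fit_classifier(x, y, "dlda", probe_ids=[f"p{i}" for i in range(6)])
        with pytest.raises(ValueError, match="probe set"):
            external_validate(clf, x, y, probe_ids=[f"q{i}" for i in range(6)])

    def test_small_class_cannot_stratify(self, rng):
        x = rng.normal(size=(4, 6))
        y = np.array(["A", "A", "A", "A", "B", "B"])
        with pytest.raises(ValueError, match="too small"):
            cross_validate(x, y, "dlda", folds=5, seed=0)


class TestDeterminismAndSymmetry:
    @pytest.mark.parametrize("method", CLASSIFIERS)
    def test_fixed_inputs_give_identical_predictions(self, method):
        rng = np.random.default_rng(7)
        x, y = make_gaussian(rng, n_per_class=12, p=15, delta=1.0)
        x_new = rng.normal(0.5, 1, (15, 20))
        preds = []
        for _ in range(2):
            clf = fit_classifier(x, y, method, folds=3, seed=42)
            preds.append(clf.predict(x_new))
        assert np.array_equal(preds[0], preds[1])

    @pytest.mark.parametrize("method", ["pam", "dlda", "clanc", "knn", "svm"])
    def test_label_permutation_symmetry(self, method):
        rng = np.random.default_rng(11)
        x, y = make_gaussian(rng, n_per_class=12, p=15, delta=1.5)
        x_new = rng.normal(0.7, 1, (15, 24))
        y_new = np.array(["A"] * 12 + ["B"] * 12)
        clf = fit_classifier(x, y, method, folds=3, seed=1)
        err = external_validate(clf, x_new, y_new)
        swap = {"A": "B", "B": "A"}
        y_sw = np.array([swap[v] for v in y])
        y_new_sw = np.array([swap[v] for v in y_new])
        clf_sw = fit_classifier(x, y_sw, method, folds=3, seed=1)
        assert external_validate(clf_sw, x_new, y_new_sw) == err

    def test_misclassification_is_exact_count_ratio(self, rng):
        x, y = make_gaussian(rng, n_per_class=9, delta=0.2)
        clf = fit_classifier(x, y, "dlda")
        err = external_validate(clf, x, y)
        assert err * 18 == int(round(err * 18))
        assert 0.0 <= err <= 1.0


class TestSerialization:
    @pytest.mark.parametrize("method", ["pam", "dlda", "svm"])
    def test_save_load_predicts_identically(self, rng, method, tmp_path):
        x, y = make_gaussian(rng, n_per_class=10, p=8, delta=1.0)
        clf = fit_classifier(x, y, method, folds=3, seed=0)
        path = tmp_path / "clf.pkl"
        save_classifier(clf, path)
        back = load_classifier(path)
        x_new = rng.normal(size=(8, 12))
        assert np.array_equal(back.predict(x_new), clf.predict(x_new))
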