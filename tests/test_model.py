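"""Classifiers, SMOTE, patient-wise CV, metrics, and McNemar tests."""

import numpy as np
import pytest

from conftest import make_planted_features
from subtracad.model import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    MassClassifier,
    build_ann,
    build_classifier,
    compute_metrics,
    kfold_cv,
    lopo_cv,
    mcnemar_all_pairs,
    mcnemar_compare,
    metrics_from_confusion,
    smote_balance,
    trapezoidal_auc,
)


def _blobs(n=30, gap=3.0, seed=0, d=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-gap, 0.3, (n, d)), rng.normal(gap, 0.3, (n, d))])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestSmote:
    def test_balanced_input_unchanged(self):
        X, y = _blobs(10)
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_counts_equalized(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4))
        y = np.array([0] * 10 + [1] * 50)
        Xb, yb = smote_balance(X, y, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [50, 50]
        np.testing.assert_array_equal(Xb[:60], X)  # originals untouched

    def test_synthetic_points_on_minority_segments(self):
        """Geometric contract: every synthetic row is a convex combination
        of two minority samples."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = np.array([0] * 8 + [1] * 32)
        Xb, yb = smote_balance(X, y, k_neighbors=4, seed=3)
        minority = X[y == 0]
        for row in Xb[40:]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = d @ d
                    if denom < 1e-18:
                        continue
                    t = (row - minority[i]) @ d / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(
                        row - (minority[i] + t * d)
                    ) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_minority_too_small(self):
        X = np.zeros((5, 2))
        y = np.array([0, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            smote_balance(X, y)


class TestClassifierSuite:
    @pytest.mark.parametrize("spec", [s for s in CLASSIFIER_NAMES if s != "ann"])
    def test_separable_data_training_accuracy(self, spec):
        X, y = _blobs()
        clf = MassClassifier(spec=spec, round=1, smote=False, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_ann_separable_with_scaled_epoch_budget(self):
        """On a 60-sample set one epoch is a single Adam step, so the
        fixed learning rate needs proportionally more epochs than on a
        cohort-sized training set; architecture unchanged."""
        X, y = _blobs()
        clf = MassClassifier(
            spec="ann",
            round=1,
            smote=False,
            random_state=0,
            hyperparameters={"max_iter": 3000, "early_stopping": False},
        ).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_voting_soft_score_is_mean_of_members(self):
        X, y = _blobs(seed=4)
        clf = MassClassifier(spec="voting", round=2, smote=False, random_state=0).fit(X, y)
        voting = clf.estimator_
        member_probas = np.mean(
            [m.predict_proba(clf._transform(X)) for m in voting.estimators_], axis=0
        )
        np.testing.assert_allclose(clf.predict_proba(X), member_probas, atol=1e-12)

    @pytest.mark.parametrize("spec", ("lda", "knn", "svm", "rf", "gb"))
    def test_shuffled_labels_give_chance_auc(self, spec):
        """Label-permutation control: mean AUC near 0.5 across 10 seeds."""
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 5))
            y = rng.permutation([0] * 40 + [1] * 40)
            X_tr, X_te = X[:60], X[60:]
            y_tr, y_te = y[:60], y[60:]
            clf = MassClassifier(spec=spec, round=1, smote=False, random_state=seed)
            clf.fit(X_tr, y_tr)
            aucs.append(trapezoidal_auc(y_te == 1, clf.decision_scores(X_te)))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("transformer")
        with pytest.raises(ValueError):
            MassClassifier(spec="cnn").fit(*_blobs(5))


class TestAnnBuilder:
    def test_layer_counts_per_round(self):
        assert len(build_ann(1).hyperparameters["hidden_layer_sizes"]) == 5
        assert len(build_ann(2).hyperparameters["hidden_layer_sizes"]) == 1

    def test_optimizer_configuration(self):
        hp = build_ann(1).hyperparameters
        assert hp["solver"] == "adam"
        assert hp["batch_size"] == 128
        assert hp["learning_rate_init"] == pytest.approx(1e-4)
        assert hp["max_iter"] == 100
        assert hp["early_stopping"] is True
        assert hp["activation"] == "relu"

    def test_seeded_weight_determinism(self):
        X, y = _blobs(20)
        a = build_classifier(build_ann(2, seed=7)).fit(X, y)
        b = build_classifier(build_ann(2, seed=7)).fit(X, y)
        for wa, wb in zip(a.coefs_, b.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_round2_ann_skips_standardization(self):
        clf = MassClassifier(spec="ann", round=2)
        assert not clf._should_standardize()
        assert MassClassifier(spec="ann", round=1)._should_standardize()
        assert MassClassifier(spec="svm", round=2)._should_standardize()


def _grouped_cohort(n_patients=12, per_patient=6, gap=2.5, seed=0):
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for p in range(n_patients):
        label = p % 2
        X.append(rng.normal(gap * (2 * label - 1), 0.4, (per_patient, 4)))
        y.extend([label] * per_patient)
        groups.extend([f"P{p}"] * per_patient)
    return np.vstack(X), np.array(y), np.array(groups)


class TestPatientWiseCV:
    def test_lopo_fold_structure(self):
        X, y, groups = _grouped_cohort()
        report = lopo_cv(X, y, groups, ClassifierSpec("lda"), n_boot=0)
        assert len(np.unique(report.fold_assignment)) == 12
        # each fold holds exactly one patient's ROIs
        for fold in np.unique(report.fold_assignment):
            assert len(np.unique(groups[report.fold_assignment == fold])) == 1

    def test_perfectly_separable_cohort_is_perfect(self):
        X, y, groups = _grouped_cohort()
        report = lopo_cv(X, y, groups, ClassifierSpec("svm"), n_boot=0)
        assert report.accuracy == 100.0
        assert report.auc == 1.0

    def test_kfold_equals_lopo_at_k_n_patients(self):
        X, y, groups = _grouped_cohort(n_patients=8)
        lopo = lopo_cv(X, y, groups, ClassifierSpec("lda"), n_boot=0)
        kf = kfold_cv(X, y, groups, 8, ClassifierSpec("lda"), n_boot=0)
        lopo_folds = {frozenset(np.flatnonzero(lopo.fold_assignment == f))
                      for f in np.unique(lopo.fold_assignment)}
        kf_folds = {frozenset(np.flatnonzero(kf.fold_assignment == f))
                    for f in np.unique(kf.fold_assignment)}
        assert lopo_folds == kf_folds
        np.testing.assert_array_equal(lopo.y_pred, kf.y_pred)

    def test_kfold_partitions_patients_evenly(self):
        X, y, groups = _grouped_cohort(n_patients=11)
        report = kfold_cv(X, y, groups, 5, ClassifierSpec("lda"), n_boot=0)
        seen = {}
        for fold in np.unique(report.fold_assignment):
            for p in np.unique(groups[report.fold_assignment == fold]):
                assert p not in seen
                seen[p] = fold
        sizes = np.bincount(list(seen.values()))
        assert sizes.max() - sizes.min() <= 1

    def test_kfold_k_exceeding_patients_rejected(self):
        X, y, groups = _grouped_cohort(n_patients=4)
        with pytest.raises(ValueError):
            kfold_cv(X, y, groups, 10, ClassifierSpec("lda"))

    def test_test_fold_labels_cannot_leak(self):
        """Flipping one patient's labels must not change that patient's
        predictions: its fold is trained without them."""
        X, y, groups = _grouped_cohort()
        base = lopo_cv(X, y, groups, ClassifierSpec("lda"), n_boot=0)
        y_mod = y.copy()
        y_mod[groups == "P3"] = 1 - y_mod[groups == "P3"]
        mod = lopo_cv(X, y_mod, groups, ClassifierSpec("lda"), n_boot=0)
        sel = groups == "P3"
        np.testing.assert_array_equal(base.y_pred[sel], mod.y_pred[sel])

    def test_smote_changes_training_size_only(self):
        X, y, groups = _grouped_cohort(n_patients=10, per_patient=4)
        # imbalance: drop most positives
        keep = (y == 0) | (np.arange(len(y)) % 3 == 0)
        X, y, groups = X[keep], y[keep], groups[keep]
        with_smote = lopo_cv(X, y, groups, ClassifierSpec("lda"), smote=True, n_boot=0)
        without = lopo_cv(X, y, groups, ClassifierSpec("lda"), smote=False, n_boot=0)
        assert len(with_smote.y_pred) == len(without.y_pred) == len(y)


class TestMetrics:
    def test_confusion_worked_example(self):
        m = metrics_from_confusion(tp=97, fn=6, tn=86, fp=4)
        assert round(m["sensitivity"], 1) == 94.2
        assert round(m["specificity"], 1) == 95.6
        assert round(m["accuracy"], 1) == 94.8
        assert round(m["mcc"], 3) == 0.896

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1, 1])
        report = compute_metrics(y, y, scores=y.astype(float), n_boot=0)
        assert report.sensitivity == report.specificity == report.accuracy == 100.0
        assert report.mcc == report.kappa == 1.0
        assert report.auc == 1.0

    def test_agrees_with_brute_force_tally(self):
        """Vectorized confusion vs a per-sample Python tally."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            n = int(rng.integers(2, 12))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
            report = compute_metrics(y_true, y_pred, n_boot=0)
            assert (report.tp, report.fn, report.tn, report.fp) == (tp, fn, tn, fp)

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        s = rng.uniform(size=50)
        base = trapezoidal_auc(y == 1, s)
        for f in (np.exp, lambda x: x**3, lambda x: 1 / (1 + np.exp(-5 * x))):
            assert trapezoidal_auc(y == 1, f(s)) == pytest.approx(base)

    def test_undefined_denominators_reported_as_none(self):
        m = metrics_from_confusion(tp=0, fn=0, tn=5, fp=3)
        assert m["sensitivity"] is None
        assert m["specificity"] is not None

    def test_bootstrap_ci_present_and_ordered(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        pred = np.where(rng.uniform(size=60) < 0.8, y, 1 - y)
        report = compute_metrics(y, pred, scores=pred + rng.uniform(size=60) * 0.1,
                                 n_boot=300, seed=0)
        for key in ("sensitivity", "specificity", "accuracy", "auc"):
            lo, hi = report.ci[key]
            assert lo <= hi


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 0, 1])
        res = mcnemar_compare(y, y, y)
        assert res["b"] == res["c"] == 0
        assert res["p_value"] == 1.0

    def test_exact_binomial_value(self):
        """b=10, c=0 -> two-sided exact p = 2 * 0.5^10."""
        truth = np.zeros(10, dtype=int)
        preds_a = np.zeros(10, dtype=int)  # all correct
        preds_b = np.ones(10, dtype=int)  # all wrong
        res = mcnemar_compare(preds_a, preds_b, truth)
        assert res["exact"]
        assert res["p_value"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_chi2_matches_exact_at_moderate_counts(self):
        """Continuity-corrected chi-square tracks the exact binomial for
        b + c = 30 across random splits."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            b = int(rng.integers(0, 31))
            c = 30 - b
            truth = np.zeros(40, dtype=int)
            preds_a = np.zeros(40, dtype=int)
            preds_b = np.zeros(40, dtype=int)
            preds_a[:c] = 1  # a wrong, b right on first c
            preds_b[c : c + b] = 1  # b wrong, a right on next b
            exact = mcnemar_compare(preds_a, preds_b, truth, exact_threshold=1000)
            approx = mcnemar_compare(preds_a, preds_b, truth, exact_threshold=0)
            assert abs(exact["p_value"] - approx["p_value"]) < 0.02

    def test_all_pairs_holm_adjustment(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 2, 100)
        preds = {
            "good": np.where(rng.uniform(size=100) < 0.95, truth, 1 - truth),
            "bad": np.where(rng.uniform(size=100) < 0.55, truth, 1 - truth),
            "mid": np.where(rng.uniform(size=100) < 0.75, truth, 1 - truth),
        }
        results = mcnemar_all_pairs(preds, truth)
        assert len(results) == 3
        for r in results:
            assert r["p_holm"] >= r["p_value"] - 1e-12
        # the strongest contrast should be flagged
        gb = [r for r in results if {r["classifier_a"], r["classifier_b"]} == {"good", "bad"}][0]
        assert gb["significant"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar_compare([0, 1], [0], [0, 1])


def test_lopo_with_consensus_selection_on_planted_signal():
    """End-to-end feature selection + classification under LOPO keeps the
    planted signal learnable (regression bound, fixed seed)."""
    from subtracad.select import MajorityConsensusSelector

    X, y, groups, _ = make_planted_features(n=150, n_patients=25, effect=2.0, seed=11)
    report = lopo_cv(
        X,
        y,
        groups,
        ClassifierSpec("voting", round=1, seed=0),
        selection=MajorityConsensusSelector(target_size=10, random_state=0),
        n_boot=0,
    )
    assert report.auc > 0.8
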