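"""Two-round classification with patient-wise cross-validation.

Round 1 separates detected candidate regions into normal tissue vs. true
masses; round 2 separates true masses into benign vs. malignant.  Inside
every training fold — and only there — features are selected by the
majority-rule consensus, standardized, and the minority class is
oversampled with SMOTE before fitting.  Folds are formed per patient
(leave-one-patient-out or grouped k-fold) so no patient contributes to
both training and test.

The classifier suite mirrors a clinical-CAD comparison: LDA, k-NN (k=11
round 1, k=5 round 2, nearest tie-break), RBF-SVM, random forest, MLP,
AdaBoost, bagging, gradient boosting, a soft-voting ensemble, and a
neural network (5 hidden layers in round 1, 1 in round 2; ReLU, Adam,
batch 128, learning rate 1e-4, up to 100 epochs with early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    VotingClassifier,
)
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

from .select import MajorityConsensusSelector

CLASSIFIER_NAMES = ("lda", "knn", "svm", "rf", "mlp", "ada", "bag", "gb", "voting", "ann")

VOTING_MEMBERS = {1: ("knn", "svm", "mlp", "ada", "gb"), 2: ("lda", "rf", "gb")}


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to equal class counts.

    Each synthetic sample is a convex combination ``x + u·(x_nn − x)`` of a
    minority sample and one of its ``k_neighbors`` nearest minority
    neighbors, with ``u ~ U(0, 1)``.  Applies to training data only.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires a binary target")
    if counts.min() == counts.max():
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_needed = int(counts.max() - counts.min())
    if len(X_min) < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    rng = np.random.default_rng(seed)
    k = min(k_neighbors, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neighbor_idx = nn.kneighbors(X_min)
    synth = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        j = rng.integers(len(X_min))
        nb = neighbor_idx[j][1 + rng.integers(k)]  # skip self
        u = rng.uniform()
        synth[i] = X_min[j] + u * (X_min[nb] - X_min[j])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Classifier construction
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Named classifier with its hyperparameters and seed."""

    name: str
    round: int = 1
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")
        if self.round not in (1, 2):
            raise ValueError("round must be 1 or 2")


def build_ann(round: int, seed: int = 0, hidden_units: int = 128) -> ClassifierSpec:
    """Neural-network spec: 5 hidden layers (round 1) or 1 (round 2),
    ReLU activations, Adam, batch 128, lr 1e-4, ≤100 epochs, early
    stopping on a validation split, L2 weight decay for regularization."""
    if round not in (1, 2):
        raise ValueError("round must be 1 or 2")
    n_layers = 5 if round == 1 else 1
    return ClassifierSpec(
        name="ann",
        round=round,
        seed=seed,
        hyperparameters={
            "hidden_layer_sizes": (hidden_units,) * n_layers,
            "activation": "relu",
            "solver": "adam",
            "batch_size": 128,
            "learning_rate_init": 1e-4,
            "max_iter": 100,
            "early_stopping": True,
            "n_iter_no_change": 10,
            "alpha": 1e-3,
        },
    )


def _base_estimator(name: str, round_: int, seed: int, overrides: dict | None = None):
    overrides = dict(overrides or {})
    if name == "lda":
        est = LinearDiscriminantAnalysis(**overrides)
    elif name == "knn":
        k = overrides.pop("n_neighbors", 11 if round_ == 1 else 5)
        est = KNeighborsClassifier(n_neighbors=k, **overrides)
    elif name == "svm":
        overrides.setdefault("kernel", "rbf")
        est = SVC(probability=True, random_state=seed, **overrides)
    elif name == "rf":
        overrides.setdefault("n_estimators", 200)
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **overrides)
    elif name == "mlp":
        overrides.setdefault("hidden_layer_sizes", (100,))
        overrides.setdefault("max_iter", 400)
        est = MLPClassifier(random_state=seed, **overrides)
    elif name == "ada":
        overrides.setdefault("n_estimators", 100)
        est = AdaBoostClassifier(random_state=seed, **overrides)
    elif name == "bag":
        overrides.setdefault("n_estimators", 50)
        est = BaggingClassifier(random_state=seed, **overrides)
    elif name == "gb":
        est = GradientBoostingClassifier(random_state=seed, **overrides)
    elif name == "voting":
        members = overrides.pop("members", VOTING_MEMBERS[round_])
        est = VotingClassifier(
            estimators=[(m, _base_estimator(m, round_, seed)) for m in members],
            voting="soft",
            **overrides,
        )
    elif name == "ann":
        params = build_ann(round_, seed).hyperparameters
        params.update(overrides)
        est = MLPClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return est


def _clamp_knn(est, n_samples: int) -> None:
    """Cap k-NN neighbor counts at the training-set size."""
    if isinstance(est, KNeighborsClassifier) and est.n_neighbors > n_samples:
        est.set_params(n_neighbors=max(1, n_samples - 1))
    if isinstance(est, VotingClassifier):
        for _, member in est.estimators:
            _clamp_knn(member, n_samples)


def build_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator behind a spec."""
    return _base_estimator(spec.name, spec.round, spec.seed, spec.hyperparameters)


class MassClassifier(ClassifierMixin, BaseEstimator):
    """Standardize → SMOTE → classifier, as one sklearn estimator.

    ``standardize="auto"`` standardizes for every spec except the round-2
    neural network, whose features are fed raw (leaving the scale intact
    acts as an additional overfitting guard on the small mass set).
    SMOTE and scaler statistics are fitted inside ``fit`` only, so the
    estimator composes correctly with cross-validation.
    """

    def __init__(
        self,
        spec: str = "voting",
        round: int = 1,
        standardize: str | bool = "auto",
        smote: bool = True,
        smote_k: int = 5,
        random_state: int = 0,
        hyperparameters: Optional[dict] = None,
    ):
        self.spec = spec
        self.round = round
        self.standardize = standardize
        self.smote = smote
        self.smote_k = smote_k
        self.random_state = random_state
        self.hyperparameters = hyperparameters

    def _should_standardize(self) -> bool:
        if self.standardize == "auto":
            return not (self.spec == "ann" and self.round == 2)
        return bool(self.standardize)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.scaler_ = StandardScaler().fit(X) if self._should_standardize() else None
        Xt = self.scaler_.transform(X) if self.scaler_ is not None else X
        if self.smote and len(self.classes_) == 2:
            counts = np.unique(y, return_counts=True)[1]
            if counts.min() >= 2 and counts.min() != counts.max():
                Xt, y = smote_balance(Xt, y, self.smote_k, seed=self.random_state)
        est = _base_estimator(
            self.spec, self.round, self.random_state, self.hyperparameters
        )
        # early stopping needs a viable validation split
        if isinstance(est, MLPClassifier) and est.early_stopping and len(y) < 40:
            est.set_params(early_stopping=False)
        if self.spec == "ann" and "max_iter" not in (self.hyperparameters or {}):
            # an sklearn "epoch" is one pass = ceil(n/batch) Adam steps; on
            # small training folds that starves the fixed learning rate.
            # Train for the step budget the stated schedule performs at
            # cohort scale (~100 epochs x ~16 minibatches).
            batch = est.batch_size if isinstance(est.batch_size, int) else 128
            steps_per_epoch = max(1, -(-len(y) // batch))
            needed_epochs = -(-1600 // steps_per_epoch)
            if est.max_iter < needed_epochs:
                est.set_params(max_iter=needed_epochs)
        _clamp_knn(est, len(y))
        self.estimator_ = est.fit(Xt, y)
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(self._transform(X))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._transform(X))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (last) class, in [0, 1]."""
        return self.predict_proba(X)[:, -1]


def fit_predict(
    spec: ClassifierSpec,
    X_train,
    y_train,
    X_test,
    smote: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a spec on training data and return (labels, scores) on test."""
    clf = MassClassifier(
        spec=spec.name,
        round=spec.round,
        smote=smote,
        random_state=spec.seed,
        hyperparameters=spec.hyperparameters or None,
    ).fit(X_train, y_train)
    return clf.predict(X_test), clf.decision_scores(X_test)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Pooled cross-validated predictions and their summary metrics."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # %
    specificity: float  # %
    accuracy: float  # %
    auc: Optional[float]
    mcc: Optional[float]
    kappa: Optional[float]
    ci: dict = dc_field(default_factory=dict)  # metric -> (lo, hi)
    y_true: Optional[np.ndarray] = None
    y_pred: Optional[np.ndarray] = None
    scores: Optional[np.ndarray] = None
    fold_assignment: Optional[np.ndarray] = None
    skipped_folds: list = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def trapezoidal_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equivalent to the Mann–Whitney statistic with ties counted half.
    """
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[y_true]
    neg = scores[~y_true]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: one class absent")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def _confusion(y_true, y_pred, positive=1) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    return tp, fn, tn, fp


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity/accuracy (%), MCC and Cohen's kappa from
    raw confusion counts.  Undefined ratios are reported as None."""
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    acc = 100.0 * (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    p_obs = (tp + tn) / total
    p_exp = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total**2
    kappa = (p_obs - p_exp) / (1 - p_exp) if p_exp < 1 else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "mcc": float(mcc) if mcc is not None else None,
        "kappa": float(kappa) if kappa is not None else None,
    }


def compute_metrics(
    y_true,
    y_pred,
    scores=None,
    positive=1,
    n_boot: int = 2000,
    seed: int = 0,
    fold_assignment=None,
    skipped_folds: Sequence | None = None,
) -> EvaluationReport:
    """Full evaluation report with bootstrap percentile 95% CIs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    tp, fn, tn, fp = _confusion(y_true, y_pred, positive)
    base = metrics_from_confusion(tp, fn, tn, fp)
    auc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = trapezoidal_auc(y_true == positive, np.asarray(scores, dtype=float))

    ci: dict = {}
    if n_boot > 0 and len(y_true) > 1:
        rng = np.random.default_rng(seed)
        n = len(y_true)
        boots: dict[str, list[float]] = {m: [] for m in ("sensitivity", "specificity", "accuracy", "auc")}
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            btp, bfn, btn, bfp = _confusion(y_true[idx], y_pred[idx], positive)
            try:
                bm = metrics_from_confusion(btp, bfn, btn, bfp)
            except ValueError:
                continue
            for m in ("sensitivity", "specificity", "accuracy"):
                if bm[m] is not None:
                    boots[m].append(bm[m])
            if scores is not None:
                yt = y_true[idx] == positive
                if 0 < yt.sum() < n:
                    boots["auc"].append(
                        trapezoidal_auc(yt, np.asarray(scores, dtype=float)[idx])
                    )
        for m, vals in boots.items():
            if vals:
                ci[m] = (
                    float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)),
                )

    return EvaluationReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=base["sensitivity"],
        specificity=base["specificity"],
        accuracy=base["accuracy"],
        auc=auc,
        mcc=base["mcc"],
        kappa=base["kappa"],
        ci=ci,
        y_true=y_true,
        y_pred=y_pred,
        scores=None if scores is None else np.asarray(scores, dtype=float),
        fold_assignment=None if fold_assignment is None else np.asarray(fold_assignment),
        skipped_folds=list(skipped_folds or []),
    )


# ---------------------------------------------------------------------------
# Patient-wise cross-validation
# ---------------------------------------------------------------------------

def _run_grouped_cv(
    X,
    y,
    groups,
    folds: list[tuple[np.ndarray, np.ndarray]],
    spec: ClassifierSpec,
    selection: Optional[MajorityConsensusSelector],
    smote: bool,
    n_boot: int,
    seed: int,
) -> EvaluationReport:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    groups = np.asarray(groups)
    n = len(y)
    y_pred = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    skipped = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        assert not set(groups[train_idx]) & set(groups[test_idx])
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            skipped.append(fold_id)
            continue
        X_train, X_test = X[train_idx], X[test_idx]
        if selection is not None:
            sel = clone(selection).fit(X_train, y_train)
            X_train = sel.transform(X_train)
            X_test = sel.transform(X_test)
        labels, sc = fit_predict(spec, X_train, y_train, X_test, smote=smote)
        y_pred[test_idx] = labels
        scores[test_idx] = sc
        fold_of[test_idx] = fold_id
    evaluated = fold_of >= 0
    return compute_metrics(
        y[evaluated],
        y_pred[evaluated],
        scores[evaluated],
        n_boot=n_boot,
        seed=seed,
        fold_assignment=fold_of[evaluated],
        skipped_folds=skipped,
    )


def lopo_cv(
    X,
    y,
    groups,
    spec: ClassifierSpec,
    selection: Optional[MajorityConsensusSelector] = None,
    smote: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-patient-out CV: one fold per patient; selection,
    standardization, SMOTE and fitting are redone inside each fold."""
    groups = np.asarray(groups)
    patients = np.unique(groups)
    if len(patients) < 2:
        raise ValueError("LOPO needs at least 2 patients")
    folds = [
        (np.flatnonzero(groups != p), np.flatnonzero(groups == p)) for p in patients
    ]
    return _run_grouped_cv(X, y, groups, folds, spec, selection, smote, n_boot, seed)


def kfold_cv(
    X,
    y,
    groups,
    k: int,
    spec: ClassifierSpec,
    selection: Optional[MajorityConsensusSelector] = None,
    smote: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Grouped k-fold CV: folds partition patients, never ROIs."""
    groups = np.asarray(groups)
    n_patients = len(np.unique(groups))
    if k > n_patients:
        raise ValueError(f"k={k} exceeds the {n_patients} patients available")
    splitter = GroupKFold(n_splits=k)
    folds = [
        (train, test) for train, test in splitter.split(np.asarray(X), np.asarray(y), groups)
    ]
    return _run_grouped_cv(X, y, groups, folds, spec, selection, smote, n_boot, seed)


# ---------------------------------------------------------------------------
# McNemar comparisons
# ---------------------------------------------------------------------------

def mcnemar_compare(preds_a, preds_b, truth, exact_threshold: int = 25) -> dict:
    """Paired McNemar test on the discordant predictions of two classifiers.

    Uses the exact binomial test when the discordant count ``b + c`` is
    below ``exact_threshold``, otherwise the continuity-corrected
    chi-square approximation.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    truth = np.asarray(truth)
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction vectors must align with the truth")
    a_correct = preds_a == truth
    b_correct = preds_b == truth
    b_count = int(np.sum(a_correct & ~b_correct))
    c_count = int(np.sum(~a_correct & b_correct))
    if b_count + c_count == 0:
        return {"b": 0, "c": 0, "statistic": 0.0, "p_value": 1.0, "exact": True}
    table = [[int(np.sum(a_correct & b_correct)), b_count],
             [c_count, int(np.sum(~a_correct & ~b_correct))]]
    exact = (b_count + c_count) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return {
        "b": b_count,
        "c": c_count,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "exact": exact,
    }


def mcnemar_all_pairs(predictions: dict, truth, alpha: float = 0.05) -> list[dict]:
    """Extended McNemar: all-pairs comparisons with Holm correction."""
    names = sorted(predictions)
    results = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = mcnemar_compare(predictions[a], predictions[b], truth)
            res.update({"classifier_a": a, "classifier_b": b})
            results.append(res)
    if results:
        reject, p_adj, _, _ = multipletests(
            [r["p_value"] for r in results], alpha=alpha, method="holm"
        )
        for r, p, rej in zip(results, p_adj, reject):
            r["p_holm"] = float(p)
            r["significant"] = bool(rej)
    return results
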