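"""Consensus feature selection: 8 ranking methods, majority rule.

Each ranker scores every feature against the binary target and orders the
catalog best-first (ties broken by catalog order, non-finite scores last).
A feature is selected when it appears in the top-K of at least ``quorum``
of the 8 rankings — a majority vote that keeps only features several
unrelated criteria agree on.

Rankers: absolute two-sample t statistic, Wilcoxon rank-sum statistic,
mutual information, chi-square on quantile-binned features, Fisher score,
ReliefF, mRMR (mutual-information difference), and random-forest impurity
importance.  ReliefF and mRMR are implemented here; the rest delegate to
scipy/scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin, mutual_info_classif
from sklearn.metrics import mutual_info_score
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted, validate_data

RANKER_NAMES = (
    "ttest",
    "wilcoxon",
    "mutual_info",
    "chi2",
    "fisher",
    "relieff",
    "mrmr",
    "rf_importance",
)
DEFAULT_QUORUM = 5


@dataclass
class FeatureRanking:
    method: str
    names: tuple[str, ...]  # best first
    scores: dict = field(default_factory=dict)  # name -> score


@dataclass
class ConsensusSelection:
    selected: tuple[str, ...]
    votes: dict  # name -> count in top-K
    k: int
    quorum: int


def _validate_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y must be binary")
    return X, (y == classes[1]).astype(int)


def _quantile_bins(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(x, edges)


def _score_ttest(X, y):
    t, _ = sstats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
    return np.abs(t)


def _score_wilcoxon(X, y):
    out = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        stat, _ = sstats.ranksums(X[y == 1, f], X[y == 0, f])
        out[f] = abs(stat)
    return out


def _score_mutual_info(X, y, seed):
    return mutual_info_classif(X, y, random_state=seed)


def _score_chi2(X, y):
    out = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        binned = _quantile_bins(X[:, f])
        table = np.zeros((binned.max() + 1, 2))
        for b, label in zip(binned, y):
            table[b, label] += 1
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            out[f] = 0.0
            continue
        stat, _, _, _ = sstats.chi2_contingency(table)
        out[f] = stat
    return out


def _score_fisher(X, y):
    m = X.mean(axis=0)
    out = np.empty(X.shape[1])
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in (0, 1):
        Xc = X[y == c]
        num += len(Xc) * (Xc.mean(axis=0) - m) ** 2
        den += len(Xc) * Xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return out


def _score_relieff(X, y, seed, n_neighbors: int = 10):
    """ReliefF weights: features that separate nearest misses from nearest
    hits score high.  All samples are used; distances on [0,1]-scaled data."""
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span
    n = len(Xs)
    k = min(n_neighbors, min((y == 0).sum(), (y == 1).sum()) - 1)
    if k < 1:
        return np.zeros(X.shape[1])
    weights = np.zeros(X.shape[1])
    nbrs = {c: NearestNeighbors(n_neighbors=k + 1).fit(Xs[y == c]) for c in (0, 1)}
    idx = {c: np.flatnonzero(y == c) for c in (0, 1)}
    for i in range(n):
        c = y[i]
        _, hit_idx = nbrs[c].kneighbors(Xs[i : i + 1])
        hits = idx[c][hit_idx[0][1 : k + 1]]  # drop self
        _, miss_idx = nbrs[1 - c].kneighbors(Xs[i : i + 1], n_neighbors=k)
        misses = idx[1 - c][miss_idx[0]]
        weights += np.abs(Xs[misses] - Xs[i]).mean(axis=0)
        weights -= np.abs(Xs[hits] - Xs[i]).mean(axis=0)
    return weights / n


def _score_mrmr(X, y, n_bins: int = 4):
    """mRMR (MID): greedy rank by relevance minus mean redundancy, both as
    mutual information on quantile-binned features.  Scores encode the
    greedy selection order (earlier = higher)."""
    n_features = X.shape[1]
    binned = np.column_stack([_quantile_bins(X[:, f], n_bins) for f in range(n_features)])
    relevance = np.array([mutual_info_score(binned[:, f], y) for f in range(n_features)])
    selected: list[int] = []
    remaining = list(range(n_features))
    redundancy = np.zeros(n_features)
    order = []
    while remaining:
        if selected:
            crit = relevance[remaining] - redundancy[remaining] / len(selected)
        else:
            crit = relevance[remaining]
        best = remaining[int(np.argmax(crit))]
        order.append(best)
        selected.append(best)
        remaining.remove(best)
        if remaining:
            for f in remaining:
                redundancy[f] += mutual_info_score(binned[:, f], binned[:, best])
    scores = np.empty(n_features)
    scores[np.asarray(order)] = np.arange(n_features, 0, -1, dtype=float)
    return scores


def _score_rf(X, y, seed):
    rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf.feature_importances_


def rank_features(X, y, method: str, feature_names=None, seed: int = 0) -> FeatureRanking:
    """Complete best-first ranking of all features by one method.

    Constant features get non-finite scores under variance-dependent
    methods and are ranked last; ties break by catalog order.
    """
    X, y01 = _validate_xy(X, y)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")

    if method == "ttest":
        scores = _score_ttest(X, y01)
    elif method == "wilcoxon":
        scores = _score_wilcoxon(X, y01)
    elif method == "mutual_info":
        scores = _score_mutual_info(X, y01, seed)
    elif method == "chi2":
        scores = _score_chi2(X, y01)
    elif method == "fisher":
        scores = _score_fisher(X, y01)
    elif method == "relieff":
        scores = _score_relieff(X, y01, seed)
    elif method == "mrmr":
        scores = _score_mrmr(X, y01)
    elif method == "rf_importance":
        scores = _score_rf(X, y01, seed)
    else:
        raise ValueError(f"unknown ranking method {method!r}; choose from {RANKER_NAMES}")

    scores = np.asarray(scores, dtype=np.float64)
    scores[np.isnan(scores)] = -np.inf  # 0/0 (constant feature) ranks worst
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        method=method,
        names=tuple(feature_names[i] for i in order),
        scores=dict(zip(feature_names, scores.tolist())),
    )


def majority_select(
    rankings: list[FeatureRanking], k: int, quorum: int = DEFAULT_QUORUM
) -> ConsensusSelection:
    """Features appearing in the top-K of at least ``quorum`` rankings.

    Selected features are returned ordered by (votes desc, mean rank asc).
    """
    if not rankings:
        raise ValueError("at least one ranking required")
    catalog = rankings[0].names
    catalog_set = frozenset(catalog)
    for r in rankings:
        if frozenset(r.names) != catalog_set:
            raise ValueError("rankings cover inconsistent feature catalogs")
    votes: dict[str, int] = {name: 0 for name in sorted(catalog_set)}
    rank_sum: dict[str, float] = {name: 0.0 for name in votes}
    for r in rankings:
        for pos, name in enumerate(r.names):
            rank_sum[name] += pos
            if pos < k:
                votes[name] += 1
    selected = [n for n in votes if votes[n] >= quorum]
    selected.sort(key=lambda n: (-votes[n], rank_sum[n], n))
    return ConsensusSelection(tuple(selected), votes, k, quorum)


def consensus_for_size(
    rankings: list[FeatureRanking],
    target_size: int,
    quorum: int = DEFAULT_QUORUM,
) -> ConsensusSelection:
    """Tune the top-K depth so the consensus size is closest to
    ``target_size`` (smallest such K on ties), then truncate to it."""
    n = len(rankings[0].names)
    best = None
    for k in range(1, n + 1):
        sel = majority_select(rankings, k, quorum)
        gap = abs(len(sel.selected) - target_size)
        if best is None or gap < abs(len(best.selected) - target_size):
            best = sel
        if len(sel.selected) >= target_size:
            break
    assert best is not None
    if len(best.selected) > target_size:
        best = ConsensusSelection(
            best.selected[:target_size], best.votes, best.k, best.quorum
        )
    return best


class MajorityConsensusSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible transformer applying the 8-ranker majority rule.

    Parameters
    ----------
    k : int or None
        Top-K depth per ranking.  Ignored when ``target_size`` is given.
    target_size : int or None
        If set, K is tuned per fit so the consensus has this many features
        (e.g. 19 for the mass-vs-normal round, 17 for benign-vs-malignant).
    quorum : int
        Minimum number of rankings (of 8) that must list a feature in
        their top-K.
    methods : tuple of str
        Ranking methods to combine.
    """

    def __init__(
        self,
        k: int | None = 20,
        target_size: int | None = None,
        quorum: int = DEFAULT_QUORUM,
        methods: tuple[str, ...] = RANKER_NAMES,
        random_state: int = 0,
    ):
        self.k = k
        self.target_size = target_size
        self.quorum = quorum
        self.methods = methods
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64)
        names = tuple(f"f{i}" for i in range(X.shape[1]))
        self.rankings_ = [
            rank_features(X, y, m, names, seed=self.random_state) for m in self.methods
        ]
        if self.target_size is not None:
            sel = consensus_for_size(self.rankings_, self.target_size, self.quorum)
        else:
            sel = majority_select(self.rankings_, self.k or X.shape[1], self.quorum)
        self.selection_ = sel
        chosen = {int(n[1:]) for n in sel.selected}
        self.support_ = np.array([i in chosen for i in range(X.shape[1])])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selected_indices(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_)
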