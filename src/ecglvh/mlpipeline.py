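"""Feature selection, balanced CV training, threshold choice and the voting ensemble.

The classification stage is organised as scikit-learn estimators:

* :class:`SffsSelector` — sequential floating forward selection scored by the
  mean AUC over Monte-Carlo 70/30 stratified splits;
* :class:`ThresholdedClassifier` — one classifier (logistic regression,
  random forest or RBF SVM) trained with stratified k-fold CV, the majority
  class of each fold's training part independently downsampled, and the
  decision threshold chosen on the pooled out-of-fold ROC as the point
  closest to (FPR, TPR) = (0, 1);
* :class:`MajorityVoteEnsemble` — many :class:`ThresholdedClassifier`
  members differing only in their downsampling/CV seeds, predicting by
  majority vote with ties resolved by the first member.

Module-level functions (``sffs_select``, ``train_with_cv``,
``build_ensemble``, ``predict_majority``, ...) are thin wrappers over these
estimators. Labels may be strings (``"control"``/``"lvh"``) or 0/1; the
positive class is ``"lvh"`` / 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .records import LVH, ConfigurationError

MODEL_KINDS = ("logreg", "rf", "svm")

_SEED_MOD = 2**31 - 1


def _derive_seed(seed: int, offset: int) -> int:
    return int((int(seed) + offset) % _SEED_MOD)


def _to_binary(y) -> np.ndarray:
    """Map labels to {0, 1} with lvh/1/True as the positive class."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        out = np.asarray([1 if str(v) == LVH else 0 for v in arr])
    else:
        out = arr.astype(int)
    if not set(np.unique(out)) <= {0, 1}:
        raise ConfigurationError("labels must be control/lvh or 0/1")
    return out


def _base_learner(kind: str, seed: int):
    """The classifier behind each kind, scoring on a (0,1) probability scale.

    The RBF SVM's decision values are mapped to probabilities by a logistic
    (Platt) calibration fit on the training data, which is monotone and thus
    leaves both the ROC and the distance-to-(0,1) geometry intact.
    """
    if kind == "logreg":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        scale = True
    elif kind == "rf":
        clf = RandomForestClassifier(n_estimators=150, random_state=seed, n_jobs=1)
        scale = False
    elif kind == "svm":
        # RBF SVM with logistic (Platt) score calibration fit on the
        # training data; monotone, so ROC geometry is unchanged
        clf = CalibratedClassifierCV(SVC(kernel="rbf"), ensemble=False)
        scale = True
    else:
        raise ConfigurationError(f"unknown model kind {kind!r}; use {MODEL_KINDS}")
    steps = [("impute", SimpleImputer(strategy="median"))]
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def balance_downsample(labels, seed: int) -> np.ndarray:
    """Indices keeping all minority rows and an equal-size random majority subset."""
    y = _to_binary(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ConfigurationError("balancing needs exactly two classes")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        return np.arange(len(y))
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    keep_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    return np.sort(np.concatenate([min_idx, keep_maj]))


def choose_threshold(scores, labels) -> float:
    """Score cut minimizing FPR² + (1 − TPR)², the ROC point nearest (0, 1).

    Candidates are the midpoints between consecutive distinct sorted scores
    plus sentinels below/above all scores; a sample is called positive when
    its score is ≥ the threshold. Objective ties are broken toward the
    higher threshold (fewer positives, higher specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = _to_binary(labels)
    if not np.all(np.isfinite(s)):
        raise ConfigurationError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("both classes are required")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    best_theta, best_obj = None, np.inf
    for theta in candidates:
        pred = s >= theta
        tpr = np.count_nonzero(pred & (y == 1)) / n_pos
        fpr = np.count_nonzero(pred & (y == 0)) / n_neg
        obj = fpr**2 + (1.0 - tpr) ** 2
        if obj < best_obj or (obj == best_obj and theta > best_theta):
            best_theta, best_obj = float(theta), obj
    return best_theta


# ---------------------------------------------------------------------------
# Evaluation metrics


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    auc: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
        }


def compute_metrics(true_labels, pred_labels, scores=None) -> EvalMetrics:
    """Sensitivity, specificity, accuracy, balanced accuracy and (rank) AUC."""
    yt = _to_binary(true_labels)
    yp = _to_binary(pred_labels)
    if len(yt) != len(yp):
        raise ConfigurationError("label vectors must align")
    if len(np.unique(yt)) < 2:
        raise ConfigurationError("both classes required in true labels")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    auc = None if scores is None else float(roc_auc_score(yt, np.asarray(scores)))
    return EvalMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / len(yt),
        balanced_accuracy=(sens + spec) / 2.0,
        auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# Thresholded single classifier


class ThresholdedClassifier(BaseEstimator, ClassifierMixin):
    """One classifier with fold-balanced CV training and ROC-derived threshold.

    Parameters
    ----------
    kind : {"logreg", "rf", "svm"}
    k : int
        Number of stratified CV folds used for out-of-fold scoring.
    features : sequence of str, optional
        Column subset (requires DataFrame input) used for fitting.
    random_state : int
        Seeds the fold split, per-fold downsampling and the learner.

    Attributes
    ----------
    threshold_ : float
        Score cut chosen on the pooled out-of-fold ROC (training data only).
    cv_auc_ : float
        AUC of the pooled out-of-fold scores.
    model_ : sklearn Pipeline
        Final learner refit on the full balanced training data.
    """

    def __init__(self, kind: str = "rf", k: int = 10,
                 features: Optional[Sequence[str]] = None, random_state: int = 0):
        self.kind = kind
        self.k = k
        self.features = features
        self.random_state = random_state

    def _select(self, X):
        if self.features is not None:
            if not isinstance(X, pd.DataFrame):
                raise ConfigurationError("feature names require DataFrame input")
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise ConfigurationError(f"missing feature columns: {missing}")
            X = X[list(self.features)]
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        Xa = self._select(X)
        ya = _to_binary(y)
        if len(np.unique(ya)) < 2:
            raise ConfigurationError("training data must contain both classes")
        seed = _derive_seed(self.random_state, 0)
        skf = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=seed)
        oof_scores = np.full(len(ya), np.nan)
        for f, (tr, te) in enumerate(skf.split(Xa, ya)):
            keep = balance_downsample(ya[tr], _derive_seed(seed, 1000 + f))
            learner = _base_learner(self.kind, _derive_seed(seed, 2000 + f))
            learner.fit(Xa[tr][keep], ya[tr][keep])
            oof_scores[te] = learner.predict_proba(Xa[te])[:, 1]
        self.cv_auc_ = float(roc_auc_score(ya, oof_scores))
        self.threshold_ = choose_threshold(oof_scores, ya)
        self.oof_scores_ = oof_scores
        keep = balance_downsample(ya, _derive_seed(seed, 3000))
        self.model_ = _base_learner(self.kind, _derive_seed(seed, 4000))
        self.model_.fit(Xa[keep], ya[keep])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._select(X))

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_scores(X) >= self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# Majority-vote ensemble


class MajorityVoteEnsemble(BaseEstimator, ClassifierMixin):
    """Voting ensemble of identically-specified, differently-seeded members.

    Each member repeats the full fold-balanced CV training with its own
    derived seed, so members differ in their majority-class downsampling
    draws (and consequent thresholds). Prediction is by majority vote of the
    members' thresholded labels; an exact tie returns the first member's
    vote. Member order is fixed at fit time.
    """

    def __init__(self, kind: str = "rf", n_models: int = 100, k: int = 10,
                 features: Optional[Sequence[str]] = None, random_state: int = 0):
        self.kind = kind
        self.n_models = n_models
        self.k = k
        self.features = features
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_models < 1:
            raise ConfigurationError("n_models must be >= 1")
        self.members_ = []
        for m in range(self.n_models):
            member = ThresholdedClassifier(
                kind=self.kind, k=self.k, features=self.features,
                random_state=_derive_seed(self.random_state, 7919 * (m + 1)),
            )
            member.fit(X, y)
            self.members_.append(member)
        self.classes_ = np.array([0, 1])
        return self

    def vote_matrix(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.vstack([m.predict(X) for m in self.members_])

    def predict(self, X):
        votes = self.vote_matrix(X)
        return majority_vote(votes)

    def decision_scores(self, X) -> np.ndarray:
        """Mean member probability of the positive class (for ROC/AUC)."""
        check_is_fitted(self, "members_")
        return np.mean([m.decision_scores(X) for m in self.members_], axis=0)


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Majority label per column; exact ties take the first row's vote."""
    votes = np.atleast_2d(np.asarray(votes, dtype=int))
    n_models = votes.shape[0]
    pos = votes.sum(axis=0)
    out = np.where(pos * 2 > n_models, 1, 0)
    ties = pos * 2 == n_models
    out[ties] = votes[0, ties]
    return out


# ---------------------------------------------------------------------------
# Sequential floating forward selection


@dataclass
class SffsStep:
    subset: tuple[str, ...]
    mean_auc: float
    sd_auc: float
    action: str  #: "add" or "remove"


@dataclass
class SffsTrace:
    steps: list[SffsStep] = field(default_factory=list)
    best_by_size: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    selected: tuple[str, ...] = ()
    split_seeds: list[int] = field(default_factory=list)

    def top_k(self, k: int) -> tuple[str, ...]:
        """The first ``k`` features in order of forward inclusion."""
        order: list[str] = []
        for step in self.steps:
            if step.action == "add":
                new = [f for f in step.subset if f not in order]
                order.extend(new)
        return tuple(order[:k])


class SffsSelector(BaseEstimator):
    """Sequential floating forward feature selection scored by Monte-Carlo AUC.

    At each step the feature whose inclusion maximizes the mean AUC over
    ``n_repeats`` stratified 70/30 splits is added; afterwards, features are
    conditionally removed while removal strictly improves on the best AUC
    recorded for the smaller subset size. The search stops at
    ``max_features``; the selected subset is the best mean-AUC subset
    visited. ``transform`` restricts a DataFrame to the selected columns.
    """

    def __init__(self, kind: str = "logreg", max_features: int = 30,
                 n_repeats: int = 5, test_size: float = 0.3,
                 random_state: int = 0):
        self.kind = kind
        self.max_features = max_features
        self.n_repeats = n_repeats
        self.test_size = test_size
        self.random_state = random_state

    def _score_subset(self, X: pd.DataFrame, y: np.ndarray,
                      subset: tuple[str, ...], seeds: list[int]) -> tuple[float, float]:
        aucs = []
        Xs = X[list(subset)].to_numpy(dtype=float)
        for seed in seeds:
            sss = StratifiedShuffleSplit(n_splits=1, test_size=self.test_size,
                                         random_state=seed)
            (tr, te), = sss.split(Xs, y)
            learner = _base_learner(self.kind, seed)
            learner.fit(Xs[tr], y[tr])
            scores = learner.predict_proba(Xs[te])[:, 1]
            aucs.append(roc_auc_score(y[te], scores))
        return float(np.mean(aucs)), float(np.std(aucs))

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"f{i}" for i in range(np.shape(X)[1])])
        ya = _to_binary(y)
        if len(np.unique(ya)) < 2:
            raise ConfigurationError("need both classes for selection")
        max_features = min(self.max_features, X.shape[1])
        # constant columns can never help and are excluded from candidacy
        usable = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
        seeds = [_derive_seed(self.random_state, 100 + i)
                 for i in range(self.n_repeats)]

        trace = SffsTrace(split_seeds=seeds)
        current: tuple[str, ...] = ()

        def record(subset, mean_auc, sd_auc, action):
            trace.steps.append(SffsStep(subset, mean_auc, sd_auc, action))
            size = len(subset)
            if size not in trace.best_by_size or mean_auc > trace.best_by_size[size][1]:
                trace.best_by_size[size] = (subset, mean_auc)

        while len(current) < max_features:
            # forward: add the best-improving feature
            best = None
            for cand in usable:
                if cand in current:
                    continue
                subset = current + (cand,)
                mean_auc, sd_auc = self._score_subset(X, ya, subset, seeds)
                if best is None or mean_auc > best[0]:
                    best = (mean_auc, sd_auc, subset)
            if best is None:
                break
            mean_auc, sd_auc, current = best
            record(current, mean_auc, sd_auc, "add")

            # floating backward: remove while strictly better than the best
            # known subset of the smaller size
            improved = True
            while improved and len(current) > 2:
                improved = False
                best_rm = None
                for f in current:
                    subset = tuple(c for c in current if c != f)
                    mean_auc, sd_auc = self._score_subset(X, ya, subset, seeds)
                    if best_rm is None or mean_auc > best_rm[0]:
                        best_rm = (mean_auc, sd_auc, subset)
                prev_best = trace.best_by_size.get(len(current) - 1)
                if best_rm is not None and (prev_best is None
                                            or best_rm[0] > prev_best[1]):
                    mean_auc, sd_auc, current = best_rm
                    record(current, mean_auc, sd_auc, "remove")
                    improved = True

        if trace.best_by_size:
            best_size = max(trace.best_by_size,
                            key=lambda k: trace.best_by_size[k][1])
            trace.selected = trace.best_by_size[best_size][0]
        self.trace_ = trace
        self.selected_features_ = list(trace.selected)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_]
        raise ConfigurationError("transform requires DataFrame input")


# ---------------------------------------------------------------------------
# Spec-named convenience wrappers


def sffs_select(fm, kind: str, max_features: int = 30, n_repeats: int = 5,
                seed: int = 0) -> SffsTrace:
    """Run SFFS on a FeatureMatrix (or DataFrame + labels tuple)."""
    X, y = _unpack(fm)
    sel = SffsSelector(kind=kind, max_features=max_features,
                       n_repeats=n_repeats, random_state=seed)
    sel.fit(X, y)
    return sel.trace_


def train_with_cv(fm, kind: str, features: Optional[Sequence[str]] = None,
                  k: int = 10, seed: int = 0) -> ThresholdedClassifier:
    X, y = _unpack(fm)
    clf = ThresholdedClassifier(kind=kind, k=k, features=features,
                                random_state=seed)
    return clf.fit(X, y)


def build_ensemble(fm, kind: str, features: Optional[Sequence[str]] = None,
                   n_models: int = 100, k: int = 10,
                   seed: int = 0) -> MajorityVoteEnsemble:
    X, y = _unpack(fm)
    ens = MajorityVoteEnsemble(kind=kind, n_models=n_models, k=k,
                               features=features, random_state=seed)
    return ens.fit(X, y)


def predict_majority(ens: MajorityVoteEnsemble, fm) -> np.ndarray:
    X, _ = _unpack(fm, need_labels=False)
    return ens.predict(X)


def _unpack(fm, need_labels: bool = True):
    """Accept a FeatureMatrix, a (X, y) tuple or a bare DataFrame."""
    from .io import FeatureMatrix

    if isinstance(fm, FeatureMatrix):
        return fm.values, fm.y
    if isinstance(fm, tuple) and len(fm) == 2:
        X, y = fm
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        return X, y
    if isinstance(fm, pd.DataFrame):
        if need_labels:
            raise ConfigurationError("labels required: pass a FeatureMatrix or (X, y)")
        return fm, None
    raise ConfigurationError(f"cannot interpret features of type {type(fm)!r}")
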