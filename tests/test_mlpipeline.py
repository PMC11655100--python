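import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ecglvh.mlpipeline import (
    MajorityVoteEnsemble,
    SffsSelector,
    ThresholdedClassifier,
    balance_downsample,
    build_ensemble,
    choose_threshold,
    compute_metrics,
    majority_vote,
    predict_majority,
    sffs_select,
    train_with_cv,
)
from ecglvh.records import ConfigurationError


def _brute_force_threshold(scores, labels):
    """Exhaustive minimizer of FPR² + (1−TPR)² over all candidate cuts."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2
    cands = np.concatenate([[distinct[0] - 1], mids, [distinct[-1] + 1]])
    best = None
    for th in cands:
        pred = s >= th
        tpr = (pred & (y == 1)).sum() / (y == 1).sum()
        fpr = (pred & (y == 0)).sum() / (y == 0).sum()
        obj = fpr**2 + (1 - tpr) ** 2
        if best is None or obj < best[0] - 1e-15 or (
                abs(obj - best[0]) <= 1e-15 and th > best[1]):
            best = (obj, th)
    return best


def _objective(scores, labels, theta):
    s, y = np.asarray(scores), np.asarray(labels, dtype=int)
    pred = s >= theta
    tpr = (pred & (y == 1)).sum() / (y == 1).sum()
    fpr = (pred & (y == 0)).sum() / (y == 0).sum()
    return fpr**2 + (1 - tpr) ** 2


# ---------------------------------------------------------------------------
# choose_threshold


def test_threshold_matches_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(6, 60)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(0, 1, n), 2) + 0.5 * y
        theta = choose_threshold(s, y)
        obj_best, _ = _brute_force_threshold(s, y)
        assert _objective(s, y, theta) == pytest.approx(obj_best, abs=1e-12)


def test_threshold_picks_knee_of_three_point_roc():
    """ROC {(0,0),(0.1,0.8),(1,1)} -> the (0.1, 0.8) operating point."""
    # 10 negatives, 10 positives; scores arranged so one cut yields
    # TPR 0.8 / FPR 0.1
    y = np.array([0] * 10 + [1] * 10)
    s = np.array([0.1] * 9 + [0.6] + [0.6] * 8 + [0.05] * 2)
    theta = choose_threshold(s, y)
    pred = s >= theta
    tpr = (pred & (y == 1)).sum() / 10
    fpr = (pred & (y == 0)).sum() / 10
    assert (fpr, tpr) == (0.1, 0.8)
    assert _objective(s, y, theta) == pytest.approx(0.1**2 + 0.2**2)


def test_threshold_on_separable_scores_reaches_corner():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    theta = choose_threshold(s, y)
    assert 0.3 < theta < 0.7
    assert _objective(s, y, theta) == 0.0


def test_threshold_requires_both_classes():
    with pytest.raises(ConfigurationError):
        choose_threshold([0.1, 0.9], [1, 1])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False),
                min_size=4, max_size=30),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_threshold_oracle_property(scores, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, len(scores))
    if y.min() == y.max():
        y[0] = 1 - y[0]
    theta = choose_threshold(scores, y)
    obj_best, _ = _brute_force_threshold(scores, y)
    assert _objective(scores, y, theta) == pytest.approx(obj_best, abs=1e-12)


# ---------------------------------------------------------------------------
# balancing


def test_downsampling_counts_and_determinism():
    y = np.array(["lvh"] * 30 + ["control"] * 70)
    idx = balance_downsample(y, seed=1)
    assert len(idx) == 60
    kept = y[idx]
    assert (kept == "lvh").sum() == 30 and (kept == "control").sum() == 30
    assert np.array_equal(idx, balance_downsample(y, seed=1))
    other = balance_downsample(y, seed=2)
    assert not np.array_equal(idx, other)
    assert (y[other] == "control").sum() == 30


def test_balanced_input_passes_through():
    y = np.array([0, 1] * 10)
    assert np.array_equal(balance_downsample(y, seed=0), np.arange(20))


# ---------------------------------------------------------------------------
# metrics


def test_metrics_arithmetic():
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    p = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1])
    m = compute_metrics(y, p)
    assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 4, 2)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(2 / 3)
    assert m.accuracy == pytest.approx(0.70)
    assert m.balanced_accuracy == pytest.approx((0.75 + 2 / 3) / 2)


def test_perfect_predictions():
    y = np.array([0, 1, 0, 1])
    m = compute_metrics(y, y, scores=y.astype(float))
    assert (m.sensitivity, m.specificity, m.accuracy, m.auc) == (1, 1, 1, 1)


def test_auc_equals_pairwise_probability():
    """Rank-statistic AUC equals P(random positive outscores random negative)."""
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    s = rng.normal(0, 1, 40) + 0.8 * y
    m = compute_metrics(y, (s > 0).astype(int), scores=s)
    pos, neg = s[y == 1], s[y == 0]
    pairs = (pos[:, None] > neg[None, :]).mean() + 0.5 * (
        pos[:, None] == neg[None, :]).mean()
    assert m.auc == pytest.approx(pairs, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = rng.normal(0, 1, 50) + y
    a1 = compute_metrics(y, y, scores=s).auc
    a2 = compute_metrics(y, y, scores=np.exp(3 * s)).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


# ---------------------------------------------------------------------------
# majority vote


def test_majority_and_tie_rule():
    votes = np.zeros((100, 3), dtype=int)
    votes[:51, 0] = 1          # 51/100 vote positive
    votes[:50, 1] = 1          # exact tie, first model votes positive
    votes[1:51, 2] = 1         # exact tie, first model votes negative
    out = majority_vote(votes)
    assert list(out) == [1, 1, 0]


def test_single_member_ensemble_equals_member():
    X, y = _separable(60, seed=5)
    ens = MajorityVoteEnsemble(kind="logreg", n_models=1, k=3, random_state=0)
    ens.fit(X, y)
    assert np.array_equal(ens.predict(X), ens.members_[0].predict(X))


# ---------------------------------------------------------------------------
# training


def _separable(n, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = pd.DataFrame({
        "good": y + rng.normal(0, noise, n),
        "junk1": rng.normal(0, 1, n),
        "junk2": rng.normal(0, 1, n),
    })
    return X, y


def test_cv_training_on_separable_data():
    X, y = _separable(80, seed=6)
    clf = train_with_cv((X, y), kind="logreg", k=5, seed=0)
    assert clf.cv_auc_ == pytest.approx(1.0)
    assert np.array_equal(clf.predict(X), y)


def test_cv_training_deterministic():
    X, y = _separable(60, seed=7, noise=0.6)
    a = train_with_cv((X, y), kind="rf", k=4, seed=3)
    b = train_with_cv((X, y), kind="rf", k=4, seed=3)
    assert a.cv_auc_ == b.cv_auc_ and a.threshold_ == b.threshold_


def test_permuted_labels_give_chance_auc():
    """Label permutation kills the signal: mean CV AUC ≈ 0.5 over 20 seeds."""
    X, y = _separable(80, seed=8)
    rng = np.random.default_rng(9)
    aucs = []
    for seed in range(20):
        yp = rng.permutation(y)
        clf = train_with_cv((X, yp), kind="logreg", k=4, seed=seed)
        aucs.append(clf.cv_auc_)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)


def test_ensemble_determinism_and_agreement():
    X, y = _separable(60, seed=10)
    e1 = build_ensemble((X, y), kind="logreg", n_models=3, k=3, seed=4)
    e2 = build_ensemble((X, y), kind="logreg", n_models=3, k=3, seed=4)
    assert [m.threshold_ for m in e1.members_] == [m.threshold_ for m in e2.members_]
    votes = e1.vote_matrix(X)
    # separable cohort: every member agrees on every record
    assert np.all(votes == votes[0])
    assert np.array_equal(predict_majority(e1, (X, None)), y)


def test_feature_subset_and_missing_column_error():
    X, y = _separable(40, seed=11)
    clf = ThresholdedClassifier(kind="logreg", k=3, features=["good"],
                                random_state=0)
    clf.fit(X, y)
    assert clf.n_features_in_ == 1
    bad = ThresholdedClassifier(kind="logreg", features=["nope"])
    with pytest.raises(ConfigurationError):
        bad.fit(X, y)


def test_single_class_training_rejected():
    X, _ = _separable(20)
    with pytest.raises(ConfigurationError):
        ThresholdedClassifier(kind="logreg", k=2).fit(X, np.zeros(20, dtype=int))


# ---------------------------------------------------------------------------
# SFFS


def test_sffs_single_feature_matches_exhaustive_search():
    """max_features=1 returns the best single feature by split-mean AUC."""
    rng = np.random.default_rng(12)
    for rep in range(10):
        n = 60
        y = np.arange(n) % 2
        X = pd.DataFrame(rng.normal(0, 1, (n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        lucky = rng.integers(0, 8)
        X.iloc[:, lucky] += rng.uniform(0.5, 1.5) * y
        sel = SffsSelector(kind="logreg", max_features=1, n_repeats=3,
                           random_state=rep)
        sel.fit(X, y)
        # exhaustive oracle over single features with the same splits/seeds
        best_feat, best_auc = None, -1
        for col in X.columns:
            mean_auc, _ = sel._score_subset(X, y, (col,), sel.trace_.split_seeds)
            if mean_auc > best_auc:
                best_feat, best_auc = col, mean_auc
        assert sel.selected_features_ == [best_feat]


def test_sffs_selects_planted_feature_first():
    """A label-plus-noise feature among pure noise is picked first."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 80
        y = np.arange(n) % 2
        X = pd.DataFrame(rng.normal(0, 1, (n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f0"] = y + rng.normal(0, 0.1, n)
        trace = sffs_select((X, y), kind="logreg", max_features=3,
                            n_repeats=3, seed=seed)
        if trace.top_k(1) == ("f0",):
            hits += 1
    assert hits >= 19  # ≥ 95%


def test_sffs_deterministic_and_skips_constant_columns():
    X, y = _separable(50, seed=13)
    X["const"] = 1.0
    t1 = sffs_select((X, y), kind="logreg", max_features=2, n_repeats=2, seed=5)
    t2 = sffs_select((X, y), kind="logreg", max_features=2, n_repeats=2, seed=5)
    assert t1.selected == t2.selected
    assert [s.subset for s in t1.steps] == [s.subset for s in t2.steps]
    assert "const" not in t1.selected
    assert all("const" not in s.subset for s in t1.steps)


def test_sffs_rejects_single_class():
    X, _ = _separable(20)
    with pytest.raises(ConfigurationError):
        SffsSelector().fit(X, np.ones(20, dtype=int))
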