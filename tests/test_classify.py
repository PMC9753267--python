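import numpy as np
import pandas as pd
import pytest

from plaquekit import (
    CLASS_ORDER,
    OneVsOneMarginSVC,
    TunedClassifier,
    evaluate,
    split_dataset,
)

from oracles import metrics_from_confusion


def _balanced_table(n_per_class, seed=0, sep=6.0):
    rng = np.random.default_rng(seed)
    rows = []
    for c, label in enumerate(CLASS_ORDER):
        for i in range(n_per_class):
            rows.append({
                "id": f"{label}-{i}", "label": label,
                "f0": rng.normal(c * sep), "f1": rng.normal(-c * sep),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_balanced_sizes_and_determinism():
    t = _balanced_table(34)  # about 100 rows: 102
    tr, te, va = split_dataset(t, seed=4)
    assert len(tr) + len(te) + len(va) == len(t)
    assert len(tr) == round(0.6 * len(t))
    tr2, te2, va2 = split_dataset(t, seed=4)
    pd.testing.assert_frame_equal(tr, tr2)
    pd.testing.assert_frame_equal(te, te2)
    # per-class proportions preserved within rounding
    for part, frac in ((tr, 0.6), (te, 0.2), (va, 0.2)):
        counts = part["label"].value_counts()
        for label in CLASS_ORDER:
            assert abs(counts[label] - frac * 34) <= 1


def test_split_disjoint_exhaustive_at_cohort_scale():
    rng = np.random.default_rng(1)
    rows = []
    for label, n in (("EFS", 214), ("EF", 134), ("AA", 218)):
        for i in range(n):
            rows.append({"id": f"{label}-{i}", "label": label, "f0": rng.normal()})
    t = pd.DataFrame(rows)
    tr, te, va = split_dataset(t, seed=0)
    ids = pd.concat([tr, te, va])["id"]
    assert len(ids) == 566 and ids.is_unique
    assert len(tr) == int(0.6 * 566)  # train size floors, remainder split 1:1


def test_split_invalid_fractions_rejected():
    t = _balanced_table(10)
    with pytest.raises(ValueError):
        split_dataset(t, 0.5, 0.2, 0.2)


# ---------------------------------------------------------------------------
# one-vs-one margin-decoded SVM
# ---------------------------------------------------------------------------

def test_ovo_svm_separable_and_three_learners():
    t = _balanced_table(20, seed=2)
    X, y = t[["f0", "f1"]].to_numpy(), t["label"].to_numpy()
    clf = OneVsOneMarginSVC(C=10.0).fit(X, y)
    assert len(clf.estimators_) == 3  # all class pairs
    assert (clf.predict(X) == y).mean() > 0.95


class _StubBinary:
    """Fixed-decision binary learner used to force a voting cycle."""

    def __init__(self, classes, decision):
        self.classes_ = np.asarray(classes)
        self._d = decision

    def decision_function(self, X):
        return np.full(len(X), self._d)


def test_ovo_cycle_vote_broken_by_aggregate_margin():
    """Each binary learner names a different winner (a 3-cycle); the class
    with the largest aggregate signed margin must win, verified against a
    brute-force evaluation of the decoding rule."""
    clf = OneVsOneMarginSVC()
    clf.classes_ = np.asarray(["AA", "EF", "EFS"])  # indices 0,1,2
    clf.estimators_ = {
        (0, 1): _StubBinary(["AA", "EF"], +0.9),   # EF beats AA by 0.9
        (0, 2): _StubBinary(["AA", "EFS"], -0.4),  # AA beats EFS by 0.4
        (1, 2): _StubBinary(["EF", "EFS"], +2.0),  # EFS beats EF by 2.0
    }
    X = np.zeros((1, 2))
    votes, margins = clf.decision_components(X)
    assert (votes == 1).all()  # a perfect cycle: one vote each
    # brute force the aggregate margins from the stub decisions
    expected = {"AA": -0.9 + 0.4, "EF": 0.9 - 2.0, "EFS": -0.4 + 2.0}
    for idx, label in enumerate(clf.classes_):
        assert margins[0, idx] == pytest.approx(expected[label])
    assert clf.predict(X)[0] == max(expected, key=expected.get)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def test_tuned_classifier_budget_and_determinism():
    t = _balanced_table(20, seed=3)
    X, y = t[["f0", "f1"]].to_numpy(), t["label"].to_numpy()
    one = TunedClassifier("knn", budget=1, cv_folds=5, seed=9).fit(X, y)
    assert len(one.cv_results_) == 1
    a = TunedClassifier("dt", budget=8, cv_folds=5, seed=11).fit(X, y)
    b = TunedClassifier("dt", budget=8, cv_folds=5, seed=11).fit(X, y)
    assert a.best_params_ == b.best_params_
    assert a.cv_results_ == b.cv_results_


def test_tuned_knn_reaches_zero_cv_loss_on_separated_clouds():
    t = _balanced_table(20, seed=4, sep=30.0)
    X, y = t[["f0", "f1"]].to_numpy(), t["label"].to_numpy()
    clf = TunedClassifier("knn", budget=10, cv_folds=5, seed=1).fit(X, y)
    assert clf.best_loss_ == 0.0
    assert clf.generalization_error_ == pytest.approx(
        clf.train_accuracy_ - clf.cv_accuracy_
    )


def test_tuned_classifier_budget_zero_uses_defaults():
    t = _balanced_table(15, seed=5)
    X, y = t[["f0", "f1"]].to_numpy(), t["label"].to_numpy()
    clf = TunedClassifier("mcsvm", budget=0, cv_folds=3, seed=2).fit(X, y)
    assert clf.best_params_ == {}
    assert clf.predict(X).shape == (len(y),)


def test_unknown_algorithm_rejected():
    with pytest.raises(ValueError):
        TunedClassifier("forest").fit(np.zeros((6, 2)), np.array(["a", "b"] * 3))


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=object)


class _EchoModel:
    """Predicts a fixed, pre-recorded sequence (to realize any confusion matrix)."""

    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=object)

    def predict(self, X):
        return self.preds


def test_evaluate_perfect_predictions():
    y = np.array(["EFS"] * 5 + ["EF"] * 5 + ["AA"] * 5)
    rep = evaluate(_EchoModel(y), np.zeros((15, 1)), y)
    assert np.trace(rep.confusion) == 15
    for label in CLASS_ORDER:
        assert rep.per_class[label]["accuracy"] == 1.0
    assert rep.macro["f1"] == 1.0


def test_evaluate_constant_predictor_closed_form():
    y = np.array(["EFS"] * 10 + ["EF"] * 10 + ["AA"] * 10)
    rep = evaluate(_ConstantModel("AA"), np.zeros((30, 1)), y)
    assert rep.per_class["AA"]["recall"] == 1.0
    assert rep.per_class["AA"]["precision"] == pytest.approx(1 / 3)
    assert rep.per_class["EFS"]["recall"] == 0.0


def test_evaluate_matches_hand_computed_formulas():
    rng = np.random.default_rng(7)
    for _ in range(20):
        y_true = rng.choice(CLASS_ORDER, size=60)
        y_pred = rng.choice(CLASS_ORDER, size=60)
        rep = evaluate(_EchoModel(y_pred), np.zeros((60, 1)), y_true)
        # row sums equal true class counts
        for i, label in enumerate(rep.labels):
            assert rep.confusion[i].sum() == (y_true == label).sum()
        expected = metrics_from_confusion(rep.confusion, rep.labels)
        for label in rep.labels:
            for metric, value in expected[label].items():
                assert rep.per_class[label][metric] == pytest.approx(value)


def test_evaluate_empty_set_rejected():
    with pytest.raises(ValueError):
        evaluate(_ConstantModel("AA"), np.zeros((0, 1)), np.array([]))
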