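import numpy as np
import pytest

from aiia.classify import (
    CVConfig,
    CVReport,
    GaussianNBClassifier,
    crossvalidate,
    format_accuracy,
    make_classifier,
    make_folds,
    per_class_accuracy,
)
from aiia.errors import (
    DegenerateModelError,
    ParameterError,
    UndefinedClassError,
)

STUDY1_COUNTS = {"AF": 9, "CHF": 43, "HE": 20, "HY": 20, "WNU": 50}


def study1_labels():
    return [c for c, n in STUDY1_COUNTS.items() for _ in range(n)]


class TestFormatAccuracy:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(126 / 142, "88.7%"), (7 / 9, "77.8%"), (0.5, "50.0%"),
         (1.0, "100.0%"), (0.125, "12.5%"), (0.0625, "6.3%")],
    )
    def test_one_decimal_half_up(self, fraction, expected):
        assert format_accuracy(fraction) == expected


class TestMakeFolds:
    def test_leave_one_out_limit(self):
        folds = make_folds(["a"] * 5 + ["b"] * 5, CVConfig(folds=10))
        vals = [set(v.tolist()) for _, v in folds]
        assert all(len(v) == 1 for v in vals)
        assert set().union(*vals) == set(range(10))

    @pytest.mark.parametrize("stratified", [True, False])
    def test_validation_sets_partition_indices(self, stratified):
        labels = study1_labels()
        folds = make_folds(
            labels, CVConfig(folds=10, stratified=stratified, seed=3)
        )
        seen = np.concatenate([v for _, v in folds])
        assert sorted(seen.tolist()) == list(range(len(labels)))
        for train, val in folds:
            assert set(train) | set(val) == set(range(len(labels)))
            assert not set(train) & set(val)

    def test_stratified_counts_within_one_of_proportionality(self):
        labels = np.array(study1_labels())
        for seed in range(25):
            folds = make_folds(labels, CVConfig(folds=10, seed=seed))
            for _, val in folds:
                for cls, total in STUDY1_COUNTS.items():
                    got = int(np.sum(labels[val] == cls))
                    assert abs(got - total / 10) <= 1

    def test_deterministic_given_seed(self):
        labels = study1_labels()
        a = make_folds(labels, CVConfig(seed=5))
        b = make_folds(labels, CVConfig(seed=5))
        for (ta, va), (tb, vb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(va, vb)

    def test_more_folds_than_records(self):
        with pytest.raises(ParameterError):
            make_folds(["a", "b"], CVConfig(folds=3))


class TestCVReport:
    def test_accounting_identities(self):
        conf = np.array([[7, 2], [1, 10]])
        rep = CVReport(("x", "y"), conf, (0.8, 0.9))
        assert rep.n_total == 20
        assert rep.n_correct == 17
        assert rep.n_incorrect == 3
        assert rep.overall_accuracy == pytest.approx(17 / 20)
        assert rep.per_class_accuracy == {
            "x": pytest.approx(7 / 9),
            "y": pytest.approx(10 / 11),
        }

    def test_identity_confusion_all_classes_perfect(self):
        rep = CVReport(("a", "b", "c"), np.eye(3, dtype=int) * 4, ())
        assert all(v == 1.0 for v in per_class_accuracy(rep).values())
        assert rep.overall_accuracy == 1.0

    def test_empty_class_row_rejected(self):
        rep = CVReport(("a", "b"), np.array([[3, 0], [0, 0]]), ())
        with pytest.raises(UndefinedClassError):
            per_class_accuracy(rep)

    def test_json_round_trips_confusion(self):
        import json

        rep = CVReport(("a", "b"), np.array([[2, 1], [0, 3]]), (0.5,))
        data = json.loads(rep.to_json())
        assert data["confusion"]["a"]["b"] == 1
        assert data["n_total"] == 6


class TestCrossvalidate:
    def test_separable_constant_features_are_perfect(self):
        X = np.array([[0.0, 1.0]] * 10 + [[1.0, 0.0]] * 10)
        y = ["a"] * 10 + ["b"] * 10
        rep = crossvalidate(X, y, GaussianNBClassifier(), CVConfig(folds=5))
        assert rep.overall_accuracy == 1.0

    def test_report_accounts_for_every_record(self, rng):
        X = rng.normal(size=(30, 4))
        y = ["a", "b", "c"] * 10
        rep = crossvalidate(X, y, GaussianNBClassifier(), CVConfig(folds=5))
        assert rep.n_total == 30
        assert rep.confusion.sum() == 30
        assert len(rep.per_fold_accuracy) == 5

    def test_shuffled_labels_score_at_chance(self, rng):
        # Permutation null: with labels independent of features, mean
        # accuracy sits near 1/n_classes.
        n_classes, reps, accs = 3, 200, []
        X = rng.normal(size=(30, 3))
        base = np.array(["a", "b", "c"] * 10)
        for _ in range(reps):
            y = rng.permutation(base)
            rep = crossvalidate(
                X, y.tolist(), GaussianNBClassifier(), CVConfig(folds=3)
            )
            accs.append(rep.overall_accuracy)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(reps)
        assert abs(mean - 1 / n_classes) < 3 * max(se, 1e-3)

    def test_determinism(self, rng):
        X = rng.normal(size=(40, 5))
        y = (["a"] * 20) + (["b"] * 20)
        r1 = crossvalidate(X, y, GaussianNBClassifier(), CVConfig(seed=2))
        r2 = crossvalidate(X, y, GaussianNBClassifier(), CVConfig(seed=2))
        assert r1.to_json() == r2.to_json()

    def test_classifier_failure_names_fold(self, rng):
        class Broken:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise RuntimeError("boom")

            def predict(self, X):
                raise AssertionError

        X = rng.normal(size=(10, 2))
        with pytest.raises(RuntimeError, match="fold 0"):
            crossvalidate(X, ["a", "b"] * 5, Broken(), CVConfig(folds=2))


class TestGaussianNBClassifier:
    def test_perfect_separating_feature(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["lo", "lo", "hi", "hi"])
        clf = GaussianNBClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_symmetric_toy_boundary_at_zero(self, rng):
        X = np.r_[
            rng.normal(-1, 0.5, size=(100, 1)), rng.normal(1, 0.5, size=(100, 1))
        ]
        y = np.array(["neg"] * 100 + ["pos"] * 100)
        clf = GaussianNBClassifier().fit(X, y)
        assert clf.predict([[-0.4]])[0] == "neg"
        assert clf.predict([[0.4]])[0] == "pos"

    def test_matches_direct_log_posterior(self, rng):
        # Oracle: recompute argmax_c log pi_c + sum_j log N(x_j; mu, var)
        # from the fitted parameters with plain Python loops.
        X = rng.normal(size=(24, 3))
        y = rng.choice(["a", "b", "c"], size=24).tolist()
        while len(set(y)) < 2:
            y = rng.choice(["a", "b", "c"], size=24).tolist()
        clf = GaussianNBClassifier().fit(X, y)
        Xt = rng.normal(size=(40, 3))
        pred = clf.predict(Xt)
        for row, p in zip(Xt, pred):
            scores = {}
            for i, c in enumerate(clf.classes_):
                s = np.log(clf.class_prior_[i])
                for j in range(3):
                    var = clf.var_[i, j]
                    s += -0.5 * np.log(2 * np.pi * var)
                    s += -0.5 * (row[j] - clf.theta_[i, j]) ** 2 / var
                scores[c] = s
            assert p == max(scores, key=scores.get)

    def test_agrees_with_sklearn_gnb(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(size=(60, 4)) + np.repeat(
            np.array([[0.0], [3.0]]), 30, axis=0
        )
        y = ["a"] * 30 + ["b"] * 30
        ours = GaussianNBClassifier().fit(X, y).predict(X)
        theirs = GaussianNB().fit(X, y).predict(X)
        assert (ours == theirs).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateModelError):
            GaussianNBClassifier().fit(rng.normal(size=(5, 2)), ["a"] * 5)

    def test_constant_feature_does_not_blow_up(self):
        X = np.array([[1.0, 0.0], [1.0, 0.1], [1.0, 5.0], [1.0, 5.2]])
        y = ["lo", "lo", "hi", "hi"]
        clf = GaussianNBClassifier().fit(X, y)
        assert (clf.predict(X) == np.array(y)).all()


def test_registry_builds_every_classifier():
    from aiia.classify import CLASSIFIER_REGISTRY

    for name in CLASSIFIER_REGISTRY:
        est = make_classifier(name, seed=1)
        assert hasattr(est, "fit") and hasattr(est, "predict")
    with pytest.raises(ParameterError):
        make_classifier("nope")
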