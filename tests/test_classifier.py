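import numpy as np
import pytest
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from gaitcue import ClassifierConfig, FogModel, ValidationError, loso_cv, predict, train
from gaitcue.classifier import _confusion, _rates

from _oracles import brute_force_stump_boost


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 10))
    y = np.array(["normal"] * (n // 2) + ["fog"] * (n - n // 2))
    X[:, 3] = np.where(y == "fog", rng.uniform(0.05, 0.3, n), rng.uniform(0.9, 1.4, n))
    X[:, 1] = np.where(y == "fog", rng.uniform(1, 5, n), rng.uniform(15, 25, n))
    X += rng.normal(0, 0.01, X.shape)
    return X, y


def test_separable_data_trains_to_perfection():
    X, y = _separable()
    model = train(X, y, ClassifierConfig(seed=0))
    labels, scores = model.predict(X)
    assert np.all(labels == y)


def test_training_is_deterministic_and_serializable(tmp_path):
    X, y = _separable(seed=3)
    m1 = train(X, y, ClassifierConfig(seed=7))
    m2 = train(X, y, ClassifierConfig(seed=7))
    assert m1.to_dict() == m2.to_dict()
    path = str(tmp_path / "model.json")
    m1.save(path)
    m3 = FogModel.load(path)
    np.testing.assert_array_equal(m3.predict_scores(X), m1.predict_scores(X))


def test_single_class_input_rejected():
    X = np.random.default_rng(0).normal(size=(20, 10))
    with pytest.raises(ValidationError):
        train(X, ["normal"] * 20)


def test_missing_values_rejected():
    X, y = _separable()
    X[0, 0] = np.nan
    with pytest.raises(ValidationError):
        train(X, y)


def _stump_model(feature_idx, threshold, alphas=(1.0,)):
    """Hand-built model: each stump votes fog when X[feature] <= threshold."""
    tree = {"children_left": [1, -1, -1], "children_right": [2, -1, -1],
            "feature": [feature_idx, -2, -2], "threshold": [threshold, -2.0, -2.0],
            "node_class": [0, 1, 0]}
    from gaitcue.features import FEATURE_NAMES
    return FogModel(trees=[dict(tree) for _ in alphas], alphas=list(alphas),
                    feature_names=list(FEATURE_NAMES),
                    config=ClassifierConfig(n_estimators=len(alphas)))


def test_single_stump_prediction():
    model = _stump_model(feature_idx=3, threshold=0.5)   # stride_length < 0.5 => fog
    fv = np.zeros(10)
    fv[3] = 0.3
    label, score = predict(model, fv)
    assert label == "fog" and score == 1.0
    fv[3] = 0.9
    label, score = predict(model, fv)
    assert label == "normal" and score == 0.0
    # same input twice -> identical output
    assert predict(model, fv) == predict(model, fv)


def test_three_stump_weighted_vote():
    """Score equals the hand-computed weighted vote fraction."""
    from gaitcue.features import FEATURE_NAMES
    stump = lambda j, thr: {"children_left": [1, -1, -1], "children_right": [2, -1, -1],
                            "feature": [j, -2, -2], "threshold": [thr, -2.0, -2.0],
                            "node_class": [0, 1, 0]}
    model = FogModel(trees=[stump(3, 0.5), stump(1, 10.0), stump(9, 0.3)],
                     alphas=[0.5, 0.3, 0.2], feature_names=list(FEATURE_NAMES),
                     config=ClassifierConfig(n_estimators=3))
    fv = np.zeros(10)
    fv[3] = 0.2    # stump 1 votes fog  (alpha 0.5)
    fv[1] = 18.0   # stump 2 votes normal
    fv[9] = 0.25   # stump 3 votes fog  (alpha 0.2)
    label, score = predict(model, fv)
    assert score == pytest.approx((0.5 + 0.2) / 1.0)
    assert label == "fog"


def test_tiny_instance_matches_brute_force_boosting():
    """On tiny problems the ensemble equals an exhaustive stump-boosting
    recursion (same weak-learner criterion, same weight updates)."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=8) > 0).astype(int)
        if len(np.unique(y)) < 2:
            continue
        model = train(X, y, ClassifierConfig(n_estimators=2, max_tree_depth=1, seed=0),
                      feature_names=["f0", "f1"])
        got = (model.predict_scores(X) > 0.5).astype(int)
        want = brute_force_stump_boost(X, y, n_estimators=2)
        np.testing.assert_array_equal(got, want)


def test_matches_sklearn_adaboost_reference():
    """Cross-check the boosting loop against sklearn's SAMME ensemble."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 4))
    y = ((X[:, 0] + X[:, 1] ** 2 + 0.5 * rng.normal(size=200)) > 0.5).astype(int)
    model = train(X, y, ClassifierConfig(n_estimators=10, max_tree_depth=3, seed=0),
                  feature_names=list("abcd"))
    ref = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=3, random_state=0),
        n_estimators=10, random_state=0)
    ref.fit(X, y)
    got = (model.predict_scores(X) > 0.5).astype(int)
    agreement = np.mean(got == ref.predict(X))
    assert agreement >= 0.95


def test_null_labels_give_chance_auc():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(500, 10))
    y = rng.integers(0, 2, 500)
    model = train(X[:250], y[:250], ClassifierConfig(seed=0))
    scores = model.predict_scores(X[250:])
    auc = roc_auc_score(y[250:], scores)
    assert 0.4 <= auc <= 0.6


def test_threshold_monotonicity():
    """Raising the decision threshold never increases sensitivity and never
    decreases specificity."""
    X, y = _separable(n=200, seed=5)
    rng = np.random.default_rng(0)
    X += rng.normal(0, 0.5, X.shape)    # blur the margin
    model = train(X, y, ClassifierConfig(seed=0))
    scores = model.predict_scores(X)
    yi = (np.asarray(y) == "fog").astype(int)
    prev_sens, prev_spec = np.inf, -np.inf
    for thr in np.linspace(0, 1, 21):
        pred = (scores > thr).astype(int)
        c = _confusion(pred, yi)
        r = _rates(c)
        assert r["sensitivity"] <= prev_sens + 1e-9
        assert r["specificity"] >= prev_spec - 1e-9
        prev_sens, prev_spec = r["sensitivity"], r["specificity"]


def test_loso_two_identical_subjects():
    X, y = _separable(n=40, seed=2)
    X2 = np.vstack([X, X])
    y2 = np.concatenate([y, y])
    groups = np.array([0] * 40 + [1] * 40)
    cv = loso_cv(X2, y2, groups, ClassifierConfig(seed=0))
    assert cv.accuracy_mean == 100.0
    assert len(cv.per_fold) == 2


def test_summed_confusion_consistency():
    X, y = _separable(n=60, seed=4)
    rng = np.random.default_rng(1)
    X += rng.normal(0, 1.0, X.shape)
    groups = rng.integers(0, 4, 60)
    cv = loso_cv(X, y, groups, ClassifierConfig(seed=0))
    c = cv.total_confusion
    total = sum(c.values())
    assert total == 60
    assert cv.total_accuracy == pytest.approx(100.0 * (c["tp"] + c["tn"]) / total)


def test_loso_requires_two_subjects():
    X, y = _separable(n=20)
    with pytest.raises(ValidationError):
        loso_cv(X, y, np.zeros(20, dtype=int))


def test_schema_mismatch_rejected():
    X, y = _separable()
    model = train(X, y, ClassifierConfig(seed=0))
    with pytest.raises(ValidationError):
        model.predict(np.zeros((2, 7)))
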