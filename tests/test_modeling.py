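"""Split, feature selection, training, thresholding, SHAP explanation."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from kymovoice.modeling import (
    ClassifierResults,
    LesionClassifier,
    choose_threshold,
    evaluate_scores,
    select_features,
    shap_attributions,
    split_dataset,
    stratified_train_counts,
    task_labels,
    train_model,
)


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def test_largest_remainder_counts():
    counts = {"normophonic": 38, "benign": 64, "malignant": 36}
    out = stratified_train_counts(counts, 0.7)
    assert out == {"normophonic": 27, "benign": 45, "malignant": 25}
    assert sum(out.values()) == 97


def _toy_frame(n_per_group, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in n_per_group.items():
        for i in range(n):
            rows.append({"group": g, "Jitt": rng.normal(), "gender": i % 2})
    return pd.DataFrame(rows)


def test_split_counts_and_chi2():
    df = _toy_frame({"normophonic": 38, "benign": 64, "malignant": 36})
    out = split_dataset(df, 0.7, seed=1)
    got = out[out["split"] == "train"]["group"].value_counts().to_dict()
    assert got == {"benign": 45, "normophonic": 27, "malignant": 25}
    assert 0 <= out.attrs["split_chi2_p"] <= 1


def test_split_full_fraction_and_seed_behaviour():
    df = _toy_frame({"normophonic": 10, "benign": 10, "malignant": 10})
    assert (split_dataset(df, 1.0, seed=0)["split"] == "train").all()
    a = split_dataset(df, 0.7, seed=0)
    b = split_dataset(df, 0.7, seed=1)
    counts_a = a[a["split"] == "train"]["group"].value_counts().to_dict()
    counts_b = b[b["split"] == "train"]["group"].value_counts().to_dict()
    assert counts_a == counts_b
    assert not (a["split"] == b["split"]).all()


def test_split_rejects_tiny_groups():
    df = _toy_frame({"normophonic": 1, "benign": 5, "malignant": 5})
    with pytest.raises(ValueError):
        split_dataset(df, 0.7, seed=0)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _selection_frame(seed=0, n=60):
    """One perfectly separating feature among pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    df = pd.DataFrame({
        "group": np.where(y == 1, "benign", "normophonic"),
        "Jitt": y * 4 + rng.normal(0, 0.1, n),  # the informative feature
        "Jita": rng.normal(size=n),
        "PPF": rng.normal(size=n),
        "Shimmer": rng.normal(size=n),
        "gender": rng.integers(0, 2, n),
    })
    return df


def test_perfect_feature_wins_selection():
    df = _selection_frame()
    table = select_features(df, "organic_detection", seed=0,
                            candidates=["Jitt", "Jita", "PPF", "Shimmer", "gender"])
    assert "Jitt" in table.iloc[0]["features"]
    assert (table["mean_cv_accuracy"].diff().dropna() <= 1e-12).all()


def test_redundancy_filter_keeps_one_copy():
    df = _selection_frame()
    for copy in ("Jita", "PPF", "Shimmer"):
        df[copy] = df["Jitt"]
    table = select_features(df, "organic_detection", seed=0,
                            candidates=["Jitt", "Jita", "PPF", "Shimmer", "gender"])
    red = table[table["set_name"] == "redundancy_filtered"].iloc[0]["features"]
    assert len([f for f in red if f != "gender"]) == 1


def test_constant_feature_excluded_with_warning():
    df = _selection_frame()
    df["PPF"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        table = select_features(df, "organic_detection", seed=0,
                                candidates=["Jitt", "PPF", "gender"])
    assert all("PPF" not in feats for feats in table["features"])


# ---------------------------------------------------------------------------
# training and thresholds
# ---------------------------------------------------------------------------

def test_separable_training_auc_is_one():
    df = _selection_frame()
    df["split"] = "train"
    model, params, cv_auc = train_model(df, ["Jitt"], "organic_detection",
                                        seed=0, trials=4)
    s = model.predict_proba(df[["Jitt"]].to_numpy())[:, 1]
    y = task_labels(df, "organic_detection")
    assert np.min(s[y == 1]) > np.max(s[y == 0])


def test_single_class_training_errors():
    df = _selection_frame().query("group == 'benign'").copy()
    with pytest.raises(ValueError, match="both classes"):
        train_model(df, ["Jitt"], "organic_detection", seed=0, trials=2)


def test_threshold_rules():
    y = np.r_[np.zeros(5), np.ones(5)]
    scores = np.r_[np.linspace(0.1, 0.4, 5), np.linspace(0.6, 0.9, 5)]
    # separated blocks: both rules give perfect sensitivity and specificity
    for task in ("organic_detection", "malignancy_detection"):
        t = choose_threshold(scores, y, task)
        m = evaluate_scores(scores, y, t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
    # malignancy rule guarantees 100% sensitivity even with overlap
    rng = np.random.default_rng(0)
    scores = rng.random(40)
    y = rng.integers(0, 2, 40)
    t = choose_threshold(scores, y, "malignancy_detection")
    assert evaluate_scores(scores, y, t)["sensitivity"] == 1.0
    # degenerate equal scores: forced sensitivity 1, specificity 0
    t = choose_threshold(np.full(10, 0.5), np.r_[np.zeros(5), np.ones(5)],
                         "organic_detection")
    m = evaluate_scores(np.full(10, 0.5), np.r_[np.zeros(5), np.ones(5)], t)
    assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0


def test_confusion_metrics_hand_example():
    """TP=9 FN=0 TN=12 FP=7: sensitivity 100%, specificity 63.2%, accuracy 75%."""
    scores = np.r_[np.full(9, 0.9), np.full(12, 0.1), np.full(7, 0.9)]
    y = np.r_[np.ones(9), np.zeros(19)]
    m = evaluate_scores(scores, y, 0.5)
    assert m["sensitivity"] == 1.0
    assert m["specificity"] == pytest.approx(12 / 19, abs=1e-12)
    assert round(100 * m["specificity"], 1) == 63.2
    assert m["accuracy"] == pytest.approx(0.75, abs=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_confusion_metrics_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    scores = rng.random(30)
    y = rng.integers(0, 2, 30)
    t = 0.5
    m = evaluate_scores(scores, y, t)
    tp = sum(1 for s, yy in zip(scores, y) if s >= t and yy == 1)
    tn = sum(1 for s, yy in zip(scores, y) if s < t and yy == 0)
    fp = sum(1 for s, yy in zip(scores, y) if s >= t and yy == 0)
    fn = sum(1 for s, yy in zip(scores, y) if s < t and yy == 1)
    assert (m["tp"], m["tn"], m["fp"], m["fn"]) == (tp, tn, fp, fn)
    assert m["accuracy"] == pytest.approx((tp + tn) / 30)


def test_evaluate_one_class_absent_warns():
    with pytest.warns(UserWarning, match="AUC omitted"):
        m = evaluate_scores(np.array([0.2, 0.8]), np.array([1, 1]), 0.5)
    assert m["auc"] is None
    assert m["sensitivity"] == 0.5


# ---------------------------------------------------------------------------
# SHAP explanation
# ---------------------------------------------------------------------------

def test_unused_feature_has_zero_attribution():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
    y = (X["a"] > 0).astype(int)
    model = xgb.XGBClassifier(n_estimators=10, max_depth=1, random_state=0,
                              n_jobs=1, colsample_bytree=1.0)
    model.fit(X[["a"]].assign(b=0.0), y)  # b constant: never split on
    table, base = shap_attributions(model, X.assign(b=0.0))
    assert np.allclose(table["b"], 0.0)


def test_single_stump_matches_exhaustive_shapley():
    """For a one-feature stump the exact Shapley value is the margin minus
    the mean margin (single-player game)."""
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"a": rng.normal(size=200)})
    y = (X["a"] > 0).astype(int)
    model = xgb.XGBClassifier(n_estimators=1, max_depth=1, learning_rate=1.0,
                              random_state=0, n_jobs=1)
    model.fit(X, y)
    table, base = shap_attributions(model, X)
    booster = model.get_booster()
    margin = booster.predict(xgb.DMatrix(X.to_numpy(), feature_names=["a"]),
                             output_margin=True)
    # single player: phi = v({a}) - v({}) = margin - base
    assert np.allclose(table["a"], margin - base, atol=1e-5)


def test_shap_local_accuracy(small_cohort_features):
    res = LesionClassifier(small_cohort_features, "organic_detection",
                           features="published").fit(seed=0, trials=3)
    table, base = res.shap_table()
    data = res.model_spec.data
    margin = res.model.get_booster().predict(
        xgb.DMatrix(data[res.features].to_numpy()), output_margin=True)
    assert np.allclose(table.sum(axis=1) + base, margin, atol=1e-4)


# ---------------------------------------------------------------------------
# the model/results pair
# ---------------------------------------------------------------------------

def test_fit_is_deterministic(small_cohort_features):
    r1 = LesionClassifier(small_cohort_features, "organic_detection",
                          features="published").fit(seed=3, trials=4)
    r2 = LesionClassifier(small_cohort_features, "organic_detection",
                          features="published").fit(seed=3, trials=4)
    assert r1.report() == r2.report()


def test_no_leakage_from_test_split(small_cohort_features):
    """Corrupting every test-split feature value must not change feature
    selection, tuned hyperparameters, or the decision threshold."""
    clean = small_cohort_features
    corrupt = clean.copy()
    feature_cols = [c for c in corrupt.columns
                    if c not in ("subject_id", "group", "split")]
    corrupt.loc[corrupt["split"] == "test", feature_cols] = 1e9
    r_clean = LesionClassifier(clean, "organic_detection", "auto").fit(
        seed=0, trials=4)
    r_corrupt = LesionClassifier(corrupt, "organic_detection", "auto").fit(
        seed=0, trials=4)
    assert r_clean.features == r_corrupt.features
    assert r_clean.hyperparams == r_corrupt.hyperparams
    assert r_clean.threshold == r_corrupt.threshold
    assert r_clean.train_metrics == r_corrupt.train_metrics


def test_malignancy_training_sensitivity_is_total(small_cohort_features):
    res = LesionClassifier(small_cohort_features, "malignancy_detection",
                           features="published").fit(seed=0, trials=4)
    assert res.train_metrics["sensitivity"] == 1.0


def test_summary_and_report(small_cohort_features):
    res = LesionClassifier(small_cohort_features, "organic_detection",
                           features="published").fit(seed=0, trials=3)
    text = res.summary()
    assert "organic_detection" in text and "AUC" in text
    rep = res.report()
    assert set(rep["shap_mean_abs"]) == set(res.features)
    for m in (rep["train_metrics"], rep["test_metrics"]):
        for key in ("accuracy", "sensitivity", "specificity"):
            assert 0.0 <= m[key] <= 1.0


def test_model_persistence_roundtrip(tmp_path, small_cohort_features):
    res = LesionClassifier(small_cohort_features, "organic_detection",
                           features="published").fit(seed=0, trials=3)
    path = tmp_path / "model.json"
    res.to_json(path)
    booster, meta = ClassifierResults.load_booster(path)
    data = res.model_spec.data
    dm = xgb.DMatrix(data[meta["features"]].to_numpy(),
                     feature_names=meta["features"])
    reloaded = booster.predict(dm)
    assert np.allclose(reloaded, res.predict_proba(data), atol=1e-6)
    assert meta["task"] == "organic_detection"
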