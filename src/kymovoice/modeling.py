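"""Predictive modeling of glottic lesions from vibration parameters.

Implements the full protocol: group-stratified 70/30 split, a
select-then-benchmark feature-selection stage, XGBoost training with
Bayesian hyperparameter optimization (cross-validated AUC on the training
split only), task-specific decision-threshold selection, evaluation with
DeLong confidence intervals, and exact TreeSHAP attributions.

Two diagnostic tasks are supported:

* ``organic_detection`` — any organic lesion (benign or malignant) vs
  normophonic; threshold at the training-split Youden optimum.
* ``malignancy_detection`` — malignant vs benign; threshold at the largest
  value keeping training sensitivity at 100%, the clinically mandated
  operating point (no missed cancer).

The public surface is the model/results pair: build a
:class:`LesionClassifier` from a feature table carrying a ``split``
column, call :meth:`~LesionClassifier.fit`, and read metrics, threshold
and SHAP attributions off the returned :class:`ClassifierResults`.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats as sps
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from . import bayesopt
from .perturbation import FEATURE_NAMES
from .stats import CONTRASTS, _delong_ci, auc_mann_whitney

TASKS = ("organic_detection", "malignancy_detection")

#: published predictor sets, used when feature selection is skipped
PUBLISHED_FEATURES = {
    "organic_detection": ["F0Avg", "Jitt", "PPQ3", "PPQ5", "APQ3", "gender"],
    "malignancy_detection": ["F0Avg", "Jitt", "Jita", "APF", "Shimmer",
                             "PRAP", "PPQ3", "PPQ5", "APQ5", "gender"],
}

ALL_CANDIDATES = list(FEATURE_NAMES) + ["gender"]

#: hyperparameter search space for the gradient-boosted trees
SEARCH_SPACE = [
    bayesopt.Dimension("learning_rate", 0.01, 0.3, scale="log"),
    bayesopt.Dimension("max_depth", 2, 6, integer=True),
    bayesopt.Dimension("n_estimators", 50, 300, integer=True),
    bayesopt.Dimension("subsample", 0.5, 1.0),
    bayesopt.Dimension("colsample_bytree", 0.5, 1.0),
    bayesopt.Dimension("min_child_weight", 1, 10, integer=True),
]


# --------------------------------------------------------------------------
# dataset plumbing
# --------------------------------------------------------------------------

def stratified_train_counts(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-group training counts by largest-remainder rounding.

    The total is ``round(fraction * N)``; group floors are topped up in
    order of decreasing fractional remainder (ties broken by group order).
    E.g. groups (38, 64, 36) at 70% give (27, 45, 25), total 97.
    """
    names = list(counts)
    exact = {g: fraction * counts[g] for g in names}
    floors = {g: int(np.floor(exact[g])) for g in names}
    total = int(round(fraction * sum(counts.values())))
    residual = total - sum(floors.values())
    order = sorted(names, key=lambda g: (-(exact[g] - floors[g]), names.index(g)))
    out = dict(floors)
    for g in order[:max(residual, 0)]:
        out[g] += 1
    return out


def split_dataset(
    features: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Group-stratified random train/test split.

    Adds a ``split`` column (``train``/``test``). Per-group training counts
    follow :func:`stratified_train_counts`, so two seeds give different
    assignments but identical counts. A chi-square independence check of
    group composition between splits is attached as ``df.attrs['split_chi2_p']``
    (the split should show no class bias).
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must lie in (0, 1]")
    counts = features[group_col].value_counts().to_dict()
    if any(c < 2 for c in counts.values()):
        raise ValueError("every group needs at least 2 members to split")
    n_train = stratified_train_counts(counts, train_fraction)
    rng = np.random.default_rng(seed)
    out = features.copy()
    out["split"] = "test"
    for g, sub in features.groupby(group_col):
        idx = rng.permutation(sub.index.to_numpy())[: n_train[g]]
        out.loc[idx, "split"] = "train"
    if train_fraction < 1 and (out["split"] == "test").any():
        table = pd.crosstab(out[group_col], out["split"])
        _, p, _, _ = sps.chi2_contingency(table)
        out.attrs["split_chi2_p"] = float(p)
    else:
        out.attrs["split_chi2_p"] = np.nan
    return out


def task_labels(features: pd.DataFrame, task: str, group_col: str = "group") -> np.ndarray:
    """Binary labels for a task: 1 = positive (diseased/malignant) class."""
    neg, pos = CONTRASTS[task]
    mask_known = features[group_col].isin(neg + pos)
    if not mask_known.all():
        raise ValueError("dataset contains groups outside the task contrast")
    return features[group_col].isin(pos).to_numpy().astype(int)


def task_subset(features: pd.DataFrame, task: str, group_col: str = "group") -> pd.DataFrame:
    """Rows relevant to a task (malignancy detection drops normophonics)."""
    neg, pos = CONTRASTS[task]
    return features[features[group_col].isin(neg + pos)].reset_index(drop=True)


# --------------------------------------------------------------------------
# feature selection
# --------------------------------------------------------------------------

def _default_estimator(seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1,
        subsample=0.9, colsample_bytree=0.9,
        random_state=seed, n_jobs=1, tree_method="hist",
        eval_metric="logloss",
    )


def select_features(
    train: pd.DataFrame,
    task: str,
    seed: int = 0,
    candidates: list[str] | None = None,
    cv_folds: int = 5,
    cv_repeats: int = 2,
    group_col: str = "group",
) -> pd.DataFrame:
    """Select-then-benchmark feature selection on the training split only.

    Candidate sets: (a) top-k features by univariate AUC for k in {3, 5, 8},
    (b) a correlation-redundancy filter (drop the lower-AUC member of any
    pair with \\|Spearman rho\\| > 0.9), and (c) all features. Gender is
    always retained as a candidate. Each set is scored by mean accuracy
    over repeated stratified cross-validation; the table is returned sorted
    by score (best first). Constant features are excluded with a warning.
    """
    if candidates is None:
        candidates = [c for c in ALL_CANDIDATES if c in train.columns]
    y = task_labels(train, task, group_col)
    usable = []
    for c in candidates:
        if train[c].nunique() <= 1:
            warnings.warn(f"feature {c!r} is constant on the training split; excluded")
        else:
            usable.append(c)

    quantitative = [c for c in usable if c != "gender"]
    uni_auc = {}
    for c in quantitative:
        a = auc_mann_whitney(train.loc[y == 0, c], train.loc[y == 1, c])
        uni_auc[c] = max(a, 1 - a)
    ranked = sorted(quantitative, key=lambda c: -uni_auc[c])

    sets: dict[str, list[str]] = {}
    for k in (3, 5, 8):
        chosen = ranked[: min(k, len(ranked))]
        sets[f"top{k}_auc"] = chosen + (["gender"] if "gender" in usable else [])
    # redundancy filter: greedy keep-higher-AUC
    rho = train[quantitative].corr(method="spearman").abs() if len(quantitative) > 1 \
        else pd.DataFrame()
    kept: list[str] = []
    for c in ranked:
        if all(rho.loc[c, k] <= 0.9 for k in kept):
            kept.append(c)
    sets["redundancy_filtered"] = kept + (["gender"] if "gender" in usable else [])
    sets["all_features"] = list(usable)

    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=seed)
    rows = []
    for name, feats in sets.items():
        accs = []
        X = train[feats].to_numpy(float)
        for tr, va in cv.split(X, y):
            est = _default_estimator(seed)
            est.fit(X[tr], y[tr])
            accs.append(float((est.predict(X[va]) == y[va]).mean()))
        rows.append({"set_name": name, "features": feats,
                     "n_features": len(feats), "mean_cv_accuracy": np.mean(accs)})
    return (pd.DataFrame(rows)
            .sort_values("mean_cv_accuracy", ascending=False, kind="stable")
            .reset_index(drop=True))


# --------------------------------------------------------------------------
# training, thresholding, evaluation, explanation
# --------------------------------------------------------------------------

def tune_hyperparameters(
    X: np.ndarray, y: np.ndarray, seed: int = 0, trials: int = 50,
    cv_folds: int = 5, n_initial: int = 10,
) -> tuple[dict, float, list]:
    """Bayesian optimization of the XGBoost hyperparameters, maximizing
    mean stratified-CV AUC on the training data only."""
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))

    def objective(params: dict) -> float:
        aucs = []
        for tr, va in folds:
            est = xgb.XGBClassifier(
                **params, random_state=seed, n_jobs=1,
                tree_method="hist", eval_metric="logloss",
            )
            est.fit(X[tr], y[tr])
            s = est.predict_proba(X[va])[:, 1]
            aucs.append(auc_mann_whitney(s[y[va] == 0], s[y[va] == 1]))
        return float(np.mean(aucs))

    return bayesopt.maximize(objective, SEARCH_SPACE, n_trials=trials,
                             n_initial=n_initial, seed=seed)


def train_model(
    train: pd.DataFrame, features: list[str], task: str,
    seed: int = 0, trials: int = 50, cv_folds: int = 5,
    group_col: str = "group",
) -> tuple[xgb.XGBClassifier, dict, float]:
    """Tune and fit the gradient-boosted classifier on the training split.

    Returns (fitted model, tuned hyperparameters, best CV AUC).
    """
    y = task_labels(train, task, group_col)
    if len(np.unique(y)) < 2:
        raise ValueError("training split must contain both classes")
    X = train[features].to_numpy(float)
    params, cv_auc, _ = tune_hyperparameters(X, y, seed=seed, trials=trials,
                                             cv_folds=cv_folds)
    model = xgb.XGBClassifier(**params, random_state=seed, n_jobs=1,
                              tree_method="hist", eval_metric="logloss")
    model.fit(X, y)
    return model, params, cv_auc


def choose_threshold(scores: np.ndarray, y: np.ndarray, task: str) -> float:
    """Decision threshold on training scores (classify positive at
    score >= threshold).

    ``malignancy_detection``: the largest threshold with 100% training
    sensitivity, i.e. the minimum positive-class score — no cancer case may
    fall below the operating point. ``organic_detection``: the Youden-optimal
    (sensitivity + specificity - 1) threshold; ties resolved toward the
    largest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if task == "malignancy_detection":
        return float(scores[y == 1].min())
    best_t, best_j = None, -np.inf
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_scores(scores: np.ndarray, y: np.ndarray, threshold: float) -> dict:
    """Confusion-matrix metrics at a fixed threshold plus threshold-free
    AUC with a DeLong 95% CI. With one class absent the AUC is omitted
    (None) with a warning; confusion metrics are still reported."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pred = scores >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    metrics = {
        "accuracy": (tp + tn) / max(len(y), 1),
        "sensitivity": tp / n_pos if n_pos else np.nan,
        "specificity": tn / n_neg if n_neg else np.nan,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
    if n_pos and n_neg:
        auc, lo, hi = _delong_ci(scores[y == 0], scores[y == 1])
        metrics.update(auc=auc, auc_ci_lower=lo, auc_ci_upper=hi)
    else:
        warnings.warn("one class absent; AUC omitted")
        metrics.update(auc=None, auc_ci_lower=None, auc_ci_upper=None)
    return metrics


def shap_attributions(model: xgb.XGBClassifier, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Exact TreeSHAP per-sample attributions on the log-odds (margin) scale.

    Returns (attributions, base_value); per sample, attributions plus the
    base value equal the model's margin output (local accuracy).
    """
    booster = model.get_booster()
    dm = xgb.DMatrix(X.to_numpy(float), feature_names=list(X.columns))
    contribs = booster.predict(dm, pred_contribs=True)
    base = float(contribs[0, -1])
    table = pd.DataFrame(contribs[:, :-1], columns=list(X.columns), index=X.index)
    return table, base


def explain_model(model: xgb.XGBClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Feature importance ranking by mean |SHAP| over the given samples."""
    table, _ = shap_attributions(model, X)
    imp = table.abs().mean(axis=0).sort_values(ascending=False)
    return imp.rename("mean_abs_shap").rename_axis("feature").reset_index()


def plot_shap_summary(shap_table: pd.DataFrame, X: pd.DataFrame, path) -> None:
    """Beeswarm-style SHAP summary: one row per feature (importance-ordered),
    points colored by the feature value."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = shap_table.abs().mean(axis=0).sort_values().index
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(order) + 1.5))
    for i, feat in enumerate(order):
        v = shap_table[feat].to_numpy()
        x_feat = X[feat].to_numpy(float)
        lo, hi = np.min(x_feat), np.max(x_feat)
        c = (x_feat - lo) / (hi - lo) if hi > lo else np.full_like(x_feat, 0.5)
        jitter = rng.normal(0, 0.08, v.size)
        ax.scatter(v, np.full(v.size, i) + jitter, c=c, cmap="coolwarm",
                   s=10, alpha=0.8)
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0, color="gray", lw=0.8)
    ax.set_xlabel("SHAP value (log-odds)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# the model / results pair
# --------------------------------------------------------------------------

class LesionClassifier:
    """Gradient-boosted lesion classifier built from a feature table.

    Parameters
    ----------
    data : DataFrame with the 12 vibration parameters, ``gender``,
        ``group`` and a ``split`` column (see :func:`split_dataset`).
    task : ``organic_detection`` or ``malignancy_detection``.
    features : ``"published"`` (the reference predictor sets),
        ``"auto"`` (run the select-then-benchmark stage on the training
        split), or an explicit list of column names.
    """

    def __init__(self, data: pd.DataFrame, task: str = "organic_detection",
                 features: str | list[str] = "published",
                 group_col: str = "group"):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        if "split" not in data.columns:
            raise ValueError("data must carry a 'split' column; see split_dataset()")
        self.task = task
        self.group_col = group_col
        self.data = task_subset(data, task, group_col)
        self.features = features

    @classmethod
    def from_cohort(cls, dataset, task: str = "organic_detection",
                    train_fraction: float = 0.7, seed: int = 0, **kwargs):
        """Build from a simulated :class:`~kymovoice.simulate.CohortDataset`:
        extracts features and applies the stratified split."""
        from .simulate import cohort_features

        feats = cohort_features(dataset, on_error="skip")
        feats = split_dataset(feats, train_fraction=train_fraction, seed=seed)
        return cls(feats, task=task, **kwargs)

    def fit(self, seed: int = 0, trials: int = 50, cv_folds: int = 5) -> "ClassifierResults":
        train = self.data[self.data["split"] == "train"]
        selection_table = None
        if isinstance(self.features, str) and self.features == "auto":
            selection_table = select_features(train, self.task, seed=seed,
                                              cv_folds=cv_folds,
                                              group_col=self.group_col)
            feats = list(selection_table.iloc[0]["features"])
        elif isinstance(self.features, str) and self.features == "published":
            feats = [f for f in PUBLISHED_FEATURES[self.task]
                     if f in self.data.columns]
        else:
            feats = list(self.features)
        model, params, cv_auc = train_model(train, feats, self.task, seed=seed,
                                            trials=trials, cv_folds=cv_folds,
                                            group_col=self.group_col)
        y_train = task_labels(train, self.task, self.group_col)
        s_train = model.predict_proba(train[feats].to_numpy(float))[:, 1]
        threshold = choose_threshold(s_train, y_train, self.task)
        return ClassifierResults(self, model, feats, params, float(cv_auc),
                                 float(threshold), seed, trials,
                                 selection_table)


class ClassifierResults:
    """Fitted classifier with metrics, threshold, and SHAP attributions."""

    def __init__(self, spec: LesionClassifier, model, features, hyperparams,
                 cv_auc, threshold, seed, trials, selection_table=None):
        self.model_spec = spec
        self.task = spec.task
        self.model = model
        self.features = features
        self.hyperparams = hyperparams
        self.cv_auc = cv_auc
        self.threshold = threshold
        self.seed = seed
        self.trials = trials
        self.selection_table = selection_table
        self.train_metrics = self._metrics("train")
        self.test_metrics = self._metrics("test") \
            if (spec.data["split"] == "test").any() else None

    # -- prediction ------------------------------------------------------
    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(X[self.features].to_numpy(float))[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def _metrics(self, split: str) -> dict:
        sub = self.model_spec.data[self.model_spec.data["split"] == split]
        y = task_labels(sub, self.task, self.model_spec.group_col)
        return evaluate_scores(self.predict_proba(sub), y, self.threshold)

    # -- explanation -----------------------------------------------------
    def shap_table(self, split: str | None = None) -> tuple[pd.DataFrame, float]:
        data = self.model_spec.data
        if split is not None:
            data = data[data["split"] == split]
        return shap_attributions(self.model, data[self.features])

    def shap_summary(self, split: str | None = None) -> pd.DataFrame:
        table, _ = self.shap_table(split)
        imp = table.abs().mean(axis=0).sort_values(ascending=False)
        return imp.rename("mean_abs_shap").rename_axis("feature").reset_index()

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"LesionClassifier results — task: {self.task}",
            f"  features ({len(self.features)}): {', '.join(self.features)}",
            f"  tuned hyperparameters: {self.hyperparams}",
            f"  CV AUC (train): {self.cv_auc:.4f}   threshold: {self.threshold:.4f}",
        ]
        for name, m in (("train", self.train_metrics), ("test", self.test_metrics)):
            if m is None:
                continue
            auc = f"{m['auc']:.3f} ({m['auc_ci_lower']:.3f}-{m['auc_ci_upper']:.3f})" \
                if m["auc"] is not None else "n/a"
            lines.append(
                f"  {name}: AUC {auc}  accuracy {100 * m['accuracy']:.1f}%  "
                f"sensitivity {100 * m['sensitivity']:.1f}%  "
                f"specificity {100 * m['specificity']:.1f}%"
            )
        top = self.shap_summary().head(3)
        lines.append("  top SHAP features: "
                     + ", ".join(f"{r.feature} ({r.mean_abs_shap:.3f})"
                                 for r in top.itertuples()))
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "task": self.task,
            "features": self.features,
            "hyperparameters": self.hyperparams,
            "cv_auc": self.cv_auc,
            "threshold": self.threshold,
            "seed": self.seed,
            "trials": self.trials,
            "train_metrics": _jsonable(self.train_metrics),
            "test_metrics": _jsonable(self.test_metrics),
            "shap_mean_abs": self.shap_summary().set_index("feature")
                                 ["mean_abs_shap"].to_dict(),
        }

    # -- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = self.report()
        payload["booster_json"] = self.model.get_booster() \
            .save_raw(raw_format="json").decode()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load_booster(path) -> tuple[xgb.Booster, dict]:
        """Load the persisted booster and report metadata."""
        with open(path) as fh:
            payload = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(payload.pop("booster_json"), "utf-8"))
        return booster, payload


def _jsonable(metrics: dict | None):
    if metrics is None:
        return None
    return {k: (None if v is None else float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in metrics.items()}
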