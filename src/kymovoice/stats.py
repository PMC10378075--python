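"""Group comparison and per-parameter ROC analysis.

The three cohorts (normophonic / benign / malignant) are compared per
parameter with the tie-corrected Kruskal-Wallis rank test; single-parameter
discriminative power is quantified by the empirical ROC curve, the AUC via
the midrank Mann-Whitney identity, and a 95% confidence interval by
DeLong's asymptotic method. Following the analysis protocol this package
mirrors, no multiple-testing correction is applied across parameters —
interpret the p-value table accordingly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .perturbation import FEATURE_NAMES

#: the two diagnostic contrasts
CONTRASTS = {
    # positive class second
    "organic_detection": (("normophonic",), ("benign", "malignant")),
    "malignancy_detection": (("benign",), ("malignant",)),
}


def kruskal_wallis_table(
    features: pd.DataFrame,
    group_col: str = "group",
    parameters: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H and p per quantitative parameter.

    Parameters with no variation at all across groups are reported with
    NaN statistics and note ``"no variation"`` rather than an error.
    Significance threshold alpha = 0.05, uncorrected.
    """
    groups = [g for g, sub in features.groupby(group_col) if len(sub)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    rows = []
    for param in parameters:
        samples = [features.loc[features[group_col] == g, param].to_numpy()
                   for g in groups]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"parameter {param!r} missing observations in a group")
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            rows.append({"parameter": param, "H": np.nan, "p_value": np.nan,
                         "significant": False, "note": "no variation"})
            continue
        h, p = sps.kruskal(*samples)
        rows.append({"parameter": param, "H": float(h), "p_value": float(p),
                     "significant": bool(p < 0.05), "note": ""})
    return pd.DataFrame(rows)


def auc_mann_whitney(neg: np.ndarray, pos: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) identity with midrank tie handling."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    n, m = neg.size, pos.size
    if n == 0 or m == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _delong_ci(neg: np.ndarray, pos: np.ndarray, level: float = 0.95):
    """DeLong variance of the AUC via placement values; normal-theory CI
    clipped to [0, 1]."""
    auc = auc_mann_whitney(neg, pos)
    m, n = pos.size, neg.size
    # placement of each positive among negatives, and vice versa (midranks)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


@dataclasses.dataclass
class RocResult:
    """Single-parameter ROC analysis for one diagnostic contrast."""

    parameter: str
    contrast: str
    auc: float
    ci_lower: float
    ci_upper: float
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: int  # +1: higher value indicates disease; -1: flipped

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter, "contrast": self.contrast,
            "AUC": self.auc, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "orientation": self.orientation,
        }


def roc_analysis(
    features: pd.DataFrame,
    parameter: str,
    contrast: str = "organic_detection",
    group_col: str = "group",
    orient: bool = True,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC of one parameter for one contrast.

    The parameter is oriented so that larger values indicate disease
    (``orientation`` records whether a sign flip was applied); the
    orientation makes the AUC >= 0.5 by construction. CI by DeLong's
    method, or percentile bootstrap with ``ci_method='bootstrap'``.
    """
    from sklearn.metrics import roc_curve

    neg_groups, pos_groups = CONTRASTS[contrast]
    neg = features.loc[features[group_col].isin(neg_groups), parameter].to_numpy(float)
    pos = features.loc[features[group_col].isin(pos_groups), parameter].to_numpy(float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError(f"contrast {contrast!r}: one class is empty")

    orientation = 1
    if orient and auc_mann_whitney(neg, pos) < 0.5:
        orientation = -1
        neg, pos = -neg, -pos

    if ci_method == "bootstrap":
        auc = auc_mann_whitney(neg, pos)
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = auc_mann_whitney(
                rng.choice(neg, neg.size, replace=True),
                rng.choice(pos, pos.size, replace=True),
            )
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        auc, lo, hi = _delong_ci(neg, pos)

    y = np.r_[np.zeros(neg.size), np.ones(pos.size)]
    score = np.r_[neg, pos]
    fpr, tpr, _ = roc_curve(y, score)
    return RocResult(parameter=parameter, contrast=contrast, auc=float(auc),
                     ci_lower=float(lo), ci_upper=float(hi),
                     fpr=fpr, tpr=tpr, orientation=orientation)


def roc_table(
    features: pd.DataFrame,
    contrast: str = "organic_detection",
    parameters: tuple[str, ...] = FEATURE_NAMES,
    **kwargs,
) -> pd.DataFrame:
    """Per-parameter ROC summary for one contrast, sorted by AUC."""
    rows = [roc_analysis(features, p, contrast, **kwargs).as_row()
            for p in parameters]
    return (pd.DataFrame(rows)
            .sort_values("AUC", ascending=False)
            .reset_index(drop=True))


def plot_roc(results: list[RocResult], path) -> None:
    """ROC curve panel figure (one axis per parameter)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    ncol = min(3, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.2 * nrow),
                             squeeze=False)
    for ax, res in zip(axes.ravel(), results):
        ax.plot(res.fpr, res.tpr, color="tab:blue")
        ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
        ax.set_title(f"{res.parameter}\nAUC={res.auc:.3f} "
                     f"({res.ci_lower:.3f}-{res.ci_upper:.3f})", fontsize=9)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
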