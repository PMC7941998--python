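"""Outcome modelling: feature screening, repeated stratified cross-validation
with per-patient probability averaging, ROC comparison, and the clinical
univariate panel.

The classifier is a gradient-boosted tree ensemble (xgboost).  Evaluation
follows a repeated stratified k-fold protocol: each of ``runs`` repetitions
draws a fresh stratified split (seeded ``seed + run``), producing one
out-of-fold recurrence probability per patient per run; the per-patient
probabilities are averaged across runs and the ROC panel (AUC, accuracy,
precision, recall) is computed from the averaged probabilities.  Paired AUCs
are compared with the DeLong covariance-adjusted z test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

logger = logging.getLogger("atriashape")


class ModelError(ValueError):
    """Invalid input to the outcome models."""


#: Required clinical table columns (binary columns coded 0/1).
CLINICAL_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "la_volume",
    "lvef",
    "bmi",
    "sinus_rhythm",
    "persistent_af",
    "cryoablation",
    "recurrence",
)
CONTINUOUS_VARS: tuple[str, ...] = ("lvef", "bmi", "age", "la_volume")
BINARY_VARS: tuple[str, ...] = ("sex", "sinus_rhythm", "persistent_af", "cryoablation")

#: Gradient-boosting defaults (trees, depth, learning rate, subsample).
DEFAULT_MODEL_CONFIG: dict = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
}

#: Named feature-set configurations of the outcome analysis.
MODEL_SETS: tuple[str, ...] = ("shape", "csoi", "clinical", "combined")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical table schema: all columns present, no missing values,
    binary columns and the label in {0, 1}."""
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ModelError(f"clinical table is missing columns: {missing}")
    if table[list(CLINICAL_COLUMNS)].isna().any().any():
        raise ModelError("clinical table contains missing values")
    for col in BINARY_VARS + ("recurrence",):
        if not table[col].isin([0, 1]).all():
            raise ModelError(f"column {col!r} must be coded 0/1")
    return table


# ---------------------------------------------------------------------------
# Feature screening
# ---------------------------------------------------------------------------

def wilcoxon_select(
    feature_table: pd.DataFrame, labels, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Two-sided Wilcoxon rank-sum screen per feature.

    Exact null distribution for group sizes <= 10 (no ties), normal
    approximation with tie correction otherwise; constant features get p = 1.
    Returns (selected feature names with p < alpha, per-feature p-values).
    """
    labels = np.asarray(labels)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ModelError("need >= 2 members per class for the rank-sum screen")
    pvals = {}
    for col in feature_table.columns:
        x = feature_table.loc[labels == 1, col].to_numpy(dtype=float)
        y = feature_table.loc[labels == 0, col].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            pvals[col] = 1.0
            continue
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 10 and not ties) else "asymptotic"
        pvals[col] = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        )
    pseries = pd.Series(pvals)
    selected = [c for c in feature_table.columns if pseries[c] < alpha]
    return selected, pseries


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Repeated-CV result: per-patient averaged out-of-fold probabilities and
    the ROC metric panel."""

    model_name: str
    probabilities: np.ndarray
    labels: np.ndarray
    auc: float
    accuracy: float
    precision: float
    recall: float
    roc_points: np.ndarray
    runs: int
    folds: int
    seed: int
    per_run_probabilities: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "runs": self.runs,
            "folds": self.folds,
            "seed": self.seed,
            "probabilities": self.probabilities.tolist(),
            "labels": self.labels.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _rank_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula; ties count one half."""
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(probs)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve_points(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ROC points (fpr, tpr) at every distinct threshold, endpoints included."""
    order = np.argsort(-probs, kind="stable")
    y_sorted = np.asarray(y)[order]
    p_sorted = probs[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-threshold block
    keep = np.r_[np.diff(p_sorted) != 0, True]
    tpr = np.r_[0.0, tp[keep] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[keep] / max(fp[-1], 1)]
    return np.column_stack([fpr, tpr])


def classification_metrics(
    avg_probs: np.ndarray, y, threshold: float = 0.5
) -> dict[str, float]:
    """AUC (rank definition, ties one half) plus accuracy/precision/recall at
    the threshold.  Positive class = recurrence."""
    avg_probs = np.asarray(avg_probs, dtype=float)
    y = np.asarray(y)
    if avg_probs.min() < 0 or avg_probs.max() > 1:
        raise ModelError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ModelError("AUC is undefined for a single-class label vector")
    pred = (avg_probs >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "auc": _rank_auc(avg_probs, y),
        "accuracy": float((pred == y).mean()),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
    }


def repeated_stratified_cv(
    X,
    y,
    runs: int = 100,
    folds: int = 5,
    seed: int = 0,
    model_config: dict | None = None,
    model_name: str = "shape",
    threshold: float = 0.5,
) -> CVReport:
    """Repeated stratified k-fold CV of a gradient-boosted classifier.

    Run ``r`` uses a stratified ``folds``-fold split seeded ``seed + r``; each
    patient receives one out-of-fold probability per run, and the final
    per-patient probability is the mean across runs.  Metrics are computed on
    the averaged probabilities.  Leave-one-out (folds == n) is not supported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if folds < 2:
        raise ModelError("folds must be >= 2")
    if folds >= len(y):
        raise ModelError("leave-one-out is not supported; use k-fold with k < n")
    if counts.min() < folds:
        raise ModelError(
            f"each class needs >= folds members (counts {counts.tolist()}, folds {folds})"
        )
    config = {**DEFAULT_MODEL_CONFIG, **(model_config or {})}
    per_run = np.empty((runs, len(y)))
    for r in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train, test in skf.split(X, y):
            clf = XGBClassifier(
                **config,
                random_state=seed + r,
                n_jobs=1,
                verbosity=0,
                eval_metric="logloss",
            )
            clf.fit(X[train], y[train])
            per_run[r, test] = clf.predict_proba(X[test])[:, 1]
    avg = per_run.mean(axis=0)
    metrics = classification_metrics(avg, y, threshold=threshold)
    return CVReport(
        model_name=model_name,
        probabilities=avg,
        labels=y,
        roc_points=roc_curve_points(avg, y),
        runs=runs,
        folds=folds,
        seed=seed,
        per_run_probabilities=per_run,
        **metrics,
    )


# ---------------------------------------------------------------------------
# DeLong AUC comparison
# ---------------------------------------------------------------------------

def _structural_components(probs: np.ndarray, y: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) placement values."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    # pairwise win/tie matrix, positives x negatives
    wins = (pos[:, None] > neg[None, :]).astype(float)
    wins += 0.5 * (pos[:, None] == neg[None, :])
    return wins.mean(axis=1), 1.0 - wins.mean(axis=0)


def compare_auc(avg_probs_model1, avg_probs_model2, y) -> float:
    """Two-sided DeLong test for equality of two correlated (paired) AUCs.

    The two probability vectors must score the same patients against the same
    labels.  Returns the p-value.
    """
    p1 = np.asarray(avg_probs_model1, dtype=float)
    p2 = np.asarray(avg_probs_model2, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ModelError("AUC comparison is undefined for single-class labels")
    v10_1, v01_1 = _structural_components(p1, y)
    v10_2, v01_2 = _structural_components(p2, y)
    auc1, auc2 = v10_1.mean(), v10_2.mean()
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([(1 - v01_1), (1 - v01_2)]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc1 - auc2
    if var <= 1e-15:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Clinical univariate panel and correlation map
# ---------------------------------------------------------------------------

def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test from group summary statistics.

    ``variant='welch'`` uses unequal variances; ``'pooled'`` assumes equal
    variances.  Returns (t, p)."""
    if variant not in ("welch", "pooled"):
        raise ModelError(f"unknown t-test variant {variant!r}")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ModelError("zero variance in both groups: t-test undefined")
        raise ModelError("zero variance in both groups")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return float(res.statistic), float(res.pvalue)


def univariate_clinical(records: pd.DataFrame, variant: str = "welch") -> pd.DataFrame:
    """Per-variable between-outcome comparison of the clinical covariates.

    Continuous variables get a two-sided two-sample t-test of the chosen
    variant; binary variables get Fisher's exact test on the 2x2 table.
    Groups are defined by the ``recurrence`` label (0 = no recurrence).
    """
    validate_clinical(records)
    g0 = records[records["recurrence"] == 0]
    g1 = records[records["recurrence"] == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ModelError("need >= 2 patients per outcome group")
    rows = []
    for var in CONTINUOUS_VARS:
        t, p = ttest_from_summary(
            g0[var].mean(), g0[var].std(ddof=1), len(g0),
            g1[var].mean(), g1[var].std(ddof=1), len(g1),
            variant=variant,
        )
        rows.append({"variable": var, "test": f"t ({variant})", "statistic": t, "p": p})
    for var in BINARY_VARS:
        table = [
            [int(g0[var].sum()), len(g0) - int(g0[var].sum())],
            [int(g1[var].sum()), len(g1) - int(g1[var].sum())],
        ]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append({"variable": var, "test": "fisher", "statistic": float(odds), "p": float(p)})
    return pd.DataFrame(rows)


def correlation_map(table: pd.DataFrame) -> pd.DataFrame:
    """Signed Pearson correlation matrix of numeric columns.

    Zero-variance columns get correlation 0 with everything (and 1 with
    themselves), with a warning.  The absolute-value companion used for
    magnitude display is ``correlation_map(df).abs()``.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ModelError("need >= 3 rows for a correlation map")
    corr = numeric.corr(method="pearson")
    degenerate = numeric.columns[numeric.std(ddof=0) == 0]
    if len(degenerate):
        logger.warning("zero-variance columns in correlation map: %s", list(degenerate))
        corr.loc[degenerate, :] = 0.0
        corr.loc[:, degenerate] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr
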