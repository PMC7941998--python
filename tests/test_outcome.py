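import itertools

import numpy as np
import pandas as pd
import pytest

from atriashape import (
    ModelError,
    classification_metrics,
    compare_auc,
    correlation_map,
    generate_clinical,
    repeated_stratified_cv,
    roc_curve_points,
    ttest_from_summary,
    univariate_clinical,
    validate_clinical,
    wilcoxon_select,
)

FAST_XGB = {"n_estimators": 20, "max_depth": 2}


# ---------------------------------------------------------------------------
# Clinical table validation
# ---------------------------------------------------------------------------

def test_validate_clinical_errors():
    table = generate_clinical(5, 5, seed=0)
    validate_clinical(table)  # passes
    with pytest.raises(ModelError, match="missing columns"):
        validate_clinical(table.drop(columns=["bmi"]))
    bad = table.copy()
    bad.loc[0, "age"] = np.nan
    with pytest.raises(ModelError, match="missing values"):
        validate_clinical(bad)
    bad = table.copy()
    bad.loc[0, "sex"] = 2
    with pytest.raises(ModelError, match="0/1"):
        validate_clinical(bad)


# ---------------------------------------------------------------------------
# Wilcoxon screen
# ---------------------------------------------------------------------------

def test_wilcoxon_exact_example():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    labels = [1, 1, 1, 0, 0, 0]
    selected, pvals = wilcoxon_select(table, labels, alpha=0.05)
    assert pvals["f"] == pytest.approx(0.1)
    assert selected == []  # 0.1 >= 0.05


def test_wilcoxon_no_separation_and_constant():
    table = pd.DataFrame({
        "same": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5],
        "const": [7.0] * 8,
    })
    labels = [1, 1, 1, 1, 0, 0, 0, 0]
    _, pvals = wilcoxon_select(table, labels)
    assert pvals["same"] > 0.5
    assert pvals["const"] == 1.0


def test_wilcoxon_alpha_zero_selects_nothing():
    table = pd.DataFrame({"f": list(range(12))}, dtype=float)
    selected, _ = wilcoxon_select(table, [1] * 6 + [0] * 6, alpha=0.0)
    assert selected == []


def test_wilcoxon_exact_matches_enumeration():
    """Exact rank-sum path equals exhaustive relabelling enumeration."""
    rng = np.random.default_rng(4)
    values = rng.normal(size=8)
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    table = pd.DataFrame({"f": values})
    _, pvals = wilcoxon_select(table, labels)

    n, n1 = 8, 4
    ranks = np.argsort(np.argsort(values)) + 1
    mid = n1 * (n - n1) / 2 + n1 * (n1 + 1) / 2  # mean rank-sum under H0
    obs = abs(ranks[labels == 1].sum() - mid)
    count = sum(
        abs(ranks[list(combo)].sum() - mid) >= obs - 1e-12
        for combo in itertools.combinations(range(n), n1)
    )
    assert pvals["f"] == pytest.approx(count / 70.0)


def test_wilcoxon_small_group_raises():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    with pytest.raises(ModelError):
        wilcoxon_select(table, [1, 0, 0])


# ---------------------------------------------------------------------------
# AUC / metrics
# ---------------------------------------------------------------------------

def _brute_force_auc(probs, y):
    pos = probs[np.asarray(y) == 1]
    neg = probs[np.asarray(y) == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def test_auc_hand_examples():
    m = classification_metrics(np.array([0.9, 0.8, 0.7, 0.1]), [1, 0, 1, 0])
    assert m["auc"] == pytest.approx(0.75)
    assert classification_metrics(np.array([0.9, 0.8, 0.2, 0.1]), [1, 1, 0, 0])["auc"] == 1.0
    assert classification_metrics(np.array([0.1, 0.2, 0.8, 0.9]), [1, 1, 0, 0])["auc"] == 0.0
    assert classification_metrics(np.full(6, 0.5), [1, 1, 1, 0, 0, 0])["auc"] == 0.5


def test_auc_equals_brute_force_random():
    rng = np.random.default_rng(12)
    for n in (10, 100, 500):
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        probs = np.round(rng.random(n), 2)  # rounding forces ties
        m = classification_metrics(probs, y)
        assert m["auc"] == pytest.approx(_brute_force_auc(probs, y), abs=1e-12)


def test_classification_metrics_errors():
    with pytest.raises(ModelError, match=r"\[0, 1\]"):
        classification_metrics(np.array([0.5, 1.5]), [1, 0])
    with pytest.raises(ModelError, match="single-class"):
        classification_metrics(np.array([0.5, 0.6]), [1, 1])


def test_classification_metrics_panel():
    m = classification_metrics(np.array([0.9, 0.8, 0.2, 0.4]), [1, 1, 0, 0])
    assert m["accuracy"] == 1.0
    assert m["precision"] == 1.0
    assert m["recall"] == 1.0


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(2)
    probs = rng.random(30)
    y = rng.integers(0, 2, size=30)
    pts = roc_curve_points(probs, y)
    assert np.allclose(pts[0], [0.0, 0.0])
    assert np.allclose(pts[-1], [1.0, 1.0])
    assert (np.diff(pts[:, 0]) >= 0).all()
    assert (np.diff(pts[:, 1]) >= 0).all()


# ---------------------------------------------------------------------------
# Repeated stratified CV
# ---------------------------------------------------------------------------

def test_cv_perfectly_separable():
    y = np.array([1, 0] * 10)
    X = y.reshape(-1, 1).astype(float)
    rep = repeated_stratified_cv(X, y, runs=2, folds=2, seed=0,
                                 model_config=FAST_XGB)
    assert rep.auc == 1.0
    assert rep.probabilities.shape == (20,)
    assert rep.per_run_probabilities.shape == (2, 20)


def test_cv_deterministic():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    y = np.array([1, 0] * 10)
    r1 = repeated_stratified_cv(X, y, runs=2, folds=2, seed=3, model_config=FAST_XGB)
    r2 = repeated_stratified_cv(X, y, runs=2, folds=2, seed=3, model_config=FAST_XGB)
    assert np.array_equal(r1.probabilities, r2.probabilities)
    assert r1.auc == r2.auc


def test_cv_contract_errors():
    X = np.zeros((10, 1))
    y = np.array([1] * 5 + [0] * 5)
    with pytest.raises(ModelError, match="folds"):
        repeated_stratified_cv(X, y, runs=1, folds=1, seed=0)
    with pytest.raises(ModelError, match="leave-one-out"):
        repeated_stratified_cv(X, y, runs=1, folds=10, seed=0)
    with pytest.raises(ModelError, match="class"):
        repeated_stratified_cv(X, y, runs=1, folds=6, seed=0)


def test_cv_probability_averaging_reduces_variance():
    """Averaged probabilities are more stable across protocol repetitions
    than single-run probabilities."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(24, 4))
    y = np.array([1, 0] * 12)
    config = {**FAST_XGB, "subsample": 0.5}
    rep = repeated_stratified_cv(X, y, runs=8, folds=2, seed=0, model_config=config)
    runs = rep.per_run_probabilities
    single_run_gap = np.abs(runs[0] - runs[1]).mean()
    averaged_gap = np.abs(runs[:4].mean(axis=0) - runs[4:].mean(axis=0)).mean()
    assert averaged_gap < single_run_gap


def test_cv_report_roundtrip():
    y = np.array([1, 0] * 8)
    X = np.random.default_rng(0).normal(size=(16, 2))
    rep = repeated_stratified_cv(X, y, runs=1, folds=2, seed=0, model_config=FAST_XGB)
    d = rep.to_dict()
    assert d["runs"] == 1 and d["folds"] == 2
    assert len(d["probabilities"]) == 16
    assert 0.0 <= d["auc"] <= 1.0


# ---------------------------------------------------------------------------
# DeLong comparison
# ---------------------------------------------------------------------------

def test_compare_auc_identical_models():
    y = np.array([1, 0] * 10)
    p = np.random.default_rng(0).random(20)
    assert compare_auc(p, p, y) == 1.0


def test_compare_auc_monotone_transform_invariance():
    y = np.array([1, 0] * 10)
    p = np.random.default_rng(1).random(20)
    assert compare_auc(p, p**3, y) == 1.0  # same ranks, same AUC


def test_compare_auc_maximal_separation():
    y = np.array([1] * 10 + [0] * 10)
    perfect = np.concatenate([np.linspace(0.6, 1.0, 10), np.linspace(0.0, 0.4, 10)])
    anti = 1.0 - perfect
    assert compare_auc(perfect, anti, y) < 0.05


def test_compare_auc_detects_difference():
    rng = np.random.default_rng(5)
    y = np.array([1] * 30 + [0] * 30)
    good = np.clip(y + rng.normal(0, 0.3, 60), 0, 1)
    noise = rng.random(60)
    p = compare_auc(good, noise, y)
    assert p < 0.05
    # symmetric in model order
    assert compare_auc(noise, good, y) == pytest.approx(p)


def test_compare_auc_single_class_error():
    with pytest.raises(ModelError):
        compare_auc(np.array([0.1, 0.2]), np.array([0.3, 0.4]), [1, 1])


# ---------------------------------------------------------------------------
# Clinical univariate panel
# ---------------------------------------------------------------------------

def test_ttest_from_summary_published_values():
    _, p = ttest_from_summary(153.5, 42.44, 37, 157.3, 45.14, 31, variant="welch")
    assert round(p, 2) == 0.72
    t, p = ttest_from_summary(62.6, 9.46, 37, 68.0, 8.24, 31, variant="pooled")
    assert p == pytest.approx(0.015, abs=1e-3)
    assert t == pytest.approx(-2.485, abs=1e-3)
    _, p = ttest_from_summary(28.9, 5.2, 37, 31.4, 5.82, 31, variant="pooled")
    assert p == pytest.approx(0.066, abs=1e-3)


def test_ttest_from_summary_degenerate():
    t, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10, variant="pooled")
    assert t == 0.0 and p == 1.0
    with pytest.raises(ModelError, match="zero variance"):
        ttest_from_summary(5.0, 0.0, 10, 6.0, 0.0, 10)
    with pytest.raises(ModelError, match="variant"):
        ttest_from_summary(1, 1, 5, 2, 1, 5, variant="student")


def test_univariate_clinical_panel():
    table = generate_clinical(40, 40, seed=1).reset_index()
    out = univariate_clinical(table, variant="welch")
    assert len(out) == 8
    assert set(out["test"]) == {"t (welch)", "fisher"}
    assert ((out["p"] > 0) & (out["p"] <= 1)).all()


def test_univariate_clinical_matches_summary_path():
    """The raw-data t-test equals the summary-statistics path."""
    table = generate_clinical(30, 25, seed=3).reset_index()
    out = univariate_clinical(table, variant="welch").set_index("variable")
    g0 = table[table["recurrence"] == 0]
    g1 = table[table["recurrence"] == 1]
    t, p = ttest_from_summary(
        g0["age"].mean(), g0["age"].std(ddof=1), len(g0),
        g1["age"].mean(), g1["age"].std(ddof=1), len(g1), variant="welch",
    )
    assert out.loc["age", "statistic"] == pytest.approx(t)
    assert out.loc["age", "p"] == pytest.approx(p)


def test_univariate_clinical_small_group():
    table = generate_clinical(2, 5, seed=0).reset_index()
    table = table[table["recurrence"] == 0].reset_index(drop=True)
    table.loc[0, "recurrence"] = 1  # one positive only
    with pytest.raises(ModelError):
        univariate_clinical(table)


# ---------------------------------------------------------------------------
# Correlation map
# ---------------------------------------------------------------------------

def test_correlation_map_properties():
    rng = np.random.default_rng(0)
    x = rng.normal(size=1000)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": rng.normal(size=1000)})
    corr = correlation_map(df)
    assert np.allclose(np.diag(corr.values), 1.0)
    assert corr.loc["x", "y"] == pytest.approx(1.0)
    assert abs(corr.loc["x", "z"]) < 0.1
    assert np.allclose(corr.values, corr.values.T)
    assert corr.abs().values.max() <= 1.0 + 1e-12


def test_correlation_map_degenerate_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "flat": [5.0] * 4})
    corr = correlation_map(df)
    assert corr.loc["flat", "a"] == 0.0
    assert corr.loc["flat", "flat"] == 1.0


def test_correlation_map_needs_rows():
    with pytest.raises(ModelError):
        correlation_map(pd.DataFrame({"a": [1.0, 2.0]}))
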