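"""Logistic malignancy model, ROC analysis, rank-sum tests, correlations."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qvasc.classification import (FEATURE_SETS, PredictionModel, compare_groups,
                                  correlation_matrix, fit_model,
                                  malignancy_probability, roc_analysis)


def pair_count_auc(scores, labels):
    """Independent AUC oracle: concordant pos/neg pairs (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------------- probability

def test_probability_formula_values():
    m = PredictionModel(intercept=-1.0, coefficients={"x": 2.0}, features=["x"])
    assert malignancy_probability(m, {"x": 1.0}) == pytest.approx(
        1 / (1 + math.exp(-1)), abs=1e-12)
    m0 = PredictionModel(intercept=0.0, coefficients={"x": 0.0}, features=["x"])
    assert malignancy_probability(m0, {"x": 123.0}) == 0.5
    big = PredictionModel(intercept=0.0, coefficients={"x": 1.0}, features=["x"])
    assert malignancy_probability(big, {"x": 1e4}) == pytest.approx(1.0)
    assert 0 < malignancy_probability(big, {"x": -1e4}) < 1  # stays open interval


def test_probability_missing_feature_named():
    m = PredictionModel(intercept=0.0, coefficients={"x": 1.0, "y": 1.0},
                        features=["x", "y"])
    with pytest.raises(ValueError, match="y"):
        malignancy_probability(m, {"x": 1.0})


@settings(max_examples=50, deadline=None)
@given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-100, 100))
def test_probability_always_in_open_unit_interval(b, c, x):
    m = PredictionModel(intercept=b, coefficients={"x": c}, features=["x"])
    p = malignancy_probability(m, {"x": x})
    assert 0.0 < p < 1.0


def test_probability_monotone_in_positive_coefficient():
    m = PredictionModel(intercept=0.3, coefficients={"x": 1.7}, features=["x"])
    xs = np.linspace(-3, 3, 25)
    ps = m.predict_proba(pd.DataFrame({"x": xs}))
    assert np.all(np.diff(ps) > 0)


# --------------------------------------------------------------- model fit

def test_fit_recovers_known_logistic_model():
    rng = np.random.default_rng(123)
    X = rng.normal(size=(2000, 2))
    p = 1 / (1 + np.exp(-(X[:, 0] - X[:, 1])))
    df = pd.DataFrame({"f1": X[:, 0], "f2": X[:, 1],
                       "label": (rng.random(2000) < p).astype(int)})
    m = fit_model(df, ["f1", "f2"])
    assert m.coefficients["f1"] == pytest.approx(1.0, abs=0.15)
    assert m.coefficients["f2"] == pytest.approx(-1.0, abs=0.15)
    assert m.intercept == pytest.approx(0.0, abs=0.15)
    assert not m.separation_flag


def test_fit_is_deterministic():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"f": rng.normal(size=80),
                       "label": rng.integers(0, 2, 80)})
    a = fit_model(df, ["f"])
    b = fit_model(df, ["f"])
    assert a.coefficients == b.coefficients and a.intercept == b.intercept


def test_perfectly_separable_flagged_with_auc_one():
    df = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)],
                       "label": np.r_[np.zeros(20), np.ones(20)].astype(int)})
    with pytest.warns(UserWarning, match="separation"):
        m = fit_model(df, ["f"])
    assert m.separation_flag
    roc = roc_analysis(m.predict_proba(df), df.label, n_boot=10, seed=0)
    assert roc.auc == 1.0


def test_permuted_labels_give_chance_auc():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"f1": rng.normal(size=200), "f2": rng.normal(size=200),
                       "label": rng.permutation([0] * 100 + [1] * 100)})
    m = fit_model(df, ["f1", "f2"])
    roc = roc_analysis(m.predict_proba(df), df.label, n_boot=10, seed=0)
    assert roc.auc == pytest.approx(0.5, abs=0.1)


def test_fit_validates_inputs():
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0], "label": [1, 1, 1]})
    with pytest.raises(ValueError, match="classes"):
        fit_model(df, ["f"])
    with pytest.raises(KeyError):
        fit_model(pd.DataFrame({"f": [1, 2], "label": [0, 1]}), "no-such-set")


def test_listwise_deletion_counts():
    df = pd.DataFrame({"f": [1.0, np.nan, 3.0, 4.0, 0.5, np.inf, 2.0, 0.1],
                       "label": [0, 0, 1, 1, 0, 1, 1, 0]})
    m = fit_model(df, ["f"])
    assert m.n_used == 6 and m.n_dropped == 2


# ---------------------------------------------------------------------- ROC

def test_auc_matches_pair_counting_oracle():
    scores = [0.1, 0.4, 0.35, 0.8]
    labels = [0, 0, 1, 1]
    r = roc_analysis(scores, labels, n_boot=10, seed=0)
    assert r.auc == pytest.approx(0.75)
    assert r.auc == pytest.approx(pair_count_auc(scores, labels))
    rng = np.random.default_rng(3)
    s = rng.normal(size=40)
    y = rng.integers(0, 2, 40)
    if y.min() != y.max():
        assert roc_analysis(s, y, n_boot=10, seed=0).auc == pytest.approx(
            pair_count_auc(s, y))


def test_perfect_and_inverted_scores():
    labels = [0, 0, 1, 1]
    perfect = roc_analysis([0, 0, 1, 1], labels, n_boot=10, seed=0)
    assert (perfect.auc, perfect.sensitivity, perfect.specificity) == (1.0, 1.0, 1.0)
    inverted = roc_analysis([1, 1, 0, 0], labels, n_boot=10, seed=0)
    assert inverted.auc == 0.0


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(11)
    s = rng.normal(size=60)
    y = (rng.random(60) < 1 / (1 + np.exp(-s))).astype(int)
    a1 = roc_analysis(s, y, n_boot=10, seed=0).auc
    a2 = roc_analysis(np.exp(3 * s) + 7, y, n_boot=10, seed=0).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_analysis([0.1, 0.9], [1, 1], n_boot=10)


def test_bootstrap_ci_reproducible_and_shrinks_with_n():
    def cohort(n, seed=7):
        rng = np.random.default_rng(seed)
        lab = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        return rng.normal(size=n) + lab, lab
    s, y = cohort(100)
    r1 = roc_analysis(s, y, n_boot=200, seed=3)
    r2 = roc_analysis(s, y, n_boot=200, seed=3)
    assert r1.auc_ci == r2.auc_ci
    s2, y2 = cohort(1000)
    r3 = roc_analysis(s2, y2, n_boot=200, seed=3)
    assert (r3.auc_ci[1] - r3.auc_ci[0]) < (r1.auc_ci[1] - r1.auc_ci[0])


# ------------------------------------------------------------- group tests

def test_rank_sum_identical_groups_p_near_one():
    df = pd.DataFrame({"v": [1, 2, 3, 1, 2, 3], "label": [0, 0, 0, 1, 1, 1]})
    out = compare_groups(df, "v")
    assert out.loc[0, "p_value"] > 0.99


def test_rank_sum_extreme_split_exact_p():
    """n=3 vs 3 fully separated: exact permutation two-sided p = 2/20 = 0.1."""
    df = pd.DataFrame({"v": [1, 2, 3, 10, 11, 12], "label": [0, 0, 0, 1, 1, 1]})
    out = compare_groups(df, "v")
    assert out.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-9)


def test_rank_sum_stratified_skips_small_strata():
    df = pd.DataFrame({"v": np.arange(10.0),
                       "label": [0, 1] * 5,
                       "size": ["a"] * 8 + ["b"] * 2})
    out = compare_groups(df, "v", strata_col="size")
    assert set(out["stratum"]) == {"all", "a", "b"}
    b_row = out[out.stratum == "b"].iloc[0]
    assert math.isnan(b_row["p_value"]) and "skipped" in b_row["note"]


# ------------------------------------------------------------- correlations

def test_correlation_identities():
    rng = np.random.default_rng(4)
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
    r, low = correlation_matrix(df, ["a", "b", "c"])
    assert r.loc["a", "a"] == 1.0
    assert r.loc["a", "b"] == pytest.approx(-1.0)
    assert np.allclose(r.values, r.values.T, equal_nan=True)
    assert not low.loc["a", "a"] and not low.loc["a", "b"]


def test_correlation_hand_computed_example():
    df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
    r, low = correlation_matrix(df, ["x", "y"])
    assert r.loc["x", "y"] == pytest.approx(0.6)   # cov 3 / (s_x s_y) = 3/5
    assert not low.loc["x", "y"]                   # |r| >= 0.45


def test_correlation_zero_variance_is_missing():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [5.0, 5, 5, 5]})
    r, _ = correlation_matrix(df, ["x", "y"])
    assert math.isnan(r.loc["x", "y"])
    with pytest.raises(ValueError):
        correlation_matrix(df.iloc[:2], ["x", "y"])


# ----------------------------------------------------- nested-model property

def test_combined_model_dominates_singles_on_training_data(small_cohort_table):
    df = small_cohort_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        combined = fit_model(df, "combined")
        auc_combined = roc_analysis(combined.predict_proba(df), df.label,
                                    n_boot=10, seed=0).auc
        for f in FEATURE_SETS["combined"]:
            single = fit_model(df, [f])
            auc_single = roc_analysis(single.predict_proba(df), df.label,
                                      n_boot=10, seed=0).auc
            assert auc_combined >= auc_single - 1e-9
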