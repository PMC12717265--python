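"""Dataset construction, CART/LSBoost correctness, metrics and strata."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vapredict.boost_regression import (DEFOCUS_LEVELS, LSBoostModel,
                                        build_observation_table,
                                        defocus_column, evaluate,
                                        feature_importance, fit_lsboost,
                                        fit_tree, fit_xgboost, make_features,
                                        percent_change, remove_outliers_3sigma,
                                        removal_percentage, split_train_test,
                                        stratify)


# ---------------------------------------------------------------------------
# Observation table


def test_observation_table_counts(study_cohort):
    table = build_observation_table(study_cohort)
    assert table.attrs["n_built"] == 1755
    assert table.attrs["n_built_by_condition"]["uncorrected"] == 270
    assert table.attrs["n_built_by_condition"]["corrected"] == 270
    assert table.attrs["n_built_by_condition"]["defocus"] == 1215
    assert table.attrs["n_retained"] == 1744


def test_observation_table_single_subject_no_defocus(small_cohort):
    one = small_cohort[small_cohort["subject_id"] == "S0000"].copy()
    for lv in DEFOCUS_LEVELS:
        one[defocus_column(lv)] = np.nan
    table = build_observation_table(one)
    assert len(table) == 4  # 2 uncorrected + 2 corrected


def test_aa_gating_rule(small_cohort):
    table = build_observation_table(small_cohort)
    neg = table[(table["condition"] == "defocus") & (table["delta_d"] == -1.5)]
    pos = table[(table["condition"] == "defocus") & (table["delta_d"] == 0.5)]
    assert (neg["aa_gated"] > 0).all()
    assert (pos["aa_gated"] == 0).all()
    corr = table[table["condition"] == "corrected"]
    assert (corr["aa_gated"] == 0).all()


def test_missing_dominant_flag_skips_subject(small_cohort):
    broken = small_cohort.copy()
    broken.loc[broken.index[:2], "dominant"] = np.nan
    with pytest.warns(UserWarning):
        table = build_observation_table(broken)
    assert table.attrs["n_built"] < build_observation_table(small_cohort).attrs["n_built"]


def test_split_sizes_and_partition(study_cohort):
    table = build_observation_table(study_cohort)
    train, test = split_train_test(table, seed=0)
    assert len(test) == 348 and len(train) == 1396
    train2, test2 = split_train_test(table, seed=0)
    assert train.index.equals(train2.index) and test.index.equals(test2.index)
    assert len(set(train.index) & set(test.index)) == 0
    assert len(train) + len(test) == len(table)


# ---------------------------------------------------------------------------
# CART tree vs exhaustive oracle


def _oracle_sse(X, y, max_depth, min_leaf, depth=0):
    """Brute-force greedy tree: exhaustive split search at every node."""
    n = len(y)
    sse_leaf = float(np.sum((y - y.mean()) ** 2))
    if depth >= max_depth or n < 2 * min_leaf:
        return sse_leaf
    best = sse_leaf
    best_split = None
    for f in range(X.shape[1]):
        for thr in np.unique(X[:, f]):
            left = X[:, f] <= thr
            if min_leaf <= left.sum() <= n - min_leaf:
                s = (np.sum((y[left] - y[left].mean()) ** 2)
                     + np.sum((y[~left] - y[~left].mean()) ** 2))
                if s < best - 1e-12:
                    best, best_split = s, (f, thr)
    if best_split is None:
        return sse_leaf
    f, thr = best_split
    left = X[:, f] <= thr
    return (_oracle_sse(X[left], y[left], max_depth, min_leaf, depth + 1)
            + _oracle_sse(X[~left], y[~left], max_depth, min_leaf, depth + 1))


def test_tree_constant_and_step_targets():
    tree = fit_tree(np.arange(6.0).reshape(-1, 1), np.full(6, 2.5), min_leaf=1)
    assert "value" in tree.node and tree.node["value"] == 2.5
    X = np.arange(6.0).reshape(-1, 1)
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    tree = fit_tree(X, y, max_depth=1, min_leaf=1)
    assert tree.node["threshold"] == pytest.approx(2.5)
    np.testing.assert_allclose(tree.predict(X), y)


@pytest.mark.parametrize("seed", range(25))
def test_tree_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 13))
    d = int(rng.integers(1, 5))
    X = np.round(rng.normal(size=(n, d)), 2)
    y = np.round(rng.normal(size=n), 2)
    for max_depth, min_leaf in ((2, 1), (3, 2)):
        tree = fit_tree(X, y, max_depth=max_depth, min_leaf=min_leaf)
        got = float(np.sum((y - tree.predict(X)) ** 2))
        want = _oracle_sse(X, y, max_depth, min_leaf)
        assert got == pytest.approx(want, abs=1e-9)


# ---------------------------------------------------------------------------
# LSBoost


def test_lsboost_interpolation_limit():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(15, 2))
    y = rng.normal(size=15)
    model = fit_lsboost(X, y, n_stages=1, nu=1.0, max_depth=30, min_leaf=1)
    np.testing.assert_allclose(model.predict(X), y, atol=1e-9)


def test_empty_ensemble_predicts_mean():
    model = LSBoostModel(f0=0.7, trees=[], nu=0.1, n_features=3)
    np.testing.assert_allclose(model.predict(np.zeros((4, 3))), 0.7)
    with pytest.raises(ValueError):
        model.predict(np.zeros((4, 2)))


def test_boosting_descent():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    y = X[:, 0] ** 2 + 0.3 * rng.normal(size=20)
    model = fit_lsboost(X, y, n_stages=50, nu=0.3, max_depth=2, min_leaf=2)
    partial = np.full(20, model.f0)
    mses = [np.mean((y - partial) ** 2)]
    for tree in model.trees:
        partial = partial + model.nu * tree.predict(X)
        mses.append(np.mean((y - partial) ** 2))
    assert np.all(np.diff(mses) <= 1e-12)


def test_predict_matches_hand_rolled_sum():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    model = fit_lsboost(X, y, n_stages=5, nu=0.2, max_depth=3, min_leaf=2)
    Xq = rng.normal(size=(5, 4))
    manual = model.f0 + sum(model.nu * t.predict(Xq) for t in model.trees)
    np.testing.assert_allclose(model.predict(Xq), manual, atol=1e-12)


def test_lsboost_json_roundtrip():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 3))
    y = rng.normal(size=25)
    model = fit_lsboost(X, y, n_stages=4, nu=0.5, max_depth=2, min_leaf=2)
    clone = LSBoostModel.from_json(model.to_json())
    np.testing.assert_allclose(clone.predict(X), model.predict(X), atol=1e-12)


def test_xgboost_wrapper_contracts():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 3))
    const = np.full(40, 1.25)
    model = fit_xgboost(X, const, n_estimators=20)
    np.testing.assert_allclose(model.predict(X), 1.25, atol=1e-5)
    y = X[:, 1] + 0.1 * rng.normal(size=40)
    m1 = fit_xgboost(X, y, seed=7)
    m2 = fit_xgboost(X, y, seed=7)
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


def test_cross_engine_sanity(small_cohort):
    table = build_observation_table(small_cohort)
    train, test = split_train_test(table, seed=0)
    X, y, names = make_features(train, 9, use_aa=True)
    Xt, yt, _ = make_features(test, 9, use_aa=True)
    ls = fit_lsboost(X, y)
    xg = fit_xgboost(X, y)
    r_ls = evaluate(yt, ls.predict(Xt)).rmse
    r_xg = evaluate(yt, xg.predict(Xt)).rmse
    assert abs(r_xg - r_ls) / r_ls < 0.25


# ---------------------------------------------------------------------------
# Metrics


def test_evaluate_perfect_and_hand_example():
    rep = evaluate(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
    assert rep.mse == 0 and rep.r2 == 1 and rep.max_e == 0 and rep.mode_e == 0
    y = np.array([0.0, 0.1, 0.2])
    yhat = np.array([0.02, 0.1, 0.16])
    rep = evaluate(y, yhat)
    assert rep.mae == pytest.approx(0.02)
    assert rep.max_e == pytest.approx(0.04)
    assert rep.median_e == pytest.approx(0.02)
    # grid modes 0.00/0.02/0.04 tie -> smallest wins
    assert rep.mode_e == 0.0


def test_rmse_is_sqrt_mse():
    rng = np.random.default_rng(5)
    y, yhat = rng.normal(size=50), rng.normal(size=50)
    rep = evaluate(y, yhat)
    assert rep.rmse == pytest.approx(math.sqrt(rep.mse), abs=1e-12)


def test_zero_variance_targets_r2_nan():
    with pytest.warns(UserWarning):
        rep = evaluate(np.full(5, 0.3), np.linspace(0, 1, 5))
    assert math.isnan(rep.r2)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_evaluate_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    y, yhat = rng.normal(size=20), rng.normal(size=20)
    perm = rng.permutation(20)
    a = evaluate(y, yhat)
    b = evaluate(y[perm], yhat[perm])
    for k in ("mse", "rmse", "mae", "r2", "max_e", "min_e", "mode_e", "median_e"):
        assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-12)


def test_outlier_rule_percentages():
    assert removal_percentage(348, 328) == pytest.approx(5.75, abs=0.005)
    assert removal_percentage(348, 348 - 16) == pytest.approx(4.6, abs=0.005)
    e = np.concatenate([np.full(99, 0.02), [5.0]])
    mask, pct = remove_outliers_3sigma(e)
    assert mask.sum() == 99 and not mask[-1]
    assert pct == pytest.approx(1.0)
    # zero-spread errors: nothing removed
    mask, pct = remove_outliers_3sigma(np.full(10, 0.04))
    assert mask.all() and pct == 0.0


def test_percent_change_printed_delta():
    assert percent_change(0.0063, 0.0082) == pytest.approx(30.0, abs=0.5)


def test_feature_importance_normalization_and_planted_signal():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 5))
    y = 2.0 * X[:, 2] + 0.05 * rng.normal(size=200)
    model = fit_lsboost(X, y, n_stages=30, nu=0.3, max_depth=2, min_leaf=5)
    imp = feature_importance(model)
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    assert imp[2] > 0.9
    # single-feature data: that feature takes all the importance
    model1 = fit_lsboost(X[:, [2]], y, n_stages=10, nu=0.5, max_depth=2)
    assert feature_importance(model1)[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Stratification


def test_age_bins_boundaries(small_cohort):
    table = build_observation_table(small_cohort)
    table = table.copy()
    table.loc[table.index[0], "age"] = 44.0
    table.loc[table.index[1], "age"] = 45.0
    strata = stratify(table, "age_bins")
    assert set(strata) == {"30-40", "41-44", "45-50", "51-55", "56-60", "61-65"}
    assert table.index[0] in strata["41-44"].index
    assert table.index[1] in strata["45-50"].index


def test_se_groups_rules(small_cohort):
    table = build_observation_table(small_cohort)
    strata = stratify(table, "se_groups")
    for sub in strata.values():
        assert (sub["condition"] == "uncorrected").all()
    # boundary: SE = -0.5 exactly is emmetropic
    row = table[table["condition"] == "uncorrected"].iloc[[0]].copy()
    row["sphere_d"], row["cylinder_d"] = -0.5, 0.0
    strata = stratify(pd.concat([row]), "se_groups")
    assert len(strata["emmetropic"]) == 1 and len(strata["myopic"]) == 0
    # SE -2.5 from S=-2, C=-1 is myopic
    row["sphere_d"], row["cylinder_d"] = -2.0, -1.0
    strata = stratify(pd.concat([row]), "se_groups")
    assert len(strata["myopic"]) == 1
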