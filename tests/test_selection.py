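import numpy as np
import pandas as pd
import pytest

from canopylink.selection import (
    best_subsets,
    fit_ols,
    independent_columns,
    info_criteria,
    kfold_cv,
    pearson_prefilter,
    press_pred_r2,
)

from oracles import ols_pinv


def _random_regression(rng, n=100, p=6, noise=1.0, support=None, coefs=None):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
    )
    if support is None:
        y = rng.standard_normal(n)
    else:
        y = sum(c * X[s].to_numpy() for s, c in zip(support, coefs))
        y = y + rng.normal(0, noise, n)
    return X, np.asarray(y, float)


# ------------------------------------------------------------- prefilter


def test_duplicated_feature_keeps_one_copy(rng):
    X, y = _random_regression(rng, 200, 3)
    X["x0_copy"] = X["x0"]
    kept = pearson_prefilter(X, y)
    assert ("x0" in kept) != ("x0_copy" in kept)


def test_independent_features_all_retained(rng):
    X, y = _random_regression(rng, 500, 8)
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    np.fill_diagonal(corr, 0)
    assert np.abs(corr).max() < 0.85  # premise
    assert set(pearson_prefilter(X, y)) == set(X.columns)


def test_dropped_member_has_lower_response_correlation(rng):
    for trial in range(10):
        r = np.random.default_rng(trial)
        n = 120
        a = r.standard_normal(n)
        b = 0.97 * a + 0.03 * r.standard_normal(n)  # |r| > 0.85 with a
        c = r.standard_normal(n)
        y = 1.0 * a + 0.2 * c + r.normal(0, 0.3, n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        kept = pearson_prefilter(X, y)
        assert "c" in kept
        survivor = "a" if "a" in kept else "b"
        loser = "b" if survivor == "a" else "a"
        ry = {k: abs(np.corrcoef(X[k], y)[0, 1]) for k in ("a", "b")}
        assert ry[survivor] >= ry[loser]


def test_constant_feature_dropped_with_notice(rng):
    X, y = _random_regression(rng, 50, 3)
    X["flat"] = 1.23
    with pytest.warns(UserWarning, match="flat"):
        kept = pearson_prefilter(X, y)
    assert "flat" not in kept


def test_independent_columns_detects_sum_constraint(rng):
    X, y = _random_regression(rng, 80, 3)
    X["x3"] = 1.0 - X["x0"] - X["x1"] - X["x2"]
    kept = independent_columns(X, list(X.columns))
    assert len(kept) == 3


# ------------------------------------------------------------- OLS


def test_noiseless_fit_is_exact(rng):
    X, y = _random_regression(rng, 60, 4, noise=0.0,
                              support=["x0", "x2"], coefs=[2.0, -1.5])
    fit = fit_ols(X, y)
    assert fit["r2"] == pytest.approx(1.0)
    assert fit["sse"] == pytest.approx(0.0, abs=1e-18)
    assert fit["coefficients"]["x0"] == pytest.approx(2.0)
    assert fit["coefficients"]["x2"] == pytest.approx(-1.5)


def test_coefficients_match_pseudoinverse_oracle(rng):
    for _ in range(5):
        X, y = _random_regression(rng, 80, 5, noise=0.7,
                                  support=["x1"], coefs=[1.0])
        fit = fit_ols(X, y)
        beta, sse = ols_pinv(X.to_numpy(), y)
        assert np.abs(fit["beta"] - beta).max() < 1e-10
        assert fit["sse"] == pytest.approx(sse, abs=1e-8)


def test_adding_predictor_never_decreases_r2(rng):
    X, y = _random_regression(rng, 100, 6, noise=1.0,
                              support=["x0"], coefs=[1.0])
    r2_small = fit_ols(X[["x0"]], y)["r2"]
    r2_big = fit_ols(X[["x0", "x5"]], y)["r2"]
    assert r2_big >= r2_small - 1e-12


def test_rank_deficiency_names_offender(rng):
    X, y = _random_regression(rng, 50, 3)
    X["dup"] = X["x1"] * 2.0
    with pytest.raises(ValueError, match="dup"):
        fit_ols(X, y)


# ------------------------------------------------------------- PRESS


def test_press_at_least_sse(rng):
    for _ in range(20):
        X, y = _random_regression(rng, 40, 4, noise=1.0, support=["x0"], coefs=[1.0])
        fit = fit_ols(X, y)
        press, pred_r2 = press_pred_r2(fit)
        assert press >= fit["sse"] - 1e-10
        assert pred_r2 <= fit["r2"] + 1e-12


def test_press_equals_explicit_loo_refits(rng):
    X, y = _random_regression(rng, 40, 3, noise=0.8, support=["x0", "x1"],
                              coefs=[1.0, 0.5])
    fit = fit_ols(X, y)
    press, _ = press_pred_r2(fit)
    A = X.to_numpy()
    explicit = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        D = np.column_stack([np.ones(keep.sum()), A[keep]])
        beta = np.linalg.lstsq(D, y[keep], rcond=None)[0]
        pred = np.concatenate([[1.0], A[i]]) @ beta
        explicit += (y[i] - pred) ** 2
    assert press == pytest.approx(explicit, abs=1e-8)


# ------------------------------------------------------------- criteria


def test_full_model_cp_is_p_plus_one(rng):
    X, y = _random_regression(rng, 60, 5, noise=1.0, support=["x0"], coefs=[1.0])
    fit = fit_ols(X, y)
    full_mse = fit["sse"] / (fit["n"] - fit["p"] - 1)
    cp, _, _ = info_criteria(fit["sse"], fit["n"], fit["p"], full_mse)
    assert cp == pytest.approx(fit["p"] + 1)


def test_bic_penalty_monotone_in_p():
    for n in (8, 20, 100):
        bics = [info_criteria(50.0, n, p, 1.0)[2] for p in range(1, 6)]
        assert np.all(np.diff(bics) > 0)


def test_criteria_shift_invariant_in_response(rng):
    X, y = _random_regression(rng, 70, 4, noise=1.0, support=["x1"], coefs=[2.0])
    t1 = best_subsets(X, y, 4)
    t2 = best_subsets(X, y + 100.0, 4)
    for a, b in zip(t1.models, t2.models):
        assert a.predictors == b.predictors
        assert a.r2 == pytest.approx(b.r2, abs=1e-9)
        assert a.aicc == pytest.approx(b.aicc, abs=1e-7)
        assert a.bic == pytest.approx(b.bic, abs=1e-7)


# ------------------------------------------------------------- best subsets


def test_planted_support_is_selected(rng):
    X, y = _random_regression(
        rng, 200, 6, noise=0.1, support=["x1", "x4"], coefs=[2.0, 3.0]
    )
    table = best_subsets(X, y, 6)
    assert set(table.selected.predictors) == {"x1", "x4"}


def test_selection_flag_marks_minimum_aicc(rng):
    X, y = _random_regression(rng, 100, 7, noise=1.0,
                              support=["x0", "x3"], coefs=[1.0, -2.0])
    table = best_subsets(X, y, 7)
    df = table.to_frame()
    assert df["selected"].sum() == 1
    finite = df["AICc"].dropna()
    assert df.loc[df["selected"], "AICc"].iloc[0] == pytest.approx(finite.min())


def test_combinatorial_guard(rng):
    X = pd.DataFrame(rng.standard_normal((50, 26)),
                     columns=[f"v{i:02d}" for i in range(26)])
    with pytest.raises(ValueError, match="prefilter"):
        best_subsets(X, rng.standard_normal(50), 5)


def test_selection_pipeline_is_pure(rng):
    X, y = _random_regression(rng, 80, 5, noise=0.5, support=["x2"], coefs=[1.5])
    a = best_subsets(X, y, 5).to_frame()
    b = best_subsets(X, y, 5).to_frame()
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------------- k-fold CV


def test_loo_identity(rng):
    X, y = _random_regression(rng, 30, 3, noise=0.6, support=["x0"], coefs=[1.0])
    fit = fit_ols(X, y)
    loo_resid = fit["residuals"] / (1.0 - fit["leverage"])
    cv = kfold_cv(X, y, list(X.columns), k=len(y), seed=0)
    assert np.abs((cv["predictions"] - y) + loo_resid).max() < 1e-8


def test_fold_sizes_differ_by_at_most_one(rng):
    for n, k in ((53, 10), (40, 7), (21, 2)):
        y = rng.standard_normal(n)
        X = pd.DataFrame({"x0": rng.standard_normal(n)})
        # reach into the partition through the prediction vector length only
        cv = kfold_cv(X, y, ["x0"], k=k, seed=1)
        assert len(cv["predictions"]) == n
        sizes = [len(f) for f in np.array_split(np.arange(n), k)]
        assert max(sizes) - min(sizes) <= 1


def test_cv_rmse_shows_optimism_gap(rng):
    """Out-of-fold RMSE is no better than training RMSE on average."""
    gaps = []
    for s in range(100):
        r = np.random.default_rng(s)
        X = pd.DataFrame(r.standard_normal((40, 4)),
                         columns=["x0", "x1", "x2", "x3"])
        y = X["x0"].to_numpy() + r.normal(0, 1.0, 40)
        fit = fit_ols(X, y)
        cv = kfold_cv(X, y, list(X.columns), k=10, seed=s)
        gaps.append(cv["rmse"] - fit["rmse"])
    assert np.mean(gaps) > 0


def test_cv_rejects_bad_k(rng):
    X, y = _random_regression(rng, 30, 2)
    with pytest.raises(ValueError):
        kfold_cv(X, y, list(X.columns), k=1)
    with pytest.raises(ValueError):
        kfold_cv(X, y, list(X.columns), k=31)
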