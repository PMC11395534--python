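"""BMLR selection, OLS statistics, leave-one-out q2, external validation."""
import numpy as np
import pandas as pd
import pytest

from pyrimqsar.bmlr import BMLR, fit_ols, prune_pool, q2_loo, r2_external


def _random_pool(n_rows, n_cols, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, n_cols))
    return pd.DataFrame(X, columns=[f"d{i:02d}" for i in range(n_cols)])


# -- prune_pool -------------------------------------------------------
def test_prune_removes_constant_and_missing():
    X = _random_pool(10, 3, 0)
    X["const"] = 1.0
    X["holes"] = [np.nan] + [1.0] * 9
    kept, removed = prune_pool(X)
    assert set(removed) == {"const", "holes"}
    assert list(kept.columns) == [f"d{i:02d}" for i in range(3)]


def test_prune_clean_pool_unchanged():
    X = _random_pool(10, 4, 1)
    kept, removed = prune_pool(X)
    assert removed == [] and kept.equals(X)


def test_prune_empty_pool_error():
    X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError):
        prune_pool(X)


# -- fit_ols ----------------------------------------------------------
def test_fit_ols_normal_equations_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 1))
    y = 2.0 + 3.0 * X[:, 0] + rng.normal(0, 0.3, 6)
    model, stats = fit_ols(X, y)
    Xc = np.hstack([np.ones((6, 1)), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    assert model.intercept == pytest.approx(beta[0], abs=1e-10)
    assert model.coefficients[0] == pytest.approx(beta[1], abs=1e-10)
    resid = y - Xc @ beta
    assert stats.s2 == pytest.approx(resid @ resid / (6 - 2), abs=1e-10)
    assert stats.N == 6 and stats.k == 1


def test_fit_ols_perfect_fit():
    X = _random_pool(12, 2, 2)
    y = 1.0 + X["d00"] - 2.0 * X["d01"]
    model, stats = fit_ols(X, y.to_numpy())
    assert stats.R2 == pytest.approx(1.0, abs=1e-10)
    assert model.coefficients == pytest.approx([1.0, -2.0], abs=1e-8)


def test_fit_ols_f_statistic_definition():
    X = _random_pool(20, 3, 3)
    y = X.to_numpy() @ [1.0, 0.5, -1.0] + np.random.default_rng(3).normal(0, 1, 20)
    _, stats = fit_ols(X, y)
    expect = (stats.R2 / 3) / ((1 - stats.R2) / (20 - 3 - 1))
    assert stats.F == pytest.approx(expect, abs=1e-10)


def test_fit_ols_rank_deficient():
    rng = np.random.default_rng(4)
    x = rng.normal(size=10)
    X = np.column_stack([x, 2.0 * x])
    with pytest.raises(np.linalg.LinAlgError):
        fit_ols(X, rng.normal(size=10))


# -- q2_loo -----------------------------------------------------------
def test_q2_shortcut_equals_explicit():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(25, 3))
    y = X @ [1.0, -0.5, 2.0] + rng.normal(0, 0.5, 25)
    assert q2_loo(X, y) == pytest.approx(q2_loo(X, y, explicit=True), abs=1e-10)


def test_q2_perfect_linear():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(15, 2))
    y = 3.0 + X @ [1.0, 2.0]
    assert q2_loo(X, y) == pytest.approx(1.0, abs=1e-10)


def test_q2_below_r2_on_noise():
    """q2 <= R2 for pure-noise responses in nearly all replicates."""
    rng = np.random.default_rng(8)
    wins = 0
    for _ in range(50):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        _, stats = fit_ols(X, y)
        if q2_loo(X, y) <= stats.R2:
            wins += 1
    assert wins >= 49


def test_q2_needs_enough_rows():
    with pytest.raises(ValueError):
        q2_loo(np.random.default_rng(0).normal(size=(4, 2)), np.zeros(4))


# -- r2_external ------------------------------------------------------
def test_r2_external_conventions():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(8, 2))
    y = 1.0 + X @ [2.0, -1.0]
    model, _ = fit_ols(X, y)
    assert r2_external(model, X, y) == pytest.approx(1.0, abs=1e-10)
    assert r2_external(model, X, y, convention="predictive") == pytest.approx(1.0, abs=1e-10)
    # linear transform of observations still gives 1.0 under correlation
    assert r2_external(model, X, 2.0 * y + 5.0) == pytest.approx(1.0, abs=1e-10)
    # ... but not under the predictive convention
    assert r2_external(model, X, 2.0 * y + 5.0, convention="predictive") < 1.0
    with pytest.raises(ValueError):
        r2_external(model, X, y, convention="banana")
    with pytest.raises(ValueError):
        r2_external(model, X[:2], y[:2])  # fewer than 3 test compounds
    constant_model, _ = fit_ols(X, y)
    constant_model.coefficients[:] = 0.0
    with pytest.raises(ValueError):
        r2_external(constant_model, X, y)  # zero-variance predictions


# -- BMLR selection ---------------------------------------------------
def test_bmlr_two_descriptor_pool_is_ols():
    rng = np.random.default_rng(10)
    X = _random_pool(20, 2, 10)
    y = 1.0 + X["d00"] - X["d01"] + rng.normal(0, 0.1, 20)
    res = BMLR(X, y, max_k=2).fit()
    _, stats = fit_ols(X, np.asarray(y, float))
    assert sorted(res.model.descriptor_names) == ["d00", "d01"]
    assert res.rsquared == pytest.approx(stats.R2, abs=1e-12)
    coefs = res.params.drop("intercept")
    assert coefs["d00"] == pytest.approx(1.0, abs=0.2)
    assert coefs["d01"] == pytest.approx(-1.0, abs=0.2)


def test_bmlr_collinear_never_coselected():
    rng = np.random.default_rng(11)
    X = _random_pool(40, 6, 11)
    X["twin"] = X["d00"] + rng.normal(0, 1e-3, 40)  # pairwise R2 ~ 1
    y = 2.0 * X["d00"] - 1.0 * X["d03"] + rng.normal(0, 0.2, 40)
    for k in (2, 3, 4):
        sel = set(BMLR(X, y, max_k=k).fit().model.descriptor_names)
        assert not {"d00", "twin"} <= sel


def test_bmlr_planted_pair_recovery():
    rng = np.random.default_rng(12)
    hits = 0
    for rep in range(20):
        X = _random_pool(40, 10, 100 + rep)
        y = 3.0 * X["d01"] - 2.0 * X["d05"] + rng.normal(0, 0.1, 40)
        sel = set(BMLR(X, y, max_k=2).fit().model.descriptor_names)
        hits += sel == {"d01", "d05"}
    assert hits >= 19


def test_bmlr_natural_scale_equals_normalized_fit():
    """Fitted values of the natural-scale report match an OLS on z-scores."""
    rng = np.random.default_rng(13)
    X = _random_pool(30, 8, 13)
    y = X["d02"] - 2 * X["d06"] + rng.normal(0, 0.3, 30)
    res = BMLR(X, y, max_k=3).fit()
    sub = X[list(res.model.descriptor_names)].to_numpy()
    Z = (sub - sub.mean(0)) / sub.std(0, ddof=1)
    Zc = np.hstack([np.ones((30, 1)), Z])
    beta = np.linalg.lstsq(Zc, np.asarray(y, float), rcond=None)[0]
    assert res.fittedvalues == pytest.approx(Zc @ beta, abs=1e-10)


def test_bmlr_results_accessors():
    rng = np.random.default_rng(14)
    X = _random_pool(30, 6, 14)
    y = 1.0 + 2.0 * X["d00"] - X["d04"] + rng.normal(0, 0.2, 30)
    res = BMLR(X, y, max_k=3).fit()
    assert res.params.index[0] == "intercept"
    assert len(res.tvalues) == len(res.params)
    assert 0.0 <= res.rsquared <= 1.0
    assert res.q2 <= res.rsquared + 1e-12
    assert res.resid == pytest.approx(np.asarray(y) - res.fittedvalues)
    assert "BMLR" in res.summary() and "R2" in res.summary()
    # external validation records the convention
    r2t = res.validate_external(X, y)
    assert res.stats.R2_test == r2t and res.stats.r2_test_convention == "correlation"
    rep = res.ad_report()
    assert len(rep.leverage) == 30 and rep.h_star > 0


def test_bmlr_from_dataframe_and_validation():
    X = _random_pool(25, 4, 15)
    X["pic50"] = X["d00"] + np.random.default_rng(15).normal(0, 0.2, 25)
    res = BMLR.from_dataframe(X, max_k=2).fit()
    assert "d00" in res.model.descriptor_names
    with pytest.raises(ValueError):
        BMLR(_random_pool(6, 3, 0), np.zeros(6), max_k=5)  # N too small
    with pytest.raises(ValueError):
        BMLR(_random_pool(20, 3, 0), np.zeros(20), max_k=1)  # max_k < 2
    with pytest.raises(ValueError):
        BMLR(_random_pool(20, 3, 0), np.zeros(10))  # length mismatch


def test_bmlr_all_pairs_collinear_error():
    rng = np.random.default_rng(16)
    base = rng.normal(size=20)
    X = pd.DataFrame({f"c{i}": base + rng.normal(0, 1e-6, 20) for i in range(3)})
    with pytest.raises(ValueError):
        BMLR(X, rng.normal(size=20), max_k=2).fit()
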