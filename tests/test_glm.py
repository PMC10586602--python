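"""Tests of the model-fitting engine against closed forms and independent
oracles (direct likelihood maximization, statsmodels, hand arithmetic)."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

import musselpatch as mp
from musselpatch.glm import (
    LogLinearModel,
    QuasiBinomialLogit,
    RankDeficientError,
    build_design,
    holm_adjust,
    robust_se,
)


def small_fixture(seed=5, n=15):
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 2, n)
    x2 = rng.uniform(-1, 1, n)
    w = rng.uniform(20, 60, n)
    p = expit(0.3 + 0.8 * x1 - 1.1 * x2)
    y = np.clip(p + rng.normal(0, 0.08, n), 0.02, 0.98)
    X = np.column_stack([np.ones(n), x1, x2])
    return y * w, (1 - y) * w, X


# ------------------------------------------------------------------ #
# quasi-binomial GLM
# ------------------------------------------------------------------ #

def test_intercept_only_closed_form():
    succ = np.full(12, 0.8 * 40)
    fail = np.full(12, 0.2 * 40)
    fit = QuasiBinomialLogit(succ, fail, np.ones((12, 1)), ["(Intercept)"]).fit()
    assert fit.params.iloc[0] == pytest.approx(logit(0.8), abs=1e-10)
    assert fit.converged


def test_irls_matches_direct_likelihood_maximization():
    succ, fail, X = small_fixture()
    fit = QuasiBinomialLogit(succ, fail, X).fit()

    def nll(b):
        mu = np.clip(expit(X @ b), 1e-12, 1 - 1e-12)
        return -(succ * np.log(mu) + fail * np.log(1 - mu)).sum()

    opt = minimize(nll, np.zeros(3), method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
    assert np.max(np.abs(fit.params.to_numpy() - opt.x)) < 1e-6


def test_irls_matches_statsmodels_coefficients():
    sm = pytest.importorskip("statsmodels.api")
    succ, fail, X = small_fixture()
    fit = QuasiBinomialLogit(succ, fail, X).fit()
    ref = sm.GLM(np.column_stack([succ, fail]), X,
                 family=sm.families.Binomial()).fit()
    assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-8)


def test_pure_binomial_dispersion_near_one():
    rng = np.random.default_rng(3)
    n = 2000
    x = rng.uniform(-1, 1, n)
    w = np.full(n, 50)
    p = expit(0.5 + 0.7 * x)
    succ = rng.binomial(50, p).astype(float)
    fit = QuasiBinomialLogit(succ, w - succ,
                             np.column_stack([np.ones(n), x])).fit()
    assert fit.dispersion == pytest.approx(1.0, rel=0.10)


def test_count_scaling_invariance():
    """Scaling all counts by c leaves coefficients unchanged and scales phi by c."""
    succ, fail, X = small_fixture()
    base = QuasiBinomialLogit(succ, fail, X).fit()
    scaled = QuasiBinomialLogit(3.0 * succ, 3.0 * fail, X).fit()
    assert np.allclose(base.params.to_numpy(), scaled.params.to_numpy(), atol=1e-8)
    assert scaled.dispersion == pytest.approx(3.0 * base.dispersion, rel=1e-6)


def test_dispersion_recovers_betabinomial_target():
    """phi-hat -> 1 + (N-1)rho on beta-binomial data with common N."""
    from musselpatch.synthetic import draw_betabinomial
    rng = np.random.default_rng(9)
    n_cages, N, rho = 10_000, 200, 0.05
    x = rng.uniform(-1, 1, n_cages)
    p = expit(0.3 + 0.5 * x)
    fails = np.array([draw_betabinomial(rng, N, 1 - pi, rho) for pi in p])
    fit = QuasiBinomialLogit(N - fails.astype(float), fails.astype(float),
                             np.column_stack([np.ones(n_cages), x])).fit()
    assert fit.dispersion == pytest.approx(1 + (N - 1) * rho, rel=0.10)


def test_rank_deficiency_names_collinear_terms():
    n = 20
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(RankDeficientError, match="dup"):
        QuasiBinomialLogit(np.full(n, 5.0), np.full(n, 5.0), X,
                           ["(Intercept)", "x", "dup"])


def test_holm_column_properties_on_fit(cages_default):
    from musselpatch.metrics import derive_survival_columns
    df = derive_survival_columns(cages_default)
    fit = QuasiBinomialLogit.from_dataframe(
        df, ["D0", "temp_C", "chl_ug_l", "turb_FTU"],
        [("temp_C", "chl_ug_l"), ("temp_C", "turb_FTU"),
         ("chl_ug_l", "turb_FTU")]).fit()
    p, ph = fit.pvalues.to_numpy(), fit.pvalues_holm.to_numpy()
    assert (ph >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(ph[order]) >= -1e-15).all()
    assert "dispersion" in fit.summary()


# ------------------------------------------------------------------ #
# log-linear models and sandwich covariance
# ------------------------------------------------------------------ #

def test_loglinear_exact_recovery():
    x = np.linspace(0.5, 4, 30)
    y = np.exp(0.8 - 0.3 * x)
    fit = LogLinearModel(y, np.column_stack([np.ones(30), x])).fit(cov_type="model")
    assert fit.params.iloc[0] == pytest.approx(0.8, abs=1e-12)
    assert fit.params.iloc[1] == pytest.approx(-0.3, abs=1e-12)


def test_duplicating_rows_shrinks_model_se():
    rng = np.random.default_rng(0)
    n, k = 40, 2
    x = rng.uniform(0, 3, n)
    y = np.exp(1 + 0.5 * x + rng.normal(0, 0.2, n))
    X = np.column_stack([np.ones(n), x])
    base = LogLinearModel(y, X).fit(cov_type="model")
    dup = LogLinearModel(np.concatenate([y, y]), np.vstack([X, X])).fit(cov_type="model")
    assert np.allclose(dup.params.to_numpy(), base.params.to_numpy(), atol=1e-12)
    # exact factor: sqrt((n-k)/(2n-k)); ~1/sqrt(2) for large n
    factor = np.sqrt((n - k) / (2 * n - k))
    assert np.allclose(dup.bse.to_numpy(), base.bse.to_numpy() * factor, rtol=1e-10)
    assert factor == pytest.approx(1 / np.sqrt(2), rel=0.02)


def test_nonpositive_response_rejected():
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    with pytest.raises(ValueError, match="2"):
        LogLinearModel([1.0, 2.0, 0.0, 3.0], X)


def test_hc0_matches_hand_computed_sandwich():
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
    y = np.exp(np.array([0.1, 1.4, 1.9]))
    fit = LogLinearModel(y, X).fit(cov_type="HC0")
    e = np.log(y) - X @ fit.params.to_numpy()
    bread = np.linalg.inv(X.T @ X)
    meat = sum(np.outer(X[i], X[i]) * e[i] ** 2 for i in range(3))
    expected = bread @ meat @ bread
    assert np.allclose(fit.cov_robust.to_numpy(), expected, atol=1e-14)


def test_hc3_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    n = 50
    x = rng.uniform(0, 3, n)
    y = np.exp(1 + 0.4 * x + rng.normal(0, 0.1 * (1 + x), n))
    X = np.column_stack([np.ones(n), x])
    fit = LogLinearModel(y, X).fit(cov_type="HC3")
    ref = sm.OLS(np.log(y), X).fit(cov_type="HC3")
    assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-12)
    assert np.allclose(fit.bse.to_numpy(), ref.bse, atol=1e-12)


def test_robust_close_to_model_when_homoskedastic():
    rng = np.random.default_rng(4)
    n = 4000
    x = rng.uniform(0, 3, n)
    y = np.exp(1 + 0.4 * x + rng.normal(0, 0.3, n))
    fit = LogLinearModel(y, np.column_stack([np.ones(n), x])).fit(cov_type="HC3")
    assert np.allclose(fit.bse.to_numpy(), fit.bse_model.to_numpy(), rtol=0.10)


def test_robust_coverage_under_heteroskedasticity():
    """SD of ln response proportional to x: HC3 intervals keep ~95% coverage
    of the true slope while model-based intervals undercover."""
    rng = np.random.default_rng(42)
    n, reps, b_true = 80, 2000, 0.4
    cov_robust = cov_model = 0
    for _ in range(reps):
        x = rng.uniform(0.2, 3.0, n) ** 2
        y = np.exp(1.0 + b_true * x + rng.normal(0, 0.5 * x))
        fit = LogLinearModel(y, np.column_stack([np.ones(n), x])).fit(cov_type="HC3")
        q = stats.t.ppf(0.975, fit.df_resid)
        err = abs(fit.params.iloc[1] - b_true)
        cov_robust += err <= q * fit.bse.iloc[1]
        cov_model += err <= q * fit.bse_model.iloc[1]
    assert 0.93 <= cov_robust / reps <= 0.97
    assert cov_model / reps < 0.90


def test_hc3_rejects_leverage_one():
    X = np.column_stack([np.ones(3), [0.0, 0.0, 5.0]])  # third row has h = 1
    y = np.exp([0.3, 0.5, 2.0])
    fit = LogLinearModel(y, X).fit(cov_type="model")
    with pytest.raises(ValueError, match="leverage"):
        robust_se(fit, "HC3")


def test_condition_model_parameter_recovery(default_config, env_default):
    """Refitting the condition model on generated data recovers the density
    coefficient within 3 SEs (n = 2100 cages, log-scale noise 0.2)."""
    cfg = dataclasses.replace(default_config, replicates=30, ci_log_sd=0.2).validate()
    cages = mp.gen_cage_experiment(cfg, env_default, seed=30)
    cages["condition_index"] = mp.gen_condition(cfg, cages, seed=31)
    dirs = cages["temp_direction"].astype(str)
    cages["TempDir-"] = (dirs == "-").astype(float)
    cages["TempDir+"] = (dirs == "+").astype(float)
    fit = LogLinearModel.from_dataframe(
        cages, "condition_index",
        ["D0", "TempDir-", "TempDir+", "chl_ug_l", "turb_FTU"]).fit(cov_type="HC3")
    true_d0 = dict(zip(mp.config.CI_TERMS, cfg.ci_coeffs))["D0"]
    assert abs(fit.params["D0"] - true_d0) < 3 * fit.bse["D0"]


# ------------------------------------------------------------------ #
# Holm adjustment
# ------------------------------------------------------------------ #

def test_holm_worked_example():
    assert np.allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])


def test_holm_edge_cases():
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])


def test_holm_matches_statsmodels():
    multipletests = pytest.importorskip(
        "statsmodels.stats.multitest").multipletests
    rng = np.random.default_rng(6)
    p = rng.uniform(0, 1, 25)
    assert np.allclose(holm_adjust(p), multipletests(p, method="holm")[1])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_holm_properties(p):
    adj = holm_adjust(p)
    m = len(p)
    assert ((0 <= adj) & (adj <= 1)).all()
    assert (adj >= np.asarray(p) - 1e-15).all()          # never smaller than raw
    assert (adj <= np.minimum(1, m * np.asarray(p)) + 1e-12).all()  # dominates Bonferroni
    order = np.argsort(np.asarray(p), kind="stable")
    assert (np.diff(adj[order]) >= -1e-15).all()          # monotone in raw order
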