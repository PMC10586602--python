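"""Model fitting and inference for the three cage-experiment models.

Implemented from first principles (numpy/scipy only):

* :class:`QuasiBinomialLogit` — quasi-binomial GLM with logit link fitted by
  iteratively reweighted least squares on possibly non-integer
  success/failure counts; Pearson-based dispersion; t-reference p-values.
* :class:`LogLinearModel` — OLS on the log of a positive ratio response,
  with model-based and heteroskedasticity-consistent (HC0–HC3 sandwich)
  covariances.
* :func:`holm_adjust` — step-down Holm family-wise correction, applied
  per model across that model's coefficient tests.

The quasi-binomial score equations coincide with the binomial ones, so the
IRLS point estimates equal binomial ML estimates; only the covariance is
inflated by the Pearson dispersion

    phi = sum_i  n_i (y_i - mu_i)^2 / (mu_i (1 - mu_i))  /  (n - p).

Standard errors are model SEs scaled by sqrt(phi) and p-values use a
t reference on the residual degrees of freedom (the convention of R's
``glm(..., family = quasibinomial)`` summary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full rank."""


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        _, _, v = np.linalg.svd(X)
        null = np.abs(v[-1])
        involved = [n for n, w in zip(names, null) if w > 0.1 * null.max()]
        raise RankDeficientError(f"collinear terms: {involved}")


def build_design(df: pd.DataFrame, terms: Sequence[str],
                 interactions: Sequence = ()) -> tuple:
    """Design matrix with intercept, main effects and pairwise interactions.

    ``terms`` name numeric columns of ``df``; ``interactions`` is a sequence
    of (a, b) column pairs.  Returns (X, names).
    """
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in terms:
        cols.append(df[t].to_numpy(dtype=float))
        names.append(t)
    for a, b in interactions:
        cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, order restored to the input.

    Sorted ascending, p_(i) is multiplied by (m - i), a running maximum is
    enforced, and values are capped at 1.  Dominates Bonferroni and controls
    the family-wise error rate.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _summary_table(names, params, bse, tvals, pvals, p_holm) -> pd.DataFrame:
    return pd.DataFrame({
        "Term": list(names),
        "Estimate": params,
        "Std. error": bse,
        "t value": tvals,
        "p.value": pvals,
        "p.holm": p_holm,
    })


# ---------------------------------------------------------------------- #
# quasi-binomial GLM
# ---------------------------------------------------------------------- #

@dataclass
class QuasiBinomialResults:
    """Fit of a quasi-binomial logit GLM."""

    model: "QuasiBinomialLogit"
    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float
    df_resid: int
    converged: bool
    n_iter: int
    fittedvalues: np.ndarray = field(repr=False, default=None)

    @property
    def exog_names(self):
        return list(self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df_resid),
            index=self.params.index,
        )

    @property
    def pvalues_holm(self) -> pd.Series:
        return pd.Series(holm_adjust(self.pvalues.to_numpy()), index=self.params.index)

    @property
    def pearson_residuals(self) -> np.ndarray:
        m = self.model
        mu = self.fittedvalues
        return (m.y - mu) * np.sqrt(m.n_weights / (mu * (1 - mu)))

    @property
    def deviance_residuals(self) -> np.ndarray:
        m = self.model
        mu = self.fittedvalues
        y = m.y
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        dev = 2 * m.n_weights * (t1 + t2)
        return np.sign(y - mu) * np.sqrt(np.clip(dev, 0, None))

    def predict(self, exog: np.ndarray) -> np.ndarray:
        return expit(np.asarray(exog, float) @ self.params.to_numpy())

    def summary(self) -> str:
        tab = _summary_table(self.exog_names, self.params.to_numpy(),
                             self.bse.to_numpy(), self.tvalues.to_numpy(),
                             self.pvalues.to_numpy(), self.pvalues_holm.to_numpy())
        lines = [
            "Quasi-binomial GLM (logit link)",
            f"  n = {len(self.model.y)}, df_resid = {self.df_resid}, "
            f"dispersion = {self.dispersion:.4g}, "
            f"converged = {self.converged} ({self.n_iter} iterations)",
            tab.to_string(index=False, float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        tab = _summary_table(self.exog_names, self.params.to_numpy(),
                             self.bse.to_numpy(), self.tvalues.to_numpy(),
                             self.pvalues.to_numpy(), self.pvalues_holm.to_numpy())
        return tab


class QuasiBinomialLogit:
    """Quasi-binomial GLM with logit link on (possibly non-integer) counts.

    Parameters
    ----------
    successes, failures : array-like of non-negative reals
        Per-row standardized binomial counts; their sum is the prior weight.
    exog : 2-D array
        Design matrix including the intercept column.
    exog_names : sequence of str, optional
    """

    def __init__(self, successes, failures, exog, exog_names=None):
        successes = np.asarray(successes, dtype=float)
        failures = np.asarray(failures, dtype=float)
        if np.any(successes < 0) or np.any(failures < 0):
            raise ValueError("successes and failures must be non-negative")
        n = successes + failures
        if np.any(n <= 0):
            raise ValueError("successes + failures must be positive in every row")
        self.successes = successes
        self.failures = failures
        self.n_weights = n
        self.y = successes / n
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != successes.size:
            raise ValueError("exog must be (nobs, k)")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{i}" for i in range(self.exog.shape[1])])
        _check_full_rank(self.exog, self.exog_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, terms: Sequence[str],
                       interactions: Sequence = (),
                       successes: str = "successes",
                       failures: str = "failures") -> "QuasiBinomialLogit":
        X, names = build_design(df, terms, interactions)
        return cls(df[successes].to_numpy(float), df[failures].to_numpy(float),
                   X, names)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> QuasiBinomialResults:
        """IRLS with logit link; converges when max |delta beta| < tol."""
        X, y, n = self.exog, self.y, self.n_weights
        nobs, k = X.shape
        # starting values: WLS on the link-transformed adjusted response
        mu = (self.successes + 0.5) / (n + 1.0)
        eta = logit(mu)
        beta = np.zeros(k)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            mu = expit(eta)
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = n * mu * (1 - mu)
            z = eta + (y - mu) / (mu * (1 - mu))
            WX = X * w[:, None]
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            step = np.max(np.abs(beta_new - beta)) if it > 1 else np.inf
            beta = beta_new
            eta = X @ beta
            if step < tol:
                converged = True
                break
        if not converged:
            import warnings
            warnings.warn("IRLS did not converge", RuntimeWarning, stacklevel=2)
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        df_resid = nobs - k
        pearson = np.sum(n * (y - mu) ** 2 / (mu * (1 - mu)))
        dispersion = pearson / df_resid if df_resid > 0 else np.nan
        w = n * mu * (1 - mu)
        cov = dispersion * np.linalg.inv(X.T @ (X * w[:, None]))
        return QuasiBinomialResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            dispersion=float(dispersion),
            df_resid=df_resid,
            converged=converged,
            n_iter=it,
            fittedvalues=mu,
        )


# ---------------------------------------------------------------------- #
# log-linear ratio models
# ---------------------------------------------------------------------- #

_HC_VARIANTS = ("HC0", "HC1", "HC2", "HC3")


@dataclass
class LogLinearResults:
    """OLS fit of a log-transformed ratio response.

    Carries both the model-based covariance and, when requested, the
    heteroskedasticity-consistent sandwich covariance; ``pvalues`` follow
    whichever covariance is active (``cov_type``).
    """

    model: "LogLinearModel"
    params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: Optional[pd.DataFrame]
    cov_type: str          # "model" or an HC variant
    sigma2: float
    df_resid: int
    resid: np.ndarray = field(repr=False, default=None)

    @property
    def exog_names(self):
        return list(self.params.index)

    @property
    def _active_cov(self) -> pd.DataFrame:
        return self.cov_robust if self.cov_robust is not None else self.cov_model

    @property
    def bse_model(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_model.to_numpy())),
                         index=self.params.index)

    @property
    def bse_robust(self) -> Optional[pd.Series]:
        if self.cov_robust is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov_robust.to_numpy())),
                         index=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._active_cov.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df_resid),
            index=self.params.index,
        )

    @property
    def pvalues_holm(self) -> pd.Series:
        return pd.Series(holm_adjust(self.pvalues.to_numpy()), index=self.params.index)

    @property
    def pearson_residuals(self) -> np.ndarray:
        return self.resid / np.sqrt(self.sigma2)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Prediction on the log scale."""
        return np.asarray(exog, float) @ self.params.to_numpy()

    def summary(self) -> str:
        tab = self.coef_table()
        lines = [
            f"Log-linear model (OLS on ln response), cov_type = {self.cov_type}",
            f"  n = {self.df_resid + len(self.params)}, df_resid = {self.df_resid}, "
            f"residual SD = {np.sqrt(self.sigma2):.4g}",
            tab.to_string(index=False, float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        return _summary_table(self.exog_names, self.params.to_numpy(),
                              self.bse.to_numpy(), self.tvalues.to_numpy(),
                              self.pvalues.to_numpy(), self.pvalues_holm.to_numpy())


class LogLinearModel:
    """Linear model for a positive ratio response, fitted on its log.

    Used for the perimeter-to-area and condition-index models; ratio
    responses are heteroskedastic on the natural scale, so inference
    defaults to HC3 sandwich standard errors.
    """

    def __init__(self, response, exog, exog_names=None):
        response = np.asarray(response, dtype=float)
        if np.any(response <= 0) or np.any(~np.isfinite(response)):
            bad = np.where((response <= 0) | ~np.isfinite(response))[0]
            raise ValueError(f"response must be positive; offending rows: {bad.tolist()}")
        self.response = response
        self.logy = np.log(response)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != response.size:
            raise ValueError("exog must be (nobs, k)")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{i}" for i in range(self.exog.shape[1])])
        _check_full_rank(self.exog, self.exog_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       terms: Sequence[str]) -> "LogLinearModel":
        # interactions deliberately unsupported here: in these ratio models
        # they are collinear with the main effects (7 distinct covariate
        # points per year), so the design restricts them to the survival GLM
        X, names = build_design(df, terms)
        return cls(df[response].to_numpy(float), X, names)

    def fit(self, cov_type: str = "HC3") -> LogLinearResults:
        """OLS; ``cov_type`` is "model" or one of HC0–HC3 (default HC3)."""
        X, y = self.exog, self.logy
        nobs, k = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df_resid = nobs - k
        sigma2 = float(resid @ resid / df_resid)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov_model = sigma2 * xtx_inv
        res = LogLinearResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_model=pd.DataFrame(cov_model, index=self.exog_names,
                                   columns=self.exog_names),
            cov_robust=None,
            cov_type="model",
            sigma2=sigma2,
            df_resid=df_resid,
            resid=resid,
        )
        if cov_type != "model":
            res = robust_se(res, variant=cov_type)
        return res


def robust_se(fit: LogLinearResults, variant: str = "HC3") -> LogLinearResults:
    """Attach a sandwich (bread @ meat @ bread) covariance to an OLS fit.

    HC0 uses squared residuals as-is; HC1 applies the n/(n-k) small-sample
    factor; HC2 and HC3 divide by (1-h) and (1-h)^2 where h is leverage.
    p-values are recomputed from the robust covariance.
    """
    if variant not in _HC_VARIANTS:
        raise ValueError(f"variant must be one of {_HC_VARIANTS}")
    X = fit.model.exog
    e = fit.resid
    nobs, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    if variant == "HC0":
        omega = e ** 2
    elif variant == "HC1":
        omega = e ** 2 * nobs / (nobs - k)
    else:
        if np.any(h >= 1 - 1e-12):
            raise ValueError(f"{variant} undefined: leverage 1 row(s) present")
        omega = e ** 2 / (1 - h) if variant == "HC2" else e ** 2 / (1 - h) ** 2
    meat = X.T @ (X * omega[:, None])
    cov = xtx_inv @ meat @ xtx_inv
    return LogLinearResults(
        model=fit.model,
        params=fit.params,
        cov_model=fit.cov_model,
        cov_robust=pd.DataFrame(cov, index=fit.params.index, columns=fit.params.index),
        cov_type=variant,
        sigma2=fit.sigma2,
        df_resid=fit.df_resid,
        resid=fit.resid,
    )
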