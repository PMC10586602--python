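"""Per-run log-log slope statistics for density dependence.

For each experimental run the strength and sign of the density effect is
summarized by the slope M of a log-log regression pooled over all cages of
the run (10 densities x 3 replicates):

* survival:   ln(end density)   ~ M * ln(start density) + b, neutral at M = 1
  (proportional attrition: if the same fraction survives at every density,
  end density is proportional to start density and M = 1 exactly);
* condition:  ln(condition idx) ~ M * ln(start density) + b, neutral at M = 0.

M above the neutral value indicates facilitation (cooperation): performance
improves with density.  M below it indicates competition.  Classification
uses a two-sided t-test of M against the neutral value at a configurable
alpha.  Ordering the per-run slopes by start date gives the seasonal
profile; its concavity (quadratic coefficient of M against run order) is the
operational "bell shape" indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SlopeEstimate:
    """One run's log-log density-dependence slope."""

    run_id: str
    M: float
    b: float
    se_M: float
    n: int
    threshold: float                 # neutral value: 1 (survival) or 0 (CI)
    classification: str              # cooperative | competitive | neutral | unavailable
    p_vs_threshold: float
    available: bool = True

    @classmethod
    def unavailable(cls, run_id: str, threshold: float) -> "SlopeEstimate":
        return cls(run_id=run_id, M=np.nan, b=np.nan, se_M=np.nan, n=0,
                   threshold=threshold, classification="unavailable",
                   p_vs_threshold=np.nan, available=False)


def _loglog_slope(run_id: str, x, y, threshold: float, alpha: float) -> SlopeEstimate:
    x = np.log(np.asarray(x, dtype=float))
    y = np.log(np.asarray(y, dtype=float))
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    b, M = beta
    resid = y - X @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se_M = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    exact = se_M <= 1e-10 * max(1.0, abs(M))  # numerically noiseless fit
    if not exact and df > 0:
        t = (M - threshold) / se_M
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        # noiseless data: the slope is exact, any real deviation is certain
        p = 1.0 if np.isclose(M, threshold, atol=1e-10) else 0.0
    if p < alpha:
        classification = "cooperative" if M > threshold else "competitive"
    else:
        classification = "neutral"
    return SlopeEstimate(run_id=run_id, M=float(M), b=float(b), se_M=se_M,
                         n=n, threshold=threshold, classification=classification,
                         p_vs_threshold=p)


def survival_slope(run_records: pd.DataFrame, alpha: float = 0.05) -> SlopeEstimate:
    """M_survival for one run: ln(D1) on ln(D0), neutral threshold 1.

    Cages with zero end density are excluded (their log is undefined) with a
    warning; at least 3 usable cages are required.
    """
    run_id = str(run_records["run_id"].iloc[0]) if len(run_records) else "?"
    d0 = run_records["D0"].to_numpy(float)
    d1 = run_records["D1"].to_numpy(float)
    keep = (d0 > 0) & (d1 > 0)
    if np.count_nonzero(~keep):
        warnings.warn(
            f"run {run_id}: excluded {np.count_nonzero(~keep)} cage(s) with zero "
            "end density from the log-log fit", stacklevel=2)
    if np.count_nonzero(keep) < 3:
        raise ValueError(f"run {run_id}: need >= 3 cages with positive densities")
    return _loglog_slope(run_id, d0[keep], d1[keep], threshold=1.0, alpha=alpha)


def ci_slope(run_records: pd.DataFrame, alpha: float = 0.05,
             ci_column: str = "condition_index") -> SlopeEstimate:
    """M_CI for one run: ln(CI) on ln(D0), neutral threshold 0.

    A run without usable condition data (missing column or fewer than 3
    positive values) yields an "unavailable" estimate rather than an error.
    """
    run_id = str(run_records["run_id"].iloc[0]) if len(run_records) else "?"
    if ci_column not in run_records.columns:
        return SlopeEstimate.unavailable(run_id, threshold=0.0)
    ci = run_records[ci_column].to_numpy(float)
    d0 = run_records["D0"].to_numpy(float)
    keep = np.isfinite(ci) & (ci > 0) & (d0 > 0)
    if np.count_nonzero(keep) < 3:
        return SlopeEstimate.unavailable(run_id, threshold=0.0)
    return _loglog_slope(run_id, d0[keep], ci[keep], threshold=0.0, alpha=alpha)


@dataclass
class SeasonalProfile:
    """Per-run slopes in seasonal order plus a bell-shape indicator."""

    table: pd.DataFrame              # run_id, start_day, M, se_M, classification
    concavity: float                 # quadratic coefficient of M vs run order
    concavity_se: float
    peak_run_id: Optional[str]       # run with the largest slope

    @property
    def is_bell_shaped(self) -> bool:
        """Concave profile (negative quadratic coefficient)."""
        return self.concavity < 0


def seasonal_profile(slopes: Sequence[SlopeEstimate],
                     run_designs: Sequence) -> SeasonalProfile:
    """Order per-run slopes by start date and quantify the seasonal shape.

    The concavity indicator is the quadratic coefficient of an OLS fit of M
    against run order (0, 1, 2, ...); a negative value with a small SE
    indicates the bell-shaped summer peak.
    """
    ids = [r.run_id for r in run_designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate run ids in run_designs")
    if len(slopes) < 3:
        raise ValueError("need at least 3 runs for a seasonal profile")
    start = {r.run_id: r.start_day for r in run_designs}
    missing = [s.run_id for s in slopes if s.run_id not in start]
    if missing:
        raise ValueError(f"slopes for unknown runs: {missing}")
    ordered = sorted(slopes, key=lambda s: start[s.run_id])
    tab = pd.DataFrame({
        "run_id": [s.run_id for s in ordered],
        "start_day": [start[s.run_id] for s in ordered],
        "M": [s.M for s in ordered],
        "se_M": [s.se_M for s in ordered],
        "n": [s.n for s in ordered],
        "threshold": [s.threshold for s in ordered],
        "classification": [s.classification for s in ordered],
        "p_vs_threshold": [s.p_vs_threshold for s in ordered],
    })
    usable = tab[np.isfinite(tab["M"])]
    if len(usable) >= 3:
        i = np.arange(len(usable), dtype=float)
        X = np.column_stack([np.ones_like(i), i, i ** 2])
        m = usable["M"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, m, rcond=None)
        resid = m - X @ beta
        df = len(usable) - 3
        if df > 0:
            sigma2 = float(resid @ resid) / df
            se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[2, 2]))
        else:
            se = np.nan
        concavity, conc_se = float(beta[2]), se
        peak = str(usable.iloc[int(np.argmax(m))]["run_id"])
    else:
        concavity, conc_se, peak = np.nan, np.nan, None
    return SeasonalProfile(table=tab, concavity=concavity,
                           concavity_se=conc_se, peak_run_id=peak)
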