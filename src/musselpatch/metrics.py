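"""Per-cage derived quantities.

Implements the field calculations of the cage experiment: translating seeded
biomass into individual counts, the bivalve condition index, the survival
proportion with its estimation-error clamp, the constant-death-rate
standardization of survival onto a common horizon, and the categorical
temperature-direction label.

The standardization converts each cage's outcome into non-integer binomial
"failures" and "successes" on a common 22-day horizon:

    daily death rate = (N0 - N1) / days
    failures         = daily death rate * 22
    successes        = N0 - failures
    p                = successes / N0

Runs differ slightly in duration, so modelling raw survival proportions would
conflate duration with treatment; the standardization removes that, at the
price of non-integer counts (which the quasi-binomial fit accepts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Common horizon (days) onto which all cage outcomes are standardized.
DEFAULT_HORIZON_DAYS = 22.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def count_per_plot(density_kg_m2: float, mean_individual_weight_g: float,
                   plot_area_m2: float) -> int:
    """Number of mussels seeded on a plot of given area at a biomass density.

    Round-to-nearest, matching the study design counts (e.g. 155.7 -> 156).
    """
    if density_kg_m2 <= 0:
        raise ValueError("density_kg_m2 must be > 0")
    if mean_individual_weight_g <= 0:
        raise ValueError("mean_individual_weight_g must be > 0")
    if plot_area_m2 <= 0:
        raise ValueError("plot_area_m2 must be > 0")
    return _round_half_up(density_kg_m2 * plot_area_m2 * 1000.0 / mean_individual_weight_g)


def count_per_plot_from_density(individuals_m2: float, plot_area_m2: float) -> int:
    """Plot count from a numeric density (individuals per square metre)."""
    if individuals_m2 <= 0:
        raise ValueError("individuals_m2 must be > 0")
    if plot_area_m2 <= 0:
        raise ValueError("plot_area_m2 must be > 0")
    return _round_half_up(individuals_m2 * plot_area_m2)


def condition_index(afdw_mg, shell_length_cm):
    """Condition index CI = AFDW / L^3 (mg cm^-3).

    Ash-free dry weight per cubic shell length; an instantaneous proxy for
    growth/fitness.  Accepts scalars or arrays; all inputs must be positive.
    """
    afdw = np.asarray(afdw_mg, dtype=float)
    length = np.asarray(shell_length_cm, dtype=float)
    if np.any(afdw <= 0) or np.any(length <= 0):
        raise ValueError("afdw_mg and shell_length_cm must be > 0")
    out = afdw / length ** 3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SubsampleSummary:
    """Summary of a homogenized subsample measured per cage."""

    n_individuals: int
    mean_wet_weight_g: float
    mean_shell_length_cm: float
    mean_afdw_mg: float

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("mean_wet_weight_g", "mean_shell_length_cm", "mean_afdw_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def condition_index(self) -> float:
        """CI = AFDW / L^3 of the subsample means (mg cm^-3)."""
        return condition_index(self.mean_afdw_mg, self.mean_shell_length_cm)


@dataclass(frozen=True)
class SurvivalProportion:
    p: float
    n1_clamped: int
    clamped: bool


def survival_proportion(n0: int, n1: int) -> SurvivalProportion:
    """Proportion surviving, N1/N0, with the estimation-error clamp.

    End counts occasionally exceed start counts (recounting error; there is
    no recruitment inside the cages), in which case N1 is replaced by N0 and
    the record flagged.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if n1 < 0:
        raise ValueError("n1 must be >= 0")
    clamped = n1 > n0
    n1c = min(n1, n0)
    return SurvivalProportion(p=n1c / n0, n1_clamped=n1c, clamped=clamped)


@dataclass(frozen=True)
class StandardizedSurvival:
    """Duration-standardized binomial outcome of one cage."""

    daily_death_rate: float
    binomial_failures: float
    binomial_successes: float
    p: float
    clipped: bool = False  # failures exceeded N0 and were clipped

    @property
    def n0(self) -> float:
        return self.binomial_failures + self.binomial_successes


def standardize_survival(n0: int, n1: int, duration_days: float,
                         horizon_days: float = DEFAULT_HORIZON_DAYS) -> StandardizedSurvival:
    """Standardize a cage outcome onto a common horizon (default 22 days).

    Assumes a constant daily death rate within the run.  ``n1`` must already
    be clamped to ``n0`` (apply :func:`survival_proportion` first); failures
    are left non-integer.  If heavy mortality over a short run implies more
    failures than individuals, failures are clipped to N0 and flagged.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    if n1 > n0:
        raise ValueError("n1 must be <= n0; clamp with survival_proportion first")
    if n1 < 0:
        raise ValueError("n1 must be >= 0")
    rate = (n0 - n1) / duration_days
    failures = rate * horizon_days
    clipped = failures > n0
    if clipped:
        failures = float(n0)
    successes = n0 - failures
    return StandardizedSurvival(
        daily_death_rate=rate,
        binomial_failures=failures,
        binomial_successes=successes,
        p=successes / n0,
        clipped=clipped,
    )


def derive_survival_columns(cages: pd.DataFrame,
                            horizon_days: float = DEFAULT_HORIZON_DAYS) -> pd.DataFrame:
    """Add clamped and standardized survival columns to a cage table.

    Returns a copy with columns ``N1_clamped, clamp_flag, p_survival,
    daily_death_rate, failures, successes, p, clip_flag`` appended.  The
    input frame is not mutated.
    """
    out = cages.copy()
    rows = []
    for n0, n1, days in zip(out["N0"], out["N1"], out["duration_days"]):
        sp = survival_proportion(int(n0), int(n1))
        st = standardize_survival(int(n0), sp.n1_clamped, float(days), horizon_days)
        rows.append((sp.n1_clamped, sp.clamped, sp.p, st.daily_death_rate,
                     st.binomial_failures, st.binomial_successes, st.p, st.clipped))
    (out["N1_clamped"], out["clamp_flag"], out["p_survival"],
     out["daily_death_rate"], out["failures"], out["successes"],
     out["p"], out["clip_flag"]) = map(list, zip(*rows))
    return out


def temp_direction(temperatures, threshold_C: float = 1.5) -> str:
    """Categorical temperature trajectory over an experimental window.

    Compares the mean of the first quarter of the window with the mean of
    the last quarter: "+" if it rose by more than ``threshold_C``, "-" if it
    fell by more, else "0" (stable).  The window must contain at least two
    observations.
    """
    t = np.asarray(temperatures, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature window")
    if t.size < 2:
        raise ValueError("temperature window must span at least 2 observations")
    q = max(1, t.size // 4)
    delta = float(np.mean(t[-q:]) - np.mean(t[:q]))
    if delta > threshold_C:
        return "+"
    if delta < -threshold_C:
        return "-"
    return "0"
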