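"""Seeded synthetic-data generators for the seasonal cage experiment.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs.  The generators emulate

* one year of 10-minute environmental logger data (seasonal temperature,
  spring chlorophyll bloom, winter turbidity storms),
* 7 runs x 10 density treatments x 3 replicate cages of ~30-day survival
  outcomes with density- and environment-dependent, overdispersed mortality,
* per-cage condition indices and perimeter-to-area ratios drawn from the
  log-linear condition / patch-shape models,
* binary cover masks whose clumps coalesce with increasing density.

Overdispersion model
--------------------
The survival analysis estimates a single quasi-binomial dispersion phi but
is silent about its mechanism.  Cages are therefore simulated beta-
binomially: each cage draws a latent mortality probability from a Beta
distribution with pairwise correlation rho, then deaths binomially.  At
common cage size N this reproduces the quasi-binomial mean-variance relation
exactly, with phi = 1 + (N-1)rho; :func:`musselpatch.config.rho_for_dispersion`
maps a target dispersion to rho.

Mortality is simulated on the 22-day standardized scale (where the survival
model lives) and rescaled to each run's actual duration under the constant
daily death rate assumption, rounding to whole individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter
from scipy.special import expit

from .config import (
    CI_TERMS,
    ConfigError,
    MaskConfig,
    PTOA_TERMS,
    SURVIVAL_TERMS,
    SimConfig,
)
from .geometry import CoverMask
from .metrics import DEFAULT_HORIZON_DAYS, count_per_plot


class SimulationError(RuntimeError):
    """Raised when a generator produces an invalid intermediate value."""


# ---------------------------------------------------------------------- #
# environment
# ---------------------------------------------------------------------- #

@dataclass
class EnvironmentSeries:
    """One year of logger data at a fixed interval."""

    frame: pd.DataFrame  # columns: time, day, temperature_C, chlorophyll_ug_l, turbidity_FTU

    @property
    def day(self) -> np.ndarray:
        return self.frame["day"].to_numpy()

    def window(self, start_day: float, duration_days: float) -> pd.DataFrame:
        d = self.frame["day"]
        return self.frame[(d >= start_day) & (d < start_day + duration_days)]

    def window_means(self, start_day: float, duration_days: float) -> dict:
        w = self.window(start_day, duration_days)
        if w.empty:
            raise SimulationError(
                f"environment does not cover days [{start_day}, {start_day + duration_days})"
            )
        return {
            "temp_C": float(w["temperature_C"].mean()),
            "chl_ug_l": float(w["chlorophyll_ug_l"].mean()),
            "turb_FTU": float(w["turbidity_FTU"].mean()),
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EnvironmentSeries":
        frame = pd.read_csv(path, parse_dates=["time"], comment="#")
        return cls(frame=frame)


def _periodic_spline(anchors, year_days: float) -> CubicSpline:
    pts = sorted((float(d) % year_days, float(v)) for d, v in anchors)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    x = np.concatenate([x, [x[0] + year_days]])
    y = np.concatenate([y, [y[0]]])
    return CubicSpline(x, y, bc_type="periodic")


def _eval_periodic(spline, x0: float, t: np.ndarray, year_days: float) -> np.ndarray:
    tt = (t - x0) % year_days + x0
    return spline(tt)


def _ar1_noise(rng, n: int, sd: float, corr_days: float, dt_days: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    a = float(np.exp(-dt_days / corr_days))
    innov_sd = sd * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -a], eps)


def _in_window(day, lo, hi, year_days):
    day = np.asarray(day)
    if lo <= hi:
        return (day >= lo) & (day < hi)
    return (day >= lo) | (day < hi)  # wraps the year end


def gen_environment(config: SimConfig, seed: int) -> EnvironmentSeries:
    """Generate one year of 10-minute environmental logger data."""
    config.validate()
    env = config.env
    rng = np.random.default_rng(seed)

    dt_days = env.interval_minutes / (24.0 * 60.0)
    n = int(round(env.year_days / dt_days))
    t = np.arange(n) * dt_days

    # temperature: seasonal curve + AR(1)
    if env.temp_shape == "sinusoid":
        amp = env.temp_seasonal_range_C / 2.0
        seasonal_t = env.temp_mean_C + amp * np.cos(
            2 * np.pi * (t - env.temp_peak_day) / env.year_days
        )
    else:
        sp = _periodic_spline(env.temp_anchors, env.year_days)
        seasonal_t = _eval_periodic(sp, sp.x[0], t, env.year_days)
    temp = seasonal_t + _ar1_noise(rng, n, env.temp_noise_sd, env.noise_corr_days, dt_days)

    # chlorophyll: seasonal baseline (+ optional extra bloom pulse) + AR(1), >= 0
    sp = _periodic_spline(env.chl_anchors, env.year_days)
    chl = _eval_periodic(sp, sp.x[0], t, env.year_days)
    if env.chl_bloom_amplitude > 0:
        chl = chl + env.chl_bloom_amplitude * np.exp(
            -0.5 * ((t - env.chl_bloom_day) / env.chl_bloom_width_days) ** 2
        )
    chl = chl + _ar1_noise(rng, n, env.chl_noise_sd, env.noise_corr_days, dt_days)
    chl = np.clip(chl, 0.0, None)

    # turbidity: seasonal baseline + winter storm spikes + AR(1), >= 0
    sp = _periodic_spline(env.turb_anchors, env.year_days)
    turb = _eval_periodic(sp, sp.x[0], t, env.year_days)
    lo, hi = env.storm_window
    window_len = (hi - lo) % env.year_days or env.year_days
    n_storms = rng.poisson(env.storm_rate_per_day * window_len)
    storm_days = (lo + rng.uniform(0, window_len, size=n_storms)) % env.year_days
    shape = env.storm_amplitude_shape
    storm_amps = rng.gamma(shape, env.storm_mean_amplitude_FTU / shape, size=n_storms)
    for day0, amp in zip(storm_days, storm_amps):
        delta = (t - day0) % env.year_days
        turb = turb + amp * np.exp(-delta / env.storm_decay_days)
    turb = turb + _ar1_noise(rng, n, env.turb_noise_sd, env.noise_corr_days, dt_days)
    turb = np.clip(turb, 0.0, None)

    time = pd.Timestamp("2017-01-01") + pd.to_timedelta(t, unit="D")
    frame = pd.DataFrame({
        "time": time.round("s"),
        "day": t,
        "temperature_C": temp,
        "chlorophyll_ug_l": chl,
        "turbidity_FTU": turb,
    })
    return EnvironmentSeries(frame=frame)


# ---------------------------------------------------------------------- #
# cage experiment
# ---------------------------------------------------------------------- #

def survival_linear_predictor(coeffs, d0, temp, chl, turb,
                              density_temp_coeff: float = 0.0,
                              temp_ref_C: float = 11.0) -> float:
    """Logit-scale linear predictor of 22-day survival for one cage.

    Term order follows :data:`musselpatch.config.SURVIVAL_TERMS`:
    intercept, D0 (kg m^-2), Temp, Chl, Turb, and the three pairwise
    environment interactions.  ``density_temp_coeff`` optionally makes the
    density effect itself seasonal (zero by default).
    """
    c = dict(zip(SURVIVAL_TERMS, coeffs))
    eta = (c["(Intercept)"] + c["D0"] * d0 + c["Temp"] * temp + c["Chl"] * chl
           + c["Turb"] * turb + c["Temp:Chl"] * temp * chl
           + c["Temp:Turb"] * temp * turb + c["Chl:Turb"] * chl * turb)
    eta += density_temp_coeff * d0 * (temp - temp_ref_C)
    return float(eta)


def draw_betabinomial(rng, n, q, rho):
    """Beta-binomial draw with mean n*q and pairwise correlation rho."""
    if rho == 0:
        return int(rng.binomial(n, q))
    if q <= 0:
        return 0
    if q >= 1:
        return int(n)
    s = (1.0 - rho) / rho
    pi = rng.beta(q * s, (1.0 - q) * s)
    return int(rng.binomial(n, pi))


def gen_cage_experiment(config: SimConfig, env: EnvironmentSeries, seed: int) -> pd.DataFrame:
    """Simulate all run x density x replicate cage outcomes.

    For each cage: the 22-day survival probability p* is the inverse logit of
    the survival predictor at the cage's density and its run-window
    environmental means; 22-day deaths are beta-binomial(N0, 1-p*, rho) and
    are rescaled to the run's duration (constant daily death rate, rounded,
    capped at N0).  A small fraction of cages is perturbed so the end count
    exceeds the start count, emulating recounting error.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rho = config.rho
    horizon = DEFAULT_HORIZON_DAYS

    rows = []
    for run in config.runs:
        wm = env.window_means(run.start_day, run.duration_days)
        for density in config.densities_kg_m2:
            n0 = count_per_plot(density, run.mean_start_weight_g, config.plot_area_m2)
            eta = survival_linear_predictor(
                config.survival_coeffs, density, wm["temp_C"], wm["chl_ug_l"],
                wm["turb_FTU"], config.density_temp_coeff, config.temp_ref_C,
            )
            if not np.isfinite(eta):
                raise SimulationError(
                    f"non-finite linear predictor for cage run={run.run_id} "
                    f"density={density}"
                )
            p_star = float(expit(eta))
            for rep in range(1, config.replicates + 1):
                failures22 = draw_betabinomial(rng, n0, 1.0 - p_star, rho)
                failures_dur = min(n0, int(np.floor(failures22 * run.duration_days / horizon + 0.5)))
                n1 = n0 - failures_dur
                if config.count_error_rate > 0 and rng.random() < config.count_error_rate:
                    n1 += 1 + int(rng.poisson(1.0))  # recounted too high
                n1_eff = min(n1, n0)
                rows.append({
                    "run_id": run.run_id,
                    "start_day": run.start_day,
                    "duration_days": run.duration_days,
                    "density_treatment": density,
                    "replicate": rep,
                    "D0": float(density),
                    "N0": n0,
                    "N1": n1,
                    "D1": float(density) * n1_eff / n0,
                    "total_weight_start_g": n0 * run.mean_start_weight_g,
                    "total_weight_end_g": n1_eff * run.mean_start_weight_g,
                    "temp_C": wm["temp_C"],
                    "chl_ug_l": wm["chl_ug_l"],
                    "turb_FTU": wm["turb_FTU"],
                    "temp_direction": run.temp_direction,
                    "p_expected": p_star,
                    "failures_22d_true": failures22,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# condition index and PtoA samplers
# ---------------------------------------------------------------------- #

def gen_condition(config: SimConfig, records: pd.DataFrame, seed: int) -> np.ndarray:
    """Per-cage condition indices (mg cm^-3) from the log-linear model.

    ln CI = ci_coeffs . (1, D0, 1{dir=-}, 1{dir=+}, Chl, Turb) + N(0, ci_log_sd);
    the exponential guarantees CI > 0.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    c = dict(zip(CI_TERMS, config.ci_coeffs))
    d0 = records["D0"].to_numpy(float)
    dirs = records["temp_direction"].astype(str).to_numpy()
    chl = records["chl_ug_l"].to_numpy(float)
    turb = records["turb_FTU"].to_numpy(float)
    ln_ci = (c["(Intercept)"] + c["D0"] * d0
             + c["TempDir-"] * (dirs == "-") + c["TempDir+"] * (dirs == "+")
             + c["Chl"] * chl + c["Turb"] * turb)
    ln_ci = ln_ci + rng.normal(0.0, config.ci_log_sd, size=len(records))
    return np.exp(ln_ci)


def gen_ptoa(config: SimConfig, records: pd.DataFrame, seed: int) -> np.ndarray:
    """Per-cage perimeter-to-area ratios from the log-linear patch-shape model.

    Complements :func:`gen_patch_mask`: masks carry the geometry, this
    sampler carries the fitted covariate structure of the patch-shape model
    so its coefficients can be recovered by refitting.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    c = dict(zip(PTOA_TERMS, config.ptoa_coeffs))
    ln_ptoa = (c["(Intercept)"] + c["D0"] * records["D0"].to_numpy(float)
               + c["Temp"] * records["temp_C"].to_numpy(float)
               + c["Chl"] * records["chl_ug_l"].to_numpy(float)
               + c["Turb"] * records["turb_FTU"].to_numpy(float))
    ln_ptoa = ln_ptoa + rng.normal(0.0, config.ptoa_log_sd, size=len(records))
    return np.exp(ln_ptoa)


# ---------------------------------------------------------------------- #
# cover masks
# ---------------------------------------------------------------------- #

def gen_patch_mask(density_kg_m2: float, mask_params: MaskConfig, seed: int) -> CoverMask:
    """Synthetic binary cover mask for one cage.

    Cover is a union of filled discs whose radius grows with density, so
    clumps coalesce into larger, smoother patches at high density (falling
    PtoA).  Density 0 yields an empty mask.
    """
    mask_params.validate()
    if density_kg_m2 < 0:
        raise ConfigError("density must be >= 0")
    if density_kg_m2 > mask_params.density_max:
        raise ConfigError(
            f"density {density_kg_m2} above configured maximum {mask_params.density_max}"
        )
    h, w = mask_params.height_px, mask_params.width_px
    pixels = np.zeros((h, w), dtype=bool)
    if density_kg_m2 == 0:
        return CoverMask(pixels, mask_params.scale_mm_per_px, "synthetic")

    rng = np.random.default_rng(seed)
    n_clumps = (mask_params.clump_count if mask_params.clump_count is not None
                else mask_params.n_clumps)
    radius = mask_params.base_radius_px + mask_params.radius_per_density_px * density_kg_m2
    yy, xx = np.mgrid[:h, :w]
    for _ in range(n_clumps):
        r = radius * float(np.exp(rng.normal(0.0, mask_params.radius_jitter)))
        r = min(r, (min(h, w) - 2) / 2.0)
        lo_y, hi_y = r, h - 1 - r
        lo_x, hi_x = r, w - 1 - r
        cy = rng.uniform(lo_y, hi_y) if hi_y > lo_y else (h - 1) / 2.0
        cx = rng.uniform(lo_x, hi_x) if hi_x > lo_x else (w - 1) / 2.0
        pixels |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return CoverMask(pixels, mask_params.scale_mm_per_px, "synthetic")
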