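"""Tests for the synthetic-data generators: determinism, the statistical
structure they promise, and consistency with the field calculations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import musselpatch as mp
from musselpatch.config import ConfigError, EnvConfig, MaskConfig, RunDesign
from musselpatch.geometry import patch_metrics
from musselpatch.metrics import derive_survival_columns
from musselpatch.synthetic import draw_betabinomial, survival_linear_predictor

from conftest import STUDY_WINDOWS


# ------------------------------------------------------------------ #
# determinism
# ------------------------------------------------------------------ #

def test_generators_are_pure_functions_of_seed(default_config, env_default):
    env2 = mp.gen_environment(default_config, seed=11)
    pd.testing.assert_frame_equal(env_default.frame, env2.frame)
    assert not env_default.frame["temperature_C"].equals(
        mp.gen_environment(default_config, seed=12).frame["temperature_C"])

    c1 = mp.gen_cage_experiment(default_config, env_default, seed=5)
    c2 = mp.gen_cage_experiment(default_config, env_default, seed=5)
    pd.testing.assert_frame_equal(c1, c2)

    m1 = mp.gen_patch_mask(9.0, default_config.mask, seed=3)
    m2 = mp.gen_patch_mask(9.0, default_config.mask, seed=3)
    assert np.array_equal(m1.pixels, m2.pixels)


# ------------------------------------------------------------------ #
# environment
# ------------------------------------------------------------------ #

def test_noise_free_sinusoid_has_configured_range(default_config):
    env_cfg = dataclasses.replace(
        default_config.env, temp_shape="sinusoid", temp_noise_sd=0.0)
    cfg = dataclasses.replace(default_config, env=env_cfg).validate()
    env = mp.gen_environment(cfg, seed=0)
    t = env.frame["temperature_C"].to_numpy()
    assert t.max() - t.min() == pytest.approx(env_cfg.temp_seasonal_range_C, abs=1e-6)
    day = env.frame["day"].to_numpy()
    expected = env_cfg.temp_mean_C + env_cfg.temp_seasonal_range_C / 2 * np.cos(
        2 * np.pi * (day - env_cfg.temp_peak_day) / env_cfg.year_days)
    assert np.allclose(t, expected)


def test_environment_seasonality(default_config, env_default):
    env = env_default
    summer = env.window_means(190, 30)["temp_C"]
    winter = env.window_means(15, 30)["temp_C"]
    assert summer > winter
    day = env.frame["day"].to_numpy()
    turb = env.frame["turbidity_FTU"].to_numpy()
    winter_half = (day < 90) | (day >= 273)
    assert turb[winter_half].mean() > turb[~winter_half].mean()
    assert (env.frame["chlorophyll_ug_l"] >= 0).all()
    assert (env.frame["turbidity_FTU"] >= 0).all()


@pytest.mark.parametrize("seed", [11, 23])
def test_environment_run_window_envelope(default_config, seed):
    """Run-window means stay inside 3x the observed 95% CIs of the study year."""
    env = mp.gen_environment(default_config, seed=seed)
    for run in default_config.runs:
        wm = env.window_means(run.start_day, run.duration_days)
        for channel, (value, tol) in STUDY_WINDOWS[run.run_id].items():
            assert abs(wm[channel] - value) <= tol, (run.run_id, channel, wm[channel])


def test_invalid_interval_rejected(default_config):
    env_cfg = dataclasses.replace(default_config.env, interval_minutes=0.0)
    cfg = dataclasses.replace(default_config, env=env_cfg)
    with pytest.raises(ConfigError):
        mp.gen_environment(cfg, seed=0)


# ------------------------------------------------------------------ #
# cage experiment
# ------------------------------------------------------------------ #

def test_survival_predictor_matches_hand_arithmetic():
    # benign mid-summer covariates at 10 kg/m2, coefficient-by-coefficient
    coeffs = (15.44, 0.034, -0.68, -9.12, -0.10, 0.58, -0.16, 0.42)
    temp, chl, turb, d0 = 19.56, 2.46, 3.43, 10.0
    expected = (15.44 + 0.034 * d0 - 0.68 * temp - 9.12 * chl - 0.10 * turb
                + 0.58 * temp * chl - 0.16 * temp * turb + 0.42 * chl * turb)
    eta = survival_linear_predictor(coeffs, d0, temp, chl, turb)
    assert eta == pytest.approx(expected, abs=1e-12)
    assert expit(eta) == pytest.approx(1 / (1 + np.exp(-expected)))


def test_certain_survival_yields_no_deaths(default_config, env_default):
    coeffs = (50.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)  # p* = 1
    cfg = dataclasses.replace(
        default_config, survival_coeffs=coeffs,
        intracage_correlation=0.0, count_error_rate=0.0).validate()
    cages = mp.gen_cage_experiment(cfg, env_default, seed=4)
    assert (cages["N1"] == cages["N0"]).all()
    assert (cages["D1"] == cages["D0"]).all()


def test_binomial_mean_law(default_config, env_default):
    """At rho = 0 the empirical death fraction matches 1 - p* (50k cages)."""
    run = default_config.runs[3]
    cfg = dataclasses.replace(
        default_config, runs=(dataclasses.replace(run, duration_days=22),),
        densities_kg_m2=(9.0,), replicates=50_000,
        intracage_correlation=0.0, count_error_rate=0.0).validate()
    cages = mp.gen_cage_experiment(cfg, env_default, seed=99)
    p_star = cages["p_expected"].iloc[0]
    q = 1 - p_star
    frac = 1 - cages["N1"].to_numpy() / cages["N0"].to_numpy()
    n0 = int(cages["N0"].iloc[0])
    mc_se = np.sqrt(q * (1 - q) / n0 / len(cages))
    assert abs(frac.mean() - q) < 3 * mc_se


def test_betabinomial_dispersion_matches_theory():
    """Pearson dispersion of beta-binomial counts is 1 + (N-1)rho."""
    rng = np.random.default_rng(17)
    n, q, rho, reps = 400, 0.3, 0.04, 10_000
    draws = np.array([draw_betabinomial(rng, n, q, rho) for _ in range(reps)])
    pearson = np.mean((draws - n * q) ** 2 / (n * q * (1 - q)))
    assert pearson == pytest.approx(1 + (n - 1) * rho, rel=0.10)


def test_standardization_round_trip(default_config, env_default):
    """Rescaling 22-day deaths to run duration and re-standardizing recovers
    them within rounding (+-0.5) for every non-extinct cage."""
    cfg = dataclasses.replace(default_config, count_error_rate=0.0).validate()
    cages = mp.gen_cage_experiment(cfg, env_default, seed=21)
    derived = derive_survival_columns(cages)
    ok = derived["N1"] > 0  # extinct cages are duration-capped, not recoverable
    err = (derived.loc[ok, "failures"] - derived.loc[ok, "failures_22d_true"]).abs()
    assert (err <= 0.5 + 1e-9).all()


def test_count_error_exercises_clamping(default_config, env_default):
    cfg = dataclasses.replace(default_config, count_error_rate=0.5).validate()
    cages = mp.gen_cage_experiment(cfg, env_default, seed=8)
    assert (cages["N1"] > cages["N0"]).any()
    derived = derive_survival_columns(cages)
    assert derived["clamp_flag"].any()
    assert (derived["N1_clamped"] <= derived["N0"]).all()


def test_nonfinite_predictor_names_cage(default_config, env_default):
    coeffs = (np.inf, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    cfg = dataclasses.replace(default_config, survival_coeffs=coeffs)
    with pytest.raises(mp.synthetic.SimulationError, match="run1"):
        mp.gen_cage_experiment(cfg, env_default, seed=0)


# ------------------------------------------------------------------ #
# condition index and PtoA samplers
# ------------------------------------------------------------------ #

def _toy_records(d0_values, direction="0", chl=0.0, turb=0.0):
    return pd.DataFrame({
        "run_id": "runX",
        "D0": d0_values,
        "temp_direction": direction,
        "temp_C": 10.0,
        "chl_ug_l": chl,
        "turb_FTU": turb,
    })


def test_condition_deterministic_limit(default_config):
    cfg = dataclasses.replace(
        default_config, ci_coeffs=(0.7, 0, 0, 0, 0, 0), ci_log_sd=0.0).validate()
    ci = mp.gen_condition(cfg, _toy_records(np.linspace(1, 19, 12)), seed=0)
    assert np.allclose(ci, np.exp(0.7))


def test_condition_declines_with_density(default_config):
    cfg = dataclasses.replace(default_config, ci_log_sd=0.0).validate()
    ci = mp.gen_condition(cfg, _toy_records(np.arange(1.0, 20.0, 2.0)), seed=0)
    assert (np.diff(ci) < 0).all()
    assert (ci > 0).all()


def test_condition_log_sd(default_config):
    cfg = dataclasses.replace(default_config, ci_log_sd=0.2).validate()
    ci = mp.gen_condition(cfg, _toy_records(np.full(10_000, 9.0)), seed=3)
    assert np.log(ci).std(ddof=1) == pytest.approx(0.2, rel=0.05)


def test_ptoa_sampler_declines_with_density(default_config):
    cfg = dataclasses.replace(default_config, ptoa_log_sd=0.0).validate()
    ptoa = mp.gen_ptoa(cfg, _toy_records(np.arange(1.0, 20.0, 2.0)), seed=0)
    assert (np.diff(ptoa) < 0).all()


# ------------------------------------------------------------------ #
# masks
# ------------------------------------------------------------------ #

def test_mask_zero_density_is_empty(default_config):
    mask = mp.gen_patch_mask(0.0, default_config.mask, seed=0)
    assert not mask.pixels.any()


def test_mask_too_small_rejected():
    with pytest.raises(ConfigError):
        mp.gen_patch_mask(5.0, MaskConfig(width_px=8, height_px=8), seed=0)


def test_single_clump_matches_circle_ptoa():
    cfg = MaskConfig(clump_count=1, base_radius_px=20.0,
                     radius_per_density_px=0.0, radius_jitter=0.0)
    mask = mp.gen_patch_mask(1.0, cfg, seed=7)
    analytic = 2.0 / (20.0 * cfg.scale_mm_per_px)
    assert patch_metrics(mask).ptoa == pytest.approx(analytic, rel=0.15)


def test_median_ptoa_nonincreasing_in_density(default_config):
    densities = (1, 5, 9, 13, 17, 19)
    medians = []
    for d in densities:
        vals = [patch_metrics(mp.gen_patch_mask(d, default_config.mask, s)).ptoa
                for s in range(50)]
        medians.append(np.median(vals))
    assert (np.diff(medians) <= 0).all()
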