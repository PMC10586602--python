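"""Configuration objects for the seasonal cage-experiment simulator.

A :class:`SimConfig` fully determines a synthetic study: the seven ~30-day
experimental runs, the ten density treatments, the environmental forcing, the
generating coefficients of the survival / condition / patch-shape models, and
the overdispersion structure.  Together with an integer seed it makes every
generator in :mod:`musselpatch.synthetic` a pure function.

Default values reproduce the design of the field study the package models:
7 runs spread over one year, densities 1–19 kg m⁻² in steps of 2, three
replicate cages per density on 0.3 m × 0.3 m plots, and generating
coefficients equal to the fitted values of the published survival and
condition models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


#: Term order of the survival (quasi-binomial, logit) linear predictor.
SURVIVAL_TERMS = (
    "(Intercept)", "D0", "Temp", "Chl", "Turb",
    "Temp:Chl", "Temp:Turb", "Chl:Turb",
)

#: Term order of the log-condition linear predictor.
CI_TERMS = ("(Intercept)", "D0", "TempDir-", "TempDir+", "Chl", "Turb")

#: Term order of the log perimeter-to-area linear predictor.
PTOA_TERMS = ("(Intercept)", "D0", "Temp", "Chl", "Turb")

# Fitted coefficients of the published models, used as generator truth.
DEFAULT_SURVIVAL_COEFFS = (15.44, 0.034, -0.68, -9.12, -0.10, 0.58, -0.16, 0.42)
DEFAULT_CI_COEFFS = (1.82, -0.007, -0.30, -0.33, 0.12, -0.09)
DEFAULT_PTOA_COEFFS = (3.83, -0.02, 0.01, -0.24, 0.19)

#: Pearson dispersion of the published survival model; the default
#: within-cage correlation is calibrated against this value.
DEFAULT_TARGET_DISPERSION = 17.37


@dataclass(frozen=True)
class RunDesign:
    """One experimental run: a ~30-day deployment of all 30 cages.

    ``temp_direction`` is the categorical temperature-trajectory label used by
    the condition model ("0" = high and stable, "+" = rising, "-" = falling).
    Defaults are assigned from the seasonal temperature curve with the
    first-quarter/last-quarter rule of :func:`musselpatch.metrics.temp_direction`.
    """

    run_id: str
    start_day: float            # day of year, 0-based
    duration_days: int
    mean_start_weight_g: float  # W0: average individual wet weight at start
    temp_direction: str = "0"

    def validate(self) -> None:
        if self.duration_days < 1:
            raise ConfigError(f"run {self.run_id}: duration_days must be >= 1")
        if self.mean_start_weight_g <= 0:
            raise ConfigError(f"run {self.run_id}: mean_start_weight_g must be > 0")
        if self.temp_direction not in ("-", "0", "+"):
            raise ConfigError(f"run {self.run_id}: temp_direction must be -, 0 or +")


# Anchor points (day of year at run midpoint, window mean) for the default
# seasonal curves; the periodic spline through them reproduces the observed
# run-window means of the study year.
DEFAULT_TEMP_ANCHORS = (
    (70.5, 2.30), (84.0, 8.89), (121.0, 11.63), (166.0, 19.08),
    (224.0, 19.56), (277.5, 15.51), (329.0, 8.59),
)
DEFAULT_CHL_ANCHORS = (
    (70.5, 2.15), (84.0, 1.73), (121.0, 2.96), (166.0, 1.79),
    (224.0, 2.46), (277.5, 1.70), (329.0, 1.08),
)
# Turbidity anchors are the baseline *without* storms; the expected storm
# contribution (rate x amplitude x decay ~ 2.2 FTU inside the winter window)
# tops winter windows back up to the observed means.
DEFAULT_TURB_ANCHORS = (
    (70.5, 5.45), (84.0, 2.30), (121.0, 1.63), (166.0, 2.57),
    (224.0, 3.43), (277.5, 1.97), (329.0, 1.48),
)


@dataclass
class EnvConfig:
    """Parameters of the synthetic environmental logger series.

    The series emulates one year of 10-minute logger data: water temperature
    (°C), chlorophyll-a (µg l⁻¹, food proxy) and turbidity (FTU, hydrodynamic
    stress proxy).  Each channel is a smooth seasonal curve plus stationary
    AR(1) noise; turbidity additionally carries Poisson-timed storm spikes
    restricted to a winter window, and chlorophyll an optional extra spring
    bloom pulse (the default anchors already encode the observed bloom).
    """

    interval_minutes: float = 10.0
    year_days: int = 365

    temp_shape: str = "anchors"          # "anchors" | "sinusoid"
    temp_anchors: tuple = DEFAULT_TEMP_ANCHORS
    temp_mean_C: float = 11.0            # sinusoid shape only
    temp_seasonal_range_C: float = 20.0  # max - min of the sinusoid
    temp_peak_day: float = 224.0
    temp_noise_sd: float = 0.6

    chl_anchors: tuple = DEFAULT_CHL_ANCHORS
    chl_bloom_amplitude: float = 0.0     # extra pulse on top of the anchors
    chl_bloom_day: float = 115.0
    chl_bloom_width_days: float = 12.0
    chl_noise_sd: float = 0.2

    turb_anchors: tuple = DEFAULT_TURB_ANCHORS
    turb_noise_sd: float = 0.7
    storm_rate_per_day: float = 0.8
    storm_mean_amplitude_FTU: float = 4.5
    storm_amplitude_shape: float = 4.0   # gamma shape of spike amplitudes
    storm_decay_days: float = 0.6
    storm_window: tuple = (305.0, 90.0)  # day-of-year interval, wraps the year

    noise_corr_days: float = 0.5

    def validate(self) -> None:
        if self.interval_minutes <= 0:
            raise ConfigError("interval_minutes must be > 0")
        if self.year_days < 1:
            raise ConfigError("year_days must be >= 1")
        if self.temp_shape not in ("anchors", "sinusoid"):
            raise ConfigError("temp_shape must be 'anchors' or 'sinusoid'")
        for name in ("temp_noise_sd", "chl_noise_sd", "turb_noise_sd",
                     "storm_rate_per_day", "storm_mean_amplitude_FTU"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.storm_decay_days <= 0 or self.noise_corr_days <= 0:
            raise ConfigError("decay/correlation times must be > 0")


@dataclass
class MaskConfig:
    """Parameters of the synthetic binary cover masks.

    Cover is modelled phenomenologically as a union of filled discs
    ("clumps"); disc radius grows with density so clumps coalesce into
    larger, smoother patches at high density, reproducing the observed
    decline of the perimeter-to-area ratio with density.
    """

    width_px: int = 192
    height_px: int = 192
    scale_mm_per_px: float = 2.0
    n_clumps: int = 14
    clump_count: Optional[int] = None    # override: force an exact clump count
    base_radius_px: float = 6.0
    radius_per_density_px: float = 1.2   # radius growth per kg m^-2
    radius_jitter: float = 0.15          # lognormal-ish relative jitter
    density_max: float = 20.0

    def validate(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ConfigError("mask dimensions must be at least 16x16 px")
        if self.scale_mm_per_px <= 0:
            raise ConfigError("scale_mm_per_px must be > 0")
        if self.base_radius_px <= 0:
            raise ConfigError("base_radius_px must be > 0")
        if self.clump_count is not None and self.clump_count < 0:
            raise ConfigError("clump_count must be >= 0")


def default_runs() -> tuple:
    """The seven runs of the study year (start day, duration, W0).

    Temperature-direction labels follow the quarter-mean rule applied to the
    default seasonal curve.
    """
    return (
        RunDesign("run1", 69, 30, 1.33, "+"),
        RunDesign("run2", 108, 26, 3.35, "+"),
        RunDesign("run3", 152, 28, 3.20, "+"),
        RunDesign("run4", 208, 32, 3.46, "0"),
        RunDesign("run5", 263, 29, 3.75, "-"),
        RunDesign("run6", 313, 32, 4.95, "-"),
        RunDesign("run7", 52, 37, 1.51, "+"),
    )


@dataclass
class SimConfig:
    """Full specification of one synthetic cage study."""

    runs: tuple = field(default_factory=default_runs)
    densities_kg_m2: tuple = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)
    replicates: int = 3
    plot_area_m2: float = 0.09

    survival_coeffs: tuple = DEFAULT_SURVIVAL_COEFFS
    #: optional modulation of the density effect by temperature:
    #: the D0 coefficient becomes  D0 + density_temp_coeff * (Temp - temp_ref_C)
    density_temp_coeff: float = 0.0
    temp_ref_C: float = 11.0
    #: beta-binomial pairwise within-cage correlation rho; None means
    #: "calibrate to DEFAULT_TARGET_DISPERSION at the design's mean N".
    intracage_correlation: Optional[float] = None
    count_error_rate: float = 0.03   # probability a cage is re-counted too high

    ci_coeffs: tuple = DEFAULT_CI_COEFFS
    ci_log_sd: float = 0.2
    ptoa_coeffs: tuple = DEFAULT_PTOA_COEFFS
    ptoa_log_sd: float = 0.15

    env: EnvConfig = field(default_factory=EnvConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> "SimConfig":
        if not self.runs:
            raise ConfigError("at least one run required")
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ConfigError("run ids must be unique")
        for r in self.runs:
            r.validate()
        d = tuple(self.densities_kg_m2)
        if not d or any(x <= 0 for x in d):
            raise ConfigError("densities must be strictly positive")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ConfigError("densities must be strictly increasing")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.plot_area_m2 <= 0:
            raise ConfigError("plot_area_m2 must be > 0")
        rho = self.rho
        if not (0 <= rho < 1):
            raise ConfigError("intracage_correlation must be in [0, 1)")
        if not (0 <= self.count_error_rate <= 1):
            raise ConfigError("count_error_rate must be in [0, 1]")
        if len(self.survival_coeffs) != len(SURVIVAL_TERMS):
            raise ConfigError(f"survival_coeffs must have {len(SURVIVAL_TERMS)} entries")
        if len(self.ci_coeffs) != len(CI_TERMS):
            raise ConfigError(f"ci_coeffs must have {len(CI_TERMS)} entries")
        if len(self.ptoa_coeffs) != len(PTOA_TERMS):
            raise ConfigError(f"ptoa_coeffs must have {len(PTOA_TERMS)} entries")
        if self.ci_log_sd < 0 or self.ptoa_log_sd < 0:
            raise ConfigError("log-scale residual SDs must be >= 0")
        self.env.validate()
        self.mask.validate()
        return self

    # ------------------------------------------------------------------ #

    @property
    def rho(self) -> float:
        """Within-cage beta-binomial correlation actually used."""
        if self.intracage_correlation is not None:
            return self.intracage_correlation
        return rho_for_dispersion(DEFAULT_TARGET_DISPERSION, self.mean_plot_count())

    def plot_counts(self) -> list:
        """Start counts N0 for every run x density combination."""
        from .metrics import count_per_plot
        return [
            count_per_plot(d, r.mean_start_weight_g, self.plot_area_m2)
            for r in self.runs for d in self.densities_kg_m2
        ]

    def mean_plot_count(self) -> float:
        import numpy as np
        return float(np.mean(self.plot_counts()))

    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "runs" in d:
            d["runs"] = tuple(
                r if isinstance(r, RunDesign) else RunDesign(**r) for r in d["runs"]
            )
        if "env" in d and not isinstance(d["env"], EnvConfig):
            d["env"] = EnvConfig(**_tuplify(d["env"]))
        if "mask" in d and not isinstance(d["mask"], MaskConfig):
            d["mask"] = MaskConfig(**d["mask"])
        for key in ("densities_kg_m2", "survival_coeffs", "ci_coeffs", "ptoa_coeffs"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config document must be a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def rho_for_dispersion(dispersion: float, mean_n: float) -> float:
    """Beta-binomial correlation giving Pearson dispersion ``dispersion``.

    For cages of common size N the quasi-binomial dispersion of beta-binomial
    counts is exactly 1 + (N-1)·rho, hence rho = (phi-1)/(N-1).
    """
    if dispersion < 1:
        raise ConfigError("dispersion must be >= 1")
    if mean_n <= 1:
        raise ConfigError("mean_n must be > 1")
    return (dispersion - 1.0) / (mean_n - 1.0)
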