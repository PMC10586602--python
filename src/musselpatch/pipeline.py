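"""End-to-end pipeline: simulate -> metrics -> fit -> slopes -> report.

Owns all file dialects: cage tables and environment series are UTF-8 CSV
with a header row and a leading format-version comment line; masks are
single-channel PNGs with a JSON calibration sidecar; each pipeline run
writes a JSON manifest recording the resolved config hash, the seed, and
every stage output.

One global seed deterministically spawns per-stage child seeds, so a stage
can be re-run in isolation and reproduce the full run's output bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import CI_TERMS, RunDesign, SimConfig
from .geometry import patch_metrics, read_mask, write_mask
from .glm import LogLinearModel, QuasiBinomialLogit
from .metrics import derive_survival_columns
from .slopes import SeasonalProfile, ci_slope, seasonal_profile, survival_slope
from .synthetic import gen_cage_experiment, gen_condition, gen_environment, gen_patch_mask

log = logging.getLogger("musselpatch")

STAGES = ("simulate", "metrics", "fit", "slopes", "report")

CAGE_TABLE_VERSION = "musselpatch cage-table v1"
ENV_TABLE_VERSION = "musselpatch environment v1"

#: columns every cage table must carry
CAGE_REQUIRED = (
    "run_id", "start_day", "duration_days", "density_treatment", "replicate",
    "D0", "N0", "N1", "D1", "temp_C", "chl_ug_l", "turb_FTU", "temp_direction",
)
_CAGE_NUMERIC = (
    "start_day", "duration_days", "density_treatment", "replicate",
    "D0", "N0", "N1", "D1", "temp_C", "chl_ug_l", "turb_FTU",
)


class SchemaError(ValueError):
    """A table does not match the pipeline's CSV dialect."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------- #
# table I/O
# ---------------------------------------------------------------------- #

def write_cage_table(records: pd.DataFrame, path) -> None:
    missing = [c for c in CAGE_REQUIRED if c not in records.columns]
    if missing:
        raise SchemaError(f"cage table missing required columns: {missing}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {CAGE_TABLE_VERSION}\n")
        records.to_csv(fh, index=False)


def read_cage_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"run_id": str, "temp_direction": str})
    missing = [c for c in CAGE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    bad_lines = []
    for col in _CAGE_NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] if df[col].dtype == object else []
        # header + version comment occupy the first two lines
        bad_lines.extend((int(i) + 3, col) for i in bad)
        df[col] = vals
    nan_rows = df[list(_CAGE_NUMERIC)].isna().any(axis=1)
    bad_lines.extend(
        (int(i) + 3, "missing value") for i in df.index[nan_rows]
        if (int(i) + 3) not in [b[0] for b in bad_lines]
    )
    if bad_lines:
        detail = "; ".join(f"line {ln} ({what})" for ln, what in sorted(set(bad_lines)))
        raise SchemaError(f"{path}: malformed rows: {detail}")
    return df


def _write_versioned_csv(df: pd.DataFrame, path, version: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {version}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------- #
# manifest
# ---------------------------------------------------------------------- #

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str = __version__
    stage_outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def record(self, stage: str, outputs: Sequence[str]) -> None:
        self.stage_outputs[stage] = list(outputs)
        self.timestamps[stage] = datetime.now(timezone.utc).isoformat()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------- #
# stages
# ---------------------------------------------------------------------- #

def _mask_path(out: Path, run_id: str, density, replicate) -> Path:
    return out / "masks" / f"{run_id}_d{density:g}_r{replicate}.png"


def simulate_stage(config: SimConfig, seed: int, out: Path) -> list:
    env = gen_environment(config, stage_seed(seed, "simulate"))
    cages = gen_cage_experiment(config, env, stage_seed(seed, "simulate") + 1)
    cages["condition_index"] = gen_condition(config, cages, stage_seed(seed, "simulate") + 2)

    env_path = out / "environment.csv"
    with open(env_path, "w", newline="") as fh:
        fh.write(f"# {ENV_TABLE_VERSION}\n")
        env.frame.to_csv(fh, index=False)
    cages_path = out / "cages.csv"
    write_cage_table(cages, cages_path)

    (out / "masks").mkdir(exist_ok=True)
    mask_seed = stage_seed(seed, "simulate") + 3
    outputs = [str(env_path), str(cages_path)]
    for i, row in cages.iterrows():
        mask = gen_patch_mask(float(row["density_treatment"]), config.mask,
                              mask_seed + int(i))
        mpath = _mask_path(out, row["run_id"], row["density_treatment"],
                           int(row["replicate"]))
        write_mask(mask, mpath)
    outputs.append(str(out / "masks"))
    return outputs


def metrics_stage(config: SimConfig, out: Path) -> list:
    cages = read_cage_table(out / "cages.csv")
    derived = derive_survival_columns(cages)
    ptoa = []
    for _, row in derived.iterrows():
        mpath = _mask_path(out, row["run_id"], row["density_treatment"],
                           int(row["replicate"]))
        if mpath.exists():
            ptoa.append(patch_metrics(read_mask(mpath)).ptoa)
        else:
            ptoa.append(np.nan)
    derived["ptoa"] = ptoa
    path = out / "cages_derived.csv"
    write_cage_table(derived, path)
    return [str(path)]


def _tempdir_dummies(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    dirs = out["temp_direction"].astype(str)
    out["TempDir-"] = (dirs == "-").astype(float)
    out["TempDir+"] = (dirs == "+").astype(float)
    return out


def fit_stage(config: SimConfig, out: Path) -> list:
    df = read_cage_table(out / "cages_derived.csv")
    outputs = []

    m1 = QuasiBinomialLogit.from_dataframe(
        df, terms=["D0", "temp_C", "chl_ug_l", "turb_FTU"],
        interactions=[("temp_C", "chl_ug_l"), ("temp_C", "turb_FTU"),
                      ("chl_ug_l", "turb_FTU")],
    ).fit()
    tab1 = m1.coef_table()
    tab1.attrs["dispersion"] = m1.dispersion
    p1 = out / "model1_survival.csv"
    _write_versioned_csv(tab1, p1, f"musselpatch model1 dispersion={m1.dispersion:.4f}")
    outputs.append(str(p1))

    if df["ptoa"].notna().all():
        m2 = LogLinearModel.from_dataframe(
            df, response="ptoa", terms=["D0", "temp_C", "chl_ug_l", "turb_FTU"],
        ).fit(cov_type="HC3")
        p2 = out / "model2_ptoa.csv"
        _write_versioned_csv(m2.coef_table(), p2, "musselpatch model2 cov=HC3")
        outputs.append(str(p2))

    dfd = _tempdir_dummies(df)
    m3 = LogLinearModel.from_dataframe(
        dfd, response="condition_index",
        terms=["D0", "TempDir-", "TempDir+", "chl_ug_l", "turb_FTU"],
    ).fit(cov_type="HC3")
    p3 = out / "model3_condition.csv"
    _write_versioned_csv(m3.coef_table(), p3, "musselpatch model3 cov=HC3")
    outputs.append(str(p3))
    return outputs


def slopes_stage(config: SimConfig, out: Path) -> list:
    df = read_cage_table(out / "cages_derived.csv")
    designs = [
        RunDesign(run_id=rid, start_day=float(g["start_day"].iloc[0]),
                  duration_days=int(g["duration_days"].iloc[0]),
                  mean_start_weight_g=1.0,
                  temp_direction=str(g["temp_direction"].iloc[0]))
        for rid, g in df.groupby("run_id", sort=False)
    ]
    surv = [survival_slope(g) for _, g in df.groupby("run_id", sort=False)]
    cond = [ci_slope(g) for _, g in df.groupby("run_id", sort=False)]
    prof_s = seasonal_profile(surv, designs)
    prof_c = seasonal_profile(cond, designs)
    p1, p2 = out / "slopes_survival.csv", out / "slopes_condition.csv"
    _write_versioned_csv(
        prof_s.table, p1,
        f"musselpatch survival slopes concavity={prof_s.concavity:.4f} "
        f"peak={prof_s.peak_run_id}")
    _write_versioned_csv(
        prof_c.table, p2,
        f"musselpatch condition slopes concavity={prof_c.concavity:.4f} "
        f"peak={prof_c.peak_run_id}")
    return [str(p1), str(p2)]


def report_stage(config: SimConfig, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = []
    env = pd.read_csv(out / "environment.csv", comment="#")
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    for ax, col, label in zip(
            axes, ("temperature_C", "chlorophyll_ug_l", "turbidity_FTU"),
            ("Temperature (°C)", "Chlorophyll-a (µg/l)", "Turbidity (FTU)")):
        daily = env.groupby(env["day"].astype(int))[col].mean()
        ax.plot(daily.index, daily.values, lw=0.8)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("Day of year")
    fig.tight_layout()
    p = out / "environment.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs.append(str(p))

    for name, thr in (("slopes_survival", 1.0), ("slopes_condition", 0.0)):
        tab = pd.read_csv(out / f"{name}.csv", comment="#")
        fig, ax = plt.subplots(figsize=(7, 4))
        i = np.arange(len(tab))
        ax.errorbar(i, tab["M"], yerr=tab["se_M"], fmt="o-", capsize=3)
        ax.axhline(thr, color="grey", ls="--", lw=1)
        ax.set_xticks(i, tab["run_id"])
        ax.set_ylabel("M (log-log slope)")
        ax.set_xlabel("Run (seasonal order)")
        fig.tight_layout()
        p = out / f"{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs.append(str(p))

    df = read_cage_table(out / "cages_derived.csv")
    if df["ptoa"].notna().any():
        fig, ax = plt.subplots(figsize=(7, 4))
        med = df.groupby("density_treatment")["ptoa"].median()
        ax.plot(med.index, med.values, "o-")
        ax.set_xlabel("Starting density (kg m$^{-2}$)")
        ax.set_ylabel("Median PtoA (mm$^{-1}$)")
        fig.tight_layout()
        p = out / "ptoa_vs_density.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs.append(str(p))
    return outputs


_STAGE_FUNCS = {
    "metrics": metrics_stage,
    "fit": fit_stage,
    "slopes": slopes_stage,
    "report": report_stage,
}


def run_pipeline(config, seed: int, out_dir,
                 stages: Sequence[str] = STAGES) -> RunManifest:
    """Run the requested stages in order; later stages read earlier outputs.

    ``config`` is a :class:`SimConfig` or a path to a YAML document.  On a
    stage failure the manifest records the failed stage and downstream
    stages are skipped.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=int(seed))
    config.to_yaml(out / "config_resolved.yaml")
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                outputs = simulate_stage(config, seed, out)
            else:
                outputs = _STAGE_FUNCS[stage](config, out)
        except Exception:
            log.exception("stage %s failed", stage)
            manifest.failed_stage = stage
            break
        manifest.record(stage, outputs)
    manifest.save(out / "manifest.json")
    return manifest
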