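# musselpatch

Density-dependent survival, condition and patch-shape analysis for seasonal
blue-mussel (*Mytilus edulis*) cage experiments.

Aggregating into dense patches exposes semi-sessile animals to a trade-off:
neighbours provide shelter against dislodgement and burial (facilitation)
but compete for the same food (competition). The balance between the two
shifts with the season. This package implements, as a tested and reusable
pipeline, the statistical machinery for quantifying that balance from a
repeated cage experiment — ten biomass densities (1–19 kg m⁻², i.e. 52–988
mussels on a 0.3 m × 0.3 m plot), three replicate cages each, deployed for
roughly a month, seven times over one year, with continuous 10-minute
logging of water temperature, chlorophyll-a (food proxy) and turbidity
(hydrodynamic-stress proxy). Because no raw data from such an experiment is
distributable, the package ships a first-class synthetic-data generator
that emulates the design, so every stage of the analysis is testable
end to end.

## The models

**Survival (quasi-binomial GLM).** Each cage's outcome is standardized to a
common 22-day horizon assuming a constant daily death rate:

    daily death rate = (N₀ − N₁) / days
    failures = daily death rate × 22,  successes = N₀ − failures,  p = successes / N₀

where N₀, N₁ are start and end counts (N₁ is clamped to N₀ when recounting
exceeds the start count — there is no recruitment inside a cage). The
possibly non-integer counts are fitted with a quasi-binomial GLM with logit
link (iteratively reweighted least squares, written from first principles):

    logit p* = β₀ + β₁ D₀ + β₂ Temp + β₃ Chl + β₄ Turb
             + β₅ Temp:Chl + β₆ Temp:Turb + β₇ Chl:Turb

with prior weights N₀ and Pearson-based dispersion φ; standard errors are
scaled by √φ and tested against a t reference on the residual degrees of
freedom, with per-model Holm correction.

**Condition and patch shape (log-linear ratio models).** The condition
index CI = AFDW / L³ (mg cm⁻³) and the perimeter-to-area ratio PtoA
(mm⁻¹, measured on binary cover masks with a calibrated weighted boundary
estimator) are ratios, modelled as linear models on the log response with
heteroskedasticity-consistent (HC3 sandwich) standard errors. The
condition model replaces mean temperature with a categorical temperature
direction ("0" high and stable — the reference level, "+" rising, "−"
falling).

**Seasonal slope statistics.** Per run, the strength of the density effect
is the slope M of a log-log regression pooled over the run's 30 cages:
ln D₁ = M ln D₀ + b for survival (neutral at M = 1) and
ln CI = M ln D₀ + b for condition (neutral at M = 0). M above the neutral
value indicates facilitation, below it competition; the slopes ordered by
run start date form the seasonal profile, whose concavity quantifies the
bell-shaped summer peak.

## Worked example

```python
import musselpatch as mp
from musselpatch.recovery import fit_survival_model
from musselpatch.slopes import survival_slope, seasonal_profile

config = mp.SimConfig().validate()          # the 7-run, 10-density study design
env = mp.gen_environment(config, seed=11)   # one year of 10-minute logger data
cages = mp.gen_cage_experiment(config, env, seed=12)   # 210 cage outcomes

fit = fit_survival_model(cages)             # standardize + quasi-binomial GLM
print(fit.summary())
```

```
Quasi-binomial GLM (logit link)
  n = 210, df_resid = 202, dispersion = 17.04, converged = True (6 iterations)
             Term  Estimate  Std. error  t value    p.value     p.holm
      (Intercept)     13.88       1.894    7.329  5.469e-12  3.828e-11
               D0    0.0334    0.006908    4.836  2.627e-06  7.881e-06
           temp_C   -0.9388      0.1478    -6.35  1.394e-09  8.366e-09
         chl_ug_l    -10.17      0.8931   -11.39  1.528e-23  1.222e-22
         turb_FTU     3.014       1.675    1.799    0.07348      0.147
  temp_C:chl_ug_l    0.8601      0.1489    5.776  2.851e-08   1.14e-07
  temp_C:turb_FTU   -0.2369      0.0401   -5.909  1.443e-08  7.213e-08
chl_ug_l:turb_FTU   -0.7845      0.6473   -1.212     0.2269     0.2269
```

The cages were generated with a positive density coefficient of 0.034 on
the logit scale and a within-cage correlation calibrated to dispersion
17.37; the single-year refit recovers an estimate of 0.0334 (SE 0.0069,
significant after Holm correction) and dispersion 17.04, i.e. denser cages
survive better once the environment is accounted for. The per-run slopes
summarize the same data seasonally:

```python
slopes = [survival_slope(g) for _, g in cages.groupby("run_id", sort=False)]
profile = seasonal_profile(slopes, config.runs)
print(profile.table[["run_id", "M", "se_M", "classification"]].to_string(index=False))
```

```
run_id        M     se_M classification
  run7 1.033023 0.148101        neutral
  run1 1.241196 0.258865        neutral
  run2 1.271501 0.076850    cooperative
  run3 1.096471 0.071463        neutral
  run4 1.033911 0.086436        neutral
  run5 1.036965 0.035231        neutral
  run6 1.035187 0.012514    cooperative
```

Every slope sits at or above 1, as expected when the generating density
effect is positive in all seasons; a configuration whose density effect
peaks in summer (``musselpatch.recovery.bell_shape_config``) instead
produces the bell-shaped profile with competition (M < 1) in the coldest
run.

The same pipeline is available from the shell:

```bash
musselpatch all --seed 42 --out out/      # simulate → metrics → fit → slopes → report
```

which writes the environment and cage CSVs, per-cage cover masks (PNG +
calibration sidecar), the three model coefficient tables, the slope
profiles and summary plots, plus a JSON manifest of the run.

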