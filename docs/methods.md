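# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `musselpatch`. It is written for a
reader who wants to know exactly what the package computes and what passing
its tests does — and does not — demonstrate about real data.

## Survival standardization and the quasi-binomial model

Runs differ in duration (26–37 days), so raw survival proportions confound
treatment with exposure time. Assuming a constant daily death rate within a
run, each cage is standardized to a 22-day horizon: failures =
(N₀ − N₁)/days × 22, successes = N₀ − failures, p = successes/N₀. Failures
are deliberately left non-integer; the quasi-binomial quasi-likelihood only
requires a mean–variance relation, not integer counts. Two guard rails:

* **Clamp before standardizing.** End counts occasionally exceed start
  counts (recounting error; cages exclude recruitment), and N₁ is replaced
  by N₀ *before* the standardization — otherwise failures would be negative,
  violating the binomial contract. Clamped records carry a flag.
* **Clip fast extinctions.** When mortality is total and the run is shorter
  than the horizon, the extrapolated failures can exceed N₀; they are
  clipped to N₀ with a flag rather than rejected, keeping p in [0, 1].
  The mirror-image effect — a run *longer* than the horizon whose cages
  die out completely — compresses their standardized failures below N₀.
  This mild right-censoring of the worst cages is inherent to the
  constant-rate standardization and attenuates fitted coefficients by a
  few percent; the parameter-recovery study shows the size of the effect.

The GLM itself is IRLS with logit link, prior weights N₀, starting values
from the link-transformed adjusted response, convergence at max |Δβ| < 1e-8
(cap 100 iterations). Dispersion is Pearson χ²/(n−p); standard errors are
model SEs × √φ and p-values use a t reference on n−p degrees of freedom,
matching the convention of R's `glm(..., family = quasibinomial)` summary.
Rank deficiency is detected by SVD (condition > 1e10) and reported with the
names of the collinear terms. The identical score equations mean the point
estimates equal binomial ML estimates; the test suite exploits this by
checking IRLS against direct likelihood maximization (Nelder–Mead) to 1e-6.

## Ratio models and sandwich covariance

The condition index (CI = AFDW/L³, mg cm⁻³) and the perimeter-to-area
ratio are fitted as OLS on the log response. Ratio responses are
heteroskedastic on the natural scale, so inference defaults to the HC3
sandwich covariance (the default of R's `sandwich::vcovHC`); HC0–HC2 are
available, and HC2/HC3 refuse rows with leverage 1, where their weighting
is undefined. p-values are recomputed from whichever covariance is active.
Interaction terms are deliberately unsupported in these two models: with
one covariate triple per run (seven distinct points per year) they are
collinear with the main effects, so the design restricts interactions to
the survival model.

The condition model uses a categorical temperature direction instead of
mean temperature. The category is not defined numerically in field
protocols, so the package adopts an explicit rule: compare the mean of the
first quarter of the run window with the mean of the last quarter; a change
beyond ±1.5 °C (configurable) is "+" or "−", otherwise "0" (high and
stable, the reference level — "low and stable" does not occur in the
default year). Default run labels are frozen from this rule applied to the
default seasonal curve.

Holm's step-down correction is applied per model across that model's
coefficient tests: sort ascending, multiply p₍ᵢ₎ by (m−i+1), enforce a
running maximum, cap at 1.

## Per-run slope statistics

For each run, M is the OLS slope of ln(end density) on ln(start density)
pooled over all 30 cages (not averaged per density). Proportional attrition
gives M = 1 exactly, so 1 is the neutral value; for the condition slope
(ln CI on ln D₀) the neutral value is 0. Both statistics are invariant to
multiplicative unit changes of either axis, which is why density can be
used on both axes even where a count appears in one formulation. Cages with
zero end density are excluded (log undefined) with a warning; at least
three usable cages are required, and a run without usable condition data is
reported "unavailable" rather than failing. Classification uses a
two-sided t-test against the neutral value at α = 0.05 (configurable); OLS
standard errors are used, since nothing heavier is warranted at n = 30.
A fit with numerically zero residual variance (se below 1e-10) is treated
as exact: the classification then follows the sign of M − threshold alone.

The seasonal profile orders the slopes by run start date. "Bell-shaped" is
operationalized as a negative quadratic coefficient of M against run order
(with its OLS SE); the peak run is the argmax of M. This is this package's
operationalization of a qualitative claim, not a canonical statistic.

## The synthetic-data generator

The generator's defaults reproduce the design and conditions of the study
year the package models; they are the conditions under which all recovery
studies run.

**Environment.** One year of 10-minute data. Each channel is a smooth
seasonal curve plus stationary AR(1) noise (correlation time 0.5 days;
marginal SDs 0.6 °C, 0.2 µg l⁻¹, 0.7 FTU). The default seasonal curves are
periodic cubic splines through anchors at the seven run-window means of the
study year. A plain sinusoid cannot represent that year: its two
late-winter runs were measured in different calendar years only two weeks
apart on the day-of-year axis and differ by 6.6 °C, implying a spring
warming slope no annual sinusoid achieves — the anchored spline carries
that asymmetry, and a sinusoid remains available as a configurable shape
(mean 11 °C, range 20 °C, peak day 224). Turbidity additionally carries
storm spikes inside a winter window (day 305 through day 90): a Poisson
process at 0.8 storms/day of gamma-distributed amplitude (mean 4.5 FTU,
shape 4) with exponential decay (0.6 days), contributing ≈ 2.2 FTU to
deep-winter window means; the winter turbidity anchors are baseline values
with that expected contribution removed. Chlorophyll's spring bloom is
encoded in the anchors themselves; an optional extra Gaussian pulse is off
by default. Many small storms rather than few large ones keep the
between-window variability close to the observed 95% CIs, which is what the
envelope test asserts.

**Cage outcomes.** N₀ comes from the biomass-to-count relation
round(D₀ · area · 1000 / W₀) with the run's mean start weight; the rounding
is round-to-nearest, which reproduces all ten printed per-plot counts of
the design (155.7 → 156 requires it). The 22-day survival probability p*
is the inverse logit of the survival predictor (density on the kg m⁻²
treatment scale, where the published coefficients produce plausible logit
ranges). Deaths are drawn beta-binomially: a latent cage mortality from a
Beta with pairwise correlation ρ, then a binomial draw. At common N this
gives the quasi-binomial variance exactly, φ = 1 + (N−1)ρ; the default ρ
is calibrated so φ = 17.37 at the design's mean cage size. This mechanism
is an assumption — the analysis side estimates only a single dispersion —
and ρ is fully configurable. The 22-day deaths are rescaled to the run's
duration (constant daily rate, rounded to whole individuals, capped at N₀);
a configurable recounting-error rate (default 3%) occasionally perturbs
N₁ above N₀ to exercise the clamping rule. End density is computed from
count attrition only; individual weight change is not simulated, because
the survival model and the slope statistics need density bookkeeping, not
growth in weight.

An optional density×temperature coefficient (default 0) makes the density
effect itself seasonal; `recovery.bell_shape_config` uses
0.02 + 0.008 (Temp − 11 °C), giving competition in the coldest run and
strong facilitation in summer — the configuration behind the bell-shaped
profile study. The magnitudes were chosen so that both regimes are clearly
expressed at n = 30 cages without driving whole winter runs extinct.

**Condition and PtoA.** Condition indices are lognormal around the fitted
condition model (default residual SD 0.2 on the log scale, a ~20%
coefficient of variation typical of bivalve condition data); the analogous
PtoA sampler (log SD 0.15) carries the fitted patch-shape model so its
coefficients can be recovered by refitting. Cover masks are generated
separately and phenomenologically: a union of filled discs whose radius
grows with density, so clumps coalesce into larger, smoother patches and
the measured PtoA declines with density. Masks carry geometry, the sampler
carries covariate structure; no attempt is made to make one encode the
other.

**What the generator does not emulate.** No hydrodynamic or
individual-based movement model, no predation (the experiment excluded
predators), no recruitment, no within-run temporal structure in mortality
beyond the constant rate, no food-quality effects. Passing the recovery
studies therefore shows that the estimators are correct under the assumed
generating process, not that the process itself is the true field
mechanism.

## Patch geometry

Patches are 8-connected components (physical contact includes diagonal
touching; connectivity is configurable). Area is the foreground pixel count
times the squared calibration (default reference: a 153 mm marker).
Perimeter uses the marching-squares boundary polygon with weighted segment
lengths — straight segments 0.985, diagonal corner segments 0.665 —
calibrated by least squares over analytic discs, axis-aligned squares and
rotated squares. Accuracy: within ~2.6% for discs (r ≥ 16 px) and
axis-aligned squares (side ≥ 32 px); worst case ~6% under-estimation for
edges at exactly 45°. Naive pixel-edge counting (up to +27% on smooth
boundaries) and the pure Crofton estimator (−6% on axis-aligned squares)
both fail one of those regimes, which motivated the calibrated weights.
PtoA is total perimeter over total area per cage, matching one value per
cage rather than a per-patch average. Interior hole boundaries are included
by default (`include_holes=False` fills holes first); whether a hand-traced
"circumference" includes holes is genuinely ambiguous, so the choice is
exposed.

## Simulation studies and problem sizes

`musselpatch.recovery` packages the three standard studies: survival-model
recovery (default 100 replicate years × 210 cages — the scale at which
Monte-Carlo SEs of the mean estimates are an order of magnitude below the
coefficients), common-N dispersion recovery (N = 500, 100 × 210 cages,
exact theoretical target 17.37), and ratio-model recovery (50 replicates).
The seasonal bell study uses 100 replicate years. All studies spawn their
randomness from one integer seed via `numpy.random.SeedSequence`.

## Pipeline

`simulate → metrics → fit → slopes → report`, orchestrated by
`run_pipeline` and the `musselpatch` CLI. One global seed spawns
deterministic per-stage child seeds, so stages re-run in isolation
reproduce a full run bit for bit; every CSV carries a header and a
format-version comment line, masks are single-channel PNGs with a JSON
calibration sidecar, and each run writes a manifest (config digest, seed,
stage outputs, timestamps). A failed stage is recorded and downstream
stages are skipped. Densities are stored in kg m⁻² (treatment scale)
throughout the cage tables, with counts alongside, to keep the two density
notions from blurring in files.

## Known limitations

* The beta-binomial overdispersion mechanism and its ρ calibration are
  modelling choices, not observed facts; only the resulting dispersion is
  anchored to an empirical value.
* The constant-death-rate standardization right-censors total-mortality
  cages in runs longer than 22 days (see above); coefficient recovery is
  accurate to a few percent, not exact.
* The 22-day horizon is a convention kept as a default parameter, not a
  hard-coded constant.
* The perimeter estimator trades exactness on any single shape family for
  uniform few-percent accuracy across shapes; masks digitized by hand in
  other tools will not be reproduced bit-exactly.
* The temperature-direction rule and the concavity indicator are explicit
  operationalizations of qualitative field notions; both are configurable
  and flagged as assumptions.
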