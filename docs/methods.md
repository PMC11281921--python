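# Methods

`luxepi` re-implements, as a tested and reusable pipeline, an
epidemiological analysis linking personal light-exposure patterns measured
by wrist-worn sensors to the incidence of type 2 diabetes: construction of
24-hour light profiles, simulation of a light-driven circadian pacemaker
model, derivation of exposure groups and polygenic risk scores, and Cox
proportional-hazards estimation at tiered covariate adjustment. Because the
underlying cohort data are access-restricted, a synthetic-cohort generator
is a first-class component: it defines the statistical conditions under
which every downstream stage is validated.

## Light profiles and exposure windows

A participant-week of illuminance (lux, ≥0) with a per-epoch wear flag is
cleaned by *dropping* non-wear epochs (never zero-filling them), then
pooled into 48 half-hour clock-time bins: bin *k* covers
[*k*·30 min, (*k*+1)·30 min) of the 24-h wall clock (bin 0 starts at
midnight), and a bin mean aggregates all epochs of the week whose clock
time falls in it. Wall-clock time is used without daylight-saving
adjustment within the week; all bin intervals are half-open.

Day-light and night-light exposures are the pooled (count-weighted) epoch
means over two clock-time windows. By default the windows are fixed at
07:30–20:30 (day, 26 bins) and 00:30–06:00 (night, 11 bins). Alternatively
the windows can be derived from the data: a two-factor model
(`sklearn.decomposition.FactorAnalysis`, varimax rotation) is fitted to
log(lux+1)-transformed bin means across participants (requiring ≥480
participants, i.e. 10× the bin count), each bin is assigned to the factor
with the larger absolute loading (ties to the day factor), and the largest
contiguous clock arc per factor becomes the window — the arc containing
12:00 labeled day, the arc containing 03:00 labeled night. The log
transform tames the extreme skew of lux data; rotation is configurable.

Participant-level QC is explicit and configurable because the source
study's exact cleaning rules are not public: a participant passes when
they have at least `min_days` (default 3) distinct days of data *and*
every one of the 48 bins has at least `min_bin_coverage` (default 1)
epochs. Decisions are logged per participant.

## The circadian pacemaker model

Circadian phase and amplitude are estimated by forcing a limit-cycle
oscillator model of the human central pacemaker with the week of light.
The model is the classic two-stage formulation (Process L photic
transduction feeding a van-der-Pol-type oscillator):

    dn/dt  = 60 [ α(I)(1−n) − βn ],        α(I) = α₀ (I/I₀)^p
    B      = G α(I) (1−n) (1−0.4x)(1−0.4x_c)
    dx/dt  = (π/12) [ x_c + B ]
    dx_c/dt= (π/12) { μ [x_c − (4/3)x_c³] − x [ (24/(f τ_x))² + kB ] }

with defaults τ_x = 24.2 h, μ = 0.13, k = 0.55, G = 33.75,
α₀ = 0.05 min⁻¹, β = 0.0075 min⁻¹, p = 0.5, I₀ = 9500 lx, f = 0.99669 —
the published constants of the model family this implementation follows.
All constants are configuration, not logic.

Numerics: fixed-step 4th-order Runge–Kutta at dt = 1 min (any dt ≤ 0.05 h
dividing the epoch length is accepted), light held piecewise-constant per
epoch, `n` clamped to [0,1], divergence (|x| > 10) raised as an error.
Model input must be a complete forcing series, so non-wear gaps shorter
than 2 h are linearly interpolated and longer gaps set to 0 lx (long gaps
are most plausibly sleep or an unworn device in the dark).

Initial conditions are handled by *entrainment to the week*: the weekly
pattern is repeated end-to-end until the circular-mean phase changes by
less than 0.1 h between successive weeks (at most 10 weeks); the final
week is analyzed and non-convergence (e.g. free-run in darkness) is
flagged rather than fatal. In darkness the free-running inter-minimum
interval reproduces τ_x within 0.1 h; light pulses before the minimum of
x delay phase, pulses after it advance phase, and light centered on the
minimum suppresses amplitude — these qualitative properties are enforced
by the test suite since no numeric reference values are available.

Phase is reported per cycle as the clock time of each local minimum of x
(parabolic refinement on the integration grid, plus a configurable CBTmin
offset, default 0 — the offset only translates phases and cancels in the
centered-quintile analysis). Cycles are delimited by successive x-minima,
not calendar days. Amplitude per cycle is the cycle-mean radial distance
r = √(x² + x_c²) — the model's natural phase-amplitude radius; the source
analysis does not define its amplitude functional, so this choice is ours
and is documented rather than asserted. Weekly summaries are the circular
mean and circular SD (√(−2 ln R)·24/2π hours) of the per-cycle phases and
the mean/min/max of per-cycle amplitudes.

## Exposure derivation

Continuous exposures become analysis variables as follows. Light exposures
are grouped into percentile ranges 0–50 / 50–70 / 70–90 / 90–100 with
thresholds from linear-interpolation empirical quantiles; assignment is by
half-open [lower, upper) intervals, ties joining the upper group and the
maximum included in the top group. Phase is handled circularly: signed
deviations from the sample circular mean are wrapped into (−12, 12] h and
split into quintiles whose central 40–60% band (containing the mean) is
the referent. Amplitude and phase-variability predictors are z-scored
(population SD) so hazard ratios are per SD. Polygenic risk scores are the
weighted dosage sum S_i = Σ_j β̂_j g_ij over aligned SNP columns, split
into quartiles with the same quantile conventions.

## Survival analysis

Hazard ratios are estimated by Cox proportional-hazards regression on the
follow-up timescale with Efron tie handling (lifelines `CoxPHFitter`,
Newton precision tightened to 1e−10 so coefficients are optimizer-grade),
categorical exposures dummy-coded against their referent, Wald 95% CIs and
p-values. Three nested covariate tiers mirror the usual adjustment ladder:
Model 1 — age, sex, ethnicity; Model 2 — plus income, material
deprivation, education, employment; Model 3 — plus smoking, alcohol,
diet, physical activity, urbanicity. Complete-case rows per tier; per-tier
n and event counts are reported. The proportional-hazards assumption is
checked by the scaled Schoenfeld-residual test against rank time, with a
Bonferroni combination of per-covariate p-values standing in for a global
statistic. Crude incidence is reported per 1000 person-years. Interaction
terms are supported generically through the model specification;
competing-risk (Fine–Gray) models are out of scope.

## The synthetic cohort

The light generator emulates one week of wrist-sensor data at 60-s epochs
(any divisor of 1800 s is accepted): participant-level log-normal day
illuminance (log-mean 4.5 ≈ 90 lx, log-SD 0.8), a night regime in which a
`night_dark_fraction` (default 0.6) of participants stay below 1 lx
(log-mean −3) while the remainder form a bright-night subpopulation
(log-mean 1.6 ≈ 5 lx, log-SD 1.0), steep logistic switches between the
regimes at 07:00 and 22:30 (lights-on/lights-off), log-normal epoch noise,
and Poisson non-wear gaps of 0.5–3 h. Assigning bright nights at the
participant level reproduces the strongly skewed night-light distribution
(majority <1 lx) that makes the 0–50% percentile group a dark referent.
The generator does not model sensor saturation, spectral weighting, or
seasonal photoperiod change, so passing tests say nothing about those
aspects of real recordings.

Survival outcomes are exponential (constant-hazard) event times under a
proportional-hazards model — the simplest PH-consistent choice, since no
baseline-shape information is available — with participant log-hazard =
log(baseline rate) + group effect + covariate effects, administrative
censoring at the follow-up horizon for everyone and optional exponential
mortality censoring. Group sizes follow configured proportions exactly
(largest-remainder apportionment, membership permuted). The cohort
generator defaults to the study scale: ~3 events per 1000 person-years
over 8 years in cohorts of ~85,000; the pipeline's small demo config
instead defaults to an inflated rate (0.05/person-year) so that every
exposure level carries events at demo n. All generators are
bit-reproducible: per-participant RNG substreams derive from
(seed, participant index).

PRS inputs are Hardy–Weinberg Binomial(2, p) dosages with per-SNP allele
frequencies uniform on (0.05, 0.95) and N(0, 0.1) effect weights.

## Recovery experiments

Published hazard ratios from the source cohort cannot be reproduced at
desk scale, so validation is by parameter recovery: cohorts are generated
with the published values as true effects (night-light Model 3 groups
1.29/1.39/1.53 at proportions 50/20/20/10; day-light Model 1 groups
0.97/0.84/0.73; per-SD minimum-amplitude effect 0.93; PRS-only Model 1
quartiles 1.69/2.55/4.68 at equal proportions, n = 80,000), the Cox model
is refitted, and the median estimate over 60 independent cohorts must fall
within ±0.05 (group HRs), ±0.02 (per-SD HR) or ±0.15 (PRS top quartile)
of truth, with every per-cohort estimate within 3 SE. Sixty repeats keep
3× the Monte-Carlo SD of the median (≈1.25·SE/√k) inside those bands.
`scripts/acceptance.py` runs exactly these experiments.

## Known limitations

- The pacemaker equations and constants follow the published model family;
  the source study's exact supplementary formulation may differ in detail.
  The formulation is configurable but only this variant is implemented.
- Circular SD is used for phase variability; a study using linear SD would
  differ for highly dispersed phases.
- The synthetic covariates are mutually independent, so covariate-adjusted
  tiers exercise the machinery but not confounding structure.
- Factor-derived windows assume the two dominant variance sources are day
  and night light levels; cohorts whose evening light varies independently
  may need a third factor, which is not implemented.
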