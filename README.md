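# luxepi

Light exposure at night disrupts the central circadian pacemaker, and
circadian disruption is a risk factor for type 2 diabetes. `luxepi` is a
reusable Python pipeline for testing that link in cohorts with wrist-worn
light sensors: it turns a week of personal illuminance data into day- and
night-light exposures and model-based circadian phase/amplitude estimates,
and relates them — together with polygenic risk — to incident disease via
Cox proportional-hazards models. Because cohort-scale sensor data are
typically access-restricted, the package ships a synthetic-cohort
generator that reproduces the statistical structure of such studies, so
every stage is testable end to end.

It is aimed at circadian/sleep epidemiologists and biostatisticians who
want an auditable implementation of this analysis or a simulation bench
for planning similar studies.

## What it computes

- **Light profiles.** Non-wear epochs are dropped, the week is pooled into
  48 half-hour clock-time bins, and exposures are pooled epoch means over
  a day window (07:30–20:30) and a night window (00:30–06:00) — fixed, or
  derived by two-factor analysis of the bin profiles.
- **Circadian modeling.** The weekly lux series forces the classic
  two-stage pacemaker model (Process L photic transduction
  dn/dt = 60[α(I)(1−n) − βn] with α(I) = α₀(I/I₀)^p, driving a
  van-der-Pol-type oscillator in (x, x_c)). Phase per cycle is the clock
  time of the x-minimum (the predicted core-body-temperature minimum);
  amplitude per cycle is the mean radius √(x² + x_c²). Weekly summaries
  use circular statistics.
- **Exposure derivation.** Percentile groups (0–50/50–70/70–90/90–100,
  half-open bins, referent 0–50%), circadian-phase quintiles centered at
  the sample circular mean, z-scored amplitude/phase-variability, and
  polygenic risk scores S_i = Σ_j β̂_j g_ij with quartiles.
- **Survival analysis.** Cox PH (Efron ties) at three covariate tiers,
  hazard ratios with Wald 95% CIs, incidence rates per 1000 person-years,
  and scaled Schoenfeld proportional-hazards checks.

## Worked example

Run the whole pipeline on a small synthetic cohort (the `luxepi run-all`
CLI accepts the same settings as a YAML `--config` file):

```python
from luxepi.pipeline import run_pipeline

artifacts = run_pipeline(
    {
        "seed": 123,
        "synthetic": {"n_participants": 200, "epoch_seconds": 300, "n_snps": 30},
        "circadian": {"dt": 1 / 24, "max_weeks": 5},
        "outcome": {"baseline_rate": 0.05},
        "models": [{"tier": 1, "predictors": ["night_group", "day_group"]}],
    },
    out_dir="demo",
)
print(artifacts["report"])
```

which prints:

```
Cohort: 200 participants, 61 events, 1345 person-years (45.36 cases per 1000 person-years)

Model 1 (N = 200; events = 61)
 night_group
  0-50%                           -        -   cases 24.00% (24)
  50-70%       1.61 [0.80-3.23]     p=0.18   cases 32.50% (13)
  70-90%       1.91 [1.00-3.63]     p=0.049   cases 40.00% (16)
  90-100%      2.26 [1.00-5.10]     p=0.051   cases 40.00% (8)
 day_group
  0-50%                           -        -   cases 24.00% (24)
  50-70%       2.27 [1.21-4.27]     p=0.011   cases 47.50% (19)
  70-90%       1.33 [0.65-2.74]     p=0.43   cases 30.00% (12)
  90-100%      1.41 [0.56-3.55]     p=0.46   cases 30.00% (6)
```

Each block is one adjustment tier; rows are exposure levels with the
referent marked "-", the hazard ratio with its 95% CI and p-value, and
the case percentage and count per level. The generator's true night-light
hazard ratios here are 1.29/1.39/1.53 and the estimated dose–response is
monotone, though at this demo size (and an event rate inflated so every
level carries events) the CIs are wide; the recovery experiments below do
the same comparison at cohort scale. The run directory also contains every
intermediate
as CSV: per-participant light recordings, `exposures.csv`,
`circadian.csv` (phase and amplitude summaries), `cohort.csv`,
`hazards.csv` and `report.txt`.

Stages can be run individually (`luxepi simulate`, `process-light`,
`circadian`, `derive`, `fit`, `report`) against the same run directory.

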