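"""Synthetic cohort generators for light recordings, covariates, PRS inputs
and survival outcomes.

The light generator emulates a one-week wrist-sensor recording: log-normally
distributed daytime illuminance, a mostly dark (<1 lx) night with a
participant-level bright-night subpopulation, dawn/dusk crossfades between
the two regimes, and non-wear gaps.  The cohort generator draws event times
from an exponential proportional-hazards model so that configured hazard
ratios are the ground truth the downstream Cox models should recover.

Every generator is reproducible bit-for-bit from its config seed; per
participant substreams are derived from ``(seed, participant index)`` so
results do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .light import LightRecording

#: Recording start (a Monday, local midnight); arbitrary but fixed so that
#: clock-time structure is deterministic.
_START = np.datetime64("2015-01-05T00:00:00", "s")

# Clock hours at which the generated light regime switches between the
# participant's night level and day level (lights-on / lights-off), with a
# steep logistic crossfade.  The day regime spans [07:00, 22:30) so that the
# analysis plateau windows (day 07:30-20:30, night 00:30-06:00) sit strictly
# inside the day- and night-signal regions.
_LIGHTS_ON, _LIGHTS_OFF = 7.0, 22.5
_RAMP_H = 0.1  # logistic time scale of the regime switch


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class LightGenConfig:
    """Configuration of the synthetic weekly light-recording generator.

    Illuminance levels are specified on the natural-log lux scale.
    ``night_dark_fraction`` of participants spend the night window below
    1 lx; the remainder form the bright-night subpopulation with their own
    participant-level log-lux draw.
    """

    n_participants: int = 100
    days: int = 7
    epoch_seconds: int = 60
    day_lux_log_mean: float = 4.5  # ~90 lx median daytime wrist illuminance
    day_lux_log_sd: float = 0.8
    night_dark_fraction: float = 0.6
    night_bright_lux_log_mean: float = 1.6  # ~5 lx median for bright nights
    night_bright_lux_log_sd: float = 1.0
    dark_night_lux_log_mean: float = -3.0  # ~0.05 lx
    dark_night_lux_log_sd: float = 0.5
    epoch_lux_log_sd: float = 0.4
    nonwear_gap_rate: float = 0.5  # gaps per day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days <= 0 or self.epoch_seconds <= 0:
            raise ConfigError("days and epoch_seconds must be positive")
        if 1800 % self.epoch_seconds != 0:
            raise ConfigError("epoch_seconds must divide 1800 (half-hour bins)")
        if not 0.0 <= self.night_dark_fraction <= 1.0:
            raise ConfigError("night_dark_fraction must be in [0, 1]")
        if self.nonwear_gap_rate < 0:
            raise ConfigError("nonwear_gap_rate must be >= 0")

    @property
    def day_signal_bins(self) -> frozenset:
        """Half-hour bins governed by the participant's day light level."""
        return frozenset(
            k for k in range(48)
            if k * 0.5 >= _LIGHTS_ON and (k + 1) * 0.5 <= _LIGHTS_OFF
        )

    @property
    def night_signal_bins(self) -> frozenset:
        """Half-hour bins governed by the participant's night light level."""
        return frozenset(range(48)) - self.day_signal_bins


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_light_recording(cfg: LightGenConfig, participant_id: int) -> LightRecording:
    """Generate one participant-week of synthetic light data.

    Parameters
    ----------
    participant_id : int
        Participant index; the output id is ``P{index:05d}`` and the RNG
        substream is derived from ``(cfg.seed, index)``.
    """
    rng = _participant_rng(cfg.seed, participant_id)
    n = cfg.days * 86400 // cfg.epoch_seconds
    timestamps = _START + (np.arange(n) * cfg.epoch_seconds).astype("timedelta64[s]")
    t = (np.arange(n) * cfg.epoch_seconds % 86400) / 3600.0  # clock hours

    day_level = rng.normal(cfg.day_lux_log_mean, cfg.day_lux_log_sd)
    dark_night = rng.random() < cfg.night_dark_fraction
    if dark_night:
        night_level = cfg.dark_night_lux_log_mean
        night_sd = cfg.dark_night_lux_log_sd
    else:
        night_level = rng.normal(
            cfg.night_bright_lux_log_mean, cfg.night_bright_lux_log_sd
        )
        night_sd = cfg.epoch_lux_log_sd

    # Weight toward the day level: ~1 between lights-on and lights-off,
    # ~0 otherwise, with a steep logistic switch at the boundaries.
    from scipy.special import expit

    w = expit((t - _LIGHTS_ON) / _RAMP_H) * expit((_LIGHTS_OFF - t) / _RAMP_H)
    sd = np.where(w < 0.5, night_sd, cfg.epoch_lux_log_sd)
    loglux = w * day_level + (1.0 - w) * night_level + rng.normal(0.0, 1.0, n) * sd
    lux = np.exp(loglux)

    wear = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(cfg.nonwear_gap_rate * cfg.days)
    total_h = cfg.days * 24.0
    for _ in range(n_gaps):
        start = rng.uniform(0.0, total_h)
        length = rng.uniform(0.5, 3.0)
        i0 = int(start * 3600 // cfg.epoch_seconds)
        i1 = min(n, int((start + length) * 3600 // cfg.epoch_seconds))
        wear[i0:i1] = False

    return LightRecording(
        participant_id=f"P{participant_id:05d}",
        timestamps=timestamps,
        lux=lux,
        wear=wear,
    )


def generate_toy_light(
    pattern: str,
    lux: float = 1000.0,
    on_hour: float = 8.0,
    off_hour: float = 20.0,
    pulse_hour: float = 4.0,
    pulse_duration_h: float = 1.0,
    days: int = 7,
    epoch_seconds: int = 60,
    participant_id: str = "toy",
) -> LightRecording:
    """Noiseless light fixtures: ``square_wave``, ``dark``, or ``pulse``.

    ``square_wave`` emits ``lux`` during clock hours ``[on_hour, off_hour)``
    and 0 otherwise; ``pulse`` is dark except one block per day starting at
    ``pulse_hour``.
    """
    n = days * 86400 // epoch_seconds
    timestamps = _START + (np.arange(n) * epoch_seconds).astype("timedelta64[s]")
    t = (np.arange(n) * epoch_seconds % 86400) / 3600.0
    if pattern == "dark":
        values = np.zeros(n)
    elif pattern == "square_wave":
        values = np.where((t >= on_hour) & (t < off_hour), float(lux), 0.0)
    elif pattern == "pulse":
        end = pulse_hour + pulse_duration_h
        if end <= 24.0:
            on = (t >= pulse_hour) & (t < end)
        else:  # wraps past midnight
            on = (t >= pulse_hour) | (t < end - 24.0)
        values = np.where(on, float(lux), 0.0)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return LightRecording(
        participant_id=participant_id,
        timestamps=timestamps,
        lux=values,
        wear=np.ones(n, dtype=bool),
    )


@dataclass
class CohortGenConfig:
    """Configuration of the synthetic survival-cohort generator.

    Event times are exponential with participant rate
    ``baseline_rate * exp(true_log_hr[level] + sum covariate effects)``,
    right-censored administratively at ``follow_up_years`` and optionally by
    exponential mortality at ``censor_mortality_rate``.
    """

    n_participants: int = 1000
    follow_up_years: float = 8.0
    baseline_rate: float = 0.003  # events per person-year in the referent
    true_log_hr: dict = field(default_factory=dict)  # level -> log HR
    group_proportions: dict = field(default_factory=lambda: {"ref": 1.0})
    censor_mortality_rate: float = 0.0
    covariate_effects: dict = field(default_factory=dict)  # column -> log HR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0 or self.follow_up_years <= 0:
            raise ConfigError("baseline_rate and follow_up_years must be > 0")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"group proportions sum to {total}, not 1")
        unknown = set(self.true_log_hr) - set(self.group_proportions)
        if unknown:
            raise ConfigError(f"true_log_hr levels not in group_proportions: {unknown}")


def _exact_group_sizes(proportions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n participants to groups."""
    levels = list(proportions)
    raw = np.array([proportions[g] * n for g in levels])
    sizes = np.floor(raw).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    return dict(zip(levels, sizes))


# Standardization used when applying covariate_effects, so a configured log
# hazard ratio is per SD (continuous) or per category step (coded) exactly.
_COVARIATE_SCALE = {
    "age": (62.3, 7.9),
    "deprivation": (-1.78, 2.78),
    "alcohol": (3.0, 2.5),
    "physical_activity": (28.4, 8.05),
}


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline covariate table with distributions typical of an older
    community cohort (ages ~62 +/- 8, mostly white, urban)."""
    return pd.DataFrame(
        {
            "age": rng.normal(62.3, 7.9, n).clip(43.0, 80.0),
            "sex": rng.choice(["female", "male"], n, p=[0.58, 0.42]),
            "ethnicity": rng.choice(["white", "other"], n, p=[0.97, 0.03]),
            "income": rng.integers(1, 6, n),
            "deprivation": rng.normal(-1.78, 2.78, n),
            "education": rng.choice(
                ["none", "other", "university"], n, p=[0.08, 0.48, 0.44]
            ),
            "employment": rng.choice([0, 1], n, p=[0.37, 0.63]),
            "smoking": rng.choice(
                ["never", "previous", "current"], n, p=[0.578, 0.355, 0.067]
            ),
            "alcohol": rng.uniform(0.0, 7.0, n),
            "diet_healthy": rng.choice([0, 1], n, p=[0.74, 0.26]),
            "physical_activity": rng.normal(28.4, 8.05, n).clip(4.0, 70.0),
            "urbanicity": rng.choice([0, 1], n, p=[0.16, 0.84]),
        }
    )


def _covariate_log_hazard(df: pd.DataFrame, effects: dict) -> np.ndarray:
    lhr = np.zeros(len(df))
    for col, beta in effects.items():
        if col not in df.columns:
            raise ConfigError(f"covariate_effects references unknown column {col!r}")
        x = df[col]
        if col in _COVARIATE_SCALE:
            mean, sd = _COVARIATE_SCALE[col]
            z = (x.to_numpy(dtype=float) - mean) / sd
        elif x.dtype == object:
            z = pd.factorize(x, sort=True)[0].astype(float)
        else:
            z = x.to_numpy(dtype=float)
        lhr += beta * z
    return lhr


def simulate_survival(
    log_hazard: np.ndarray,
    baseline_rate: float,
    follow_up_years: float,
    rng: np.random.Generator,
    censor_mortality_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, status) under exponential proportional hazards.

    ``status`` is 1 when the event precedes both mortality and the
    administrative end of follow-up.
    """
    n = len(log_hazard)
    rate = baseline_rate * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if censor_mortality_rate > 0:
        t_mort = rng.exponential(1.0 / censor_mortality_rate, n)
    else:
        t_mort = np.full(n, np.inf)
    t_cens = np.minimum(t_mort, follow_up_years)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    # Cox requires strictly positive durations.
    return np.maximum(time, 1e-8), status


def generate_cohort(cfg: CohortGenConfig) -> pd.DataFrame:
    """Generate a cohort table with group labels, covariates and outcomes.

    Group sizes follow ``group_proportions`` exactly (largest-remainder
    apportionment) with membership randomly permuted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    n = cfg.n_participants
    sizes = _exact_group_sizes(cfg.group_proportions, n)
    labels = np.repeat(list(sizes), list(sizes.values()))
    rng.shuffle(labels)

    df = _simulate_covariates(rng, n)
    df.insert(0, "participant_id", [f"P{i:05d}" for i in range(n)])
    df["group"] = labels

    lhr = np.array([cfg.true_log_hr.get(g, 0.0) for g in labels])
    lhr = lhr + _covariate_log_hazard(df, cfg.covariate_effects)
    time, status = simulate_survival(
        lhr, cfg.baseline_rate, cfg.follow_up_years, rng, cfg.censor_mortality_rate
    )
    df["time"] = time
    df["status"] = status
    return df


def generate_prs_inputs(
    n_participants: int,
    n_snps: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.95),
    beta_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a SNP effect-weight table and a genotype dosage matrix.

    Dosages are Binomial(2, p) counts of the effect allele under
    Hardy-Weinberg equilibrium with per-SNP allele frequency p drawn
    uniformly from ``maf_range``; weights are N(0, beta_sd).

    Returns
    -------
    weights : DataFrame with columns ``snp_id``, ``effect_allele``, ``beta``.
    dosages : DataFrame (participants x SNPs) indexed by participant_id.
    """
    if n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**21]))
    snp_ids = [f"rs{j:06d}" for j in range(n_snps)]
    freqs = rng.uniform(*maf_range, n_snps)
    weights = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": rng.choice(list("ACGT"), n_snps),
            "beta": rng.normal(0.0, beta_sd, n_snps),
        }
    )
    dosages = pd.DataFrame(
        rng.binomial(2, freqs, size=(n_participants, n_snps)),
        columns=snp_ids,
        index=pd.Index([f"P{i:05d}" for i in range(n_participants)], name="participant_id"),
    )
    return weights, dosages
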