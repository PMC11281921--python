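"""Light-recording cleaning, half-hour clock-time profiles, and exposure windows.

A participant-week of wrist-sensor illuminance is reduced to a 48-bin
24-hour profile (bin ``k`` covers clock time ``[k*30min, (k+1)*30min)``,
bin 0 starting at midnight), from which day-light and night-light exposure
means are computed over fixed or factor-derived clock-time windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 48
BIN_HOURS = 0.5

#: Fixed day window 07:30-20:30 -> bins [15, 41); night window 00:30-06:00
#: -> bins [1, 12).  Half-open on the right.
DAY_WINDOW_BINS = frozenset(range(15, 41))
NIGHT_WINDOW_BINS = frozenset(range(1, 12))


class LightFormatError(ValueError):
    """Malformed light CSV input."""


class EmptyRecordingError(ValueError):
    """No wear epochs available for aggregation."""


class FactorAnalysisError(RuntimeError):
    """Exposure-window factor analysis failed or was degenerate."""


@dataclass
class LightRecording:
    """Timestamped illuminance samples with wear flags for one participant.

    Attributes
    ----------
    participant_id : str
    timestamps : np.ndarray of datetime64[s], strictly increasing
    lux : np.ndarray of float, illuminance per epoch (>= 0 where worn)
    wear : np.ndarray of bool
    """

    participant_id: str
    timestamps: np.ndarray
    lux: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.lux = np.asarray(self.lux, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        n = len(self.timestamps)
        if len(self.lux) != n or len(self.wear) != n:
            raise ValueError("timestamps, lux and wear must have equal length")
        if n > 1 and not (np.diff(self.timestamps.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.lux[self.wear] < 0):
            raise ValueError("negative lux in worn epochs")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def clock_hours(self) -> np.ndarray:
        """Clock time of each epoch as fractional hours in [0, 24)."""
        secs = self.timestamps.astype("int64")
        return (secs % 86400) / 3600.0

    @property
    def epoch_seconds(self) -> int:
        if len(self) < 2:
            raise ValueError("need >= 2 epochs to infer epoch length")
        return int(np.diff(self.timestamps.astype("int64")).min())


@dataclass
class LightProfile:
    """48 half-hour clock-time bin means plus coverage metadata."""

    participant_id: str
    bin_means: np.ndarray  # NaN where bin_counts == 0
    bin_counts: np.ndarray
    valid_days: int

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if self.bin_means.shape != (N_BINS,) or self.bin_counts.shape != (N_BINS,):
            raise ValueError(f"profiles have exactly {N_BINS} bins")
        if (self.bin_counts < 0).any():
            raise ValueError("bin_counts must be >= 0")


@dataclass
class ExposureWindows:
    """Disjoint sets of half-hour bin indices defining day and night."""

    day_window: frozenset = field(default_factory=lambda: DAY_WINDOW_BINS)
    night_window: frozenset = field(default_factory=lambda: NIGHT_WINDOW_BINS)

    def __post_init__(self) -> None:
        self.day_window = frozenset(self.day_window)
        self.night_window = frozenset(self.night_window)
        if not self.day_window or not self.night_window:
            raise ValueError("windows must be non-empty")
        if self.day_window & self.night_window:
            raise ValueError("day and night windows must be disjoint")


@dataclass
class ExposureSummary:
    """Mean day-light and night-light exposure for one participant."""

    participant_id: str
    day_lux: float
    night_lux: float
    qc_pass: bool


def read_light_csv(path) -> LightRecording:
    """Read a light CSV (columns ``timestamp``, ``lux``, ``wear``).

    Raises :class:`LightFormatError` with the offending row number for
    unparseable timestamps or negative lux values.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "lux", "wear"}
    missing = required - set(df.columns)
    if missing:
        raise LightFormatError(f"missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0]) + 2  # header is line 1
        raise LightFormatError(f"unparseable timestamp at line {row}")
    lux = pd.to_numeric(df["lux"], errors="coerce")
    if lux.isna().any():
        row = int(np.flatnonzero(lux.isna())[0]) + 2
        raise LightFormatError(f"unparseable lux at line {row}")
    wear = df["wear"].astype(int).astype(bool).to_numpy()
    if (lux.to_numpy() < 0)[wear].any():
        row = int(np.flatnonzero((lux.to_numpy() < 0) & wear)[0]) + 2
        raise LightFormatError(f"negative lux at line {row}")
    pid = str(df["participant_id"].iloc[0]) if "participant_id" in df else "unknown"
    return LightRecording(
        participant_id=pid,
        timestamps=ts.to_numpy().astype("datetime64[s]"),
        lux=lux.to_numpy(),
        wear=wear,
    )


def write_light_csv(rec: LightRecording, path) -> None:
    """Write a recording in the Light CSV schema (ISO-8601 timestamps)."""
    pd.DataFrame(
        {
            "participant_id": rec.participant_id,
            "timestamp": np.datetime_as_string(rec.timestamps, unit="s"),
            "lux": rec.lux,
            "wear": rec.wear.astype(int),
        }
    ).to_csv(path, index=False)


def mask_nonwear(rec: LightRecording) -> LightRecording:
    """Drop non-wear epochs entirely (no zero-filling)."""
    keep = rec.wear
    return LightRecording(
        participant_id=rec.participant_id,
        timestamps=rec.timestamps[keep],
        lux=rec.lux[keep],
        wear=rec.wear[keep],
    )


def bin_half_hour(rec: LightRecording) -> LightProfile:
    """Pool a (masked) recording into 48 half-hour clock-time bins.

    ``bin_means[k]`` is the arithmetic mean of lux over every epoch of the
    week whose clock time falls in bin ``k``; days are pooled, so one bin
    aggregates up to ``days`` separate half-hours.
    """
    if len(rec) == 0:
        raise EmptyRecordingError(f"{rec.participant_id}: no epochs to bin")
    bins = np.floor(rec.clock_hours / BIN_HOURS).astype(int)
    counts = np.bincount(bins, minlength=N_BINS)
    sums = np.bincount(bins, weights=rec.lux, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    days = rec.timestamps.astype("datetime64[D]")
    return LightProfile(
        participant_id=rec.participant_id,
        bin_means=means,
        bin_counts=counts,
        valid_days=int(len(np.unique(days))),
    )


def _largest_circular_arc(members: np.ndarray) -> set:
    """Largest contiguous run of True values on a circular index set."""
    idx = np.flatnonzero(members)
    if idx.size == 0:
        return set()
    if idx.size == N_BINS:
        return set(range(N_BINS))
    # Walk runs on the doubled circle to handle wrap-around.
    doubled = np.concatenate([members, members])
    best, cur = [], []
    for i in range(2 * N_BINS):
        if doubled[i]:
            cur.append(i % N_BINS)
            if len(cur) > len(best):
                best = list(cur)
            if len(cur) >= N_BINS:
                break
        else:
            cur = []
    return set(best)


def derive_windows(
    bin_matrix: np.ndarray,
    n_factors: int = 2,
    rotation: str = "varimax",
) -> ExposureWindows:
    """Derive day/night windows by factor analysis of pooled light profiles.

    A two-factor model is fitted to log(lux+1)-transformed bin means across
    participants; each bin is assigned to the factor with the larger absolute
    loading (ties to the day factor), and the largest contiguous clock arc
    per factor becomes the window.  The arc containing 12:00 is labeled day
    and the arc containing 03:00 night.

    Parameters
    ----------
    bin_matrix : (n_participants, 48) array of bin means (lux).
    """
    from sklearn.decomposition import FactorAnalysis

    X = np.asarray(bin_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_BINS:
        raise ValueError(f"expected (n, {N_BINS}) matrix")
    if X.shape[0] < 10 * N_BINS:
        raise ValueError(
            f"factor analysis needs >= {10 * N_BINS} participants, got {X.shape[0]}"
        )
    if np.isnan(X).all(axis=0).any():
        raise ValueError("a bin is missing for all participants")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    X = np.log1p(X)
    if np.any(X.std(axis=0) < 1e-12):
        raise FactorAnalysisError(
            "degenerate covariance: at least one bin has (near-)zero variance"
        )
    try:
        fa = FactorAnalysis(n_components=n_factors, rotation=rotation, max_iter=2000)
        fa.fit(X)
    except Exception as exc:  # pragma: no cover - sklearn failure path
        raise FactorAnalysisError(f"factor analysis failed: {exc}") from exc
    loadings = fa.components_  # (n_factors, 48)
    absload = np.abs(loadings[:2])
    # ties (exact equality) go to factor 0; relabeled below by clock anchor
    assign = np.where(absload[1] > absload[0], 1, 0)
    arc0 = _largest_circular_arc(assign == 0)
    arc1 = _largest_circular_arc(assign == 1)
    noon_bin, three_am_bin = 24, 6
    if noon_bin in arc0 or three_am_bin in arc1:
        day_arc, night_arc = arc0, arc1
    elif noon_bin in arc1 or three_am_bin in arc0:
        day_arc, night_arc = arc1, arc0
    else:
        raise FactorAnalysisError(
            "could not label factors: neither arc contains 12:00 or 03:00"
        )
    if not day_arc or not night_arc or (day_arc & night_arc):
        raise FactorAnalysisError("derived windows are empty or overlapping")
    return ExposureWindows(day_window=day_arc, night_window=night_arc)


def summarize_exposure(profile: LightProfile, windows: ExposureWindows) -> ExposureSummary:
    """Count-weighted (pooled-epoch) mean lux over the day and night windows.

    Zero coverage in either window fails QC; the corresponding means are NaN.
    """

    def _pooled(bins: frozenset) -> float:
        idx = np.array(sorted(bins))
        counts = profile.bin_counts[idx]
        if counts.sum() == 0:
            return np.nan
        means = np.where(counts > 0, profile.bin_means[idx], 0.0)
        return float(np.sum(means * counts) / counts.sum())

    day = _pooled(windows.day_window)
    night = _pooled(windows.night_window)
    ok = np.isfinite(day) and np.isfinite(night)
    if not ok:
        logger.info("participant %s: zero window coverage, QC fail", profile.participant_id)
    return ExposureSummary(
        participant_id=profile.participant_id,
        day_lux=day,
        night_lux=night,
        qc_pass=bool(ok),
    )


def qc_participant(
    profile: LightProfile, min_days: int = 3, min_bin_coverage: int = 1
) -> bool:
    """Pass iff >= min_days valid days AND every bin has >= min_bin_coverage epochs."""
    ok = profile.valid_days >= min_days and bool(
        (profile.bin_counts >= min_bin_coverage).all()
    )
    logger.info(
        "participant %s QC %s (valid_days=%d, min bin count=%d)",
        profile.participant_id,
        "pass" if ok else "FAIL",
        profile.valid_days,
        int(profile.bin_counts.min()),
    )
    return ok
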