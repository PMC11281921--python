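"""Analysis-variable derivation: percentile exposure groups, circular phase
quintiles centered at the sample mean, z-scored continuous predictors, and
polygenic risk scores with quartiles.

All groupings use linear-interpolation empirical quantiles and half-open
``[lower, upper)`` intervals: a value equal to a threshold joins the upper
group, and the top group includes the sample maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd


class DegenerateGroupingWarning(UserWarning):
    """All values identical: everyone assigned to the referent group."""


@dataclass
class PercentileGrouping:
    cutpoints: np.ndarray  # percentile boundaries, e.g. (0, 50, 70, 90, 100)
    thresholds: np.ndarray  # exposure values at those percentiles
    labels: list  # group names, ordered
    assignment: np.ndarray  # label per participant


@dataclass
class PhaseQuintiles:
    center: float  # circular mean phase (h)
    deviations: np.ndarray  # signed offsets in (-12, 12]
    boundaries: np.ndarray  # 20/40/60/80th percentiles of deviations
    labels: list
    assignment: np.ndarray
    referent: str = "40-60%"


@dataclass
class PRSResult:
    scores: pd.Series  # participant_id -> S_i
    quartile_assignment: pd.Series  # participant_id -> label


def _group_labels(cutpoints) -> list:
    return [f"{lo:g}-{hi:g}%" for lo, hi in zip(cutpoints[:-1], cutpoints[1:])]


def percentile_groups(values, cutpoints=(0, 50, 70, 90, 100)) -> PercentileGrouping:
    """Assign each value to a percentile range group.

    Thresholds are linear-interpolation empirical quantiles of ``values`` at
    ``cutpoints``; assignment is by half-open intervals, ties to the upper
    group, maximum included in the top group.
    """
    values = np.asarray(values, dtype=float)
    cutpoints = np.asarray(cutpoints, dtype=float)
    if values.size < 10:
        raise ValueError("need >= 10 values for percentile grouping")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if cutpoints[0] != 0 or cutpoints[-1] != 100 or np.any(np.diff(cutpoints) <= 0):
        raise ValueError("cutpoints must increase strictly from 0 to 100")
    labels = _group_labels(cutpoints)
    thresholds = np.quantile(values, cutpoints / 100.0)
    if np.ptp(values) == 0.0:
        warnings.warn(
            "all values identical; assigning everyone to the referent group",
            DegenerateGroupingWarning,
        )
        assignment = np.full(values.shape, labels[0], dtype=object)
    else:
        idx = np.searchsorted(thresholds[1:-1], values, side="right")
        assignment = np.asarray(labels, dtype=object)[idx]
    return PercentileGrouping(
        cutpoints=cutpoints, thresholds=thresholds, labels=labels, assignment=assignment
    )


def circular_mean_phase(phases) -> float:
    """Circular mean of clock times (h), mapped back to [0, 24)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need >= 1 phase")
    rad = phases * (2 * np.pi / 24.0)
    R = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    if R < 1e-12:
        raise ValueError("zero resultant length: circular mean undefined")
    return float(circmean(phases, high=24.0, low=0.0))


def circular_sd_phase(phases) -> float:
    """Circular SD sqrt(-2 ln R) * 24/(2 pi), in hours."""
    return float(circstd(np.asarray(phases, dtype=float), high=24.0, low=0.0))


def wrap_deviation(phases, center) -> np.ndarray:
    """Signed clock-time offsets from ``center``, wrapped into (-12, 12]."""
    d = (np.asarray(phases, dtype=float) - center) % 24.0
    return np.where(d > 12.0, d - 24.0, d)


def phase_quintiles(phases) -> PhaseQuintiles:
    """Quintiles of circadian phase centered at the sample circular mean.

    Deviations from the circular mean are wrapped into (-12, 12]; quintile
    boundaries are the 20/40/60/80th percentiles of the deviations, and the
    40-60% band (which contains the center) is the referent.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 25:
        raise ValueError("need >= 25 phases for quintiles")
    center = circular_mean_phase(phases)
    d = wrap_deviation(phases, center)
    labels = ["0-20%", "20-40%", "40-60%", "60-80%", "80-100%"]
    if np.ptp(d) == 0.0:
        warnings.warn(
            "all phases identical; assigning everyone to the referent quintile",
            DegenerateGroupingWarning,
        )
        boundaries = np.zeros(4)
        assignment = np.full(d.shape, "40-60%", dtype=object)
    else:
        boundaries = np.quantile(d, [0.2, 0.4, 0.6, 0.8])
        idx = np.searchsorted(boundaries, d, side="right")
        assignment = np.asarray(labels, dtype=object)[idx]
    return PhaseQuintiles(
        center=center,
        deviations=d,
        boundaries=boundaries,
        labels=labels,
        assignment=assignment,
    )


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values to z-score")
    sd = values.std()
    if sd == 0.0:
        raise ValueError("zero standard deviation")
    return (values - values.mean()) / sd


def prs_score(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Polygenic score S_i = sum_j beta_j g_ij.

    ``dosages`` columns and ``weights.snp_id`` must match as sets; columns
    are aligned by SNP id before the weighted sum.
    """
    wanted = list(weights["snp_id"])
    missing = set(wanted) - set(dosages.columns)
    extra = set(dosages.columns) - set(wanted)
    if missing or extra:
        raise ValueError(
            f"SNP-ID mismatch between dosages and weights "
            f"(missing: {sorted(missing)[:5]}, extra: {sorted(extra)[:5]})"
        )
    g = dosages[wanted].to_numpy(dtype=float)
    if np.any(g < 0) or np.any(g > 2):
        raise ValueError("dosages must lie in [0, 2]")
    beta = weights["beta"].to_numpy(dtype=float)
    return pd.Series(g @ beta, index=dosages.index, name="prs")


def quartiles(scores) -> PercentileGrouping:
    """Quartile assignment (0-25/25-50/50-75/75-100%) of PRS scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need >= 4 scores for quartiles")
    # reuse the percentile machinery; relax its n >= 10 guard for tiny inputs
    if scores.size >= 10:
        return percentile_groups(scores, (0, 25, 50, 75, 100))
    labels = _group_labels(np.array([0, 25, 50, 75, 100]))
    thresholds = np.quantile(scores, [0, 0.25, 0.5, 0.75, 1.0])
    idx = np.searchsorted(thresholds[1:-1], scores, side="right")
    return PercentileGrouping(
        cutpoints=np.array([0.0, 25.0, 50.0, 75.0, 100.0]),
        thresholds=thresholds,
        labels=labels,
        assignment=np.asarray(labels, dtype=object)[idx],
    )


def score_and_bin_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> PRSResult:
    """Score the PRS and split it into quartiles."""
    scores = prs_score(dosages, weights)
    grouping = quartiles(scores.to_numpy())
    return PRSResult(
        scores=scores,
        quartile_assignment=pd.Series(
            grouping.assignment, index=scores.index, name="prs_quartile"
        ),
    )
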