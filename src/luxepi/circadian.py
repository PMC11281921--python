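"""Light-driven human circadian pacemaker model.

Implements the classic two-stage model of the human circadian system's
response to light: a photic transduction stage (Process L) in which a
fraction ``n`` of photoreceptor elements is activated at an
illuminance-dependent rate, and a van-der-Pol-type limit-cycle oscillator
``(x, xc)`` representing the central pacemaker.  The model equations are

    dn/dt  = 60 [ alpha(I) (1 - n) - beta n ]
    B      = G alpha(I) (1 - n) (1 - b_x x)(1 - b_xc xc)
    dx/dt  = (pi/12) [ xc + B ]
    dxc/dt = (pi/12) { mu [ xc - (4/3) xc^3 ]
                       - x [ (24 / (f tau_x))^2 + k B ] }

with time in hours, ``alpha(I) = alpha0 (I/I0)^p`` and rate constants
``alpha0``, ``beta`` in min^-1.  Light near the minimum of ``x`` (the
modeled core-body-temperature minimum, CBTmin) suppresses the oscillation
amplitude; light late in the biological night advances phase and light
early in the night delays it.

Phase is reported as the clock time of each CBTmin (x-minimum plus a
configurable offset); amplitude as the cycle-mean radial distance
``r = sqrt(x^2 + xc^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean, circstd

from .light import LightRecording


class IntegrationError(RuntimeError):
    """Trajectory diverged or is degenerate."""


@dataclass
class CircadianParams:
    """Pacemaker model constants (defaults: published values of the
    Kronauer-family model this implementation follows)."""

    tau_x: float = 24.2  # intrinsic period (h)
    mu: float = 0.13  # oscillator stiffness
    k: float = 0.55  # light-drive coupling into dxc/dt
    G: float = 33.75  # drive gain
    alpha0: float = 0.05  # maximal photic activation rate (min^-1)
    beta: float = 0.0075  # photoreceptor recovery rate (min^-1)
    p: float = 0.5  # lux exponent
    I0: float = 9500.0  # reference illuminance (lux)
    f: float = 0.99669  # period correction factor
    b_x: float = 0.4  # drive modulation by x
    b_xc: float = 0.4  # drive modulation by xc
    cbt_min_offset: float = 0.0  # hours added to the x-minimum for CBTmin

    def __post_init__(self) -> None:
        if not 20.0 < self.tau_x < 28.0:
            raise ValueError("tau_x must be in (20, 28) h")
        if min(self.alpha0, self.beta, self.G, self.I0) <= 0:
            raise ValueError("alpha0, beta, G, I0 must be > 0")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")


@dataclass
class CircadianState:
    """Instantaneous model state: pacemaker (x, xc) and activated fraction n."""

    t: float = 0.0
    x: float = -1.0
    xc: float = 0.0
    n: float = 0.5


@dataclass
class CircadianTrajectory:
    """Uniformly sampled model trajectory aligned with its light input.

    ``t`` is hours since the start of the light series;
    ``start_clock_hour`` anchors it to the 24-h clock.
    """

    t: np.ndarray
    x: np.ndarray
    xc: np.ndarray
    n: np.ndarray
    light_input: np.ndarray
    dt: float
    start_clock_hour: float = 0.0
    entrained: bool | None = None


@dataclass
class CircadianSummary:
    """Weekly phase and amplitude statistics for one participant."""

    participant_id: str
    phase_per_day: np.ndarray  # CBTmin clock times (h), one per cycle
    mean_phase: float  # circular mean (h in [0, 24))
    phase_sd: float  # circular SD (h)
    amp_mean: float
    amp_min: float
    amp_max: float


def photic_alpha(I, params: CircadianParams):
    """Photic activation rate alpha(I) = alpha0 (I/I0)^p, in min^-1."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("illuminance must be >= 0")
    return params.alpha0 * (I / params.I0) ** params.p


def derivatives(state, I, params: CircadianParams):
    """Time derivatives (dx/dt, dxc/dt, dn/dt) in h^-1.

    ``state`` may be a :class:`CircadianState` or an ``(x, xc, n)`` tuple of
    scalars/arrays; with ``I = 0`` the photic drive B vanishes and the
    oscillator runs autonomously.
    """
    if isinstance(state, CircadianState):
        x, xc, n = state.x, state.xc, state.n
    else:
        x, xc, n = state
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xc)) and np.all(np.isfinite(n))):
        raise IntegrationError("non-finite state")
    return _derivs(np.asarray(x, float), np.asarray(xc, float), np.asarray(n, float),
                   np.asarray(I, float), params)


def _derivs(x, xc, n, I, p: CircadianParams):
    alpha = p.alpha0 * (I / p.I0) ** p.p
    B = p.G * alpha * (1.0 - n) * (1.0 - p.b_x * x) * (1.0 - p.b_xc * xc)
    pi12 = np.pi / 12.0
    dx = pi12 * (xc + B)
    dxc = pi12 * (
        p.mu * (xc - (4.0 / 3.0) * xc**3)
        - x * ((24.0 / (p.f * p.tau_x)) ** 2 + p.k * B)
    )
    dn = 60.0 * (alpha * (1.0 - n) - p.beta * n)
    return dx, dxc, dn


def _rk4(lux, epoch_hours, dt, params, x0, xc0, n0, store=True):
    """Fixed-step RK4 over a piecewise-constant light series.

    ``lux`` has shape (T,) or (P, T); states broadcast accordingly.
    Returns (x_traj, xc_traj, n_traj, final_state) where trajectories hold
    the state at the start of each step (None when ``store`` is False).
    """
    lux = np.atleast_2d(np.asarray(lux, dtype=float))
    P, T = lux.shape
    steps_per_epoch = epoch_hours / dt
    spe = int(round(steps_per_epoch))
    if spe < 1 or abs(steps_per_epoch - spe) > 1e-9:
        raise ValueError("dt must divide the epoch length")
    x = np.broadcast_to(np.asarray(x0, float), (P,)).copy()
    xc = np.broadcast_to(np.asarray(xc0, float), (P,)).copy()
    n = np.broadcast_to(np.asarray(n0, float), (P,)).copy()
    nsteps = T * spe
    if store:
        xs = np.empty((P, nsteps))
        xcs = np.empty((P, nsteps))
        ns = np.empty((P, nsteps))
    else:
        xs = xcs = ns = None
    for step in range(nsteps):
        I = lux[:, step // spe]
        if store:
            xs[:, step], xcs[:, step], ns[:, step] = x, xc, n
        k1 = _derivs(x, xc, n, I, params)
        k2 = _derivs(x + 0.5 * dt * k1[0], xc + 0.5 * dt * k1[1], n + 0.5 * dt * k1[2], I, params)
        k3 = _derivs(x + 0.5 * dt * k2[0], xc + 0.5 * dt * k2[1], n + 0.5 * dt * k2[2], I, params)
        k4 = _derivs(x + dt * k3[0], xc + dt * k3[1], n + dt * k3[2], I, params)
        x = x + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        xc = xc + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        n = n + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        np.clip(n, 0.0, 1.0, out=n)
    if np.any(np.abs(x) > 10.0) or not np.all(np.isfinite(x)):
        raise IntegrationError(
            f"integration diverged: max|x| = {np.nanmax(np.abs(x)):.3g}"
        )
    return xs, xcs, ns, (x, xc, n)


def _recording_lux(light) -> tuple[np.ndarray, float, float]:
    """(lux array, epoch_hours, start_clock_hour) from a recording or array."""
    if isinstance(light, LightRecording):
        if not light.wear.all():
            raise ValueError("light series must be gap-filled (see fill_gaps)")
        return light.lux, light.epoch_seconds / 3600.0, float(light.clock_hours[0])
    return np.asarray(light, float), 1.0 / 60.0, 0.0


def integrate(
    light,
    params: CircadianParams | None = None,
    dt: float = 1.0 / 60.0,
    initial: CircadianState | None = None,
) -> CircadianTrajectory:
    """Integrate the pacemaker over a light series (RK4, fixed step).

    ``light`` is a gap-filled :class:`LightRecording` or a bare lux array at
    1-min epochs starting at clock midnight.  Light is held piecewise
    constant within each epoch; ``dt`` (hours) must divide the epoch length
    and be <= 0.05 h.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 h")
    params = params or CircadianParams()
    initial = initial or CircadianState()
    lux, epoch_hours, start_clock = _recording_lux(light)
    xs, xcs, ns, _ = _rk4(lux, epoch_hours, dt, params, initial.x, initial.xc, initial.n)
    nsteps = xs.shape[1]
    spe = int(round(epoch_hours / dt))
    light_steps = np.repeat(np.atleast_2d(lux)[0], spe)
    return CircadianTrajectory(
        t=np.arange(nsteps) * dt,
        x=xs[0],
        xc=xcs[0],
        n=ns[0],
        light_input=light_steps,
        dt=dt,
        start_clock_hour=start_clock,
    )


def _local_minima(x: np.ndarray, dt: float, min_separation_h: float = 12.0) -> np.ndarray:
    """Refined times (in trajectory hours) of local minima of x."""
    interior = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
    times = []
    for i in interior:
        denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
        frac = 0.5 * (x[i - 1] - x[i + 1]) / denom if abs(denom) > 1e-15 else 0.0
        t_min = (i + np.clip(frac, -0.5, 0.5)) * dt
        if times and t_min - times[-1] < min_separation_h:
            continue
        times.append(t_min)
    return np.array(times)


def extract_phase(traj: CircadianTrajectory, params: CircadianParams | None = None) -> np.ndarray:
    """Clock times (h in [0,24)) of each cycle's CBTmin.

    Each local minimum of ``x`` is refined by parabolic interpolation and
    shifted by ``cbt_min_offset``.
    """
    params = params or CircadianParams()
    minima = _local_minima(traj.x, traj.dt)
    if minima.size == 0:
        raise IntegrationError("no x-minima found: degenerate trajectory")
    return (minima + traj.start_clock_hour + params.cbt_min_offset) % 24.0


def extract_amplitude(traj: CircadianTrajectory) -> np.ndarray:
    """Cycle-mean radial amplitude r(t) = sqrt(x^2 + xc^2), one value per
    period between successive x-minima."""
    minima = _local_minima(traj.x, traj.dt)
    if minima.size < 2:
        raise IntegrationError("need >= 2 x-minima to delimit a cycle")
    r = np.hypot(traj.x, traj.xc)
    idx = np.round(minima / traj.dt).astype(int)
    return np.array([r[a:b].mean() for a, b in zip(idx[:-1], idx[1:])])


def circular_mean_hours(phases: np.ndarray) -> float:
    """Circular mean of clock times, mapped back to [0, 24)."""
    return float(circmean(np.asarray(phases, float), high=24.0, low=0.0))


def circular_sd_hours(phases: np.ndarray) -> float:
    """Circular SD sqrt(-2 ln R) scaled to hours."""
    return float(circstd(np.asarray(phases, float), high=24.0, low=0.0))


def summarize_circadian(
    phases: np.ndarray, amplitudes: np.ndarray, participant_id: str
) -> CircadianSummary:
    """Weekly phase (circular mean/SD) and amplitude (mean/min/max) summary."""
    phases = np.asarray(phases, float)
    amplitudes = np.asarray(amplitudes, float)
    if phases.size < 2:
        raise ValueError("need >= 2 daily phases to summarize")
    return CircadianSummary(
        participant_id=participant_id,
        phase_per_day=phases % 24.0,
        mean_phase=circular_mean_hours(phases),
        phase_sd=circular_sd_hours(phases),
        amp_mean=float(amplitudes.mean()),
        amp_min=float(amplitudes.min()),
        amp_max=float(amplitudes.max()),
    )


def _circ_diff_hours(a: float, b: float) -> float:
    return abs((a - b + 12.0) % 24.0 - 12.0)


def entrain_to_week(
    light,
    params: CircadianParams | None = None,
    max_weeks: int = 10,
    tol_h: float = 0.1,
    dt: float = 1.0 / 60.0,
    initial: CircadianState | None = None,
) -> CircadianTrajectory:
    """Cycle the weekly light pattern until the pacemaker phase is stable.

    The week is repeated end-to-end, integrating continuously, until the
    circular-mean CBTmin time changes by less than ``tol_h`` between
    successive weeks (or ``max_weeks`` is reached).  The final week's
    trajectory is returned with ``entrained`` set accordingly;
    non-convergence (e.g. free-run in darkness) is flagged, not fatal.
    """
    params = params or CircadianParams()
    initial = initial or CircadianState()
    lux, epoch_hours, start_clock = _recording_lux(light)
    state = (initial.x, initial.xc, initial.n)
    prev_mean = None
    entrained = False
    traj = None
    for _ in range(max_weeks):
        xs, xcs, ns, state = _rk4(lux, epoch_hours, dt, params, *state)
        traj = CircadianTrajectory(
            t=np.arange(xs.shape[1]) * dt,
            x=xs[0],
            xc=xcs[0],
            n=ns[0],
            light_input=np.repeat(np.atleast_2d(lux)[0], int(round(epoch_hours / dt))),
            dt=dt,
            start_clock_hour=start_clock,
        )
        try:
            mean_phase = circular_mean_hours(extract_phase(traj, params))
        except IntegrationError:
            mean_phase = None
        if (
            prev_mean is not None
            and mean_phase is not None
            and _circ_diff_hours(mean_phase, prev_mean) < tol_h
        ):
            entrained = True
            break
        prev_mean = mean_phase
    traj.entrained = entrained
    return traj


def fill_gaps(rec: LightRecording, max_gap_h: float = 2.0) -> LightRecording:
    """Rebuild a complete uniform epoch grid for model input.

    Missing or non-wear epochs are linearly interpolated when the gap is
    shorter than ``max_gap_h`` and set to 0 lx otherwise (long gaps are most
    plausibly sleep or an unworn device in the dark).
    """
    if len(rec) < 2:
        raise ValueError("recording too short to gap-fill")
    epoch = rec.epoch_seconds
    t0 = rec.timestamps[0].astype("int64")
    t_end = rec.timestamps[-1].astype("int64")
    n = int((t_end - t0) // epoch) + 1
    lux = np.full(n, np.nan)
    idx = ((rec.timestamps.astype("int64") - t0) // epoch).astype(int)
    on_grid = (rec.timestamps.astype("int64") - t0) % epoch == 0
    lux[idx[on_grid & rec.wear]] = rec.lux[on_grid & rec.wear]

    missing = np.isnan(lux)
    if missing.any():
        grid = np.arange(n, dtype=float)
        interped = np.interp(grid, grid[~missing], lux[~missing]) if (~missing).any() else np.zeros(n)
        # identify runs of missing epochs; long runs -> 0 lx
        run_starts = np.flatnonzero(missing & ~np.r_[False, missing[:-1]])
        run_ends = np.flatnonzero(missing & ~np.r_[missing[1:], False])
        lux = np.where(missing, interped, lux)
        max_gap_epochs = max_gap_h * 3600.0 / epoch
        for a, b in zip(run_starts, run_ends):
            if (b - a + 1) >= max_gap_epochs or a == 0 or b == n - 1:
                lux[a : b + 1] = 0.0
    timestamps = rec.timestamps[0] + (np.arange(n) * epoch).astype("timedelta64[s]")
    return LightRecording(
        participant_id=rec.participant_id,
        timestamps=timestamps,
        lux=np.maximum(lux, 0.0),
        wear=np.ones(n, dtype=bool),
    )


def simulate_participant(
    rec: LightRecording,
    params: CircadianParams | None = None,
    max_weeks: int = 10,
    tol_h: float = 0.1,
    dt: float = 1.0 / 60.0,
) -> CircadianSummary:
    """Gap-fill, entrain and summarize one participant's recording."""
    params = params or CircadianParams()
    filled = fill_gaps(rec)
    traj = entrain_to_week(filled, params, max_weeks=max_weeks, tol_h=tol_h, dt=dt)
    phases = extract_phase(traj, params)
    amps = extract_amplitude(traj)
    return summarize_circadian(phases, amps, rec.participant_id)


def simulate_cohort(
    recordings: list[LightRecording],
    params: CircadianParams | None = None,
    max_weeks: int = 10,
    tol_h: float = 0.1,
    dt: float = 1.0 / 60.0,
) -> list[CircadianSummary]:
    """Batched cohort simulation: all participants advance week-by-week in a
    single vectorized integration until each is entrained (or max_weeks).

    Recordings must share the same epoch grid and length after gap-filling.
    """
    params = params or CircadianParams()
    filled = [fill_gaps(r) for r in recordings]
    lengths = {len(f) for f in filled}
    if len(lengths) != 1:
        raise ValueError("cohort recordings must share one grid length")
    lux = np.stack([f.lux for f in filled])
    epoch_hours = filled[0].epoch_seconds / 3600.0
    start_clock = float(filled[0].clock_hours[0])
    P = lux.shape[0]
    state = (np.full(P, -1.0), np.zeros(P), np.full(P, 0.5))
    prev_mean = np.full(P, np.nan)
    done = np.zeros(P, dtype=bool)
    phases_out: list = [None] * P
    amps_out: list = [None] * P
    for week in range(max_weeks):
        xs, xcs, _, state = _rk4(lux, epoch_hours, dt, params, *state)
        means = np.full(P, np.nan)
        for i in range(P):
            if done[i]:
                continue
            minima = _local_minima(xs[i], dt)
            if minima.size < 2:
                continue
            ph = (minima + start_clock + params.cbt_min_offset) % 24.0
            means[i] = circular_mean_hours(ph)
            converged = (
                np.isfinite(prev_mean[i])
                and _circ_diff_hours(means[i], prev_mean[i]) < tol_h
            )
            if converged or week == max_weeks - 1:
                r = np.hypot(xs[i], xcs[i])
                idx = np.round(minima / dt).astype(int)
                amps_out[i] = np.array(
                    [r[a:b].mean() for a, b in zip(idx[:-1], idx[1:])]
                )
                phases_out[i] = ph
                done[i] = converged
        prev_mean = means
        if done.all():
            break
    summaries = []
    for i, rec in enumerate(recordings):
        if phases_out[i] is None or len(phases_out[i]) < 2:
            raise IntegrationError(f"{rec.participant_id}: degenerate trajectory")
        summaries.append(
            summarize_circadian(phases_out[i], amps_out[i], rec.participant_id)
        )
    return summaries
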