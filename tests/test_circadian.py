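import numpy as np
import pytest

from luxepi import circadian as c
from luxepi.synthetic import generate_toy_light

PARAMS = c.CircadianParams()


@pytest.fixture(scope="module")
def limit_cycle_state():
    """State on the dark limit cycle (5 days of free run)."""
    traj = c.integrate(generate_toy_light("dark", days=5))
    return c.CircadianState(x=traj.x[-1], xc=traj.xc[-1], n=traj.n[-1])


@pytest.fixture(scope="module")
def dark_control(limit_cycle_state):
    return c.integrate(generate_toy_light("dark", days=5), initial=limit_cycle_state)


def pulse_trajectory(limit_cycle_state, center_h, lux=5000.0, width_h=3.0, days=5):
    n = days * 1440
    light = np.zeros(n)
    light[int((center_h - width_h / 2) * 60) : int((center_h + width_h / 2) * 60)] = lux
    return c.integrate(light, initial=limit_cycle_state)


class TestPhoticAlpha:
    def test_zero_light_zero_rate(self):
        assert c.photic_alpha(0.0, PARAMS) == 0.0

    def test_reference_illuminance_gives_alpha0(self):
        assert c.photic_alpha(PARAMS.I0, PARAMS) == pytest.approx(PARAMS.alpha0)

    def test_monotone_on_lux_grid(self):
        grid = np.linspace(0, 1e4, 500)
        a = c.photic_alpha(grid, PARAMS)
        assert (np.diff(a) >= 0).all()

    def test_negative_lux_rejected(self):
        with pytest.raises(ValueError):
            c.photic_alpha(-1.0, PARAMS)


class TestDerivatives:
    def test_darkness_is_process_l_fixed_point(self):
        dx, dxc, dn = c.derivatives(c.CircadianState(x=0.5, xc=0.2, n=0.0), 0.0, PARAMS)
        assert dn == 0.0

    def test_dn_sign_matches_balance(self):
        for n0 in (0.1, 0.9):
            _, _, dn = c.derivatives(c.CircadianState(n=n0), 500.0, PARAMS)
            alpha = c.photic_alpha(500.0, PARAMS)
            assert np.sign(dn) == np.sign(alpha * (1 - n0) - PARAMS.beta * n0)

    def test_limit_cycle_closes_after_one_period(self, limit_cycle_state, dark_control):
        period = PARAMS.tau_x
        i = int(round(period / dark_control.dt))
        start = (dark_control.x[0], dark_control.xc[0])
        end = (dark_control.x[i], dark_control.xc[i])
        assert np.hypot(end[0] - start[0], end[1] - start[1]) < 0.05

    def test_nonfinite_state_rejected(self):
        with pytest.raises(c.IntegrationError):
            c.derivatives(c.CircadianState(x=np.nan), 0.0, PARAMS)


class TestIntegrate:
    def test_free_run_period_near_tau(self, dark_control):
        minima = c._local_minima(dark_control.x, dark_control.dt)
        spacing = np.diff(minima)
        assert np.all(np.abs(spacing - PARAMS.tau_x) < 0.1)

    def test_step_halving_convergence(self):
        light = generate_toy_light("square_wave", days=2, epoch_seconds=300)
        t1 = c.integrate(light, dt=1 / 24)
        t2 = c.integrate(light, dt=1 / 48)
        # compare states at the same time point (t2 samples twice as often)
        assert abs(t1.x[-1] - t2.x[-2]) < 1e-4
        assert abs(t1.xc[-1] - t2.xc[-2]) < 1e-4

    def test_entrained_drift_small(self):
        sw = generate_toy_light("square_wave", lux=1000, on_hour=8, off_hour=24)
        traj = c.entrain_to_week(sw)
        phases = c.extract_phase(traj, PARAMS)
        drift = np.abs(np.diff(np.unwrap(phases, period=24.0)))
        assert traj.entrained and np.all(drift < 0.05)

    def test_activated_fraction_stays_in_unit_interval(self):
        sw = generate_toy_light("square_wave", lux=10000, days=3)
        traj = c.integrate(sw)
        assert traj.n.min() >= 0.0 and traj.n.max() <= 1.0

    def test_large_step_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            c.integrate(generate_toy_light("dark", days=1), dt=0.1)


class TestEntrainToWeek:
    def test_darkness_flagged_non_entrained(self):
        traj = c.entrain_to_week(generate_toy_light("dark"), tol_h=0.01, max_weeks=3)
        assert traj.entrained is False

    def test_convergence_independent_of_initial_phase(self):
        sw = generate_toy_light("square_wave", lux=1000, on_hour=8, off_hour=24)
        tol = 0.1
        means = []
        for x0, xc0 in [(-1.0, 0.0), (0.2, 1.0)]:
            traj = c.entrain_to_week(sw, tol_h=tol, initial=c.CircadianState(x=x0, xc=xc0))
            assert traj.entrained
            means.append(c.circular_mean_hours(c.extract_phase(traj, PARAMS)))
        diff = abs((means[0] - means[1] + 12) % 24 - 12)
        assert diff < 2 * tol


class TestExtractPhase:
    def cosine_trajectory(self, shift_h=0.0, days=4):
        dt = 1 / 60
        t = np.arange(int(days * 24 / dt)) * dt
        x = -np.cos(2 * np.pi * (t - shift_h) / 24.0)
        return c.CircadianTrajectory(
            t=t, x=x, xc=np.zeros_like(x), n=np.zeros_like(x),
            light_input=np.zeros_like(x), dt=dt,
        )

    def test_cosine_minimum_at_midnight(self):
        phases = c.extract_phase(self.cosine_trajectory(), PARAMS)
        assert np.allclose(np.minimum(phases, 24 - phases), 0.0, atol=2e-3)

    def test_time_shift_equivariance(self):
        base = c.extract_phase(self.cosine_trajectory(shift_h=0.5), PARAMS)
        shifted = c.extract_phase(self.cosine_trajectory(shift_h=1.5), PARAMS)
        k = min(len(base), len(shifted))
        np.testing.assert_allclose((shifted[:k] - base[:k]) % 24.0, 1.0, atol=2e-3)

    def test_offset_translates_phase(self):
        p0 = c.extract_phase(self.cosine_trajectory(), c.CircadianParams())
        p1 = c.extract_phase(self.cosine_trajectory(), c.CircadianParams(cbt_min_offset=2.0))
        np.testing.assert_allclose((p1 - p0) % 24.0, 2.0, atol=1e-9)

    def test_degenerate_trajectory_errors(self):
        flat = self.cosine_trajectory()
        flat.x[:] = 1.0
        with pytest.raises(c.IntegrationError):
            c.extract_phase(flat, PARAMS)

    def test_pulse_direction_early_delays_late_advances(self, limit_cycle_state, dark_control):
        cbt = c._local_minima(dark_control.x, dark_control.dt)[1]
        last_dark = c._local_minima(dark_control.x, dark_control.dt)[-1]
        early = pulse_trajectory(limit_cycle_state, cbt - 4.0)
        late = pulse_trajectory(limit_cycle_state, cbt + 4.0)
        shift_early = c._local_minima(early.x, early.dt)[-1] - last_dark
        shift_late = c._local_minima(late.x, late.dt)[-1] - last_dark
        assert shift_early > 0.1  # light before CBTmin delays
        assert shift_late < -0.1  # light after CBTmin advances


class TestExtractAmplitude:
    def test_dark_limit_cycle_amplitudes_stationary(self, dark_control):
        amps = c.extract_amplitude(dark_control)
        assert np.ptp(amps) / amps.mean() < 0.01

    def test_night_centered_light_suppresses_amplitude(self, limit_cycle_state, dark_control):
        cbt = c._local_minima(dark_control.x, dark_control.dt)[1]
        pulsed = pulse_trajectory(limit_cycle_state, cbt)
        assert c.extract_amplitude(pulsed).min() < c.extract_amplitude(dark_control).min() - 0.05

    def test_radius_homogeneity(self, dark_control):
        scaled = c.CircadianTrajectory(
            t=dark_control.t, x=0.5 * dark_control.x, xc=0.5 * dark_control.xc,
            n=dark_control.n, light_input=dark_control.light_input, dt=dark_control.dt,
        )
        np.testing.assert_allclose(
            c.extract_amplitude(scaled), 0.5 * c.extract_amplitude(dark_control), rtol=1e-9
        )


class TestSummarize:
    def test_circular_mean_across_midnight(self):
        s = c.summarize_circadian([23.0, 1.0], [0.8, 0.8], "p")
        assert s.mean_phase == pytest.approx(0.0, abs=1e-9) or s.mean_phase == pytest.approx(24.0)

    def test_identical_phases_zero_sd(self):
        s = c.summarize_circadian([3.0, 3.0, 3.0], [1.0, 1.0, 1.0], "p")
        assert s.phase_sd == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_statistics(self):
        s = c.summarize_circadian([1.0, 2.0], [0.7, 0.9, 0.8], "p")
        assert (s.amp_mean, s.amp_min, s.amp_max) == (pytest.approx(0.8), 0.7, 0.9)

    def test_requires_two_phases(self):
        with pytest.raises(ValueError):
            c.summarize_circadian([1.0], [0.5], "p")


class TestGapFill:
    def test_short_gap_interpolated_long_gap_zeroed(self):
        from luxepi.light import LightRecording

        n = 1440
        ts = np.datetime64("2015-01-05T00:00:00", "s") + (np.arange(n) * 60).astype(
            "timedelta64[s]"
        )
        lux = np.full(n, 100.0)
        wear = np.ones(n, bool)
        wear[600:630] = False  # 30 min gap -> interpolate
        wear[800:1000] = False  # 200 min gap -> zeros
        filled = c.fill_gaps(LightRecording("p", ts, lux, wear))
        assert len(filled) == n and filled.wear.all()
        np.testing.assert_allclose(filled.lux[600:630], 100.0)
        np.testing.assert_allclose(filled.lux[800:1000], 0.0)


class TestCohortSimulation:
    def test_matches_single_participant_path(self):
        recs = [
            generate_toy_light("square_wave", lux=1000, on_hour=7, off_hour=23,
                               epoch_seconds=300, participant_id="a"),
            generate_toy_light("square_wave", lux=800, on_hour=9, off_hour=22,
                               epoch_seconds=300, participant_id="b"),
        ]
        batch = c.simulate_cohort(recs, max_weeks=6, dt=1 / 24)
        for rec, summary in zip(recs, batch):
            single = c.simulate_participant(rec, max_weeks=6, dt=1 / 24)
            assert abs((summary.mean_phase - single.mean_phase + 12) % 24 - 12) < 0.1
            assert summary.amp_mean == pytest.approx(single.amp_mean, abs=0.01)
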