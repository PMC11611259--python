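"""Observer central processing: transduction, fixed points, symmetries, DC dynamics."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from gvsim.observer import (
    ObserverParams,
    canal_transduction,
    observer_simulate,
    pitch_tilt_from_gravity,
    roll_tilt_from_gravity,
    simulate_trial,
)
from gvsim.paradigms import (
    MotionProfile,
    make_dc_paradigm,
    make_pitch_dc_paradigm,
    make_sum_of_sines_profile,
    make_coupled_gvs,
)

DT = 0.01


def _roll_motion(angle_deg: np.ndarray, dt: float = DT) -> MotionProfile:
    t = np.arange(angle_deg.size) * dt
    omega = np.zeros((t.size, 3))
    omega[:, 0] = np.gradient(angle_deg, dt)
    return MotionProfile(
        time=t,
        roll_deg=angle_deg,
        pitch_deg=np.zeros_like(t),
        yaw_deg=np.zeros_like(t),
        omega_dps=omega,
        accel_mps2=np.zeros((t.size, 3)),
    )


class TestCanalTransduction:
    def test_zero_input_zero_output(self):
        assert np.all(canal_transduction(np.zeros((100, 3))) == 0.0)

    def test_step_washes_out_with_tau(self):
        t = np.arange(0, 30, DT)
        omega = np.full_like(t, 10.0)
        out = canal_transduction(omega, tau_d=5.7, dt=DT)
        expected = 10.0 * np.exp(-t / 5.7)
        assert np.allclose(out, expected, atol=0.15)

    def test_passband_transparency(self):
        t = np.arange(0, 10, DT)
        omega = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz >> 1/(2 pi tau)
        out = canal_transduction(omega, tau_d=5.7, dt=DT)
        # residual is the small phase lead of the high-pass, ~1/(2 pi f tau)
        assert np.max(np.abs(out[200:] - omega[200:])) < 0.03


class TestTiltReadout:
    def test_upright_is_zero(self):
        assert roll_tilt_from_gravity(np.array([0.0, 0.0, 9.81])) == 0.0

    def test_signed_rotation_about_x(self):
        g = 9.81 * np.array([0.0, np.sin(np.radians(-10)), np.cos(np.radians(-10))])
        assert roll_tilt_from_gravity(g) == pytest.approx(-10.0)

    def test_matches_brute_force_oracle(self, rng):
        """Random unit gravity vectors: readout equals the atan2 construction."""
        for _ in range(50):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            roll = roll_tilt_from_gravity(v)
            pitch = pitch_tilt_from_gravity(v)
            assert roll == pytest.approx(np.degrees(np.arctan2(v[1], v[2])))
            assert pitch == pytest.approx(np.degrees(np.arctan2(v[0], v[2])))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            roll_tilt_from_gravity(np.zeros(3))


class TestObserverFixedPoints:
    def test_stationary_upright_stays_level(self):
        t = np.arange(0, 20, DT)
        trace = observer_simulate(t, np.zeros((t.size, 3)))
        assert np.allclose(trace.roll_tilt, 0.0)
        assert np.allclose(trace.omega_hat, 0.0)

    def test_static_roll_converges_to_true_tilt(self):
        """Somatogravic convergence: a held 8 deg roll is eventually perceived fully."""
        dt = 0.02
        t = np.arange(0, 90, dt)
        angle = np.clip(t * 4.0, 0.0, 8.0)  # 2 s ramp, then hold
        motion = _roll_motion(angle, dt)
        trace = simulate_trial(motion, None, observer_params=ObserverParams(dt=dt))
        assert trace.roll_tilt[-1] == pytest.approx(8.0, abs=0.3)

    def test_norm_preserved_without_somatogravic_feedback(self):
        """Pure cross-product propagation of g_hat preserves its magnitude."""
        t = np.arange(0, 20, DT)
        alpha = np.zeros((t.size, 3))
        alpha[:, 0] = 5.0
        params = ObserverParams(k_f=0.0, k_fw=0.0, k_a=0.0)
        trace = observer_simulate(t, alpha, params=params)
        norms = np.linalg.norm(trace.g_hat, axis=1)
        assert np.max(np.abs(norms - params.g0)) < 1e-6

    def test_divergence_aborts_with_diagnostic(self):
        t = np.arange(0, 5, DT)
        alpha = np.full((t.size, 3), 1e9)
        with pytest.raises(FloatingPointError, match="diverged"):
            observer_simulate(t, alpha)

    def test_halving_dt_converged(self):
        vals = {}
        for dt in (0.01, 0.005):
            cur = make_dc_paradigm(1.0, 0.0, 25.0, 26.0, dt=dt)
            tr = simulate_trial(None, cur, observer_params=ObserverParams(dt=dt))
            vals[dt] = tr.roll_tilt[-1]
        assert abs(vals[0.01] - vals[0.005]) < 0.01


class TestDcGvs:
    def test_positive_current_tilts_negative(self, trained_fusion):
        """Tilt perception shifts toward the cathode (left) side: negative roll."""
        cur = make_dc_paradigm(1.0, 0.0, 25.0, 30.0)
        trace = simulate_trial(None, cur, trained_fusion)
        i25 = np.searchsorted(trace.time, 25.0) - 1
        assert trace.roll_tilt[i25] < -0.5
        # sign flips with the current
        cur_neg = make_dc_paradigm(-1.0, 0.0, 25.0, 30.0)
        trace_neg = simulate_trial(None, cur_neg, trained_fusion)
        assert np.allclose(trace_neg.roll_tilt, -trace.roll_tilt, atol=1e-9)

    def test_bounded_steady_state(self, trained_fusion):
        """Somatogravic feedback prevents perpetually increasing tilt under DC."""
        dt = 0.02
        cur = make_dc_paradigm(1.0, 0.0, 180.0, 180.0, dt=dt)
        trace = simulate_trial(None, cur, trained_fusion, ObserverParams(dt=dt))
        i120 = np.searchsorted(trace.time, 120.0)
        assert np.max(np.abs(trace.roll_tilt)) < 10.0
        assert abs(trace.roll_tilt[-1] - trace.roll_tilt[i120]) < 0.05

    def test_post_offset_decay_has_two_time_constants(self, trained_fusion):
        """After DC offset, tilt decays as a sum of two distinct exponentials."""
        dt = 0.02
        cur = make_dc_paradigm(2.0, 0.0, 25.0, 90.0, dt=dt)
        trace = simulate_trial(None, cur, trained_fusion, ObserverParams(dt=dt))
        i_off = np.searchsorted(trace.time, 25.0) + int(1.0 / dt)
        t = trace.time[i_off:] - trace.time[i_off]
        y = trace.roll_tilt[i_off:]

        def biexp(t, a1, tau1, a2, tau2):
            return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

        p, _ = curve_fit(biexp, t, y, p0=[y[0] * 0.5, 1.0, y[0] * 0.5, 20.0], maxfev=20000)
        resid = y - biexp(t, *p)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.995
        taus = sorted([abs(p[1]), abs(p[3])])
        assert taus[1] / taus[0] > 3.0

    def test_mirror_symmetry_of_full_trial(self, trained_fusion):
        prof = make_sum_of_sines_profile(dt=0.02)
        cur = make_coupled_gvs(prof, "joint", "positive")
        prof_m = make_sum_of_sines_profile(mirror=True, dt=0.02)
        cur_m = make_coupled_gvs(prof_m, "joint", "positive")
        op = ObserverParams(dt=0.02)
        t1 = simulate_trial(prof, cur, trained_fusion, op)
        t2 = simulate_trial(prof_m, cur_m, trained_fusion, op)
        assert np.allclose(t1.roll_tilt, -t2.roll_tilt, atol=1e-9)

    def test_no_gvs_trial_matches_plain_observer(self, trained_fusion):
        prof = make_sum_of_sines_profile(dt=0.02)
        op = ObserverParams(dt=0.02)
        via_trial = simulate_trial(prof, None, trained_fusion, op)
        alpha = canal_transduction(prof.omega_dps, op.tau_d, 0.02)
        from gvsim.observer import gravity_in_head_frame

        f = gravity_in_head_frame(prof.omega_dps, 0.02, op.g0)
        direct = observer_simulate(prof.time, alpha, f, op)
        assert np.allclose(via_trial.roll_tilt, direct.roll_tilt)


class TestPitchDependence:
    def test_pitch_back_amplifies_roll_tilt(self, trained_fusion):
        """Aligning gravity with the net GVS axis strengthens and nonlinearizes the effect."""
        dt = 0.02
        op = ObserverParams(dt=dt)
        peaks = {}
        for pitch in (0.0, 45.0, 90.0):
            motion, cur = make_pitch_dc_paradigm(pitch, 4.0, dt=dt, pitch_rate_dps=3.0)
            trace = simulate_trial(motion, cur, trained_fusion, op)
            on = cur.current_ma != 0
            peaks[pitch] = np.max(np.abs(trace.roll_tilt[on]))
        assert peaks[90.0] > peaks[45.0] > peaks[0.0]
        # nonlinear in pitch angle: unequal increments
        d1 = peaks[45.0] - peaks[0.0]
        d2 = peaks[90.0] - peaks[45.0]
        assert abs(d2 - d1) > 0.25 * max(d1, d2)
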