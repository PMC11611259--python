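"""Afferent transfer-function bank: limits, step responses, polarity routing."""

import numpy as np
import pytest

from gvsim.afferent import (
    TransferFunctionSpec,
    averaged_polarity_phase,
    build_afferent_tf,
    default_tf_bank,
    frequency_response,
    simulate_afferent_response,
)

DT = 0.01


def _step(duration=60.0, amp=1.0):
    t = np.arange(0.0, duration, DT)
    return t, np.full_like(t, amp)


def analytic_step_response(tf: TransferFunctionSpec, t: np.ndarray) -> np.ndarray:
    """Closed-form step response of gain*(s-z)/(s-p): dc + (hf - dc) * exp(p t)."""
    (p,) = tf.poles
    dc = tf.dc_gain
    return dc + (tf.high_freq_gain - dc) * np.exp(np.real(p) * t)


class TestTransferFunctionLimits:
    def test_low_frequency_factor_limits(self):
        tf = TransferFunctionSpec("irregular", "cathodal", zeros=(-0.02,), poles=(-0.1,), gain=1.0)
        assert abs(tf.evaluate(1j * 1e6)) == pytest.approx(1.0, rel=1e-6)
        assert abs(tf.evaluate(0.0)) == pytest.approx(0.2, rel=1e-9)

    def test_unity_gain_realized_by_25_hz(self, tf_bank):
        for tf in tf_bank.values():
            h_l = tf.evaluate(1j * 2 * np.pi * 25.0) / tf.gain
            assert abs(h_l) == pytest.approx(1.0, rel=0.01)

    def test_dc_gain_diminished(self, tf_bank):
        for tf in tf_bank.values():
            assert 0 < tf.dc_gain < tf.high_freq_gain

    def test_unstable_poles_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            TransferFunctionSpec("regular", "anodal", zeros=(-0.1,), poles=(0.2,), gain=1.0)

    def test_missing_coefficients_named(self):
        with pytest.raises(KeyError, match="irregular.*cathodal"):
            build_afferent_tf("irregular", "cathodal", coefficients={})


class TestStepResponse:
    def test_settles_to_dc_gain(self, tf_bank):
        """Final-value theorem: a 1 mA step settles to DC gain x step size."""
        t, cur = _step(duration=300.0)
        for (channel, _pol), tf in tf_bank.items():
            resp = simulate_afferent_response(t, cur, "left", channel, tf_bank)
            cath = tf_bank[(channel, "cathodal")]
            assert resp.delta_fr[-1] == pytest.approx(cath.dc_gain, rel=1e-3)

    @pytest.mark.parametrize("channel", ["regular", "irregular"])
    def test_matches_closed_form(self, tf_bank, channel):
        """Cathode-side step response follows the analytic first-order decay."""
        t, cur = _step(duration=60.0)
        resp = simulate_afferent_response(t, cur, "left", channel, tf_bank)
        expected = analytic_step_response(tf_bank[(channel, "cathodal")], t)
        assert np.allclose(resp.delta_fr[1:], expected[1:], rtol=0.02, atol=0.05)

    def test_onset_near_high_frequency_gain(self, tf_bank):
        t, cur = _step()
        resp = simulate_afferent_response(t, cur, "left", "irregular", tf_bank)
        hf = tf_bank[("irregular", "cathodal")].high_freq_gain
        assert resp.delta_fr[1] == pytest.approx(hf, rel=0.02)
        # decays toward the DC level over tens of seconds
        assert resp.delta_fr[-1] < 0.9 * hf

    def test_irregular_decays_faster_than_regular(self, tf_bank):
        tau_irr = tf_bank[("irregular", "cathodal")].dominant_time_constant
        tau_reg = tf_bank[("regular", "cathodal")].dominant_time_constant
        assert tau_irr < tau_reg
        # confirmed on the simulated step: fraction of the onset-to-DC decay
        # completed by 10 s is larger for irregular afferents
        t, cur = _step(duration=10.0)
        frac = {}
        for ch in ("irregular", "regular"):
            resp = simulate_afferent_response(t, cur, "left", ch, tf_bank)
            tf = tf_bank[(ch, "cathodal")]
            frac[ch] = (tf.high_freq_gain - resp.delta_fr[-1]) / (tf.high_freq_gain - tf.dc_gain)
        assert frac["irregular"] > frac["regular"]


class TestPolarityRouting:
    def test_zero_current_zero_response(self, tf_bank):
        t = np.arange(0, 10, DT)
        resp = simulate_afferent_response(t, np.zeros_like(t), "left", "irregular", tf_bank)
        assert np.all(resp.delta_fr == 0.0)

    def test_montage_mirror_symmetry(self, tf_bank, rng):
        t = np.arange(0, 20, DT)
        cur = np.sin(2 * np.pi * 0.2 * t) + 0.3 * rng.standard_normal(t.size)
        left = simulate_afferent_response(t, cur, "left", "irregular", tf_bank)
        right = simulate_afferent_response(t, -cur, "right", "irregular", tf_bank)
        assert np.allclose(left.delta_fr, right.delta_fr)

    def test_depolarization_increases_rate(self, tf_bank):
        t, cur = _step()
        left = simulate_afferent_response(t, cur, "left", "irregular", tf_bank)   # cathode side
        right = simulate_afferent_response(t, cur, "right", "irregular", tf_bank)  # anode side
        assert np.all(left.delta_fr[1:] > 0)
        assert np.all(right.delta_fr[1:] < 0)

    def test_linearity_per_polarity_branch(self, tf_bank):
        t = np.arange(0, 15, DT)
        cur = np.abs(np.sin(2 * np.pi * 0.1 * t))  # strictly non-negative
        r1 = simulate_afferent_response(t, cur, "left", "regular", tf_bank)
        r2 = simulate_afferent_response(t, 2 * cur, "left", "regular", tf_bank)
        assert np.allclose(r2.delta_fr, 2 * r1.delta_fr)

    def test_continuity_at_polarity_switches(self, tf_bank):
        t = np.arange(0, 30, DT)
        cur = 2.0 * np.sin(2 * np.pi * 0.2 * t)
        resp = simulate_afferent_response(t, cur, "left", "irregular", tf_bank)
        hf = tf_bank[("irregular", "cathodal")].high_freq_gain
        max_slew = hf * np.max(np.abs(np.diff(cur))) * 1.5
        assert np.max(np.abs(np.diff(resp.delta_fr))) <= max_slew

    def test_bounded_input_bounded_output(self, tf_bank, rng):
        t = np.arange(0, 120, DT)
        cur = rng.uniform(-4, 4, t.size)
        resp = simulate_afferent_response(t, cur, "right", "irregular", tf_bank)
        assert np.all(np.isfinite(resp.delta_fr))
        assert np.max(np.abs(resp.delta_fr)) < 4 * tf_bank[("irregular", "cathodal")].high_freq_gain

    def test_invalid_inputs_rejected(self, tf_bank):
        t = np.arange(0, 1, DT)
        bad = np.zeros_like(t)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            simulate_afferent_response(t, bad, "left", "regular", tf_bank)
        with pytest.raises(ValueError, match="uniform"):
            simulate_afferent_response(np.array([0, 0.01, 0.5]), np.zeros(3), "left", "regular", tf_bank)


class TestFrequencyResponse:
    def test_nonpositive_frequency_rejected(self, tf_bank):
        with pytest.raises(ValueError):
            frequency_response(tf_bank[("regular", "cathodal")], [0.0])

    def test_phase_closed_form(self):
        """Phase of (jw - z)/(jw - p) at w = sqrt(|z p|) via explicit arctangents."""
        z, p = -0.02, -0.1
        tf = TransferFunctionSpec("regular", "cathodal", zeros=(z,), poles=(p,), gain=1.0)
        w = np.sqrt(abs(z * p))
        _, phase = frequency_response(tf, [w / (2 * np.pi)])
        expected = np.degrees(np.arctan2(w, -z) - np.arctan2(w, -p))
        assert phase[0] == pytest.approx(expected, abs=1e-9)

    def test_averaged_polarity_phase_is_arithmetic_mean(self, tf_bank):
        freqs = np.geomspace(0.01, 25, 20)
        _, ph_c = frequency_response(tf_bank[("irregular", "cathodal")], freqs)
        _, ph_a = frequency_response(tf_bank[("irregular", "anodal")], freqs)
        avg = averaged_polarity_phase(
            tf_bank[("irregular", "cathodal")], tf_bank[("irregular", "anodal")], freqs
        )
        assert np.allclose(avg, 0.5 * (ph_c + ph_a))
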