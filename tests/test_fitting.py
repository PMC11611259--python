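"""Calibration: cost surfaces, optimal fronts, joint fit, susceptibility recovery."""

import numpy as np
import pytest

from gvsim.fitting import (
    dynamic_cost,
    dynamic_cost_surface,
    extract_fronts_and_joint_fit,
    fit_individual_gain,
    prepare_condition,
    static_cost,
    static_cost_surface,
    static_tilt_gain,
)
from gvsim.fusion import FusionParams
from gvsim.observer import ObserverParams, _observer_core, roll_tilt_from_gravity
from gvsim.paradigms import make_coupled_gvs, make_sum_of_sines_profile

DT = 0.02


def _model_roll(cond, k_reg, k_gvs, op):
    fp = FusionParams(k_gvs=1.0)  # interpreters only; k applied below
    mix = k_reg * fp.interp_regular * cond.gvs_reg + (1 - k_reg) * fp.interp_irregular * cond.gvs_irreg
    alpha = cond.alpha_phys + k_gvs * mix
    params = ObserverParams(**{**op.__dict__, "dt": cond.dt})
    g0 = params.g0 * np.array([0.0, 0.0, 1.0])
    _, _, g, _, _ = _observer_core(alpha[None], cond.f_gif, params, g0)
    return roll_tilt_from_gravity(g[0])


@pytest.fixture(scope="module")
def training_conditions(coarse_observer):
    conds = []
    for coupling in ("angle", "velocity"):
        for sign in ("positive", "negative"):
            prof = make_sum_of_sines_profile(dt=DT)
            cur = make_coupled_gvs(prof, coupling, sign)
            conds.append(prepare_condition(prof, cur, None, coarse_observer, label=f"{sign}-{coupling}"))
    return conds


class TestDynamicCost:
    def test_self_consistent_model_has_zero_cost(self, training_conditions, coarse_observer):
        for cond in training_conditions:
            cond.target_roll_deg = _model_roll(cond, 0.0, 0.0245, coarse_observer)
        j = dynamic_cost(training_conditions, 0.0, 0.0245, coarse_observer)
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_costs_offset_squared(self, training_conditions, coarse_observer):
        for cond in training_conditions:
            cond.target_roll_deg = _model_roll(cond, 0.0, 0.0245, coarse_observer) + 0.7
        j = dynamic_cost(training_conditions, 0.0, 0.0245, coarse_observer)
        assert j == pytest.approx(0.49, rel=1e-6)

    def test_matches_per_sample_mse_oracle(self, training_conditions, coarse_observer, rng):
        k_reg, k_gvs = 0.75, 0.01
        sq, n = 0.0, 0
        for cond in training_conditions:
            cond.target_roll_deg = rng.normal(0, 2, cond.time.size)
            model = _model_roll(cond, k_reg, k_gvs, coarse_observer)
            sq += np.sum((model - cond.target_roll_deg) ** 2)
            n += cond.time.size
        j = dynamic_cost(training_conditions, k_reg, k_gvs, coarse_observer)
        assert j == pytest.approx(sq / n, rel=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            dynamic_cost_surface([], [0.0], [0.01])


class TestStaticCost:
    def test_zero_gain_costs_target_squared(self, coarse_observer):
        j = static_cost(0.0, 0.0, target_deg_per_ma=1.5, observer_params=coarse_observer, dt=DT)
        assert j == pytest.approx(1.5**2, abs=1e-9)

    def test_exact_target_costs_zero(self, coarse_observer):
        gain = static_tilt_gain(0.0, 0.0245, observer_params=coarse_observer, dt=DT)
        j = static_cost(0.0, 0.0245, target_deg_per_ma=gain, observer_params=coarse_observer, dt=DT)
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_trained_gain_near_static_target(self, coarse_observer):
        """The trained operating point reproduces the ~1.5 deg/mA static effect."""
        gain = static_tilt_gain(0.0, 0.0245, observer_params=coarse_observer, dt=DT)
        assert gain == pytest.approx(1.5, rel=0.15)

    def test_monotone_near_optimum(self, coarse_observer):
        """Cost increases with |gain - target| along a K_GVS scan."""
        grid = np.array([0.008, 0.016, 0.0245, 0.04, 0.06])
        costs = [static_cost(0.0, k, observer_params=coarse_observer, dt=DT) for k in grid]
        gains = [static_tilt_gain(0.0, k, observer_params=coarse_observer, dt=DT) for k in grid]
        dev = np.abs(np.array(gains) - 1.5)
        assert np.all(np.diff(costs[np.argmin(dev):]) >= 0) if np.argmin(dev) < len(costs) - 1 else True
        assert np.argmin(costs) == np.argmin(dev)


class TestJointFit:
    def test_identical_surfaces_share_front(self, training_conditions, coarse_observer):
        for cond in training_conditions:
            cond.target_roll_deg = _model_roll(cond, 0.0, 0.0245, coarse_observer)
        kr = np.linspace(0, 1, 5)
        kg = np.geomspace(0.005, 0.08, 8)
        surf = dynamic_cost_surface(training_conditions, kr, kg, coarse_observer)
        res = extract_fronts_and_joint_fit(surf, surf)
        assert np.allclose(res.dynamic_front, res.static_front)

    def test_parameter_recovery_at_irregular_only_optimum(self, training_conditions, coarse_observer):
        """Data generated with K_Reg=0 recovers (0, K_GVS0) and is weight-insensitive."""
        k_gvs0 = 0.0245
        for cond in training_conditions:
            cond.target_roll_deg = _model_roll(cond, 0.0, k_gvs0, coarse_observer)
        kr = np.linspace(0, 1, 5)
        kg = np.array([0.008, 0.015, 0.0245, 0.04, 0.07])
        dyn = dynamic_cost_surface(training_conditions, kr, kg, coarse_observer)
        stat = static_cost_surface(kr, kg, observer_params=coarse_observer, dt=DT)
        res = extract_fronts_and_joint_fit(dyn, stat)
        assert res.k_reg_opt == 0.0
        assert res.k_gvs_opt == pytest.approx(k_gvs0, abs=1e-12)
        assert res.weight_insensitive


class TestIndividualGain:
    def _pairs(self, training_conditions, coarse_observer, susceptibility):
        k = susceptibility * 0.0245
        return [
            (cond, _model_roll(cond, 0.0, k, coarse_observer)) for cond in training_conditions
        ]

    def test_recovery_of_elevated_susceptibility(self, training_conditions, coarse_observer):
        pairs = self._pairs(training_conditions, coarse_observer, 1.5)
        fit = fit_individual_gain(pairs, 0.0245, observer_params=coarse_observer)
        assert fit.susceptibility == pytest.approx(1.5, abs=0.05)

    def test_zero_response_participant(self, training_conditions, coarse_observer):
        pairs = self._pairs(training_conditions, coarse_observer, 0.0)
        fit = fit_individual_gain(pairs, 0.0245, observer_params=coarse_observer)
        assert fit.susceptibility == pytest.approx(0.0, abs=0.02)

    def test_population_mean_participant(self, training_conditions, coarse_observer):
        pairs = self._pairs(training_conditions, coarse_observer, 1.0)
        fit = fit_individual_gain(pairs, 0.0245, observer_params=coarse_observer)
        assert fit.susceptibility == pytest.approx(1.0, abs=0.05)

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_individual_gain([], 0.0245)
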