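"""Synthetic participants and SHH datasets with the assumed statistical structure.

Each synthetic participant is the model itself (K_GVS scaled by an individual
susceptibility) viewed through a reporting channel that mirrors, in the
forward direction, the distortions the preprocessing corrects: the model
perception is divided by the reporting gain, delayed by the reaction time,
offset by the bias, and corrupted with additive white Gaussian noise.  With
zero noise the correction sequence inverts the distortion exactly, so the
full preprocessing + susceptibility-fitting pipeline can be exercised (and
its recovery quantified) without any empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afferent import TransferFunctionSpec
from .fitting import ConditionData, prepare_condition
from .fusion import FusionParams
from .geometry import CanalBasis
from .observer import ObserverParams, _observer_core, roll_tilt_from_gravity
from .paradigms import TrialSpec, make_coupled_gvs, make_sum_of_sines_profile, standard_design
from .reports import ShhTrial

__all__ = ["SyntheticParticipant", "sample_participants", "generate_dataset", "simulate_design_conditions"]


@dataclass
class SyntheticParticipant:
    """Latent parameters of one simulated reporter."""

    participant_id: str
    susceptibility: float = 1.0   # normalized GVS gain (1.0 = population-trained)
    bias_deg: float = 0.0
    delay_s: float = 0.0
    gain: float = 1.0
    noise_sd_deg: float = 0.5
    small_tilt_freeze: bool = False  # park the bar near zero for |tilt| < 2 deg

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")
        if self.noise_sd_deg < 0:
            raise ValueError("noise SD must be non-negative")
        if self.gain <= 0:
            raise ValueError("reporting gain must be positive")


def sample_participants(
    n: int,
    seed: int | None = None,
    susceptibility_mu: float = 1.03,
    susceptibility_sigma: float = 0.41,
    noise_sd_deg: float = 0.5,
) -> list[SyntheticParticipant]:
    """Draw a cohort with population-distributed susceptibility and reporting quirks."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        cohort.append(
            SyntheticParticipant(
                participant_id=f"S{i + 1:02d}",
                susceptibility=float(rng.normal(susceptibility_mu, susceptibility_sigma)),
                bias_deg=float(rng.normal(0.0, 0.5)),
                delay_s=float(rng.uniform(0.2, 1.0)),
                gain=float(rng.uniform(0.7, 1.3)),
                noise_sd_deg=noise_sd_deg,
            )
        )
    return cohort


def simulate_design_conditions(
    design: list[TrialSpec] | None = None,
    observer_params: ObserverParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
    fusion_params: FusionParams | None = None,
    dt: float = 0.01,
    peak_ma: float = 4.0,
) -> list[tuple[TrialSpec, ConditionData]]:
    """Precompute peripheral signals for every trial of a design (cached by condition)."""
    if design is None:
        design = standard_design()
    if fusion_params is None:
        fusion_params = FusionParams()
    cache: dict[tuple, ConditionData] = {}
    out = []
    for spec in design:
        key = (spec.freq_set, spec.mirror, spec.coupling, spec.sign)
        if key not in cache:
            motion = make_sum_of_sines_profile(spec.freq_set, mirror=spec.mirror, dt=dt)
            current = (
                None
                if spec.coupling == "none"
                else make_coupled_gvs(motion, spec.coupling, spec.sign, peak_ma)
            )
            cache[key] = prepare_condition(
                motion, current, None, observer_params, tf_bank, basis, fusion_params.k_r, label=spec.label
            )
        out.append((spec, cache[key]))
    return out


def _participant_perception(
    cond: ConditionData,
    susceptibility: float,
    fusion_params: FusionParams,
    observer_params: ObserverParams,
) -> np.ndarray:
    gvs_mix = (
        fusion_params.k_reg * fusion_params.interp_regular * cond.gvs_reg
        + fusion_params.k_irreg * fusion_params.interp_irregular * cond.gvs_irreg
    )
    alpha = cond.alpha_phys + susceptibility * fusion_params.k_gvs * gvs_mix
    r0, p0 = np.radians(cond.initial_roll_deg), np.radians(cond.initial_pitch_deg)
    g_init = observer_params.g0 * np.array(
        [np.sin(p0) * np.cos(r0), np.sin(r0) * np.cos(p0), np.cos(r0) * np.cos(p0)]
    )
    params = ObserverParams(**{**observer_params.__dict__, "dt": cond.dt})
    _, _, g_hat, _, _ = _observer_core(alpha[None], cond.f_gif, params, g_init)
    return roll_tilt_from_gravity(g_hat[0])


def generate_dataset(
    participants: list[SyntheticParticipant],
    design: list[TrialSpec] | None = None,
    fusion_params: FusionParams | None = None,
    observer_params: ObserverParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
    seed: int | None = None,
    dt: float = 0.01,
) -> dict[str, list[ShhTrial]]:
    """Full synthetic SHH dataset: per participant, raw reports for every trial.

    The raw report is ``perception(t - delay) / gain + bias + noise``; the
    distortion order is the inverse of the correction sequence (gain, then
    delay, then bias), so corrections are exactly invertible at zero noise.
    """
    if not participants:
        raise ValueError("need at least one participant")
    if design is None:
        design = standard_design()
    if not design:
        raise ValueError("empty design")
    if fusion_params is None:
        fusion_params = FusionParams()
    if observer_params is None:
        observer_params = ObserverParams()

    conditions = simulate_design_conditions(design, observer_params, tf_bank, basis, fusion_params, dt)
    rng = np.random.default_rng(seed)
    dataset: dict[str, list[ShhTrial]] = {}
    for part in participants:
        # perception depends only on (condition, susceptibility); cache per condition
        percept_cache: dict[int, np.ndarray] = {}
        trials: list[ShhTrial] = []
        for spec, cond in conditions:
            cid = id(cond)
            if cid not in percept_cache:
                # sham conditions carry zero GVS signal, so susceptibility is inert there
                percept_cache[cid] = _participant_perception(
                    cond, part.susceptibility, fusion_params, observer_params
                )
            perception = percept_cache[cid]
            t = cond.time
            delayed = np.interp(t - part.delay_s, t, perception, left=perception[0])
            raw = delayed / part.gain + part.bias_deg
            if part.noise_sd_deg > 0:
                raw = raw + rng.normal(0.0, part.noise_sd_deg, size=raw.shape)
            actual = np.degrees(np.arctan2(cond.f_gif[:, 1], cond.f_gif[:, 2]))
            if part.small_tilt_freeze:
                raw = np.where(np.abs(actual) < 2.0, part.bias_deg, raw)
            trials.append(
                ShhTrial(
                    time=t,
                    raw_report_deg=raw,
                    actual_tilt_deg=actual,
                    participant=part.participant_id,
                    coupling=spec.coupling,
                    sign=spec.sign,
                    motion_label=spec.label,
                )
            )
        dataset[part.participant_id] = trials
    return dataset
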