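"""Model calibration: (K_Reg, K_GVS) training and individual susceptibility fits.

The two free parameters are trained on grid-searched mean-squared-error cost
surfaces.  The dynamic cost compares model roll-tilt predictions with mean
perception traces across the angle- and velocity-coupled conditions (the
joint-coupled conditions are reserved for validation).  The static cost
compares the model's end-of-stimulation DC tilt gain (deg per mA, upright,
no motion) with the population-average static effect (~1.5 deg/mA).  Either
paradigm alone is underdetermined (an optimal front in the (K_Reg, K_GVS)
plane); jointly they select a unique optimum, at K_Reg = 0 for data with
irregular-only dynamics, insensitive to the relative weighting.

Individual GVS susceptibility is the per-participant K_GVS (at K_Reg = 0)
minimizing the MSE against that participant's corrected reports over all
GVS trials, normalized by the trained K_GVS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afferent import TransferFunctionSpec, default_tf_bank
from .fusion import FusionParams, gvs_afference
from .geometry import CanalBasis, default_canal_basis
from .observer import ObserverParams, _observer_core, canal_transduction, gravity_in_head_frame, roll_tilt_from_gravity
from .paradigms import CurrentWaveform, MotionProfile, make_dc_paradigm

__all__ = [
    "ConditionData",
    "CostSurface",
    "FitResult",
    "IndividualFit",
    "prepare_condition",
    "dynamic_cost",
    "dynamic_cost_surface",
    "static_tilt_gain",
    "static_cost",
    "static_cost_surface",
    "extract_fronts_and_joint_fit",
    "fit_individual_gain",
]

DEFAULT_STATIC_TARGET_DEG_PER_MA = 1.5


@dataclass
class ConditionData:
    """Precomputed per-condition signals so grid search never re-runs the periphery.

    The GVS terms are stored per afferent channel in dspk/s; a candidate
    (k_reg, k_gvs) then assembles fused afference by linear combination, and
    only the (nonlinear) observer is re-run, batched across candidates.
    """

    time: np.ndarray
    alpha_phys: np.ndarray     # (n, 3) deg/s
    gvs_reg: np.ndarray        # (n, 3) dspk/s
    gvs_irreg: np.ndarray      # (n, 3) dspk/s
    f_gif: np.ndarray          # (n, 3) m/s^2
    target_roll_deg: np.ndarray | None = None
    initial_roll_deg: float = 0.0
    initial_pitch_deg: float = 0.0
    label: str = ""

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class CostSurface:
    """MSE cost over a (K_Reg, K_GVS) grid."""

    k_reg_grid: np.ndarray
    k_gvs_grid: np.ndarray
    j_mse: np.ndarray  # (len(k_reg), len(k_gvs)), deg^2

    def __post_init__(self) -> None:
        self.k_reg_grid = np.asarray(self.k_reg_grid, dtype=float)
        self.k_gvs_grid = np.asarray(self.k_gvs_grid, dtype=float)
        self.j_mse = np.asarray(self.j_mse, dtype=float)
        if self.j_mse.shape != (self.k_reg_grid.size, self.k_gvs_grid.size):
            raise ValueError("cost matrix shape must match the grids")
        if np.any(self.j_mse < 0) or not np.all(np.isfinite(self.j_mse)):
            raise ValueError("costs must be finite and non-negative")

    def front(self) -> np.ndarray:
        """Optimal K_GVS per K_Reg (argmin over the K_GVS axis, smallest on ties)."""
        return self.k_gvs_grid[np.argmin(self.j_mse, axis=1)]

    def to_dataframe(self):
        """Long-format (k_reg, k_gvs, j_mse) table for CSV export."""
        import pandas as pd

        kr, kg = np.meshgrid(self.k_reg_grid, self.k_gvs_grid, indexing="ij")
        return pd.DataFrame(
            {"k_reg": kr.ravel(), "k_gvs": kg.ravel(), "j_mse": self.j_mse.ravel()}
        )


@dataclass
class FitResult:
    """Joint (K_Reg, K_GVS) optimum with the per-paradigm optimal fronts."""

    k_reg_opt: float
    k_gvs_opt: float
    dynamic_front: np.ndarray
    static_front: np.ndarray
    k_reg_grid: np.ndarray
    weight_insensitive: bool
    joint_cost: np.ndarray


@dataclass
class IndividualFit:
    """Per-participant GVS gain and its population-normalized susceptibility."""

    participant: str
    k_gvs_sub: float
    susceptibility: float
    mse: float

    def __post_init__(self) -> None:
        if self.susceptibility < 0:
            import warnings

            warnings.warn(f"negative GVS susceptibility for participant {self.participant!r}")


def prepare_condition(
    motion: MotionProfile,
    current: CurrentWaveform | None,
    target_roll_deg: np.ndarray | None = None,
    observer_params: ObserverParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
    k_r: float = 0.5,
    label: str = "",
) -> ConditionData:
    """Run the peripheral stages once for a (motion, current) condition."""
    if observer_params is None:
        observer_params = ObserverParams()
    t = motion.time
    dt = motion.dt
    alpha_phys = canal_transduction(motion.omega_dps, observer_params.tau_d, dt)
    if current is not None and np.any(current.current_ma != 0.0):
        aff = gvs_afference(t, current.current_ma, tf_bank, basis, k_r)
        gvs_reg, gvs_irreg = aff["regular"].alpha, aff["irregular"].alpha
    else:
        gvs_reg = np.zeros((t.size, 3))
        gvs_irreg = np.zeros((t.size, 3))
    g_true = gravity_in_head_frame(
        motion.omega_dps, dt, observer_params.g0, motion.initial_roll_deg, motion.initial_pitch_deg
    )
    return ConditionData(
        time=t,
        alpha_phys=alpha_phys,
        gvs_reg=gvs_reg,
        gvs_irreg=gvs_irreg,
        f_gif=g_true - motion.accel_mps2,
        target_roll_deg=None if target_roll_deg is None else np.asarray(target_roll_deg, float),
        initial_roll_deg=motion.initial_roll_deg,
        initial_pitch_deg=motion.initial_pitch_deg,
        label=label or motion.label,
    )


def _batched_roll(
    cond: ConditionData,
    k_reg: np.ndarray,
    k_gvs: np.ndarray,
    observer_params: ObserverParams,
    fusion_template: FusionParams,
) -> np.ndarray:
    """Roll-tilt traces (n_candidates, n_time) for paired candidate arrays."""
    interp_r = fusion_template.interp_regular
    interp_i = fusion_template.interp_irregular
    k_reg = np.asarray(k_reg, dtype=float)[:, None, None]
    k_gvs = np.asarray(k_gvs, dtype=float)[:, None, None]
    gvs_mix = k_reg * interp_r * cond.gvs_reg[None] + (1.0 - k_reg) * interp_i * cond.gvs_irreg[None]
    alpha = cond.alpha_phys[None] + k_gvs * gvs_mix
    r0, p0 = np.radians(cond.initial_roll_deg), np.radians(cond.initial_pitch_deg)
    g_init = observer_params.g0 * np.array(
        [np.sin(p0) * np.cos(r0), np.sin(r0) * np.cos(p0), np.cos(r0) * np.cos(p0)]
    )
    params = ObserverParams(**{**observer_params.__dict__, "dt": cond.dt})
    _, _, g_hat, _, _ = _observer_core(alpha, cond.f_gif, params, g_init)
    return roll_tilt_from_gravity(g_hat)


def dynamic_cost(
    conditions: list[ConditionData],
    k_reg: float,
    k_gvs: float,
    observer_params: ObserverParams | None = None,
    fusion_template: FusionParams | None = None,
) -> float:
    """Pooled MSE (deg^2) between model roll tilt and the target traces."""
    surf = dynamic_cost_surface(conditions, [k_reg], [k_gvs], observer_params, fusion_template)
    return float(surf.j_mse[0, 0])


def dynamic_cost_surface(
    conditions: list[ConditionData],
    k_reg_grid,
    k_gvs_grid,
    observer_params: ObserverParams | None = None,
    fusion_template: FusionParams | None = None,
) -> CostSurface:
    """MSE surface over the (K_Reg, K_GVS) grid, pooled over conditions and time."""
    if not conditions:
        raise ValueError("empty training dataset")
    if observer_params is None:
        observer_params = ObserverParams()
    if fusion_template is None:
        fusion_template = FusionParams()
    k_reg_grid = np.asarray(k_reg_grid, dtype=float)
    k_gvs_grid = np.asarray(k_gvs_grid, dtype=float)
    kr, kg = np.meshgrid(k_reg_grid, k_gvs_grid, indexing="ij")
    kr, kg = kr.ravel(), kg.ravel()
    sq_sum = np.zeros(kr.size)
    n_total = 0
    for cond in conditions:
        if cond.target_roll_deg is None:
            raise ValueError(f"condition {cond.label!r} has no target perception trace")
        roll = _batched_roll(cond, kr, kg, observer_params, fusion_template)
        sq_sum += np.sum((roll - cond.target_roll_deg[None]) ** 2, axis=1)
        n_total += cond.time.size
    return CostSurface(k_reg_grid, k_gvs_grid, (sq_sum / n_total).reshape(k_reg_grid.size, k_gvs_grid.size))


def static_tilt_gain(
    k_reg: float,
    k_gvs: float,
    amplitude_ma: float = 1.0,
    readout_s: float = 25.0,
    observer_params: ObserverParams | None = None,
    fusion_template: FusionParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
    dt: float = 0.01,
) -> float:
    """End-of-stimulation DC tilt gain, |deg| per mA, for an upright stationary observer."""
    gains = _static_gain_batch([k_reg], [k_gvs], amplitude_ma, readout_s, observer_params, fusion_template, tf_bank, basis, dt)
    return float(gains[0])


def _static_gain_batch(k_reg, k_gvs, amplitude_ma, readout_s, observer_params, fusion_template, tf_bank, basis, dt):
    from .paradigms import stationary_profile

    if observer_params is None:
        observer_params = ObserverParams()
    if fusion_template is None:
        fusion_template = FusionParams()
    current = make_dc_paradigm(amplitude_ma, 0.0, readout_s, readout_s + 2 * dt, dt=dt)
    motion = stationary_profile(time=current.time, dt=dt)
    cond = prepare_condition(motion, current, None, observer_params, tf_bank, basis, fusion_template.k_r)
    roll = _batched_roll(cond, np.asarray(k_reg, float), np.asarray(k_gvs, float), observer_params, fusion_template)
    idx = int(np.searchsorted(cond.time, readout_s)) - 1
    return np.abs(roll[:, idx]) / abs(amplitude_ma)


def static_cost(
    k_reg: float,
    k_gvs: float,
    target_deg_per_ma: float = DEFAULT_STATIC_TARGET_DEG_PER_MA,
    **kwargs,
) -> float:
    """Squared error between the simulated DC tilt gain and the static target."""
    gain = static_tilt_gain(k_reg, k_gvs, **kwargs)
    return float((gain - target_deg_per_ma) ** 2)


def static_cost_surface(
    k_reg_grid,
    k_gvs_grid,
    target_deg_per_ma: float = DEFAULT_STATIC_TARGET_DEG_PER_MA,
    **kwargs,
) -> CostSurface:
    k_reg_grid = np.asarray(k_reg_grid, dtype=float)
    k_gvs_grid = np.asarray(k_gvs_grid, dtype=float)
    kr, kg = np.meshgrid(k_reg_grid, k_gvs_grid, indexing="ij")
    gains = _static_gain_batch(
        kr.ravel(), kg.ravel(),
        kwargs.pop("amplitude_ma", 1.0), kwargs.pop("readout_s", 25.0),
        kwargs.pop("observer_params", None), kwargs.pop("fusion_template", None),
        kwargs.pop("tf_bank", None), kwargs.pop("basis", None), kwargs.pop("dt", 0.01),
    )
    j = ((gains - target_deg_per_ma) ** 2).reshape(k_reg_grid.size, k_gvs_grid.size)
    return CostSurface(k_reg_grid, k_gvs_grid, j)


def extract_fronts_and_joint_fit(
    dynamic_surface: CostSurface,
    static_surface: CostSurface,
    weight: float = 1.0,
    weight_sweep: tuple[float, float] = (0.1, 10.0),
    eps: float = 1e-9,
) -> FitResult:
    """Per-paradigm optimal fronts and the weight-normalized joint optimum.

    Each surface is normalized by its own minimum (+eps) before the weighted
    sum, and the joint K_Reg is checked for stability across a sweep of the
    relative weight spanning ``weight_sweep`` (two decades by default).
    """
    if dynamic_surface.j_mse.shape != static_surface.j_mse.shape or not np.allclose(
        dynamic_surface.k_reg_grid, static_surface.k_reg_grid
    ):
        raise ValueError("cost surfaces must share one grid")

    def joint(w: float) -> np.ndarray:
        a = dynamic_surface.j_mse / (dynamic_surface.j_mse.min() + eps)
        b = static_surface.j_mse / (static_surface.j_mse.min() + eps)
        return a + w * b

    j = joint(weight)
    i, k = np.unravel_index(np.argmin(j), j.shape)
    k_reg_opt = float(dynamic_surface.k_reg_grid[i])
    k_gvs_opt = float(dynamic_surface.k_gvs_grid[k])

    sweep = np.geomspace(weight_sweep[0], weight_sweep[1], 9)
    k_regs = []
    for w in sweep:
        jj = joint(w)
        ii, _ = np.unravel_index(np.argmin(jj), jj.shape)
        k_regs.append(dynamic_surface.k_reg_grid[ii])
    return FitResult(
        k_reg_opt=k_reg_opt,
        k_gvs_opt=k_gvs_opt,
        dynamic_front=dynamic_surface.front(),
        static_front=static_surface.front(),
        k_reg_grid=dynamic_surface.k_reg_grid,
        weight_insensitive=bool(np.allclose(k_regs, k_regs[0])),
        joint_cost=j,
    )


def fit_individual_gain(
    gvs_trials: list[tuple[ConditionData, np.ndarray]],
    trained_k_gvs: float = 0.0245,
    participant: str = "",
    k_gvs_grid: np.ndarray | None = None,
    exclude_small_tilt: bool = False,
    observer_params: ObserverParams | None = None,
    fusion_template: FusionParams | None = None,
) -> IndividualFit:
    """Fit a participant's GVS gain (K_Reg = 0) from all their GVS trials.

    ``gvs_trials`` pairs each trial's precomputed condition with the
    participant's corrected perception trace.  ``exclude_small_tilt``
    ignores samples with |actual tilt| < 2 deg (outlier refits for
    participants who park the report bar near zero).
    """
    if not gvs_trials:
        raise ValueError("no GVS trials supplied")
    if observer_params is None:
        observer_params = ObserverParams()
    if fusion_template is None:
        fusion_template = FusionParams()
    if k_gvs_grid is None:
        k_gvs_grid = np.concatenate([[0.0], np.geomspace(0.002, 0.12, 40)])
    k_gvs_grid = np.asarray(k_gvs_grid, dtype=float)
    k_reg = np.zeros_like(k_gvs_grid)

    sq = np.zeros(k_gvs_grid.size)
    n_tot = 0
    for cond, perception in gvs_trials:
        perception = np.asarray(perception, dtype=float)
        roll = _batched_roll(cond, k_reg, k_gvs_grid, observer_params, fusion_template)
        if exclude_small_tilt:
            actual = _actual_roll(cond)
            keep = np.abs(actual) >= 2.0
        else:
            keep = np.ones(cond.time.size, dtype=bool)
        sq += np.sum((roll[:, keep] - perception[None, keep]) ** 2, axis=1)
        n_tot += int(np.sum(keep))
    mse = sq / max(n_tot, 1)
    best = int(np.argmin(mse))

    # one parabolic refinement pass around the grid optimum
    k_best, m_best = k_gvs_grid[best], mse[best]
    if 0 < best < k_gvs_grid.size - 1:
        x = k_gvs_grid[best - 1 : best + 2]
        y = mse[best - 1 : best + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        if abs(denom) > 0:
            a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
            b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
            if a > 0:
                k_v = -b / (2 * a)
                if x[0] <= k_v <= x[2]:
                    k_best = float(k_v)
    return IndividualFit(
        participant=participant,
        k_gvs_sub=float(k_best),
        susceptibility=float(k_best / trained_k_gvs),
        mse=float(m_best),
    )


def _actual_roll(cond: ConditionData) -> np.ndarray:
    """Actual roll tilt of a condition, reconstructed from the true gravity direction."""
    return np.degrees(np.arctan2(cond.f_gif[:, 1], cond.f_gif[:, 2]))
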