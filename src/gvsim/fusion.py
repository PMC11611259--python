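"""Fusion of GVS-evoked and physical-motion canal afference.

GVS-evoked signals arrive in firing-rate units (dspk/s) and are converted to
angular velocity with per-channel gain interpreters (the inverse passband
gain of physical canal transduction: 1.85 deg/s per dspk/s for irregular,
2.29 for regular afferents).  The joint canal afference is the convex
combination across afferent channels

    alpha_SCC = K_Reg  * (alpha_phys + K_GVS * alpha_GVS^Reg)
              + (1 - K_Reg) * (alpha_phys + K_GVS * alpha_GVS^Irreg)

with the trained operating point K_Reg = 0, K_GVS = 0.0245 (irregular-only
dynamics).  Physical afference is assumed bilaterally symmetric and identical
across channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afferent import TransferFunctionSpec, default_tf_bank, simulate_afferent_response
from .geometry import CanalBasis, HeadFrameSignal, afferent_to_head_frame, combine_ears, default_canal_basis

__all__ = [
    "FusionParams",
    "fuse_canal_signals",
    "gvs_afference",
    "gvs_virtual_rotation",
    "peak_gvs_rotation_rate",
]


@dataclass
class FusionParams:
    """Gains and unit interpreters of the canal-signal fusion stage.

    k_gvs : trained GVS-effect gain (dimensionless; absorbs species/montage scaling)
    k_reg : regular-channel contribution in [0, 1]; irregular weight is 1 - k_reg
    interp_irregular / interp_regular : deg/s per dspk/s conversion for GVS signals
    k_r : right-ear weight (left weight = 1 - k_r)
    """

    k_gvs: float = 0.0245
    k_reg: float = 0.0
    interp_irregular: float = 1.85
    interp_regular: float = 2.29
    k_r: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_reg <= 1.0:
            raise ValueError(f"k_reg must lie in [0, 1], got {self.k_reg}")
        if self.interp_irregular <= 0 or self.interp_regular <= 0:
            raise ValueError("gain interpreters must be positive")
        if not 0.0 <= self.k_r <= 1.0:
            raise ValueError(f"k_r must lie in [0, 1], got {self.k_r}")

    @property
    def k_irreg(self) -> float:
        return 1.0 - self.k_reg

    @property
    def k_l(self) -> float:
        return 1.0 - self.k_r


def _as_alpha(x) -> np.ndarray:
    if isinstance(x, HeadFrameSignal):
        return x.alpha
    return np.asarray(x, dtype=float)


def fuse_canal_signals(
    alpha_phys_reg,
    alpha_phys_irreg,
    alpha_gvs_reg,
    alpha_gvs_irreg,
    params: FusionParams,
) -> np.ndarray:
    """Joint canal afference (deg/s, head frame) from physical and GVS signals.

    Physical inputs are already in deg/s; GVS inputs are in dspk/s and are
    converted internally with each channel's gain interpreter.
    """
    phys_reg = _as_alpha(alpha_phys_reg)
    phys_irreg = _as_alpha(alpha_phys_irreg)
    gvs_reg = _as_alpha(alpha_gvs_reg) * params.interp_regular
    gvs_irreg = _as_alpha(alpha_gvs_irreg) * params.interp_irregular
    for name, x in (("alpha_gvs_reg", gvs_reg), ("alpha_gvs_irreg", gvs_irreg)):
        if x.shape != phys_reg.shape:
            raise ValueError(f"{name} grid does not match the physical signals")
    return params.k_reg * (phys_reg + params.k_gvs * gvs_reg) + params.k_irreg * (
        phys_irreg + params.k_gvs * gvs_irreg
    )


def gvs_afference(
    time: np.ndarray,
    current_ma: np.ndarray,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
    k_r: float = 0.5,
) -> dict[str, HeadFrameSignal]:
    """Per-channel ear-combined head-frame GVS afference (dspk/s) for a current waveform."""
    if tf_bank is None:
        tf_bank = default_tf_bank()
    if basis is None:
        basis = default_canal_basis()
    out: dict[str, HeadFrameSignal] = {}
    for channel in ("regular", "irregular"):
        per_ear = {}
        for ear in ("left", "right"):
            resp = simulate_afferent_response(time, current_ma, ear, channel, tf_bank)
            per_ear[ear] = afferent_to_head_frame(resp, basis)
        out[channel] = combine_ears(per_ear["right"], per_ear["left"], k_r)
    return out


def gvs_virtual_rotation(
    time: np.ndarray,
    current_ma: np.ndarray,
    params: FusionParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
) -> np.ndarray:
    """Net GVS-evoked virtual angular velocity (deg/s, (n,3)) after fusion weights.

    This is the GVS-only term of the fused canal afference:
    K_GVS * [K_Reg * interp_reg * alpha_reg + (1-K_Reg) * interp_irreg * alpha_irreg].
    """
    if params is None:
        params = FusionParams()
    aff = gvs_afference(time, current_ma, tf_bank, basis, params.k_r)
    zero = np.zeros_like(aff["regular"].alpha)
    return fuse_canal_signals(zero, zero, aff["regular"], aff["irregular"], params)


def peak_gvs_rotation_rate(
    current_peak_ma: float = 1.0,
    params: FusionParams | None = None,
    basis: CanalBasis | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    duration_s: float = 60.0,
    dt: float = 0.01,
) -> float:
    """Peak virtual rotation rate about the net GVS vector, deg/s per mA.

    Simulates a DC current onset at ``current_peak_ma`` and returns
    max_t |omega_GVS(t)| / current_peak_ma with trained fusion parameters.
    """
    if params is None:
        params = FusionParams()
    if params.k_gvs == 0.0:
        return 0.0
    time = np.arange(0.0, duration_s, dt)
    current = np.full_like(time, float(current_peak_ma))
    omega = gvs_virtual_rotation(time, current, params, tf_bank, basis)
    return float(np.max(np.linalg.norm(omega, axis=1)) / abs(current_peak_ma))
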