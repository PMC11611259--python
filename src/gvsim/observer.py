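"""Observer model of central vestibular processing.

The CNS is modeled as an observer that compares vestibular afference with
internal-model predictions of that afference and corrects its state
estimates with gain-weighted sensory conflicts:

* canal afference ``alpha`` (physical transduction + any GVS-evoked virtual
  rotation) is compared with the internal canal model applied to the angular
  velocity estimate, giving the rotational conflict ``e_w``;
* otolith afference is the gravito-inertial force (GIF) ``f = g - a`` in the
  head frame; it is compared with the expected GIF ``f_hat = g_hat - a_hat``,
  giving a rotational otolith conflict ``e_f`` (the axis that rotates
  ``f_hat`` toward ``f``) and a vector conflict driving the acceleration
  estimate.

Estimates are updated as

    w_hat = (k_w * (alpha + c_hat) + k_fw * e_f) / (1 + k_w)
    a_hat = k_a / (1 - k_a) * (f - g_hat)
    d(g_hat)/dt = g_hat x (w_hat + k_f * e_f)

where ``c_hat`` is the internal canal model's low-pass state (the canal
model is the first-order high-pass ``tau_d s / (tau_d s + 1)``) and the
``k_f`` term is the somatogravic pathway continuously pulling the tilt
estimate toward the sensed GIF direction.  The cross-product propagation of
``g_hat`` is the internal kinematic model that disambiguates tilt from
translation; the somatogravic pathway bounds the tilt that sustained
(virtual) rotation cues can produce.

Default parameters (k_w = 8, k_f = 4, k_fw = 8, k_a = -4, tau_d = 5.7 s) are
the canonical set of the passive-motion observer-model lineage; the model is
deliberately left maladapted to GVS (internal models unchanged), so
GVS-evoked afference is processed exactly like physical afference.

The integration core is batched: state arrays have shape (batch, 3), so a
Monte Carlo population or a parameter grid is propagated in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .afferent import TransferFunctionSpec
from .fusion import FusionParams, fuse_canal_signals, gvs_afference
from .geometry import CanalBasis

__all__ = [
    "ObserverParams",
    "PerceptionTrace",
    "canal_transduction",
    "observer_simulate",
    "simulate_trial",
    "roll_tilt_from_gravity",
    "pitch_tilt_from_gravity",
    "gravity_in_head_frame",
]

_DEG = np.pi / 180.0


@dataclass
class ObserverParams:
    """Central-processing gains and integration settings.

    tau_d : canal (and internal canal model) time constant, seconds
    k_w   : angular-velocity conflict gain
    k_f   : somatogravic GIF feedback gain (1/s on the rotational otolith conflict)
    k_fw  : rotational GIF-conflict feedback gain into the angular-velocity estimate
    k_a   : acceleration conflict gain (negative in the canonical set)
    g0    : gravity magnitude, m/s^2
    dt    : integration step, seconds (fixed-step Heun scheme)
    renormalize_g : optionally rescale |g_hat| to g0 each step (numerical hygiene;
        the readout uses direction only, so this does not change tilt)
    """

    tau_d: float = 5.7
    k_w: float = 8.0
    k_f: float = 4.0
    k_fw: float = 8.0
    k_a: float = -4.0
    g0: float = 9.81
    dt: float = 0.01
    renormalize_g: bool = False

    def __post_init__(self) -> None:
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("k_w", "k_f", "k_fw", "k_a"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class PerceptionTrace:
    """Time course of the observer's perceptual estimates for one simulation."""

    time: np.ndarray
    omega_hat: np.ndarray  # (n, 3) deg/s
    a_hat: np.ndarray      # (n, 3) m/s^2
    g_hat: np.ndarray      # (n, 3) m/s^2
    roll_tilt: np.ndarray  # deg, positive = right ear down
    pitch_tilt: np.ndarray # deg, positive = nose up (pitched back)
    e_omega: np.ndarray    # (n, 3) deg/s canal conflict
    e_f: np.ndarray        # (n, 3) dimensionless rotational otolith conflict


def roll_tilt_from_gravity(g_hat: np.ndarray) -> np.ndarray:
    """Signed roll tilt (deg) read out from a gravity-direction estimate.

    The angle of g_hat's projection onto the head y-z plane relative to +z;
    positive = right ear down (g_hat leaning toward +y, the left-ear axis).
    """
    g_hat = np.asarray(g_hat, dtype=float)
    if np.any(np.linalg.norm(g_hat, axis=-1) < 1e-12):
        raise ValueError("gravity estimate has zero magnitude")
    return np.degrees(np.arctan2(g_hat[..., 1], g_hat[..., 2]))


def pitch_tilt_from_gravity(g_hat: np.ndarray) -> np.ndarray:
    """Signed pitch tilt (deg), positive = nose up (g_hat leaning toward +x)."""
    g_hat = np.asarray(g_hat, dtype=float)
    if np.any(np.linalg.norm(g_hat, axis=-1) < 1e-12):
        raise ValueError("gravity estimate has zero magnitude")
    return np.degrees(np.arctan2(g_hat[..., 0], g_hat[..., 2]))


def canal_transduction(omega_dps: np.ndarray, tau_d: float = 5.7, dt: float = 0.01) -> np.ndarray:
    """Physical canal afference: first-order high-pass filtered angular velocity.

    ``tau_d s / (tau_d s + 1)`` applied per axis (bilinear discretization);
    in the passband afference equals angular velocity, and a sustained
    rotation washes out with time constant ``tau_d``.
    """
    omega_dps = np.asarray(omega_dps, dtype=float)
    b, a = _signal.bilinear([tau_d, 0.0], [tau_d, 1.0], fs=1.0 / dt)
    axis = 0 if omega_dps.ndim > 1 else -1
    return _signal.lfilter(b, a, omega_dps, axis=axis)


def gravity_in_head_frame(
    omega_dps: np.ndarray,
    dt: float,
    g0: float = 9.81,
    initial_roll_deg: float = 0.0,
    initial_pitch_deg: float = 0.0,
) -> np.ndarray:
    """True gravity vector in head coordinates over time, from head angular velocity.

    Integrates dg/dt = g x omega exactly per step (Rodrigues rotation about
    the step-average angular velocity), preserving |g| = g0.  The initial
    orientation tilts g away from [0, 0, g0]: positive roll = right ear
    down, positive pitch = nose up.
    """
    omega = np.asarray(omega_dps, dtype=float) * _DEG
    n = omega.shape[0]
    g = np.empty((n, 3))
    r0 = np.radians(initial_roll_deg)
    p0 = np.radians(initial_pitch_deg)
    g[0] = g0 * np.array([np.sin(p0) * np.cos(r0), np.sin(r0) * np.cos(p0), np.cos(r0) * np.cos(p0)])
    g[0] *= g0 / np.linalg.norm(g[0])
    for k in range(n - 1):
        w = 0.5 * (omega[k] + omega[k + 1])
        th = np.linalg.norm(w) * dt
        if th < 1e-12:
            g[k + 1] = g[k]
            continue
        axis = w / np.linalg.norm(w)
        # dg/dt = g x w  <=>  rotation of g about -w by |w| dt
        c, s = np.cos(th), np.sin(th)
        v = g[k]
        g[k + 1] = c * v + s * np.cross(v, axis) + (1 - c) * np.dot(axis, v) * axis
    return g


def _observer_core(
    alpha_dps: np.ndarray,
    f_gif: np.ndarray,
    params: ObserverParams,
    g_init: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Batched fixed-step Heun integration of the observer.

    alpha_dps : (batch, n, 3) canal afference in deg/s
    f_gif     : (n, 3) sensed GIF in m/s^2 (shared across the batch)
    g_init    : (3,) initial gravity estimate
    Returns (omega_hat, a_hat, g_hat, e_omega, e_f) with leading batch axis.
    """
    alpha = np.asarray(alpha_dps, dtype=float) * _DEG  # rad/s internally
    batch, n, _ = alpha.shape
    f = np.asarray(f_gif, dtype=float)
    dt = params.dt
    kw, kf, kfw, ka = params.k_w, params.k_f, params.k_fw, params.k_a
    ka_fac = ka / (1.0 - ka)
    eps = 1e-12

    g = np.broadcast_to(g_init, (batch, 3)).copy()
    c_hat = np.zeros((batch, 3))  # low-pass state of the internal canal model

    omega_out = np.empty((batch, n, 3))
    a_out = np.empty((batch, n, 3))
    g_out = np.empty((batch, n, 3))
    ew_out = np.empty((batch, n, 3))
    ef_out = np.empty((batch, n, 3))

    def eval_step(gv, cv, al_k, f_k):
        a_hat = ka_fac * (f_k - gv)
        f_hat = gv - a_hat
        cross = np.cross(np.broadcast_to(f_k, gv.shape), f_hat)
        denom = np.linalg.norm(f_k) * np.linalg.norm(f_hat, axis=1) + eps
        e_f = cross / denom[:, None]
        w_hat = (kw * (al_k + cv) + kfw * e_f) / (1.0 + kw)
        g_dot = np.cross(gv, w_hat + kf * e_f)
        c_dot = (w_hat - cv) / params.tau_d
        e_w = al_k - (w_hat - cv)
        return g_dot, c_dot, w_hat, a_hat, e_w, e_f

    for k in range(n):
        al_k = alpha[:, k, :]
        f_k = f[k]
        g_dot1, c_dot1, w_hat, a_hat, e_w, e_f = eval_step(g, c_hat, al_k, f_k)

        omega_out[:, k, :] = w_hat
        a_out[:, k, :] = a_hat
        g_out[:, k, :] = g
        ew_out[:, k, :] = e_w
        ef_out[:, k, :] = e_f

        if k == n - 1:
            break
        # Heun predictor-corrector with inputs at k and k+1
        g_pred = g + dt * g_dot1
        c_pred = c_hat + dt * c_dot1
        g_dot2, c_dot2, *_ = eval_step(g_pred, c_pred, alpha[:, k + 1, :], f[k + 1])
        g = g + 0.5 * dt * (g_dot1 + g_dot2)
        c_hat = c_hat + 0.5 * dt * (c_dot1 + c_dot2)
        if params.renormalize_g:
            g *= params.g0 / (np.linalg.norm(g, axis=1, keepdims=True) + eps)
        if not np.all(np.isfinite(g)) or np.any(np.abs(g) > 1e6):
            raise FloatingPointError(
                f"observer state diverged at t={k * dt:.2f}s (|g_hat| overflow); "
                "check input scaling and gains"
            )

    return omega_out / _DEG, a_out, g_out, ew_out / _DEG, ef_out


def observer_simulate(
    time: np.ndarray,
    alpha_scc_dps: np.ndarray,
    f_gif: np.ndarray | None = None,
    params: ObserverParams | None = None,
    initial_roll_deg: float = 0.0,
    initial_pitch_deg: float = 0.0,
) -> PerceptionTrace:
    """Run the observer on fused canal afference (physical + GVS).

    Parameters
    ----------
    time : uniform time grid, seconds
    alpha_scc_dps : (n, 3) fused canal afference, deg/s
    f_gif : (n, 3) sensed gravito-inertial force in head coordinates, m/s^2.
        Defaults to a stationary upright observer ([0, 0, g0] throughout);
        the net GVS effect on the otolith system is taken as zero.
    """
    if params is None:
        params = ObserverParams()
    time = np.asarray(time, dtype=float)
    grid_dt = float(time[1] - time[0])
    if not np.isclose(grid_dt, params.dt):
        params = ObserverParams(**{**params.__dict__, "dt": grid_dt})
    alpha = np.asarray(alpha_scc_dps, dtype=float)
    if alpha.ndim == 2:
        alpha = alpha[None, :, :]
    if f_gif is None:
        f_gif = np.tile([0.0, 0.0, params.g0], (time.size, 1))
    r0, p0 = np.radians(initial_roll_deg), np.radians(initial_pitch_deg)
    g_init = params.g0 * np.array(
        [np.sin(p0) * np.cos(r0), np.sin(r0) * np.cos(p0), np.cos(r0) * np.cos(p0)]
    )
    g_init *= params.g0 / np.linalg.norm(g_init)
    w, a, g, ew, ef = _observer_core(alpha, f_gif, params, g_init)
    return PerceptionTrace(
        time=time,
        omega_hat=w[0],
        a_hat=a[0],
        g_hat=g[0],
        roll_tilt=roll_tilt_from_gravity(g[0]),
        pitch_tilt=pitch_tilt_from_gravity(g[0]),
        e_omega=ew[0],
        e_f=ef[0],
    )


def simulate_trial(
    motion,
    current,
    fusion_params: FusionParams | None = None,
    observer_params: ObserverParams | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    basis: CanalBasis | None = None,
) -> PerceptionTrace:
    """End-to-end perception for one trial: GVS current + 6DoF motion -> trace.

    ``motion`` is a :class:`~gvsim.paradigms.MotionProfile` (or None for a
    stationary upright observer); ``current`` is a
    :class:`~gvsim.paradigms.CurrentWaveform` (or None for no GVS).  Both
    must share one time grid.
    """
    from .paradigms import CurrentWaveform, MotionProfile, stationary_profile

    if fusion_params is None:
        fusion_params = FusionParams()
    if observer_params is None:
        observer_params = ObserverParams()

    if motion is None and current is None:
        raise ValueError("need at least one of motion or current")
    if motion is None:
        motion = stationary_profile(time=current.time)
    t = motion.time
    dt = float(t[1] - t[0])
    if current is not None:
        if current.time.shape != t.shape or not np.allclose(current.time, t):
            raise ValueError("motion and current must share one time grid")
        current_ma = current.current_ma
    else:
        current_ma = np.zeros_like(t)

    # physical canal afference (identical dynamics for both afferent channels)
    alpha_phys = canal_transduction(motion.omega_dps, observer_params.tau_d, dt)

    if np.any(current_ma != 0.0):
        aff = gvs_afference(t, current_ma, tf_bank, basis, fusion_params.k_r)
        alpha_scc = fuse_canal_signals(alpha_phys, alpha_phys, aff["regular"], aff["irregular"], fusion_params)
    else:
        alpha_scc = alpha_phys

    g_true = gravity_in_head_frame(
        motion.omega_dps, dt, observer_params.g0, motion.initial_roll_deg, motion.initial_pitch_deg
    )
    f = g_true - motion.accel_mps2
    return observer_simulate(
        t,
        alpha_scc,
        f,
        observer_params,
        initial_roll_deg=motion.initial_roll_deg,
        initial_pitch_deg=motion.initial_pitch_deg,
    )
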