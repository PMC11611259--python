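"""Stimulus generators: motion profiles and coupled GVS waveforms.

The dynamic-tilt experiment uses whole-body roll along pseudorandom
sum-of-sines profiles (three equal-power components, 0.07-0.36 Hz, zero
phase, peak +/-8 deg, two full cycles of the 0.07 Hz component with
sigmoidal on/off ramps) with GVS current coupled to tilt angle, tilt
velocity, or their normalized average (joint), at +/-4 mA peak.  Positive
coupling delivers current of opposite sign to the physical characteristic
(left anode / right cathode when the characteristic is positive), which
amplifies perceived tilt; negative coupling attenuates it.  DC and
quasistatic pitch-tilt paradigms support the static predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "MotionProfile",
    "CurrentWaveform",
    "SOS_FREQ_SETS",
    "make_sum_of_sines_profile",
    "make_coupled_gvs",
    "make_dc_paradigm",
    "make_pitch_dc_paradigm",
    "stationary_profile",
    "standard_design",
    "TrialSpec",
]

#: The three sum-of-sines frequency triples (Hz) of the dynamic experiment.
SOS_FREQ_SETS: tuple[tuple[float, float, float], ...] = (
    (0.07, 0.18, 0.31),
    (0.07, 0.25, 0.33),
    (0.07, 0.19, 0.36),
)

COUPLINGS = ("angle", "velocity", "joint", "dc", "none")


@dataclass
class MotionProfile:
    """Passive 6DoF head-motion profile on a uniform time grid.

    Angles are head-frame Euler-style tilt readouts for single-axis profiles;
    ``omega_dps`` is the head-frame angular velocity actually integrated by
    the simulation (x roll, y pitch axis, z yaw), and ``accel_mps2`` the
    head-frame linear acceleration.
    """

    time: np.ndarray
    roll_deg: np.ndarray
    pitch_deg: np.ndarray
    yaw_deg: np.ndarray
    omega_dps: np.ndarray   # (n, 3)
    accel_mps2: np.ndarray  # (n, 3)
    label: str = ""
    initial_roll_deg: float = 0.0
    initial_pitch_deg: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.time).size
        for name in ("roll_deg", "pitch_deg", "yaw_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the time grid")
            setattr(self, name, arr)
        self.time = np.asarray(self.time, dtype=float)
        self.omega_dps = np.asarray(self.omega_dps, dtype=float).reshape(n, 3)
        self.accel_mps2 = np.asarray(self.accel_mps2, dtype=float).reshape(n, 3)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class CurrentWaveform:
    """GVS current over time.  Positive current = left cathode, right anode."""

    time: np.ndarray
    current_ma: np.ndarray
    coupling: str = "none"
    sign: str = "positive"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current_ma = np.asarray(self.current_ma, dtype=float)
        if self.time.shape != self.current_ma.shape:
            raise ValueError("time and current must be the same length")
        if self.coupling not in COUPLINGS:
            raise ValueError(f"coupling must be one of {COUPLINGS}, got {self.coupling!r}")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")

    @property
    def peak_ma(self) -> float:
        return float(np.max(np.abs(self.current_ma)))


def _raised_cosine_envelope(time: np.ndarray, t_ramp: float) -> np.ndarray:
    """Sigmoidal (raised-cosine) on/off envelope over the first/last ``t_ramp`` seconds."""
    env = np.ones_like(time)
    total = time[-1]
    head = time < t_ramp
    env[head] = 0.5 * (1.0 - np.cos(np.pi * time[head] / t_ramp))
    tail = time > total - t_ramp
    env[tail] = 0.5 * (1.0 - np.cos(np.pi * (total - time[tail]) / t_ramp))
    return env


def make_sum_of_sines_profile(
    freqs_hz: tuple[float, float, float] = SOS_FREQ_SETS[0],
    peak_deg: float = 8.0,
    mirror: bool = False,
    dt: float = 0.01,
) -> MotionProfile:
    """Pseudorandom sum-of-sines whole-body roll profile.

    Three equal-amplitude (equal-power) zero-phase sinusoids, globally scaled
    to ``peak_deg`` maximum roll; duration is two full cycles of the lowest
    component, with a raised-cosine ramp over the first and last half cycle
    of that component.  ``mirror=True`` negates the whole profile.
    """
    freqs = tuple(float(f) for f in freqs_hz)
    if len(freqs) < 3:
        raise ValueError("need three component frequencies")
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")
    f0 = min(freqs)
    duration = 2.0 / f0
    time = np.arange(0.0, duration + dt / 2, dt)
    angle = np.sum([np.sin(2 * np.pi * f * time) for f in freqs], axis=0)
    angle *= _raised_cosine_envelope(time, t_ramp=0.5 / f0)
    angle *= peak_deg / np.max(np.abs(angle))
    if mirror:
        angle = -angle
    vel = np.gradient(angle, dt)
    omega = np.zeros((time.size, 3))
    omega[:, 0] = vel
    label = f"sos-{'-'.join(f'{f:g}' for f in freqs)}{'-mirror' if mirror else ''}"
    return MotionProfile(
        time=time,
        roll_deg=angle,
        pitch_deg=np.zeros_like(angle),
        yaw_deg=np.zeros_like(angle),
        omega_dps=omega,
        accel_mps2=np.zeros((time.size, 3)),
        label=label,
    )


def make_coupled_gvs(
    profile: MotionProfile,
    coupling: str,
    sign: str = "positive",
    peak_ma: float = 4.0,
) -> CurrentWaveform:
    """GVS current coupled to a physical characteristic of a roll profile.

    ``coupling`` selects tilt angle, tilt velocity, or the mean of the two
    peak-normalized signals (``joint``).  Positive coupling delivers current
    of opposite sign to the characteristic (tilt right -> left anode / right
    cathode, i.e. negative current); negative coupling flips that.
    """
    if coupling not in ("angle", "velocity", "joint"):
        raise ValueError("coupling must be 'angle', 'velocity', or 'joint'")
    angle = profile.roll_deg
    vel = profile.omega_dps[:, 0]
    a_pk, v_pk = np.max(np.abs(angle)), np.max(np.abs(vel))
    if a_pk < 1e-12 or v_pk < 1e-12:
        raise ValueError("cannot couple GVS to a zero-amplitude profile")
    if coupling == "angle":
        char = angle / a_pk
    elif coupling == "velocity":
        char = vel / v_pk
    else:
        char = 0.5 * (angle / a_pk + vel / v_pk)
    current = -char / np.max(np.abs(char)) * peak_ma
    if sign == "negative":
        current = -current
    return CurrentWaveform(time=profile.time, current_ma=current, coupling=coupling, sign=sign)


def stationary_profile(
    duration_s: float | None = None,
    dt: float = 0.01,
    time: np.ndarray | None = None,
) -> MotionProfile:
    """Upright, physically stationary observer."""
    if time is None:
        if duration_s is None:
            raise ValueError("supply duration_s or an explicit time grid")
        time = np.arange(0.0, duration_s, dt)
    time = np.asarray(time, dtype=float)
    z = np.zeros_like(time)
    return MotionProfile(
        time=time,
        roll_deg=z,
        pitch_deg=z.copy(),
        yaw_deg=z.copy(),
        omega_dps=np.zeros((time.size, 3)),
        accel_mps2=np.zeros((time.size, 3)),
        label="stationary",
    )


def make_dc_paradigm(
    amplitude_ma: float,
    t_on: float = 0.0,
    t_off: float = 25.0,
    total_s: float = 35.0,
    dt: float = 0.01,
) -> CurrentWaveform:
    """Constant current on [t_on, t_off), zero elsewhere (upright, no motion)."""
    if not (t_on < t_off <= total_s):
        raise ValueError("need t_on < t_off <= total_s")
    time = np.arange(0.0, total_s, dt)
    current = np.where((time >= t_on) & (time < t_off), float(amplitude_ma), 0.0)
    return CurrentWaveform(time=time, current_ma=current, coupling="dc")


def make_pitch_dc_paradigm(
    pitch_deg: float,
    amplitude_ma: float = 4.0,
    dt: float = 0.01,
    pitch_rate_dps: float = 1.0,
    settle_s: float = 5.0,
    dc_duration_s: float = 25.0,
    tail_s: float = 10.0,
) -> tuple[MotionProfile, CurrentWaveform]:
    """Quasistatic pitch-back to ``pitch_deg`` held during DC stimulation.

    The pitch ramp (default 1 deg/s, slow relative to canal dynamics) runs
    first; after ``settle_s`` the DC window starts.  Nose-up pitch is a
    rotation about the -y head axis.
    """
    if not 0.0 <= pitch_deg <= 90.0:
        raise ValueError("pitch_deg must lie in [0, 90]")
    ramp_T = pitch_deg / pitch_rate_dps if pitch_deg > 0 else 0.0
    total = ramp_T + settle_s + dc_duration_s + tail_s
    time = np.arange(0.0, total, dt)
    pitch = np.minimum(time * pitch_rate_dps, pitch_deg) if pitch_deg > 0 else np.zeros_like(time)
    pitch_vel = np.gradient(pitch, dt)
    omega = np.zeros((time.size, 3))
    omega[:, 1] = -pitch_vel  # nose-up = negative rotation about +y (y out the left ear)
    motion = MotionProfile(
        time=time,
        roll_deg=np.zeros_like(time),
        pitch_deg=pitch,
        yaw_deg=np.zeros_like(time),
        omega_dps=omega,
        accel_mps2=np.zeros((time.size, 3)),
        label=f"pitch-{pitch_deg:g}",
    )
    t_on = ramp_T + settle_s
    current = np.where((time >= t_on) & (time < t_on + dc_duration_s), float(amplitude_ma), 0.0)
    return motion, CurrentWaveform(time=time, current_ma=current, coupling="dc")


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the 48-trial dynamic-tilt design."""

    block: int
    freq_set: tuple[float, float, float]
    mirror: bool
    coupling: str  # "none" for the sham condition
    sign: str      # "positive"/"negative"; ignored for sham

    @property
    def label(self) -> str:
        if self.coupling == "none":
            return f"block{self.block}-{self.freq_set[1]:g}-{'L' if self.mirror else 'R'}-noGVS"
        return (
            f"block{self.block}-{self.freq_set[1]:g}-{'L' if self.mirror else 'R'}-"
            f"{self.sign}-{self.coupling}"
        )


def standard_design() -> list[TrialSpec]:
    """Deterministic enumeration of the 48-trial, two-block experiment design.

    Each block holds a sham (No GVS) trial for all six motion profiles plus
    one trial of each of the six GVS coupling schemes paired with one
    mirror-version of each base profile; the second block covers the
    combinations the first did not.
    """
    trials: list[TrialSpec] = []
    schemes = [(c, s) for s in ("positive", "negative") for c in ("angle", "velocity", "joint")]
    for block in (1, 2):
        for fs in SOS_FREQ_SETS:
            for mirror in (False, True):
                trials.append(TrialSpec(block, fs, mirror, "none", "positive"))
        for i, (coupling, sign) in enumerate(schemes):
            for j, fs in enumerate(SOS_FREQ_SETS):
                # block 1 pairs each scheme with one mirror version per base
                # profile; block 2 covers the complementary versions
                mirror = ((i + j) % 2 == 1) ^ (block == 2)
                trials.append(TrialSpec(block, fs, mirror, coupling, sign))
    assert len(trials) == 48
    return trials
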