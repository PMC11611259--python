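"""Subjective-haptic-horizontal (SHH) report preprocessing and outcome metrics.

Raw continuous tilt reports carry a participant-specific left/right bias, a
reaction-time delay, and an over/under-deflection gain.  These are corrected
sequentially from the sham (No GVS) trials: the bias minimizing the MSE
between raw report and actual tilt; then the delay minimizing the MSE of the
bias-adjusted report; then the gain minimizing the mean absolute difference,
restricted to samples where |actual tilt| > 2 deg so near-zero reporting does
not dominate.  Two scalar outcome metrics quantify amplification and
attenuation of tilt perception: the Mean Absolute Tilt Perception (time-mean
of |perceived tilt|) and the Perceived/Actual Tilt Slope (least-squares
slope of perceived on actual tilt).  Glass's delta and Hedges' g effect
sizes accompany condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ShhTrial",
    "ReportCorrection",
    "fit_report_correction",
    "apply_correction",
    "mean_absolute_tilt",
    "perceived_actual_slope",
    "glass_delta",
    "hedges_g",
    "effect_sizes",
]

SMALL_TILT_DEG = 2.0


@dataclass
class ShhTrial:
    """One trial's continuous SHH report alongside the delivered tilt."""

    time: np.ndarray
    raw_report_deg: np.ndarray
    actual_tilt_deg: np.ndarray
    participant: str = ""
    coupling: str = "none"
    sign: str = "positive"
    motion_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw_report_deg = np.asarray(self.raw_report_deg, dtype=float)
        self.actual_tilt_deg = np.asarray(self.actual_tilt_deg, dtype=float)
        if not (self.time.shape == self.raw_report_deg.shape == self.actual_tilt_deg.shape):
            raise ValueError("time, raw report, and actual tilt must be aligned")
        if not (np.all(np.isfinite(self.raw_report_deg)) and np.all(np.isfinite(self.actual_tilt_deg))):
            raise ValueError("trial arrays must be finite")

    @property
    def is_gvs(self) -> bool:
        return self.coupling not in ("none",)


@dataclass
class ReportCorrection:
    """Per-participant report correction: subtract bias, advance by delay, scale by gain."""

    bias_deg: float
    delay_s: float
    gain: float

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def _shift_forward(time: np.ndarray, series: np.ndarray, delay: float) -> np.ndarray:
    """series evaluated at t + delay (undoes a reporting lag), edge-held."""
    return np.interp(time + delay, time, series)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def fit_report_correction(
    no_gvs_trials: list[ShhTrial],
    max_delay_s: float = 3.0,
    reference: str = "actual",
) -> ReportCorrection:
    """Sequentially fit (bias, delay, gain) from a participant's sham trials.

    ``reference`` selects the target the report is corrected toward: the
    delivered tilt (``"actual"``, the empirical procedure) or a
    model-perception column stored in ``actual_tilt_deg`` by the caller.
    The gain step uses an L1 objective restricted to |target| > 2 deg,
    solved exactly by a weighted median.
    """
    if not no_gvs_trials:
        raise ValueError("need at least one No-GVS trial")
    del reference  # the target series always arrives in actual_tilt_deg

    raw = [t.raw_report_deg for t in no_gvs_trials]
    act = [t.actual_tilt_deg for t in no_gvs_trials]

    # bias: argmin_b MSE(raw - b, actual)  ->  mean residual
    bias = float(np.mean(np.concatenate(raw) - np.concatenate(act)))

    # delay: exhaustive grid at dt resolution, linear interpolation
    dt = float(no_gvs_trials[0].time[1] - no_gvs_trials[0].time[0])
    delays = np.arange(0.0, max_delay_s + dt / 2, dt)
    costs = np.zeros_like(delays)
    for trial, r, a in zip(no_gvs_trials, raw, act):
        rb = r - bias
        for i, d in enumerate(delays):
            shifted = _shift_forward(trial.time, rb, d)
            costs[i] += np.mean((shifted - a) ** 2)
    delay = float(delays[np.argmin(costs)])

    # gain: argmin_g mean |g*adjusted - actual| over |actual| > 2 deg
    xs, ys = [], []
    for trial, r, a in zip(no_gvs_trials, raw, act):
        adj = _shift_forward(trial.time, r - bias, delay)
        keep = np.abs(a) > SMALL_TILT_DEG
        xs.append(adj[keep])
        ys.append(a[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        raise ValueError("gain undefined: no samples with |actual tilt| > 2 deg")
    usable = np.abs(x) > 1e-9
    gain = _weighted_median(y[usable] / x[usable], np.abs(x[usable]))
    if gain <= 0:
        gain = max(gain, 1e-6)
    return ReportCorrection(bias_deg=bias, delay_s=delay, gain=gain)


def apply_correction(trial: ShhTrial, correction: ReportCorrection) -> np.ndarray:
    """Corrected perception estimate: gain * (raw(t + delay) - bias)."""
    shifted = _shift_forward(trial.time, trial.raw_report_deg - correction.bias_deg, correction.delay_s)
    return correction.gain * shifted


def mean_absolute_tilt(perception_deg: np.ndarray) -> float:
    """Time-mean of |perceived tilt| (deg); amplitude of perception, tilt-agnostic."""
    perception_deg = np.asarray(perception_deg, dtype=float)
    if perception_deg.size == 0:
        raise ValueError("empty perception trace")
    return float(np.mean(np.abs(perception_deg)))


def perceived_actual_slope(perception_deg: np.ndarray, actual_deg: np.ndarray) -> float:
    """Least-squares slope of perceived tilt regressed on actual tilt."""
    perception_deg = np.asarray(perception_deg, dtype=float)
    actual_deg = np.asarray(actual_deg, dtype=float)
    if perception_deg.shape != actual_deg.shape:
        raise ValueError("perception and actual tilt must be aligned")
    if np.ptp(actual_deg) < 1e-12:
        raise ValueError("actual tilt has zero variance; slope undefined")
    return float(stats.linregress(actual_deg, perception_deg).slope)


def glass_delta(group: np.ndarray, control: np.ndarray) -> float:
    """Glass's delta: (mean(group) - mean(control)) / sd(control)."""
    group = np.asarray(group, dtype=float)
    control = np.asarray(control, dtype=float)
    if group.size < 2 or control.size < 2:
        raise ValueError("need n >= 2 per group")
    sd = np.std(control, ddof=1)
    if sd == 0:
        raise ValueError("control group has zero standard deviation")
    return float((group.mean() - control.mean()) / sd)


def hedges_g(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Hedges' g: bias-corrected standardized mean difference (pooled SD)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d * correction)


def effect_sizes(group_a: np.ndarray, group_b: np.ndarray, mode: str) -> float:
    """Dispatch to Glass's delta (b = control) or Hedges' g."""
    if mode == "glass_delta_vs_control":
        return glass_delta(group_a, group_b)
    if mode == "hedges_g":
        return hedges_g(group_a, group_b)
    raise ValueError("mode must be 'glass_delta_vs_control' or 'hedges_g'")
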