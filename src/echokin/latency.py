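"""Sensor-motor latency estimation.

Three estimators:

* threshold latencies — the first post-event click whose forward ICI
  exceeds 5 ms (a depth of field beyond 3.75 m), and the first post-event
  instant at which windowed RMS norm-jerk exceeds 300 m/s^3; both isolate
  *strong* saccade-like responses;
* loop-area minimisation — prey range plotted against the acoustic depth
  of field traces counter-clockwise hysteresis loops when the ICI lags
  target motion; advancing the depth-of-field series in 5 ms steps until
  the enclosed area is minimised estimates the loop delay;
* the inverse-latency regression of 1/latency on RMS target acceleration,
  which linearises the faster-cue/faster-response relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .click_buzz import ClickTrain
from .errors import (
    EstimationError,
    InsufficientDataError,
    ParameterError,
)
from .response_stats import norm_jerk
from .trial_io import SensorStream, TargetMotion

__all__ = [
    "LatencyEstimate",
    "TargetCue",
    "threshold_latency_ici",
    "threshold_latency_jerk",
    "loop_area_latency",
    "rms_target_acceleration",
    "inverse_latency_regression",
]


@dataclass
class LatencyEstimate:
    """A latency (s) with the method and threshold that produced it."""

    method: str  # "ici_threshold" | "jerk_threshold" | "loop_area"
    value: float
    threshold: Optional[float] = None
    grid_step: Optional[float] = None


@dataclass
class TargetCue:
    """RMS target acceleration over a fixed window after motion onset."""

    rms_accel: float
    onset_time: float
    window: float = 0.5


def threshold_latency_ici(
    train: ClickTrain, event: float, thresh: float = 0.005
) -> Optional[LatencyEstimate]:
    """Latency until the forward ICI first exceeds ``thresh`` after the event.

    Pre-event crossings are ignored; returns ``None`` if no post-event
    click's forward ICI crosses the threshold within the record.
    """
    if len(train) < 2:
        raise InsufficientDataError("need >= 2 clicks")
    if not (train.times[0] <= event <= train.times[-1]):
        raise ParameterError("event lies outside the click record")
    ici = train.ici
    t = train.times[:-1]  # forward ICI of click k is in effect at time t_k
    post = (t >= event) & (ici > thresh)
    if not np.any(post):
        return None
    k = int(np.argmax(post))
    return LatencyEstimate(
        method="ici_threshold", value=float(t[k] - event), threshold=thresh
    )


def threshold_latency_jerk(
    motion: SensorStream,
    event: float,
    thresh: float = 300.0,
    rms_window: float = 0.01,
) -> Optional[LatencyEstimate]:
    """Latency until windowed RMS norm-jerk first exceeds ``thresh`` (m/s^3).

    The norm-jerk is smoothed by an RMS sliding window (default 10 ms)
    before thresholding; returns ``None`` without a crossing.
    """
    if not (0.0 <= event <= motion.duration):
        raise ParameterError("event lies outside the motion record")
    t, j = norm_jerk(motion)
    w = max(1, int(round(rms_window * motion.fs)))
    kernel = np.ones(w) / w
    j_rms = np.sqrt(np.convolve(j**2, kernel, mode="same"))
    post = (t >= event) & (j_rms > thresh)
    if not np.any(post):
        return None
    k = int(np.argmax(post))
    return LatencyEstimate(
        method="jerk_threshold", value=float(t[k] - event), threshold=thresh
    )


def loop_area_latency(
    range_times: np.ndarray,
    range_m: np.ndarray,
    dof_times: np.ndarray,
    dof_m: np.ndarray,
    grid_step: float = 0.005,
    max_advance: float = 0.3,
    fs_interp: float = 200.0,
) -> LatencyEstimate:
    """Estimate the response delay by collapsing hysteresis loops.

    Both series are linearly interpolated onto a common uniform time base;
    for each candidate advance a in {0, grid_step, ..., max_advance} the
    depth-of-field series is shifted earlier by a (responses moved back
    toward their causes) and the enclosed loop area of the closed polygon
    (range(t), dof(t+a)) is computed as the absolute shoelace sum.  The
    advance minimising the area is returned; ties break to the smallest.
    """
    range_times = np.asarray(range_times, dtype=np.float64)
    range_m = np.asarray(range_m, dtype=np.float64)
    dof_times = np.asarray(dof_times, dtype=np.float64)
    dof_m = np.asarray(dof_m, dtype=np.float64)
    if grid_step <= 0 or max_advance < grid_step:
        raise ParameterError("require grid_step > 0 and max_advance >= grid_step")
    if range_m.size < 3 or np.var(range_m) == 0:
        raise EstimationError("degenerate range series (no variation)")
    t0 = max(range_times[0], dof_times[0])
    t1 = min(range_times[-1], dof_times[-1] - max_advance)
    if t1 - t0 < 2 * max_advance:
        raise EstimationError(
            "series overlap too short relative to the advance search range"
        )
    t_grid = np.arange(t0, t1, 1.0 / fs_interp)
    x = np.interp(t_grid, range_times, range_m)
    advances = np.arange(0.0, max_advance + grid_step / 2, grid_step)
    areas = np.empty(advances.size)
    for i, a in enumerate(advances):
        y = np.interp(t_grid + a, dof_times, dof_m)
        # absolute net shoelace area of the trajectory closed last-to-first
        areas[i] = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    best = int(np.argmin(areas))  # first minimum = smallest advance on ties
    return LatencyEstimate(
        method="loop_area", value=float(advances[best]), grid_step=grid_step
    )


def rms_target_acceleration(
    target: TargetMotion,
    baseline_s: float = 1.0,
    window_s: float = 0.5,
    onset_k_sd: float = 5.0,
) -> Optional[TargetCue]:
    """RMS target acceleration (m/s^2) over 0.5 s after the motion onset.

    The fixed gravity component is removed as the per-axis mean over a
    pre-onset baseline; the onset is the first sample at which either
    demeaned axis exceeds ``onset_k_sd`` baseline standard deviations; the
    cue is sqrt(mean(ax^2 + ay^2)) over the window.  Returns ``None`` when
    no transient is found.
    """
    fs = target.fs
    nb = int(round(baseline_s * fs))
    if nb < 2 or target.accel.shape[1] <= nb:
        raise InsufficientDataError("stream too short for the gravity baseline")
    base = target.accel[:, :nb]
    demeaned = target.accel - base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1)
    sd = np.maximum(sd, 1e-12)
    crossing = np.any(np.abs(demeaned) > onset_k_sd * sd[:, None], axis=0)
    crossing[:nb] = False
    if not np.any(crossing):
        return None
    k = int(np.argmax(crossing))
    onset = k / fs
    nwin = int(round(window_s * fs))
    if k + nwin > demeaned.shape[1]:
        raise InsufficientDataError(
            f"stream ends within {window_s} s of the detected onset"
        )
    win = demeaned[:, k : k + nwin]
    rms = float(np.sqrt(np.mean(np.sum(win**2, axis=0))))
    return TargetCue(rms_accel=rms, onset_time=onset, window=window_s)


def inverse_latency_regression(
    latencies: np.ndarray, cues: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS of 1/latency on RMS target acceleration.

    Returns ``(slope, intercept, r_squared, p_value)`` with a two-sided
    slope p-value.  Pairs with non-finite entries are dropped; at least
    three pairs with positive latency are required.
    """
    latencies = np.asarray(latencies, dtype=np.float64)
    cues = np.asarray(cues, dtype=np.float64)
    ok = np.isfinite(latencies) & np.isfinite(cues)
    latencies, cues = latencies[ok], cues[ok]
    if latencies.size < 3:
        raise InsufficientDataError("need >= 3 paired finite observations")
    if np.any(latencies <= 0):
        raise ParameterError("latencies must be > 0")
    y = 1.0 / latencies
    if np.var(y) == 0:  # constant response: flat line, no explainable variance
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(cues, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )
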