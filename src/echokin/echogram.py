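"""Echogram formation, echo-trace extraction, and motion-onset detection.

An echogram stacks, for each outgoing click, the band-limited Hilbert
envelope of the audio over the interval from the click to the maximum
two-way travel time, mapped to range via r = c*tau/2 and colour-coded by
SNR relative to a per-click noise floor.  The target's echo appears as a
ridge across clicks (the echo trace); a sudden target escape appears as a
V-shaped kink in that trace whose apex is the reference time for latency
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .click_buzz import ClickTrain, band_envelope
from .errors import EmptyTraceError, EstimationError, InsufficientDataError
from .species import SpeciesPreset, get_preset
from .trial_io import AudioStream

__all__ = [
    "Echogram",
    "EchoTrace",
    "MotionEvent",
    "form_echogram",
    "extract_trace",
    "detect_motion_onset",
]

#: minimum displayed range (m); blanks the outgoing click's own envelope tail
MIN_RANGE = 0.2

#: half-width (s) of the mask placed over other clicks' direct arrivals
CLICK_MASK_HALFWIDTH = 0.2e-3


@dataclass
class Echogram:
    """Per-click SNR (dB) on a common range axis.

    ``snr`` has shape (n_clicks, n_range_bins); bins coinciding with other
    clicks' direct arrivals are masked to 0 dB so that trace extraction
    follows echoes rather than the (far louder) outgoing clicks.
    """

    snr: np.ndarray
    click_times: np.ndarray
    range_axis: np.ndarray
    sound_speed: float

    @property
    def range_bin_width(self) -> float:
        return float(self.range_axis[1] - self.range_axis[0])


@dataclass
class EchoTrace:
    """Per-click target range estimates extracted from an echogram."""

    click_times: np.ndarray
    range_m: np.ndarray
    snr_db: np.ndarray
    valid: np.ndarray

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.valid
        return self.click_times[m], self.range_m[m]


@dataclass
class MotionEvent:
    """A detected slope change in an echo trace.

    ``v_apex`` marks a closing-to-opening transition (pre-slope < 0 <
    post-slope); any other sufficiently large slope increase is a
    ``slope_change``.
    """

    time: float
    type: str
    pre_slope: float
    post_slope: float


def form_echogram(
    audio: AudioStream,
    train: ClickTrain,
    preset: "str | SpeciesPreset" = "pp",
    max_range: float = 6.0,
    sound_speed: float = 1500.0,
) -> Echogram:
    """Form an echogram from tag audio and detected click times.

    For each click the envelope segment covering two-way delays up to
    ``2*max_range/sound_speed`` is resampled onto a uniform range axis with
    bin width c/(2*envelope_fs).  SNR is 20*log10(envelope / noise floor)
    with a per-click floor taken as the median envelope over the last 20 %
    of the segment (beyond plausible target range).
    """
    p = get_preset(preset)
    if len(train) == 0:
        raise InsufficientDataError("cannot form an echogram from an empty train")
    env = band_envelope(audio, p.band)
    fs = audio.fs
    c = sound_speed
    dr = c / (2.0 * p.envelope_fs)
    range_axis = np.arange(MIN_RANGE, max_range, dr)
    tau = 2.0 * range_axis / c

    # fractional-index gather: segment sample positions for every click
    pos = train.times[:, None] * fs + tau[None, :] * fs
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i0 = np.clip(i0, 0, env.size - 2)
    seg = env[i0] * (1.0 - frac) + env[i0 + 1] * frac

    # mask other clicks' direct arrivals inside each segment
    mask = np.zeros_like(seg, dtype=bool)
    tmax = tau[-1]
    times = train.times
    for k, t_k in enumerate(times):
        lo = np.searchsorted(times, t_k + tau[0] - CLICK_MASK_HALFWIDTH)
        hi = np.searchsorted(times, t_k + tmax + CLICK_MASK_HALFWIDTH)
        for t_j in times[lo:hi]:
            if t_j == t_k:
                continue
            rel = t_j - t_k
            mask[k, np.abs(tau - rel) < CLICK_MASK_HALFWIDTH] = True

    n_floor = max(4, int(0.2 * range_axis.size))
    tail = np.where(mask[:, -n_floor:], np.nan, seg[:, -n_floor:])
    floor = np.nanmedian(tail, axis=1)
    floor = np.where(np.isfinite(floor) & (floor > 0), floor, np.nanmedian(env))
    snr = 20.0 * np.log10(np.maximum(seg, 1e-30) / floor[:, None])
    snr[mask] = 0.0
    return Echogram(
        snr=snr, click_times=times.copy(), range_axis=range_axis, sound_speed=c
    )


def extract_trace(eg: Echogram, gate_width: float = 0.5,
                  min_snr: float = 10.0, reacquire_after: int = 25) -> EchoTrace:
    """Extract the target echo trace by gated peak tracking.

    Until the first valid click, the global SNR maximum above ``min_snr``
    is used; thereafter the highest-SNR peak within a gate of width
    ``gate_width`` centred on the previous valid range.  Clicks with no
    sufficient peak are marked invalid (the gate centre is retained); after
    ``reacquire_after`` consecutive misses the gate is abandoned and the
    tracker re-acquires globally, so a lock onto a transient noise peak
    cannot blind the rest of the buzz.  Raises :class:`EmptyTraceError`
    when no click yields a valid echo.
    """
    n_clicks = eg.snr.shape[0]
    ranges = np.full(n_clicks, np.nan)
    snrs = np.full(n_clicks, np.nan)
    valid = np.zeros(n_clicks, dtype=bool)
    prev: Optional[float] = None
    misses = 0
    half = gate_width / 2.0
    for k in range(n_clicks):
        row = eg.snr[k]
        if prev is None:
            idx = int(np.argmax(row))
        else:
            gate = (eg.range_axis >= prev - half) & (eg.range_axis <= prev + half)
            if not np.any(gate):
                continue
            sub = np.where(gate, row, -np.inf)
            idx = int(np.argmax(sub))
        if row[idx] >= min_snr:
            ranges[k] = eg.range_axis[idx]
            snrs[k] = row[idx]
            valid[k] = True
            prev = float(ranges[k])
            misses = 0
        else:
            misses += 1
            if prev is not None and misses > reacquire_after:
                prev = None
                misses = 0
    if not np.any(valid):
        raise EmptyTraceError("no click produced an echo above the SNR threshold")
    return EchoTrace(
        click_times=eg.click_times.copy(), range_m=ranges, snr_db=snrs, valid=valid
    )


def detect_motion_onset(
    trace: EchoTrace,
    speed_change_threshold: float = 0.25,
    min_points: int = 10,
) -> Optional[MotionEvent]:
    """Detect the onset of a sudden target-speed change (e.g. the V apex).

    Fits a continuous two-segment (hinge) regression r(t) = a + b*t +
    d*max(t - t0, 0) for every candidate breakpoint t0 on the valid-click
    grid and keeps the breakpoint minimising the residual sum of squares.
    The event is reported only when the slope increase ``d`` exceeds
    ``speed_change_threshold`` (m/s), mirroring the selection of escapes in
    which the target opened faster than the predator closed.  Returns
    ``None`` when no sufficient break exists.
    """
    t, r = trace.valid_points()
    if t.size < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} valid trace points, got {t.size}"
        )
    edge = max(3, min_points // 3)
    candidates = t[edge:-edge]
    if candidates.size == 0:
        raise EstimationError("trace too short to bracket a breakpoint")
    best = None
    t0_ref = t[0]
    tt = t - t0_ref
    for t0 in candidates - t0_ref:
        X = np.column_stack([np.ones_like(tt), tt, np.maximum(tt - t0, 0.0)])
        coef, res, *_ = np.linalg.lstsq(X, r, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((X @ coef - r) ** 2))
        if best is None or rss < best[0]:
            best = (rss, t0, coef)
    _, t0, coef = best
    pre_slope = float(coef[1])
    post_slope = float(coef[1] + coef[2])
    if post_slope - pre_slope < speed_change_threshold:
        return None
    kind = "v_apex" if pre_slope < 0 < post_slope else "slope_change"
    return MotionEvent(
        time=float(t0 + t0_ref), type=kind, pre_slope=pre_slope, post_slope=post_slope
    )
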