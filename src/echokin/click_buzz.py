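"""Click detection, inter-click intervals, and buzz segmentation.

Clicks are detected as envelope-peak instants of band-limited transients
exceeding a threshold above a running noise floor.  The ICI convention is
FORWARD: ``ici[k] = times[k+1] - times[k]``, the interval *after* click k,
which is also the depth-of-field in effect once click k has been emitted.

Buzzes follow the species-specific field definition: maximal runs of
consecutive ICIs below 13 ms (harbour porpoise) or 100 ms (Blainville's
beaked whale) spanning at least 0.5 s from first to last click of the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .errors import InsufficientDataError, ParameterError, ValidationError
from .species import SpeciesPreset, get_preset
from .trial_io import AudioStream

__all__ = [
    "ClickTrain",
    "Buzz",
    "band_envelope",
    "detect_clicks",
    "compute_ici",
    "segment_buzzes",
]


@dataclass
class ClickTrain:
    """Ordered click emission times (s) and forward inter-click intervals."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValidationError("ClickTrain.times must be 1-D")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("ClickTrain.times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def ici(self) -> np.ndarray:
        """Forward intervals, length n-1."""
        return np.diff(self.times)


@dataclass
class Buzz:
    """A maximal run of sub-threshold ICIs lasting >= the minimum duration.

    ``start_index``/``end_index`` index clicks in the parent train; the run
    covers ``ici[start_index:end_index]`` (clicks start_index..end_index).
    """

    start_index: int
    end_index: int
    threshold_used: float
    duration: float


def band_envelope(audio: AudioStream, band: tuple[float, float],
                  smooth_s: float = 50e-6) -> np.ndarray:
    """Band-limited Hilbert amplitude envelope of a hydrophone recording.

    4th-order zero-phase Butterworth bandpass at the band edges, magnitude
    of the analytic signal, then a short centred moving average
    (``smooth_s``) that suppresses Rayleigh noise spikes without moving
    transient peaks.
    """
    nyq = audio.fs / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ParameterError(
            f"band {band} must lie strictly inside (0, Nyquist={nyq:.0f}) Hz"
        )
    sos = butter(4, [lo, hi], btype="bandpass", fs=audio.fs, output="sos")
    filtered = sosfiltfilt(sos, audio.samples)
    # pad to a fast FFT length for the analytic signal
    n = filtered.size
    nfast = int(2 ** np.ceil(np.log2(max(n, 2))))
    env = np.abs(hilbert(filtered, N=nfast)[:n])
    if smooth_s > 0:
        w = int(round(smooth_s * audio.fs))
        w = max(3, w | 1)  # odd, centred
        kernel = np.ones(w) / w
        env = np.convolve(env, kernel, mode="same")
    return env


def _running_noise_floor(env: np.ndarray, fs: float, window_s: float = 0.05
                         ) -> np.ndarray:
    """Robust running noise floor: blockwise median envelope, interpolated.

    The median over 50 ms blocks is insensitive to the clicks themselves
    (sub-ms transients); the Rayleigh median is rescaled to the
    RMS-equivalent level sqrt(2/ln 4).
    """
    block = max(1, int(round(window_s * fs)))
    nblocks = max(1, env.size // block)
    trimmed = env[: nblocks * block].reshape(nblocks, block)
    med = np.median(trimmed, axis=1)
    centres = (np.arange(nblocks) + 0.5) * block
    floor = np.interp(np.arange(env.size), centres, med)
    return floor * np.sqrt(2.0 / np.log(4.0))


def detect_clicks(
    audio: AudioStream,
    band: "tuple[float, float] | None" = None,
    thresh_db: float = 15.0,
    blanking: Optional[float] = None,
    preset: "str | SpeciesPreset" = "pp",
    echo_reject_db: Optional[float] = 9.0,
) -> ClickTrain:
    """Detect outgoing clicks in tag audio.

    Transients whose band-limited envelope exceeds ``thresh_db`` above a
    running noise floor are detected at their envelope-peak instants, with
    no two detections closer than ``blanking`` seconds.  Because echoes from
    close targets arrive within the inter-click gap and can also clear the
    noise threshold, a second amplitude pass keeps only peaks within
    ``echo_reject_db`` of a running upper quantile of detection amplitudes:
    the outgoing click is recorded at the source and is far louder on the
    tag than any target echo.  Set ``echo_reject_db=None`` to disable.

    ``band`` and ``blanking`` default to the species preset values.
    """
    p = get_preset(preset)
    if band is None:
        band = p.band
    if blanking is None:
        blanking = p.blanking_default
    if blanking <= 0:
        raise ParameterError("blanking must be > 0")
    env = band_envelope(audio, band)
    floor = _running_noise_floor(env, audio.fs)
    threshold = floor * 10.0 ** (thresh_db / 20.0)
    distance = max(1, int(round(blanking * audio.fs)))
    peaks, props = find_peaks(env, height=threshold, distance=distance)
    if peaks.size and echo_reject_db is not None:
        amps = props["peak_heights"]
        keep = np.ones(peaks.size, dtype=bool)
        halfwin = 12
        for i in range(peaks.size):
            j0, j1 = max(0, i - halfwin), min(peaks.size, i + halfwin + 1)
            ref = np.quantile(amps[j0:j1], 0.8)
            if amps[i] < ref * 10.0 ** (-echo_reject_db / 20.0):
                keep[i] = False
        peaks = peaks[keep]
    return ClickTrain(times=peaks / audio.fs)


def compute_ici(train: ClickTrain) -> np.ndarray:
    """Forward inter-click intervals (s), length n-1."""
    if len(train) < 2:
        raise InsufficientDataError("need at least 2 clicks to compute ICIs")
    return train.ici


def segment_buzzes(train: ClickTrain, preset: "str | SpeciesPreset") -> list[Buzz]:
    """Segment buzzes: maximal runs of ICI < threshold spanning >= 0.5 s.

    The run duration is measured from the first to the last click of the
    run.  Returned buzzes are non-overlapping and ordered; an empty list is
    a valid result.
    """
    p = get_preset(preset)
    if len(train) < 2:
        return []
    ici = train.ici
    below = ici < p.buzz_ici_threshold
    buzzes: list[Buzz] = []
    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        # run covers ici[i:j], i.e. clicks i..j
        span = train.times[j] - train.times[i]
        if span >= p.buzz_min_duration:
            buzzes.append(
                Buzz(
                    start_index=i,
                    end_index=j,
                    threshold_used=p.buzz_ici_threshold,
                    duration=float(span),
                )
            )
        i = j
    return buzzes
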