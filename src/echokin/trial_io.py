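"""Trial data containers and I/O.

The unit of analysis is a :class:`TrialBundle`: one close prey/target
approach with tag audio, tag accelerometry, optionally the target's own
two-axis accelerometer, and trial metadata.  Bundles round-trip through a
single netCDF file per trial (variables prefixed per stream, metadata as
global attributes) or through a plain directory of WAV + CSV + JSON files;
both are accepted by the same reader.

All times throughout the package are seconds relative to the record start
(time zero = first audio sample).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy.io import wavfile

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "AudioStream",
    "SensorStream",
    "TargetMotion",
    "TrialBundle",
    "read_audio",
    "write_audio",
    "read_trial_bundle",
    "write_trial_bundle",
]

_INT16_SCALE = 32768.0


@dataclass
class AudioStream:
    """Mono hydrophone pressure series.

    ``samples`` are dimensionless PCM in [-1, 1] unless ``clip_level``
    (dB re 1 uPa) is given, in which case full scale maps to that level.
    """

    samples: np.ndarray
    fs: float
    clip_level: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("AudioStream.samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("AudioStream.samples must be finite")
        if not self.fs > 0:
            raise ValidationError("AudioStream.fs must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class SensorStream:
    """Tri-axial accelerometer stream, shape (3, n), in m/s^2."""

    accel: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=np.float64))
        if self.accel.shape[0] != 3:
            raise ValidationError(
                f"SensorStream.accel must have 3 channels, got {self.accel.shape[0]}"
            )
        if not self.fs > 0:
            raise ValidationError("SensorStream.fs must be > 0")

    @property
    def duration(self) -> float:
        return self.accel.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.accel.shape[1]) / self.fs


@dataclass
class TargetMotion:
    """Two-axis accelerometer embedded in the target, shape (2, n), m/s^2.

    Axes are oriented horizontally, so gravity appears only as small fixed
    per-axis offsets (imperfect levelling), not a full 1 g component.
    """

    accel: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=np.float64))
        if self.accel.shape[0] != 2:
            raise ValidationError(
                f"TargetMotion.accel must have 2 channels, got {self.accel.shape[0]}"
            )
        if not self.fs > 0:
            raise ValidationError("TargetMotion.fs must be > 0")

    @property
    def duration(self) -> float:
        return self.accel.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.accel.shape[1]) / self.fs


@dataclass
class TrialBundle:
    """One trial: audio + motion + metadata (+ ground truth if synthetic)."""

    audio: AudioStream
    body_motion: SensorStream
    species_preset: str = "pp"
    target_motion: Optional[TargetMotion] = None
    event_time: Optional[float] = None
    ground_truth: Optional["object"] = None  # SyntheticTruth for synthetic trials
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.event_time is not None:
            if not (0.0 <= self.event_time <= self.audio.duration):
                raise ValidationError(
                    f"event_time {self.event_time} s outside record "
                    f"duration {self.audio.duration:.3f} s"
                )


# ---------------------------------------------------------------------------
# WAV audio


def read_audio(path: "str | Path") -> AudioStream:
    """Read a PCM WAV file into an :class:`AudioStream` scaled to [-1, 1].

    A JSON sidecar ``<stem>.json`` with a ``clip_level`` entry, if present,
    is attached as the stream's clipping level.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        fs, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises plain ValueError on bad files
        raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        # stereo angle-of-arrival processing is out of scope: keep channel 0
        import logging

        logging.getLogger(__name__).info(
            "stereo audio in %s: using channel 0 only", path
        )
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    clip_level = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        clip_level = meta.get("clip_level")
    return AudioStream(samples=samples, fs=float(fs), clip_level=clip_level)


def write_audio(stream: AudioStream, path: "str | Path") -> None:
    """Write an :class:`AudioStream` as 16-bit PCM WAV."""
    path = Path(path)
    pcm = np.clip(np.round(stream.samples * _INT16_SCALE), -32768, 32767)
    wavfile.write(str(path), int(round(stream.fs)), pcm.astype(np.int16))
    if stream.clip_level is not None:
        path.with_suffix(".json").write_text(
            json.dumps({"clip_level": stream.clip_level})
        )


# ---------------------------------------------------------------------------
# netCDF bundles

_MANDATORY_VARS = ("audio", "body_accel")


def write_trial_bundle(bundle: TrialBundle, path: "str | Path") -> None:
    """Write a :class:`TrialBundle`.

    ``*.nc`` paths produce a single netCDF (classic) file with one set of
    prefixed variables per stream and trial metadata as global attributes;
    any other path is treated as a directory and written in the plain
    WAV + CSV + JSON layout.  Invariants are validated before any write.
    """
    bundle.validate()
    path = Path(path)
    if path.suffix == ".nc":
        _write_netcdf(bundle, path)
    else:
        _write_directory(bundle, path)


def read_trial_bundle(path: "str | Path") -> TrialBundle:
    """Read a bundle written by :func:`write_trial_bundle` (either layout)."""
    path = Path(path)
    if path.is_dir():
        return _read_directory(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return _read_netcdf(path)


def _truth_to_vars(truth) -> tuple[dict, dict]:
    rng_t, rng_m = truth.range_series
    data_vars = {
        "truth_click_times": ("click", np.asarray(truth.click_times, dtype=np.float64)),
        "truth_range_time": ("range_sample", np.asarray(rng_t, dtype=np.float64)),
        "truth_range_m": ("range_sample", np.asarray(rng_m, dtype=np.float64)),
    }
    attrs = {
        "truth_event_time": float(truth.event_time),
        "truth_response_latency_ici": float(truth.response_latency_ici),
        "truth_response_latency_jerk": float(truth.response_latency_jerk),
        "truth_closing_speed_pre": float(truth.closing_speed_pre),
        "truth_escape_speed_excess": float(truth.escape_speed_excess),
        "truth_sound_speed": float(truth.sound_speed),
    }
    return data_vars, attrs


def _truth_from_ds(ds) -> "object":
    from .synthetic_trials import SyntheticTruth

    return SyntheticTruth(
        event_time=float(ds.attrs["truth_event_time"]),
        response_latency_ici=float(ds.attrs["truth_response_latency_ici"]),
        response_latency_jerk=float(ds.attrs["truth_response_latency_jerk"]),
        closing_speed_pre=float(ds.attrs["truth_closing_speed_pre"]),
        escape_speed_excess=float(ds.attrs["truth_escape_speed_excess"]),
        sound_speed=float(ds.attrs["truth_sound_speed"]),
        click_times=np.asarray(ds["truth_click_times"].values, dtype=np.float64),
        range_series=(
            np.asarray(ds["truth_range_time"].values, dtype=np.float64),
            np.asarray(ds["truth_range_m"].values, dtype=np.float64),
        ),
    )


def _write_netcdf(bundle: TrialBundle, path: Path) -> None:
    data_vars = {
        "audio": ("audio_sample", bundle.audio.samples.astype(np.float32)),
        "body_accel": (("axis", "accel_sample"), bundle.body_motion.accel),
    }
    attrs = {
        "trial_id": bundle.trial_id,
        "species_preset": bundle.species_preset,
        "fs_audio": float(bundle.audio.fs),
        "fs_accel": float(bundle.body_motion.fs),
    }
    if bundle.audio.clip_level is not None:
        attrs["clip_level"] = float(bundle.audio.clip_level)
    if bundle.event_time is not None:
        attrs["event_time"] = float(bundle.event_time)
    if bundle.target_motion is not None:
        data_vars["target_accel"] = (
            ("target_axis", "target_sample"),
            bundle.target_motion.accel,
        )
        attrs["fs_target"] = float(bundle.target_motion.fs)
    if bundle.ground_truth is not None:
        tvars, tattrs = _truth_to_vars(bundle.ground_truth)
        data_vars.update(tvars)
        attrs.update(tattrs)
    ds = xr.Dataset(data_vars, attrs=attrs)
    # classic netCDF3 keeps the dependency surface to scipy only
    ds.to_netcdf(str(path), engine="scipy")


def _read_netcdf(path: Path) -> TrialBundle:
    try:
        with xr.open_dataset(str(path), engine="scipy") as ds:
            ds = ds.load()
    except Exception as exc:
        raise FormatError(f"unreadable bundle {path}: {exc}") from exc
    for var in _MANDATORY_VARS:
        if var not in ds:
            raise SchemaError(f"bundle {path} is missing mandatory variable '{var}'")
    for attr in ("fs_audio", "fs_accel", "species_preset", "trial_id"):
        if attr not in ds.attrs:
            raise SchemaError(f"bundle {path} is missing mandatory attribute '{attr}'")
    audio = AudioStream(
        samples=np.asarray(ds["audio"].values, dtype=np.float64),
        fs=float(ds.attrs["fs_audio"]),
        clip_level=float(ds.attrs["clip_level"]) if "clip_level" in ds.attrs else None,
    )
    body = SensorStream(
        accel=np.asarray(ds["body_accel"].values, dtype=np.float64),
        fs=float(ds.attrs["fs_accel"]),
    )
    target = None
    if "target_accel" in ds:
        if "fs_target" not in ds.attrs:
            raise SchemaError(f"bundle {path} has target_accel but no 'fs_target'")
        target = TargetMotion(
            accel=np.asarray(ds["target_accel"].values, dtype=np.float64),
            fs=float(ds.attrs["fs_target"]),
        )
    truth = _truth_from_ds(ds) if "truth_click_times" in ds else None
    event_time = float(ds.attrs["event_time"]) if "event_time" in ds.attrs else None
    try:
        return TrialBundle(
            audio=audio,
            body_motion=body,
            target_motion=target,
            species_preset=str(ds.attrs["species_preset"]),
            event_time=event_time,
            ground_truth=truth,
            trial_id=str(ds.attrs["trial_id"]),
        )
    except ValidationError as exc:
        raise SchemaError(f"bundle {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# directory fallback (WAV + CSV + JSON)


def _write_directory(bundle: TrialBundle, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    write_audio(bundle.audio, path / "audio.wav")
    body = bundle.body_motion
    pd.DataFrame(
        {
            "t": body.times,
            "ax": body.accel[0],
            "ay": body.accel[1],
            "az": body.accel[2],
        }
    ).to_csv(path / "body_accel.csv", index=False)
    meta: dict = {
        "trial_id": bundle.trial_id,
        "species_preset": bundle.species_preset,
        "fs_audio": bundle.audio.fs,
        "fs_accel": body.fs,
        "event_time": bundle.event_time,
        "clip_level": bundle.audio.clip_level,
    }
    if bundle.target_motion is not None:
        tm = bundle.target_motion
        pd.DataFrame({"t": tm.times, "ax": tm.accel[0], "ay": tm.accel[1]}).to_csv(
            path / "target_accel.csv", index=False
        )
        meta["fs_target"] = tm.fs
    if bundle.ground_truth is not None:
        truth = bundle.ground_truth
        rng_t, rng_m = truth.range_series
        meta["truth"] = {
            "event_time": truth.event_time,
            "response_latency_ici": truth.response_latency_ici,
            "response_latency_jerk": truth.response_latency_jerk,
            "closing_speed_pre": truth.closing_speed_pre,
            "escape_speed_excess": truth.escape_speed_excess,
            "sound_speed": truth.sound_speed,
            "click_times": np.asarray(truth.click_times).tolist(),
            "range_time": np.asarray(rng_t).tolist(),
            "range_m": np.asarray(rng_m).tolist(),
        }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def _read_directory(path: Path) -> TrialBundle:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError(f"directory bundle {path} is missing 'metadata.json'")
    meta = json.loads(meta_path.read_text())
    wav = path / "audio.wav"
    if not wav.exists():
        raise SchemaError(f"directory bundle {path} is missing 'audio.wav'")
    audio = read_audio(wav)
    if meta.get("clip_level") is not None:
        audio.clip_level = float(meta["clip_level"])
    csv = path / "body_accel.csv"
    if not csv.exists():
        raise SchemaError(f"directory bundle {path} is missing 'body_accel.csv'")
    body_df = pd.read_csv(csv)
    body = SensorStream(
        accel=body_df[["ax", "ay", "az"]].to_numpy().T, fs=float(meta["fs_accel"])
    )
    target = None
    tcsv = path / "target_accel.csv"
    if tcsv.exists():
        if "fs_target" not in meta:
            raise SchemaError(f"directory bundle {path} has target CSV but no fs_target")
        tdf = pd.read_csv(tcsv)
        target = TargetMotion(
            accel=tdf[["ax", "ay"]].to_numpy().T, fs=float(meta["fs_target"])
        )
    truth = None
    if "truth" in meta:
        from .synthetic_trials import SyntheticTruth

        t = meta["truth"]
        truth = SyntheticTruth(
            event_time=t["event_time"],
            response_latency_ici=t["response_latency_ici"],
            response_latency_jerk=t["response_latency_jerk"],
            closing_speed_pre=t["closing_speed_pre"],
            escape_speed_excess=t["escape_speed_excess"],
            sound_speed=t["sound_speed"],
            click_times=np.asarray(t["click_times"], dtype=np.float64),
            range_series=(
                np.asarray(t["range_time"], dtype=np.float64),
                np.asarray(t["range_m"], dtype=np.float64),
            ),
        )
    try:
        return TrialBundle(
            audio=audio,
            body_motion=body,
            target_motion=target,
            species_preset=str(meta["species_preset"]),
            event_time=None if meta.get("event_time") is None else float(meta["event_time"]),
            ground_truth=truth,
            trial_id=str(meta["trial_id"]),
        )
    except ValidationError as exc:
        raise SchemaError(f"bundle {path}: {exc}") from exc
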