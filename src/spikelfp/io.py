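"""Reading and writing laminar recordings, spike times, and spike templates.

A recording lives in two files: ``<name>.dat`` holding little-endian int16
frames (sample-major, i.e. all channels of sample 0, then all channels of
sample 1, ...) and a JSON sidecar ``<name>.json`` carrying the channel
count, sampling rate, the microvolt-per-bit quantization step, and the probe
geometry.  This is the de-facto layout of extracellular ``.dat`` files.

All public times are in seconds, amplitudes in microvolts; channel indices
are 0-based and depth increases with channel index (CA1 at the top of the
probe, dentate gyrus at the bottom).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SpikeTimes",
    "SpikeTemplate",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_recording_csv",
    "write_recording_csv",
    "read_spike_times",
    "write_spike_times",
    "read_template",
    "write_template",
]


class FormatError(ValueError):
    """Raised when a file's payload is inconsistent with its declared layout."""


@dataclass
class Recording:
    """Multichannel extracellular recording in microvolts.

    ``samples`` has shape (n_channels, n_samples).  ``channel_depths_um``
    is monotone non-decreasing with channel index.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    channel_spacing_um: float = 50.0
    channel_depths_um: np.ndarray | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if self.channel_depths_um is None:
            self.channel_depths_um = np.arange(self.n_channels) * self.channel_spacing_um
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        if self.channel_depths_um.shape != (self.n_channels,):
            raise ValueError("channel_depths_um must have one entry per channel")
        if np.any(np.diff(self.channel_depths_um) < 0):
            raise ValueError("channel_depths_um must be monotone non-decreasing")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times_s(self) -> np.ndarray:
        """Sample times on the recording clock."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def sample_index(self, time_s: float) -> int:
        """Nearest sample index for a time on the recording clock."""
        return int(round((time_s - self.start_time_s) * self.sampling_rate_hz))


@dataclass
class SpikeTimes:
    """Detected or inserted spike timestamps, sorted, in seconds."""

    timestamps_s: np.ndarray
    channel_index: int = 0
    trigger_level_uv: float = float("nan")

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float).ravel()
        if np.any(np.diff(self.timestamps_s) <= 0):
            warnings.warn("spike timestamps not strictly increasing; sorting", stacklevel=2)
            self.timestamps_s = np.unique(self.timestamps_s)

    def __len__(self) -> int:
        return self.timestamps_s.size


@dataclass
class SpikeTemplate:
    """Spike waveform with its depth profile, channels x samples, in microvolts.

    ``peak_sample`` is the index of the most negative sample on the
    reference channel (the trough used for alignment).
    """

    waveform_uv: np.ndarray
    sampling_rate_hz: float
    peak_sample: int | None = None
    reference_channel: int = 0

    def __post_init__(self) -> None:
        self.waveform_uv = np.atleast_2d(np.asarray(self.waveform_uv, dtype=float))
        if self.peak_sample is None:
            self.peak_sample = int(np.argmin(self.waveform_uv[self.reference_channel]))
        ref = self.waveform_uv[self.reference_channel]
        if ref[self.peak_sample] != ref.min():
            raise ValueError("peak_sample must be the argmin of the reference channel")

    @property
    def n_channels(self) -> int:
        return self.waveform_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveform_uv.shape[1]

    @property
    def trough_uv(self) -> float:
        return float(self.waveform_uv[self.reference_channel, self.peak_sample])

    def time_axis_ms(self) -> np.ndarray:
        """Time of each sample relative to the trough, in milliseconds."""
        return (np.arange(self.n_samples) - self.peak_sample) / self.sampling_rate_hz * 1e3


# ---------------------------------------------------------------------------
# binary recording + JSON sidecar


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_recording(rec: Recording, path: str | Path, uv_per_bit: float | None = None) -> Path:
    """Write ``<path>.dat`` (int16 LE, sample-major) and its JSON sidecar.

    The quantization step defaults to max|x|/32767 so the full int16 range
    is used without clipping; an all-zero recording uses 1 µV/bit.
    Returns the sidecar path.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    path = Path(path)
    if uv_per_bit is None:
        peak = float(np.max(np.abs(rec.samples))) if rec.n_samples else 0.0
        uv_per_bit = peak / 32767.0 if peak > 0 else 1.0
    quant = np.clip(np.round(rec.samples / uv_per_bit), -32768, 32767).astype("<i2")
    quant.T.tofile(path)  # transpose -> sample-major frames
    sidecar = {
        "n_channels": rec.n_channels,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "uv_per_bit": uv_per_bit,
        "dtype": "int16",
        "start_time_s": rec.start_time_s,
        "channel_spacing_um": rec.channel_spacing_um,
        "channel_depths_um": list(map(float, rec.channel_depths_um)),
        "channel_labels": rec.channel_labels,
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=1))
    return sc_path


def read_recording(path: str | Path, sidecar_path: str | Path | None = None) -> Recording:
    """Read a binary recording, applying the sidecar's µV-per-bit scale."""
    path = Path(path)
    sc_path = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    try:
        meta = json.loads(sc_path.read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"missing sidecar {sc_path}") from exc
    for key in ("n_channels", "sampling_rate_hz", "uv_per_bit"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path, dtype="<i2")
    if raw.size % n_ch:
        raise FormatError(
            f"payload of {raw.size} samples not divisible by {n_ch} channels"
        )
    samples = raw.reshape(-1, n_ch).T.astype(float) * float(meta["uv_per_bit"])
    if samples.size == 0:
        samples = samples.reshape(n_ch, 0)
    return Recording(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        start_time_s=float(meta.get("start_time_s", 0.0)),
        channel_spacing_um=float(meta.get("channel_spacing_um", 50.0)),
        channel_depths_um=meta.get("channel_depths_um"),
        channel_labels=meta.get("channel_labels"),
    )


# ---------------------------------------------------------------------------
# CSV recording (small readable fixtures)


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.insert(0, "time_s", rec.times_s())
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path, sampling_rate_hz: float | None = None) -> Recording:
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    if sampling_rate_hz is None:
        if times.size < 2:
            raise FormatError("cannot infer sampling rate from fewer than 2 samples")
        sampling_rate_hz = 1.0 / float(np.median(np.diff(times)))
    return Recording(
        samples=df.to_numpy().T,
        sampling_rate_hz=sampling_rate_hz,
        start_time_s=float(times[0]) if times.size else 0.0,
        channel_labels=list(df.columns),
    )


# ---------------------------------------------------------------------------
# spike times CSV


def write_spike_times(times: SpikeTimes, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "spike_id": np.arange(1, len(times) + 1),
            "time_s": times.timestamps_s,
            "channel": times.channel_index,
        }
    )
    df.to_csv(path, index=False)


def read_spike_times(path: str | Path, recording: Recording | None = None) -> SpikeTimes:
    """Read spike times; unsorted or out-of-range rows trigger a warning.

    Output timestamps are always sorted.  If ``recording`` is given, times
    outside its extent warn but are kept (the caller decides truncation).
    """
    df = pd.read_csv(path)
    ts = df["time_s"].to_numpy(dtype=float)
    channel = int(df["channel"].iloc[0]) if len(df) else 0
    if ts.size and np.any(np.diff(ts) <= 0):
        warnings.warn(f"{path}: spike times not sorted; sorting", stacklevel=2)
        ts = np.unique(ts)
    if recording is not None and ts.size:
        if ts.min() < recording.start_time_s or ts.max() > recording.end_time_s:
            warnings.warn(f"{path}: spike times outside recording extent", stacklevel=2)
    return SpikeTimes(timestamps_s=ts, channel_index=channel)


# ---------------------------------------------------------------------------
# template / waveform CSV (one column per channel plus time_ms)


def write_template(tpl: SpikeTemplate, path: str | Path) -> None:
    df = pd.DataFrame(
        tpl.waveform_uv.T, columns=[f"ch{i}" for i in range(tpl.n_channels)]
    )
    df.insert(0, "time_ms", tpl.time_axis_ms())
    df.to_csv(path, index=False)


def read_template(path: str | Path, reference_channel: int | None = None) -> SpikeTemplate:
    df = pd.read_csv(path)
    t_ms = df.pop("time_ms").to_numpy()
    if t_ms.size < 2:
        raise FormatError("template needs at least 2 samples")
    fs = 1e3 / float(np.median(np.diff(t_ms)))
    wav = df.to_numpy().T
    if reference_channel is None:
        # channel holding the deepest trough
        reference_channel = int(np.argmin(wav.min(axis=1)))
    return SpikeTemplate(
        waveform_uv=wav, sampling_rate_hz=fs, reference_channel=reference_channel
    )
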