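"""Threshold-based spike detection on the spike-bearing channel.

The detection chain follows common extracellular practice: band-pass the
channel (order-2 Butterworth high-pass at 600 Hz composed with a low-pass
at 6 kHz, causal), FIR-interpolate to 96 kHz, and trigger on negative
excursions below a fixed level (default −50 µV).  Each accepted excursion
is time-stamped at its local minimum; by default the timestamp is then
refined to the trough of the upsampled *raw* trace within ±0.3 ms, which
removes the band-pass group delay from the reported time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filters import FilterSpec, apply_filter
from .io import Recording, SpikeTimes

__all__ = [
    "DetectionConfig",
    "upsample_fir",
    "bandpass_spike_band",
    "detect_spikes",
    "spike_free_channels",
]


@dataclass
class DetectionConfig:
    band_low_hz: float = 600.0
    band_high_hz: float = 6000.0
    upsample_rate_hz: float = 96000.0
    trigger_level_uv: float = -50.0
    dead_time_ms: float = 1.0
    refine_on_raw: bool = True
    refine_window_ms: float = 0.3

    def validate(self, sampling_rate_hz: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= self.upsample_rate_hz / 2:
            raise ValueError("band_high_hz must be below Nyquist of upsample rate")
        if self.band_high_hz >= sampling_rate_hz / 2:
            raise ValueError("band_high_hz must be below Nyquist of recording")
        if self.dead_time_ms <= 0:
            raise ValueError("dead_time_ms must be positive")
        if self.trigger_level_uv >= 0:
            warnings.warn(
                "non-negative trigger level; extracellular spikes are negative-going",
                stacklevel=2,
            )


def upsample_fir(x: np.ndarray, in_rate_hz: float, out_rate_hz: float) -> np.ndarray:
    """Band-limited FIR interpolation by an integer factor.

    Output length is input length times the factor; the original samples
    are reproduced at their grid positions up to the interpolator's
    passband ripple.  A factor of 1 returns the input unchanged.
    """
    ratio = out_rate_hz / in_rate_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"output rate {out_rate_hz} is not an integer multiple of {in_rate_hz}"
        )
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    # long Kaiser-window FIR keeps passband ripple well under 0.1%
    return signal.resample_poly(x, factor, 1, window=("kaiser", 12.0))


def bandpass_spike_band(
    x: np.ndarray, sampling_rate_hz: float, cfg: DetectionConfig
) -> np.ndarray:
    """Causal order-2 Butterworth high-pass then low-pass cascade.

    Filter states are initialized to the step steady state of the first
    sample so the DC level at the start of the record does not produce a
    spurious threshold-crossing transient.
    """
    from .filters import design_filter

    out = np.asarray(x, dtype=float)
    for spec in (
        FilterSpec("butterworth2", cfg.band_low_hz, band="highpass"),
        FilterSpec("butterworth2", cfg.band_high_hz, band="lowpass"),
    ):
        b, a = design_filter(spec, sampling_rate_hz)
        zi = signal.lfilter_zi(b, a) * out[0]
        out, _ = signal.lfilter(b, a, out, zi=zi)
    return out


def detect_spikes(
    rec: Recording, channel: int, cfg: DetectionConfig | None = None
) -> SpikeTimes:
    """Detect negative-going threshold crossings and time-stamp their troughs.

    A crossing is registered when the band-passed, upsampled trace falls
    below ``trigger_level_uv``; the timestamp is the argmin within the
    contiguous sub-threshold excursion.  Events within ``dead_time_ms``
    after an accepted event are suppressed.
    """
    if cfg is None:
        cfg = DetectionConfig()
    cfg.validate(rec.sampling_rate_hz)
    if not 0 <= channel < rec.n_channels:
        raise ValueError(f"channel {channel} out of range")
    x = rec.samples[channel]
    if x.size == 0:
        return SpikeTimes(np.empty(0), channel, cfg.trigger_level_uv)
    bp = bandpass_spike_band(x, rec.sampling_rate_hz, cfg)
    up_bp = upsample_fir(bp, rec.sampling_rate_hz, cfg.upsample_rate_hz)
    up_raw = (
        upsample_fir(x, rec.sampling_rate_hz, cfg.upsample_rate_hz)
        if cfg.refine_on_raw
        else None
    )
    fs_up = cfg.upsample_rate_hz

    below = up_bp < cfg.trigger_level_uv
    if not below.any():
        return SpikeTimes(np.empty(0), channel, cfg.trigger_level_uv)
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        stops = np.r_[stops, below.size]

    dead = cfg.dead_time_ms * 1e-3
    half_refine = int(round(cfg.refine_window_ms * 1e-3 * fs_up))
    peaks: list[int] = []
    last_t = -np.inf
    for lo, hi in zip(starts, stops):
        i = lo + int(np.argmin(up_bp[lo:hi]))
        if up_raw is not None:
            a = max(0, i - half_refine)
            b = min(up_raw.size, i + half_refine + 1)
            i = a + int(np.argmin(up_raw[a:b]))
        t = i / fs_up
        if t - last_t < dead:
            continue
        peaks.append(i)
        last_t = t
    ts = rec.start_time_s + np.asarray(peaks, dtype=float) / fs_up
    return SpikeTimes(ts, channel, cfg.trigger_level_uv)


def spike_free_channels(
    rec: Recording, cfg: DetectionConfig | None = None
) -> list[int]:
    """Channels with zero threshold crossings in the spike band.

    Helper heuristic for choosing reference channels: a stratum-radiatum
    site records the shared LFP but no threshold-crossing action
    potentials.
    """
    if cfg is None:
        cfg = DetectionConfig()
    quiet = []
    for ch in range(rec.n_channels):
        bp = bandpass_spike_band(rec.samples[ch], rec.sampling_rate_hz, cfg)
        if not np.any(bp < cfg.trigger_level_uv):
            quiet.append(ch)
    return quiet
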