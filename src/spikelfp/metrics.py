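"""Quantifying waveform estimates.

Distortion is summarized the way the filter-sweep analysis does: RMS of
the (mean estimate - true template) difference in short windows before and
after the trough, plus bias and SD of the estimated trough amplitude.
Spike-triggered averaging of the broad-band signal is provided as the
classical comparison method, and a Paul-wavelet continuous transform
characterizes the spectral content of waveforms (the Paul wavelet's
asymmetric shape and high temporal resolution suit spike transients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Recording, SpikeTimes

__all__ = [
    "DistortionReport",
    "CWTConfig",
    "PaulCWTResult",
    "distortion_report",
    "amplitude_linearity",
    "spike_triggered_average",
    "paul_cwt",
    "paul_scales_for_periods",
]


@dataclass
class DistortionReport:
    """RMS waveform error around the trough plus amplitude bias/SD (µV).

    Time 0 is the template trough; the pre window is [-w, 0), the post
    window (0, +w], and the trough sample itself belongs to neither (it
    feeds the amplitude bias instead).
    """

    rms_pre_uv: float
    rms_post_uv: float
    peak_bias_uv: float
    peak_sd_uv: float
    pre_post_window_ms: float = 1.5


def distortion_report(
    estimated_traces: np.ndarray,
    true_template: np.ndarray,
    sampling_rate_hz: float,
    trough_sample: int | None = None,
    window_ms: float = 1.5,
    peak_search_ms: float | None = None,
) -> DistortionReport:
    """Compare estimated traces against the true template trace.

    Traces (n x L, or a single 1-D trace) and the template (length L) must
    be aligned on the template trough.  Per-trace amplitudes are the most
    negative sample within ``peak_search_ms`` (default: ``window_ms``) of
    the trough, accommodating the peak delay that causal filters introduce.
    """
    est = np.atleast_2d(np.asarray(estimated_traces, dtype=float))
    tpl = np.asarray(true_template, dtype=float).ravel()
    if est.shape[1] != tpl.size:
        raise ValueError(
            f"traces have {est.shape[1]} samples but template has {tpl.size}"
        )
    if trough_sample is None:
        trough_sample = int(np.argmin(tpl))
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    wlen = int(round(window_ms * 1e-3 * sampling_rate_hz))
    if wlen < 1 or trough_sample - wlen < 0 or trough_sample + wlen >= tpl.size:
        raise ValueError("window exceeds trace extent around the trough")
    with np.errstate(invalid="ignore"):
        mean_est = np.nanmean(est, axis=0)
    diff = mean_est - tpl
    pre = diff[trough_sample - wlen : trough_sample]
    post = diff[trough_sample + 1 : trough_sample + 1 + wlen]
    rms_pre = float(np.sqrt(np.nanmean(pre**2)))
    rms_post = float(np.sqrt(np.nanmean(post**2)))

    slen = wlen if peak_search_ms is None else int(round(peak_search_ms * 1e-3 * sampling_rate_hz))
    a = max(0, trough_sample - slen)
    b = min(tpl.size, trough_sample + slen + 1)
    amps = np.nanmin(est[:, a:b], axis=1)
    peak_bias = float(abs(np.nanmean(amps) - tpl[trough_sample]))
    peak_sd = float(np.nanstd(amps, ddof=1)) if amps.size > 1 else 0.0
    return DistortionReport(rms_pre, rms_post, peak_bias, peak_sd, window_ms)


def amplitude_linearity(
    true_amps: np.ndarray, est_amps: np.ndarray
) -> tuple[float, float, float]:
    """OLS line of estimated on true amplitudes: (slope, intercept, resid SD).

    Slope 1 and intercept 0 mean an unbiased amplitude estimate; a slope
    below 1 with intercept near 0 is the proportional negative bias that
    high-pass filtering produces.
    """
    t = np.asarray(true_amps, dtype=float).ravel()
    e = np.asarray(est_amps, dtype=float).ravel()
    if t.size != e.size or t.size < 3:
        raise ValueError("need >= 3 paired amplitudes")
    if np.ptp(t) == 0:
        raise ValueError("true amplitudes are all equal; line undefined")
    res = stats.linregress(t, e)
    resid = e - (res.slope * t + res.intercept)
    resid_sd = float(np.std(resid, ddof=2)) if t.size > 2 else 0.0
    return float(res.slope), float(res.intercept), resid_sd


def spike_triggered_average(
    rec: Recording,
    channel: int,
    spike_times: SpikeTimes | np.ndarray,
    window_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Mean and SD of raw broad-band snippets aligned on spike times.

    Returns (mean_trace, sd_trace, n_used, time_axis_ms).  Spikes whose
    window would be truncated by the recording edges are excluded from the
    average (their count is ``len(times) - n_used``).  When spikes are
    phase-locked to an ongoing oscillation the STA baseline inherits the
    locked phase: an apparent DC offset at the trough/peak, a sloping
    baseline on the rising/falling phase.
    """
    ts = (
        spike_times.timestamps_s
        if isinstance(spike_times, SpikeTimes)
        else np.asarray(spike_times, dtype=float).ravel()
    )
    fs = rec.sampling_rate_hz
    half = int(round(window_ms * 1e-3 * fs / 2))
    L = 2 * half + 1
    x = rec.samples[channel]
    snips = []
    for s in ts:
        c = rec.sample_index(s)
        if c - half < 0 or c + half + 1 > rec.n_samples:
            continue
        snips.append(x[c - half : c + half + 1])
    if not snips:
        raise ValueError("no spike has a full window inside the recording")
    arr = np.asarray(snips)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(L)
    t_ms = (np.arange(L) - half) / fs * 1e3
    return mean, sd, arr.shape[0], t_ms


# ---------------------------------------------------------------------------
# Paul-wavelet continuous transform


@dataclass
class CWTConfig:
    """Order-m Paul wavelet transform over a set of scales (seconds)."""

    scales: np.ndarray
    sampling_rate_hz: float
    wavelet_order_m: int = 4

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float).ravel()
        if self.wavelet_order_m < 1:
            raise ValueError("wavelet order m must be >= 1")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    def fourier_periods_s(self) -> np.ndarray:
        """Equivalent Fourier period of each scale: 4*pi*s / (2m + 1)."""
        return 4.0 * np.pi * self.scales / (2 * self.wavelet_order_m + 1)

    def fourier_freqs_hz(self) -> np.ndarray:
        return 1.0 / self.fourier_periods_s()


@dataclass
class PaulCWTResult:
    power: np.ndarray  # scales x time, |W|^2
    scales: np.ndarray
    periods_s: np.ndarray
    freqs_hz: np.ndarray


def paul_scales_for_periods(
    periods_s: np.ndarray, wavelet_order_m: int = 4
) -> np.ndarray:
    """Scales whose Paul Fourier periods equal the requested periods."""
    p = np.asarray(periods_s, dtype=float)
    return p * (2 * wavelet_order_m + 1) / (4.0 * np.pi)


def paul_cwt(x: np.ndarray, cfg: CWTConfig) -> PaulCWTResult:
    """Continuous wavelet transform with the analytic Paul wavelet.

    Frequency-domain implementation: the transform at scale s is the
    inverse FFT of x_hat(w) * conj(psi_hat(s w)), with the wavelet
    normalized to unit energy at every scale, so power is comparable
    across scales.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("signal too short for a wavelet transform")
    m = cfg.wavelet_order_m
    n = x.size
    dt = 1.0 / cfg.sampling_rate_hz
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    xh = np.fft.fft(x)
    # 2^m / sqrt(m * (2m-1)!) is the Paul admissibility normalization
    from math import factorial, sqrt

    norm0 = 2.0**m / sqrt(m * factorial(2 * m - 1))
    W = np.empty((cfg.scales.size, n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(cfg.scales):
        psi_hat = np.zeros(n)
        so = s * omega[pos]
        psi_hat[pos] = norm0 * so**m * np.exp(-so)
        # unit energy per scale (Torrence & Compo normalization)
        psi_hat *= sqrt(2.0 * np.pi * s / dt)
        W[i] = np.fft.ifft(xh * psi_hat)
    return PaulCWTResult(
        power=np.abs(W) ** 2,
        scales=cfg.scales.copy(),
        periods_s=cfg.fourier_periods_s(),
        freqs_hz=cfg.fourier_freqs_hz(),
    )
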