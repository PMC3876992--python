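"""Seeded generator of laminar-array recordings with known ground truth.

The generator emulates a 16-site, 50 µm-spaced silicon-probe recording at
16 kHz from the urethane-anesthetized mouse hippocampus: a spatially
coherent theta oscillation (~4-5 Hz) whose amplitude and phase vary
smoothly with depth, spatially correlated 1/f background noise mixed into
each channel through a smooth, mildly nonlinear transfer (so the
cross-channel relationship is well approximated — but not exactly
represented — by a cubic-plus-interactions model), and a small independent
white noise floor.  Negative-going spike templates (a fast ~1 ms trough
riding on a slower ~8 ms negative wave, decaying across ~4 adjacent
channels) are inserted additively at known times, amplitudes, and theta
phases.

An exact-model mode builds the spike channel as an *exact* cubic +
pairwise-interaction function of the reference channels, for tests that
require machine-precision waveform recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .filters import FilterSpec, apply_filter
from .io import Recording, SpikeTemplate

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "synth_lfp",
    "synth_exact_model",
    "make_template_biphasic",
    "make_template_ec_spike",
    "insert_spikes",
    "theta_phase",
    "PHASE_PEAK",
    "PHASE_FALLING",
    "PHASE_TROUGH",
]

# phase convention of the analytic signal: theta = A*cos(phase)
PHASE_PEAK = 0.0
PHASE_FALLING = np.pi / 2
PHASE_TROUGH = np.pi


@dataclass
class SynthConfig:
    """Study conditions of the emulated recording.

    theta_amp_uv may be a scalar (a smooth depth profile spanning
    0.7-1.3x is applied) or an explicit per-channel profile.
    """

    n_channels: int = 16
    spacing_um: float = 50.0
    sampling_rate_hz: float = 16000.0
    duration_s: float = 10.0
    theta_freq_hz: float = 4.0
    theta_amp_uv: float | np.ndarray = 300.0
    theta_phase_gradient_rad_per_channel: float = np.pi / 15
    noise_exponent: float = 1.0
    noise_sd_uv: float = 25.0
    channel_coupling: float = 0.3
    white_noise_sd_uv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.noise_sd_uv < 0 or self.white_noise_sd_uv < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.channel_coupling <= 1:
            raise ValueError("channel_coupling must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was actually inserted, for scoring estimates against."""

    inserted_times_s: np.ndarray
    inserted_amplitudes_uv: np.ndarray
    inserted_template: SpikeTemplate
    locking_phase_rad: float | None = None
    n_skipped: int = 0


def _powerlaw_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _depth_profile(cfg: SynthConfig) -> np.ndarray:
    amp = np.asarray(cfg.theta_amp_uv, dtype=float)
    if amp.ndim == 0:
        c = np.arange(cfg.n_channels)
        span = max(cfg.n_channels - 1, 1)
        return float(amp) * (0.7 + 0.6 * c / span)
    if amp.shape != (cfg.n_channels,):
        raise ValueError("theta_amp_uv profile must have one entry per channel")
    return amp


def synth_lfp(cfg: SynthConfig) -> Recording:
    """Generate the background laminar LFP (no spikes), deterministic in seed."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    amps = _depth_profile(cfg)
    g = cfg.channel_coupling
    u1 = _powerlaw_noise(n, cfg.noise_exponent, rng)
    u2 = _powerlaw_noise(n, cfg.noise_exponent, rng)
    samples = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        phase = cfg.theta_phase_gradient_rad_per_channel * c
        theta = amps[c] * np.cos(2 * np.pi * cfg.theta_freq_hz * t + phase)
        # smooth rotation through the two shared latents + mild saturation:
        # approximable, but not exactly representable, by a cubic model
        rot = 0.8 * c / max(cfg.n_channels - 1, 1)
        v = np.cos(rot) * u1 + np.sin(rot) * u2
        shared = cfg.noise_sd_uv * ((1 - g) * v + g * np.tanh(v))
        white = cfg.white_noise_sd_uv * rng.standard_normal(n)
        samples[c] = theta + shared + white
    return Recording(
        samples=samples,
        sampling_rate_hz=cfg.sampling_rate_hz,
        channel_spacing_um=cfg.spacing_um,
    )


def synth_exact_model(
    cfg: SynthConfig,
    spike_channel: int,
    reference_channels: list[int],
    coeff_scale_uv: float = 100.0,
) -> tuple[Recording, dict]:
    """Recording whose spike channel is an exact cubic+interaction function
    of the reference channels.

    Each reference carries theta (distinct phase) plus an independent 1/f
    latent; the spike channel is a fixed-coefficient polynomial (constant,
    linear, square, cube, pairwise products) of the references scaled by
    ``coeff_scale_uv``.  Returns the recording and the generating
    coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    k = len(reference_channels)
    if k < 1:
        raise ValueError("need at least one reference channel")
    if spike_channel in reference_channels:
        raise ValueError("spike channel cannot be its own reference")
    samples = np.zeros((cfg.n_channels, n))
    refs = np.empty((k, n))
    for j, ch in enumerate(reference_channels):
        phase = cfg.theta_phase_gradient_rad_per_channel * ch
        theta = 150.0 * np.cos(2 * np.pi * cfg.theta_freq_hz * t + phase)
        refs[j] = theta + 60.0 * _powerlaw_noise(n, cfg.noise_exponent, rng)
        samples[ch] = refs[j]
    # normalized regressors keep each term O(coeff_scale_uv)
    x = refs / 150.0
    coeffs = {
        "const": 0.2 * coeff_scale_uv,
        "linear": rng.uniform(-1, 1, k) * coeff_scale_uv,
        "square": rng.uniform(-0.5, 0.5, k) * coeff_scale_uv,
        "cube": rng.uniform(-0.3, 0.3, k) * coeff_scale_uv,
        "interaction": rng.uniform(-0.3, 0.3, (k, k)) * coeff_scale_uv,
        "ref_scale_uv": 150.0,
    }
    y = np.full(n, coeffs["const"])
    for j in range(k):
        y += coeffs["linear"][j] * x[j]
        y += coeffs["square"][j] * x[j] ** 2
        y += coeffs["cube"][j] * x[j] ** 3
    for i in range(k):
        for j in range(i + 1, k):
            y += coeffs["interaction"][i, j] * x[i] * x[j]
    samples[spike_channel] = y
    # unused channels: independent filler noise so the recording is full
    for ch in range(cfg.n_channels):
        if ch != spike_channel and ch not in reference_channels:
            samples[ch] = 50.0 * _powerlaw_noise(n, cfg.noise_exponent, rng)
    rec = Recording(
        samples=samples,
        sampling_rate_hz=cfg.sampling_rate_hz,
        channel_spacing_um=cfg.spacing_um,
    )
    return rec, coeffs


# ---------------------------------------------------------------------------
# templates


def make_template_biphasic(
    amplitude_uv: float,
    phase_width_ms: float = 0.5,
    sampling_rate_hz: float = 16000.0,
    n_channels: int = 1,
    channel: int = 0,
) -> SpikeTemplate:
    """Biphasic square pulse: -A for one phase width, +A for the next.

    Zero-integral by construction; one phase width of zero padding on each
    side.  On a multichannel template only ``channel`` carries the pulse.
    """
    if phase_width_ms <= 0:
        raise ValueError("phase_width_ms must be positive")
    w = max(1, int(round(phase_width_ms * 1e-3 * sampling_rate_hz)))
    trace = np.concatenate(
        [np.zeros(w), -amplitude_uv * np.ones(w), amplitude_uv * np.ones(w), np.zeros(w)]
    )
    wav = np.zeros((n_channels, trace.size))
    wav[channel] = trace
    return SpikeTemplate(
        waveform_uv=wav,
        sampling_rate_hz=sampling_rate_hz,
        peak_sample=w,
        reference_channel=channel,
    )


def make_template_ec_spike(
    peak_uv: float = 100.0,
    fast_width_ms: float = 0.4,
    slow_wave_uv: float | None = None,
    slow_width_ms: float = 8.0,
    slow_onset_ms: float = -1.0,
    depth_decay_per_channel: float = 0.5,
    n_channels: int = 16,
    channel: int = 3,
    sampling_rate_hz: float = 16000.0,
) -> SpikeTemplate:
    """Extracellular action-potential template with a laminar depth profile.

    The reference channel carries a fast negative trough (raised-cosine,
    ~0.4 ms full width) followed by a slower negative half-sinusoid
    starting at ``slow_onset_ms`` and lasting ``slow_width_ms`` (~8 ms) —
    the trailing slow wave whose ~60 Hz spectral content is what high-pass
    filters erase and replace with a spurious positive bump.  The fast
    lobe is scaled so the total trough equals ``peak_uv``.  Amplitude
    decays geometrically with channel distance so the spike is visible on
    about 4 adjacent sites and negligible beyond.
    """
    if not fast_width_ms < slow_width_ms:
        raise ValueError("fast_width_ms must be smaller than slow_width_ms")
    if slow_wave_uv is None:
        slow_wave_uv = 0.3 * peak_uv
    slow_w = slow_width_ms * 1e-3
    onset = slow_onset_ms * 1e-3
    pad_s = 0.5e-3
    extent = max(slow_w + onset, fast_width_ms * 1e-3, abs(onset)) + pad_s
    n_half = int(round(extent * sampling_rate_hz))
    t = (np.arange(2 * n_half + 1) - n_half) / sampling_rate_hz
    in_slow = (t >= onset) & (t <= onset + slow_w)
    slow = np.where(
        in_slow, -slow_wave_uv * np.sin(np.pi * (t - onset) / slow_w), 0.0
    )
    fw = fast_width_ms * 1e-3
    fast_amp = peak_uv + slow[n_half]  # slow is negative at t=0
    fast = np.where(
        np.abs(t) <= fw / 2,
        -fast_amp * np.cos(np.pi * t / fw) ** 2,
        0.0,
    )
    trace = slow + fast
    dist = np.abs(np.arange(n_channels) - channel)
    scale = depth_decay_per_channel**dist
    wav = scale[:, None] * trace[None, :]
    return SpikeTemplate(
        waveform_uv=wav,
        sampling_rate_hz=sampling_rate_hz,
        peak_sample=n_half,
        reference_channel=channel,
    )


# ---------------------------------------------------------------------------
# insertion


def theta_phase(
    rec: Recording, channel: int, lowpass_cutoff_hz: float = 20.0
) -> np.ndarray:
    """Instantaneous phase of the slow oscillation on one channel.

    Zero-phase low-pass then analytic signal; phase 0 is the oscillation
    peak, pi the trough, pi/2 the falling slope (x = A cos(phase)).
    """
    lp = FilterSpec("butterworth2", lowpass_cutoff_hz, band="lowpass", phase_mode="zero_phase")
    slow = apply_filter(rec.samples[channel], lp, rec.sampling_rate_hz)
    return np.angle(sps.hilbert(slow - slow.mean()))


def _phase_locked_indices(
    phase: np.ndarray, locking_phase_rad: float
) -> np.ndarray:
    """Samples where the wrapped phase crosses the requested value upward."""
    d = np.angle(np.exp(1j * (phase - locking_phase_rad)))
    crossings = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0) & (np.abs(d[:-1]) < 1.0))
    return crossings + 1


def _resample_template(tpl: SpikeTemplate, out_rate_hz: float) -> SpikeTemplate:
    if abs(tpl.sampling_rate_hz - out_rate_hz) < 1e-9:
        return tpl
    frac = Fraction(out_rate_hz / tpl.sampling_rate_hz).limit_denominator(1000)
    wav = sps.resample_poly(tpl.waveform_uv, frac.numerator, frac.denominator, axis=1)
    return SpikeTemplate(
        waveform_uv=wav,
        sampling_rate_hz=out_rate_hz,
        reference_channel=tpl.reference_channel,
    )


def insert_spikes(
    rec: Recording,
    template: SpikeTemplate,
    times_s: np.ndarray | None = None,
    n_spikes: int | None = None,
    amplitudes_uv: float | tuple[float, float] | np.ndarray = None,
    locking_phase_rad: float | None = None,
    theta_ref_channel: int = 0,
    seed: int = 0,
    edge_margin_s: float = 0.25,
) -> tuple[Recording, GroundTruth]:
    """Insert scaled copies of the template additively; return ground truth.

    Spike placement: explicit ``times_s``; or ``n_spikes`` at the requested
    theta phase of ``theta_ref_channel`` (one candidate per cycle, spread
    evenly over the recording); or ``n_spikes`` at uniform random times.
    ``amplitudes_uv`` is the requested |trough| on the template's reference
    channel: a scalar, a (low, high) range sampled uniformly, or an
    explicit array.  Insertions that would extend past the recording edge
    are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    tpl = _resample_template(template, rec.sampling_rate_hz)
    fs = rec.sampling_rate_hz
    n = rec.n_samples

    if times_s is None:
        if n_spikes is None:
            raise ValueError("give either times_s or n_spikes")
        if locking_phase_rad is not None:
            phase = theta_phase(rec, theta_ref_channel)
            cand = _phase_locked_indices(phase, locking_phase_rad)
            margin = int(round(edge_margin_s * fs))
            cand = cand[(cand >= margin) & (cand < n - margin)]
            if cand.size < n_spikes:
                warnings.warn(
                    f"only {cand.size} phase-locked slots for {n_spikes} spikes",
                    stacklevel=2,
                )
                chosen = cand
            else:
                pick = np.linspace(0, cand.size - 1, n_spikes).round().astype(int)
                chosen = cand[np.unique(pick)]
            times_s = rec.start_time_s + chosen / fs
        else:
            lo = rec.start_time_s + edge_margin_s
            hi = rec.end_time_s - edge_margin_s
            times_s = np.sort(rng.uniform(lo, hi, n_spikes))
    times_s = np.asarray(times_s, dtype=float).ravel()

    if amplitudes_uv is None:
        amplitudes_uv = abs(tpl.trough_uv)
    if isinstance(amplitudes_uv, tuple):
        amps = rng.uniform(amplitudes_uv[0], amplitudes_uv[1], times_s.size)
    else:
        amps = np.broadcast_to(
            np.asarray(amplitudes_uv, dtype=float), times_s.shape
        ).copy()

    if tpl.n_channels > rec.n_channels:
        raise ValueError("template has more channels than the recording")
    out = Recording(
        samples=rec.samples.copy(),
        sampling_rate_hz=fs,
        start_time_s=rec.start_time_s,
        channel_spacing_um=rec.channel_spacing_um,
        channel_depths_um=rec.channel_depths_um.copy(),
        channel_labels=list(rec.channel_labels),
    )
    trough = abs(tpl.trough_uv)
    if trough == 0:
        raise ValueError("template trough amplitude is zero; cannot scale")
    kept_t, kept_a = [], []
    n_skipped = 0
    for t_s, a in zip(times_s, amps):
        c = rec.sample_index(t_s)
        lo = c - tpl.peak_sample
        hi = lo + tpl.n_samples
        if lo < 0 or hi > n:
            n_skipped += 1
            continue
        out.samples[: tpl.n_channels, lo:hi] += (a / trough) * tpl.waveform_uv
        kept_t.append(rec.start_time_s + c / fs)
        kept_a.append(a)
    gt = GroundTruth(
        inserted_times_s=np.asarray(kept_t),
        inserted_amplitudes_uv=np.asarray(kept_a),
        inserted_template=tpl,
        locking_phase_rad=locking_phase_rad,
        n_skipped=n_skipped,
    )
    return out, gt
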