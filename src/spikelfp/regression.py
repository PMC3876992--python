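"""Spike waveform recovery by locally weighted polynomial regression.

The spike-bearing channel's LFP is modeled, in a local time window around
each detected spike, as a cubic polynomial (with pairwise interactions) of
simultaneously recorded spike-free reference channels.  Samples are
weighted by a tricube window centered on the spike, with notches that zero
out the neighborhood of every detected spike so the action potentials
themselves cannot contaminate the LFP model.  The model is fitted by
weighted least squares (general least squares with diagonal error
covariance v_ii = 1/w_i) via rank-revealing QR, the fitted LFP is predicted
over the whole window, and the prediction residual on the spike channel is
taken as the recovered extracellular spike waveform.

The method is filter-free: no frequency band is removed, so slow waveform
components that spectrally overlap the LFP (e.g. the ~8 ms negative wave
trailing a CA1 pyramidal-cell spike) survive intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .io import Recording, SpikeTimes

__all__ = [
    "RegressionConfig",
    "WeightVector",
    "DesignMatrix",
    "RegressionFit",
    "WaveformEstimate",
    "tricube",
    "notch_factor",
    "compute_weights",
    "build_design_matrix",
    "standardize",
    "weighted_gls_fit",
    "estimate_spike_waveform",
]


@dataclass
class RegressionConfig:
    """Parameters of the local LFP model.

    window_ms: full width T of the tricube fitting window (default 200 ms,
    much longer than a spike but short enough that the EEG state is
    approximately constant — about one theta period under urethane).
    notch_ms: full width of the zero-weight region around each detected
    spike (default 10 ms); the notch tapers back to full weight over a
    further notch_ms/2 on each side.
    """

    window_ms: float = 200.0
    notch_ms: float = 10.0
    reference_channels: list[int] = field(default_factory=list)
    include_interactions: bool = True
    rank_tolerance: float = 1e-10
    trough_refine_ms: float = 0.5

    def validate(self, spike_channel: int | None = None) -> None:
        if not 0 < self.notch_ms < self.window_ms:
            raise ValueError("need 0 < notch_ms < window_ms")
        if len(set(self.reference_channels)) != len(self.reference_channels):
            raise ValueError("duplicate reference channels")
        if spike_channel is not None and spike_channel in self.reference_channels:
            raise ValueError("reference channels must exclude the spike channel")


@dataclass
class WeightVector:
    """Temporal weights in [0, 1] over one local fitting window."""

    weights: np.ndarray
    window_center_s: float
    sample_indices: np.ndarray


@dataclass
class DesignMatrix:
    """Regressor matrix with per-column descriptors.

    Column order: constant; then per reference channel linear, square,
    cube; then pairwise interactions x_i * x_j for i < j.
    """

    values: np.ndarray
    column_descriptors: list[tuple[str, tuple[int, ...]]]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class RegressionFit:
    """One fitted local LFP model, in the z-score domain."""

    beta: np.ndarray
    response_mean_uv: float
    response_sd_uv: float
    reference_means_uv: np.ndarray
    reference_sds_uv: np.ndarray
    effective_rank: int
    weighted_rss: float


@dataclass
class WaveformEstimate:
    """Recovered per-spike waveforms (prediction residuals), in microvolts.

    Rows of ``per_spike_traces_uv`` are aligned on the (re-anchored) spike
    trough; samples falling outside the recording are NaN.  Peak amplitude
    is the most negative residual within the notch extent of each trace.
    """

    per_spike_traces_uv: np.ndarray
    mean_trace_uv: np.ndarray
    sd_trace_uv: np.ndarray
    peak_amplitudes_uv: np.ndarray
    time_axis_ms: np.ndarray
    spike_times_s: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.per_spike_traces_uv.shape[0]


def tricube(u: np.ndarray | float) -> np.ndarray | float:
    """Tricube kernel (1 - |u|^3)^3 for |u| < 1, else 0."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.where(u < 1.0, (1.0 - np.minimum(u, 1.0) ** 3) ** 3, 0.0)
    return out if out.ndim else float(out)


def notch_factor(dt_s: np.ndarray, notch_s: float) -> np.ndarray:
    """Spike-notch factor: 0 within +/- notch/2 of a spike, tapering to 1.

    The notch fully excludes the ``notch_s`` window surrounding the spike
    (weight exactly zero there, so spike samples cannot influence the fit)
    and rises smoothly as a flipped tricube over a further notch_s/2,
    reaching 1 at |dt| = notch_s.
    """
    v = np.abs(np.asarray(dt_s, dtype=float)) / notch_s  # 0.5 = plateau edge
    out = np.ones_like(v)
    out[v <= 0.5] = 0.0
    ramp = (v > 0.5) & (v < 1.0)
    out[ramp] = 1.0 - tricube(2.0 * v[ramp] - 1.0)
    return out


def compute_weights(
    window_center_s: float,
    window_s: float,
    spike_times_s: np.ndarray,
    notch_s: float,
    sample_times_s: np.ndarray,
    sample_indices: np.ndarray | None = None,
) -> WeightVector:
    """Temporal weights for one local window.

    w(t) = tricube(2 (t - t0) / T) * prod_j notch((t - s_j)), taken over
    every detected spike s_j whose notch intersects the window.  The
    weight is 0 at (and around) every spike time and at/beyond the window
    edges.
    """
    t = np.asarray(sample_times_s, dtype=float)
    if t.size == 0:
        raise ValueError("empty sample grid")
    w = np.asarray(tricube(2.0 * (t - window_center_s) / window_s))
    spikes = np.asarray(spike_times_s, dtype=float).ravel()
    near = spikes[
        (spikes > t[0] - notch_s) & (spikes < t[-1] + notch_s)
    ]
    for s in near:
        w = w * notch_factor(t - s, notch_s)
    if sample_indices is None:
        sample_indices = np.arange(t.size)
    return WeightVector(weights=w, window_center_s=window_center_s, sample_indices=sample_indices)


def build_design_matrix(
    z_refs: np.ndarray, include_interactions: bool = True
) -> DesignMatrix:
    """Polynomial design from z-scored reference signals (k x n).

    p = 1 + 3k + k(k-1)/2 with interactions, 1 + 3k without.  Interaction
    terms are products of linear terms only.
    """
    z = np.atleast_2d(np.asarray(z_refs, dtype=float))
    k, n = z.shape
    if k < 1:
        raise ValueError("need at least one reference channel")
    cols: list[np.ndarray] = [np.ones(n)]
    desc: list[tuple[str, tuple[int, ...]]] = [("constant", ())]
    for i in range(k):
        cols += [z[i], z[i] ** 2, z[i] ** 3]
        desc += [("linear", (i,)), ("square", (i,)), ("cube", (i,))]
    if include_interactions:
        for i in range(k):
            for j in range(i + 1, k):
                cols.append(z[i] * z[j])
                desc.append(("interaction", (i, j)))
    return DesignMatrix(values=np.column_stack(cols), column_descriptors=desc)


def standardize(
    x: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Z-score a signal using temporally weighted moments.

    The mean and SD are computed with the window weights, so zero-weight
    (spike) samples cannot contaminate the moments, but the whole signal
    (including zero-weight samples) is transformed.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("signal and weights must have equal length")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    mean = float(np.dot(w, x) / wsum)
    var = float(np.dot(w, (x - mean) ** 2) / wsum)
    if var <= np.finfo(float).tiny * 1e4:
        raise ValueError("zero weighted variance; cannot z-score")
    sd = float(np.sqrt(var))
    return (x - mean) / sd, mean, sd


def weighted_gls_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    rank_tolerance: float = 1e-10,
) -> tuple[np.ndarray, int, float]:
    """Weighted least squares by rank-revealing (column-pivoted) QR.

    Minimizes sum_i w_i (y_i - X_i beta)^2, the ML solution of general
    least squares with diagonal error covariance v_ii = 1/w_i: rows are
    scaled by sqrt(w_i), zero-weight rows dropped, and the scaled system
    solved by column-pivoted QR.  Returns (beta, effective_rank,
    weighted_rss); a rank-deficient system warns and returns the
    minimum-norm solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.shape[0] != y.size or y.size != w.size:
        raise ValueError("X, y, weights row counts disagree")
    mask = w > 0
    p = X.shape[1]
    if mask.sum() <= p:
        raise ValueError(
            f"only {int(mask.sum())} positive-weight samples for {p} coefficients"
        )
    sw = np.sqrt(w[mask])
    A = X[mask] * sw[:, None]
    b = y[mask] * sw
    beta, _, rank, _ = linalg.lstsq(A, b, cond=rank_tolerance, lapack_driver="gelsy")
    if rank < p:
        warnings.warn(
            f"rank-deficient design (rank {rank} < p {p}); minimum-norm solution",
            stacklevel=2,
        )
    rss = float(np.sum((b - A @ beta) ** 2))
    return beta, int(rank), rss


def _fit_window(
    y: np.ndarray,
    refs: np.ndarray,
    w: np.ndarray,
    cfg: RegressionConfig,
) -> tuple[np.ndarray, RegressionFit]:
    """Standardize, fit, and predict over one window; returns (yhat_uv, fit)."""
    y_z, y_mean, y_sd = standardize(y, w)
    k = refs.shape[0]
    z = np.empty_like(refs)
    r_means = np.empty(k)
    r_sds = np.empty(k)
    for i in range(k):
        z[i], r_means[i], r_sds[i] = standardize(refs[i], w)
    X = build_design_matrix(z, cfg.include_interactions)
    beta, rank, rss = weighted_gls_fit(X.values, y_z, w, cfg.rank_tolerance)
    yhat_uv = (X.values @ beta) * y_sd + y_mean
    fit = RegressionFit(
        beta=beta,
        response_mean_uv=y_mean,
        response_sd_uv=y_sd,
        reference_means_uv=r_means,
        reference_sds_uv=r_sds,
        effective_rank=rank,
        weighted_rss=rss,
    )
    return yhat_uv, fit


def estimate_spike_waveform(
    rec: Recording,
    spike_channel: int,
    spike_times: SpikeTimes | np.ndarray,
    cfg: RegressionConfig,
) -> tuple[WaveformEstimate, list[RegressionFit]]:
    """Recover each spike's waveform as the LFP-prediction residual.

    For each spike: the trough is re-anchored on the raw-trace local
    minimum within +/- trough_refine_ms of the given timestamp; a window
    of width T centered there is weighted (tricube window, notches at all
    spikes), response and references are z-scored with those weights, the
    local model is fitted on positive-weight samples and predicts the LFP
    over the entire window, and the residual y - yhat (in microvolts) is
    that spike's recovered trace.  Spikes whose window lies entirely
    outside the recording are skipped with a warning; partially truncated
    windows are fitted on the available samples and NaN-padded.
    """
    cfg.validate(spike_channel)
    if not cfg.reference_channels:
        raise ValueError("no reference channels configured")
    ts = (
        spike_times.timestamps_s
        if isinstance(spike_times, SpikeTimes)
        else np.asarray(spike_times, dtype=float).ravel()
    )
    fs = rec.sampling_rate_hz
    half = int(round(cfg.window_ms * 1e-3 * fs / 2))
    L = 2 * half + 1
    refine = int(round(cfg.trough_refine_ms * 1e-3 * fs))
    notch_s = cfg.notch_ms * 1e-3
    window_s = cfg.window_ms * 1e-3
    y_full = rec.samples[spike_channel]
    refs_full = rec.samples[cfg.reference_channels]
    n = rec.n_samples
    t0 = rec.start_time_s

    # re-anchor every timestamp first so notches of neighboring spikes land
    # on their troughs too
    centers = np.empty(ts.size, dtype=int)
    for i, s in enumerate(ts):
        c = rec.sample_index(s)
        a, b = max(0, c - refine), min(n, c + refine + 1)
        if a >= b:
            centers[i] = c
            continue
        centers[i] = a + int(np.argmin(y_full[a:b]))
    anchored_times = t0 + centers / fs

    traces = np.full((ts.size, L), np.nan)
    fits: list[RegressionFit] = []
    kept = np.zeros(ts.size, dtype=bool)
    notch_half = int(round(notch_s / 2 * fs))
    for i, c in enumerate(centers):
        lo, hi = c - half, c + half + 1
        if hi <= 0 or lo >= n:
            warnings.warn(
                f"spike at {ts[i]:.4f}s: window outside recording; skipped",
                stacklevel=2,
            )
            continue
        clo, chi = max(0, lo), min(n, hi)
        times = t0 + np.arange(clo, chi) / fs
        wv = compute_weights(
            anchored_times[i], window_s, anchored_times, notch_s, times,
            sample_indices=np.arange(clo, chi),
        )
        y = y_full[clo:chi]
        refs = refs_full[:, clo:chi]
        try:
            yhat, fit = _fit_window(y, refs, wv.weights, cfg)
        except ValueError as exc:
            warnings.warn(f"spike at {ts[i]:.4f}s: fit failed ({exc}); skipped", stacklevel=2)
            continue
        traces[i, clo - lo : chi - lo] = y - yhat
        fits.append(fit)
        kept[i] = True

    traces = traces[kept]
    kept_centers = centers[kept]
    peaks = np.full(traces.shape[0], np.nan)
    for i in range(traces.shape[0]):
        seg = traces[i, half - notch_half : half + notch_half + 1]
        if np.any(np.isfinite(seg)):
            peaks[i] = np.nanmin(seg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_trace = np.nanmean(traces, axis=0) if traces.size else np.full(L, np.nan)
        sd_trace = (
            np.nanstd(traces, axis=0, ddof=1)
            if traces.shape[0] > 1
            else np.zeros(L)
        )
    est = WaveformEstimate(
        per_spike_traces_uv=traces,
        mean_trace_uv=mean_trace,
        sd_trace_uv=sd_trace,
        peak_amplitudes_uv=peaks,
        time_axis_ms=(np.arange(L) - half) / fs * 1e3,
        spike_times_s=t0 + kept_centers / fs,
    )
    return est, fits
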