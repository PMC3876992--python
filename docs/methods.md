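# Methods

## Signal model and estimation procedure

A laminar extracellular recording is a channels × samples matrix in
microvolts with a sampling rate and probe geometry (16 sites, 50 µm
spacing, 16 kHz by default; depth increases with channel index).  The
spike-bearing channel *y* is assumed to share its background LFP with a
set of reference channels *x₁…x_k* recorded 150 µm or more from any soma
layer, which therefore carry no action potentials.  Within a local window
the LFP on *y* is modeled as

  y(t) ≈ Xβ,  X = [1, xᵢ, xᵢ², xᵢ³, xᵢxⱼ (i<j)]

with all signals z-scored before expansion.  The model is deliberately
low-order: the potential generated by a compartmental current source is a
smooth nonlinear function of distance, so a cubic with pairwise
interactions tracks how the LFP deforms between nearby sites without
inviting the variance of a flexible nonparametric fit.  Higher-order
interactions are excluded.

### Temporal weights

The LFP is nonstationary (transient events, drifting oscillatory states),
but it changes slowly relative to a spike.  Each spike therefore gets its
own local model, weighted by

  w(t) = tricube(2(t − t₀)/T) · Π_j notch(t − s_j)

where tricube(u) = (1 − |u|³)³ for |u| < 1, T is the window width
(default 200 ms ≈ one theta period under urethane anesthesia), and the
product runs over all detected spike times s_j.  The notch factor is zero
for |t − s_j| ≤ notch/2 (default notch = 10 ms, so the 10 ms surrounding
every spike is fully excluded from the fit) and rises smoothly as a
flipped tricube, 1 − tricube(2|Δt|/notch − 1), reaching full weight at
|Δt| = notch.  The hard-zero plateau is what makes the fit provably blind
to the spike: any artifact confined to it changes the coefficients by
nothing beyond floating-point noise.  The kernel shape itself is not
critical — the window is there to localize the fit, and moderate reshaping
moves the estimate little.

### Standardization and fitting

Means and SDs for z-scoring are computed *with the temporal weights*, so
the spike samples (weight zero) cannot inflate the response variance.
The weighted problem min Σ wᵢ(yᵢ − Xᵢβ)² — the ML estimate of generalized
least squares with diagonal error covariance vᵢᵢ = 1/wᵢ — is solved by
scaling rows with √wᵢ, dropping zero-weight rows, and factorizing with
column-pivoted QR (LAPACK `gelsy`).  The effective rank is reported; a
rank-deficient window warns and returns the minimum-norm solution, with
the rank tolerance (default 1e−10) exposed.  No ridge penalty is applied:
prediction happens strictly inside the regressor hull, where
multicollinearity does not harm the fitted values.

### Waveform recovery

The fitted model predicts the LFP over the entire window, including the
zero-weight samples; the residual y − ŷ (rescaled to µV) is the recovered
waveform.  Before windowing, each timestamp is re-anchored to the raw
trace's local minimum within ±0.5 ms, so traces are aligned on the true
trough rather than on the band-passed (group-delayed) detection time.
Windows truncated by the recording edge are fitted on the available
samples and NaN-padded; windows entirely outside are skipped with a
warning.  Per-spike peak amplitude is the most negative residual within
the notch extent; mean and SD traces are per-sample moments across spikes
(NaN-aware).

## Spike detection

The spike channel is band-passed with a causal cascade of order-2
Butterworth filters (high-pass 600 Hz, low-pass 6 kHz; states initialized
to the first sample's step steady state so the record onset does not
trigger), FIR-interpolated to 96 kHz (polyphase resampling with a
Kaiser β = 12 window; passband ripple < 1e−4), and thresholded at
−50 µV by default (negative-going; the level is a user flag, as in
practice it is adjusted per recording).  Each contiguous sub-threshold
excursion yields one event at its minimum, refined to the argmin of the
*raw* upsampled trace within ±0.3 ms — this removes the band-pass group
delay and gives timestamps accurate to one 96 kHz sample on clean spikes.
Events within a 1 ms dead time after an accepted event are suppressed —
a refractory-scale default that prevents double counting of multi-lobed
excursions.
A helper flags channels with zero threshold crossings as candidate
(spike-free) references.

## Comparison methods

**High-pass filtering.**  Order-2 Butterworth and single-pole RC designs,
digitized by bilinear transform with frequency pre-warping.  Causal mode
is a single forward pass; zero-phase mode is forward-backward filtering
with odd-symmetric edge extension (squared magnitude, zero group delay).
A high-pass may also be formed as broadband-minus-lowpass; for the RC
this is mathematically identical to the direct high-pass (first-order LP
and HP transfer functions sum to one), while for the order-2 Butterworth
the two differ in phase — both forms are exposed, and the complement form
guarantees spike + LFP = broadband exactly.

**Spike-triggered averaging.**  Per-sample mean and SD of raw broadband
snippets aligned on spike times (truncated snippets excluded and
counted).  When spikes are phase-locked to an oscillation of amplitude A
and angular frequency ω, the STA baseline inherits the locked phase
exactly: error ≈ A·cos(φ_lock + ωτ), i.e. a −A DC offset for trough
locking and a −Aω slope for falling-phase locking.  These closed forms
are what the acceptance checks compare against.

**Paul-wavelet spectrogram.**  Continuous transform with the analytic
order-m Paul wavelet (default m = 4), implemented in the frequency domain
with unit-energy normalization per scale; Fourier period λ = 4πs/(2m+1).
Chosen because its asymmetric, temporally compact shape suits spike
transients.  (No installed library provides the Paul wavelet, so the
transform is implemented here directly.)

## Synthetic laminar generator

The generator emulates the study conditions: 16 channels, 50 µm spacing,
16 kHz, a theta oscillation at 4 Hz (urethane range 4–5 Hz) whose
amplitude (default 300 µV, smooth 0.7–1.3× depth profile) and phase
(default π/15 rad/channel, a full reversal across the probe) vary with
depth, spatially correlated 1/f noise (default SD 25 µV) mixed into each
channel through a smoothly rotating pair of shared latents and a mild
tanh saturation (coupling 0.3) — deliberately *approximable but not
exactly representable* by the cubic model — plus independent white noise
(2 µV).  Everything is deterministic given the seed.

Templates: a biphasic square pulse (zero integral), and an EC spike with
a 0.4 ms raised-cosine fast trough (half-amplitude width 0.2 ms) followed
by an 8 ms negative half-sine (default 30% of peak, onset 1 ms before the
trough) — the trailing slow wave whose ~60 Hz content high-pass filters
erase.  Amplitude decays by 0.5 per channel so the spike is visible on
about 4 adjacent sites.  Insertion is additive on all template channels,
at explicit times, random times, or phase-locked to the theta of a chosen
channel (phase from the analytic signal of the 20 Hz-lowpassed trace;
0 = peak, π/2 = falling, π = trough), with ground-truth times and
amplitudes returned.

An exact-model mode builds the spike channel as an exact
cubic-plus-interaction function of the reference channels, so that
residual recovery can be checked at machine precision: affine z-scoring
maps that generative family onto the regression design exactly.

**What the generator does not emulate:** biophysical forward modeling of
extracellular potentials, sharp waves/dentate spikes, state transitions,
electrode drift, or spike-waveform variability (each insertion is a
scaled copy of the template).  Passing tests therefore demonstrate the
estimator's correctness and its advantages over filtering under
controlled overlap of spike and LFP spectra — not performance under every
in vivo pathology.

## Problem sizes and numerical choices

The validation experiments run at desk scale, chosen so the full suite
and the acceptance script complete in minutes: the solver oracle uses 200
random instances (n ≤ 500, k ≤ 4); waveform comparisons use 50 inserted
100 µV spikes across five 6 s recordings; amplitude linearity uses 63
spikes (50–150 µV, theta-trough-locked, 20 s recording — the lower bound
of the range is a package default, exposed as a flag); STA comparisons
use 40 spikes on a theta-dominant background (noise SD 5 µV) where the
closed-form baseline predictions apply; detection fidelity uses 13
noiseless insertions at 120–150 µV, about 2.5× the trigger — the causal
600 Hz–6 kHz band-pass retains only ~50–60% of the synthetic fast-lobe
amplitude, so spikes barely above 1.5× trigger are physically
undetectable at the default level and the margin is part of the study
conditions.  Reference channels 9–15 are used for realistic runs: sites
closer to the insertion channel carry up to 6% of the spike's depth
profile, which measurably biases amplitude recovery (slope ~0.92 instead
of ~0.97–1.0) — a quantitative illustration of the method's requirement
that references be spike-free.

Known limitations: one independent model per spike (no continuous sliding
estimate, by design); reference contamination degrades amplitude recovery
gracefully but silently; the filter-distortion sweep metric is the RMS in
the 1.5 ms windows before/after the trough (full-trace RMS is *not*
monotone in cutoff, because low cutoffs trade peak error for long
low-amplitude tails); the trough re-anchoring window (±0.5 ms) assumes
detection timestamps within half a millisecond of the true trough.
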