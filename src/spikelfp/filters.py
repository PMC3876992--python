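"""High- and low-pass filter designs common in extracellular recording.

Two recursive families are provided: the order-2 Butterworth and the
single-pole RC filter, each as a digital (bilinear-transform, pre-warped)
equivalent of the analog design, applied either causally (single forward
pass, as in on-line acquisition) or zero-phase (forward-backward).  A
high-pass can also be formed as the complement of the low-pass (broad-band
minus low-pass), which makes the spike and LFP traces sum exactly to the
broad-band signal; the direct IIR high-pass and the complement form differ
in phase and are both exposed.

These filters are the comparison baseline that the regression method is
measured against: a causal IIR high-pass narrows the spike, depresses its
amplitude, and appends a spurious positive "AHP-like" overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "design_filter", "apply_filter", "highpass_by_complement"]

_ORDERS = {"butterworth2": 2, "rc1": 1}


@dataclass(frozen=True)
class FilterSpec:
    """A named recursive filter design.

    family: 'butterworth2' (order-2 Butterworth) or 'rc1' (single-pole RC,
    identical to an order-1 Butterworth).
    phase_mode: 'causal' (one forward pass) or 'zero_phase'
    (forward-backward, zero group delay, squared magnitude response).
    hp_form: 'direct' realizes the high-pass transfer function itself;
    'complement' computes broad-band minus low-pass.
    """

    family: str
    cutoff_hz: float
    band: str = "highpass"
    phase_mode: str = "causal"
    hp_form: str = "direct"

    def __post_init__(self) -> None:
        if self.family not in _ORDERS:
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.band not in ("highpass", "lowpass"):
            raise ValueError(f"band must be highpass or lowpass, got {self.band!r}")
        if self.phase_mode not in ("causal", "zero_phase"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if self.hp_form not in ("direct", "complement"):
            raise ValueError(f"unknown hp_form {self.hp_form!r}")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")


def design_filter(spec: FilterSpec, sampling_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (b, a) transfer-function coefficients for the digital design.

    Uses the bilinear transform with frequency pre-warping, so the digital
    cutoff matches the named analog cutoff exactly.  DC gain is 1 for a
    lowpass and 0 for a highpass.
    """
    nyquist = sampling_rate_hz / 2.0
    if not spec.cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    band = "lowpass" if spec.hp_form == "complement" and spec.band == "highpass" else spec.band
    b, a = signal.butter(
        _ORDERS[spec.family], spec.cutoff_hz, btype=band, fs=sampling_rate_hz
    )
    return b, a


def _run(x: np.ndarray, b: np.ndarray, a: np.ndarray, phase_mode: str) -> np.ndarray:
    if phase_mode == "causal":
        return signal.lfilter(b, a, x)
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise ValueError(
            f"signal of {len(x)} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    # odd-symmetric extension suppresses startup transients at both ends
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def apply_filter(
    x: np.ndarray, spec: FilterSpec, sampling_rate_hz: float
) -> np.ndarray:
    """Filter a 1-D signal according to the spec.

    For ``hp_form='complement'`` high-pass, the output is the input minus
    its low-pass, so output + low-pass reconstructs the input exactly.
    """
    x = np.asarray(x, dtype=float)
    if spec.band == "highpass" and spec.hp_form == "complement":
        lp = replace(spec, band="lowpass", hp_form="direct")
        return x - apply_filter(x, lp, sampling_rate_hz)
    b, a = design_filter(spec, sampling_rate_hz)
    return _run(x, b, a, spec.phase_mode)


def highpass_by_complement(
    x: np.ndarray, lowpass_spec: FilterSpec, sampling_rate_hz: float
) -> np.ndarray:
    """Broad-band signal minus its low-pass: the complement-form high-pass."""
    if lowpass_spec.band != "lowpass":
        raise ValueError("highpass_by_complement needs a lowpass spec")
    x = np.asarray(x, dtype=float)
    return x - apply_filter(x, lowpass_spec, sampling_rate_hz)
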