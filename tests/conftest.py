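import numpy as np
import pytest

from spikelfp import Recording, SynthConfig, make_template_ec_spike, synth_lfp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ec_template():
    """Default 100 µV extracellular spike template with depth profile."""
    return make_template_ec_spike(peak_uv=100.0)


@pytest.fixture(scope="session")
def quiet_recording():
    """4 s silent-background recording (no theta, no noise)."""
    cfg = SynthConfig(
        duration_s=4.0, theta_amp_uv=0.0, noise_sd_uv=0.0, white_noise_sd_uv=0.0, seed=1
    )
    return synth_lfp(cfg)


@pytest.fixture(scope="session")
def realistic_recording():
    """10 s recording under the default study conditions (theta + 1/f)."""
    return synth_lfp(SynthConfig(duration_s=10.0, seed=77))


@pytest.fixture()
def tiny_recording(rng):
    """4-channel, 0.5 s recording of smooth random signals."""
    fs = 2000.0
    n = 1000
    t = np.arange(n) / fs
    samples = np.vstack(
        [
            50 * np.sin(2 * np.pi * 5 * t + p) + 5 * rng.standard_normal(n)
            for p in (0.0, 0.7, 1.4, 2.1)
        ]
    )
    return Recording(samples=samples, sampling_rate_hz=fs)


def template_on_grid(tpl, length, center, channel=None):
    """Template reference-channel trace placed on a zero grid of ``length``
    with its trough at ``center``."""
    ch = tpl.reference_channel if channel is None else channel
    out = np.zeros(length)
    lo = center - tpl.peak_sample
    out[lo : lo + tpl.n_samples] = tpl.waveform_uv[ch]
    return out
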