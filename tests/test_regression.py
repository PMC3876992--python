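import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelfp.regression import (
    RegressionConfig,
    build_design_matrix,
    compute_weights,
    estimate_spike_waveform,
    standardize,
    tricube,
    weighted_gls_fit,
)
from spikelfp.synthetic import (
    SynthConfig,
    insert_spikes,
    make_template_biphasic,
    make_template_ec_spike,
    synth_exact_model,
    synth_lfp,
)
from .conftest import template_on_grid

FS = 16000.0


class TestTricube:
    def test_closed_form_values(self):
        assert tricube(0.0) == 1.0
        assert tricube(0.5) == pytest.approx(0.669921875, abs=1e-15)  # (1-0.125)^3
        assert tricube(1.0) == 0.0
        assert tricube(-2.3) == 0.0

    @given(st.floats(-5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_symmetry_support(self, u):
        w = tricube(u)
        assert 0.0 <= w <= 1.0
        assert w == tricube(-u)
        if abs(u) >= 1:
            assert w == 0.0


class TestWeights:
    def grid(self, t0=0.0, T=0.2, fs=FS):
        half = int(T / 2 * fs)
        return t0 + np.arange(-half, half + 1) / fs

    def test_zero_at_triggering_spike(self):
        t = self.grid()
        wv = compute_weights(0.0, 0.2, np.array([0.0]), 0.01, t)
        assert wv.weights[np.abs(t) < 1e-12][0] == 0.0

    def test_tricube_value_away_from_spikes(self):
        # at t0 +/- T/4 with no spike within the notch, only the window
        # kernel is active: w = tricube(0.5)
        t = self.grid()
        wv = compute_weights(0.0, 0.2, np.array([0.09]), 0.01, t)
        i = np.argmin(np.abs(t - (-0.05)))
        assert wv.weights[i] == pytest.approx(0.669921875, abs=1e-12)

    def test_zero_at_every_spike_in_window(self):
        t = self.grid()
        spikes = np.array([-0.05, 0.0, 0.06])
        wv = compute_weights(0.0, 0.2, spikes, 0.01, t)
        for s in spikes:
            assert wv.weights[np.argmin(np.abs(t - s))] == 0.0

    def test_zero_plateau_covers_notch_window(self):
        # the notch_ms window surrounding a spike is entirely excluded
        t = self.grid()
        wv = compute_weights(0.0, 0.2, np.array([0.05]), 0.01, t)
        inside = np.abs(t - 0.05) <= 0.005
        assert np.all(wv.weights[inside] == 0.0)

    def test_zero_at_and_beyond_window_edges(self):
        t = self.grid()
        wv = compute_weights(0.0, 0.2, np.array([]), 0.01, t)
        assert wv.weights[0] == 0.0 and wv.weights[-1] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariants_with_random_overlapping_notches(self, seed):
        rng = np.random.default_rng(seed)
        t = self.grid()
        spikes = np.sort(rng.uniform(-0.12, 0.12, rng.integers(0, 8)))
        wv = compute_weights(0.0, 0.2, spikes, 0.01, t)
        assert np.all(wv.weights >= 0.0) and np.all(wv.weights <= 1.0)
        for s in spikes:
            if t[0] <= s <= t[-1]:
                assert wv.weights[np.argmin(np.abs(t - s))] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(0.0, 0.2, np.array([]), 0.01, np.array([]))


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "k,interactions,expected_p",
        [(2, True, 8), (1, True, 4), (1, False, 4), (12, True, 103), (3, False, 10)],
    )
    def test_column_count(self, rng, k, interactions, expected_p):
        z = rng.standard_normal((k, 40))
        dm = build_design_matrix(z, include_interactions=interactions)
        assert dm.p == expected_p
        assert len(dm.column_descriptors) == expected_p

    def test_column_content_and_order(self, rng):
        z = rng.standard_normal((2, 30))
        dm = build_design_matrix(z)
        np.testing.assert_array_equal(dm.values[:, 0], 1.0)
        np.testing.assert_array_equal(dm.values[:, 1], z[0])
        np.testing.assert_array_equal(dm.values[:, 2], z[0] ** 2)
        np.testing.assert_array_equal(dm.values[:, 3], z[0] ** 3)
        np.testing.assert_array_equal(dm.values[:, 4], z[1])
        np.testing.assert_array_equal(dm.values[:, 7], z[0] * z[1])
        assert dm.column_descriptors[7] == ("interaction", (0, 1))


class TestStandardize:
    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(np.full(100, 2.0), np.ones(100))

    def test_standardized_input_is_identity(self, rng):
        x = rng.standard_normal(5000)
        x = (x - x.mean()) / x.std()
        z, m, s = standardize(x, np.ones_like(x))
        np.testing.assert_allclose(z, x, atol=1e-12)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_artifact_in_zero_weight_samples_ignored(self, rng):
        x = rng.standard_normal(1000)
        w = np.ones(1000)
        w[100:150] = 0.0
        contaminated = x.copy()
        contaminated[100:150] += 1e6
        _, m_clean, s_clean = standardize(x, w)
        _, m_dirty, s_dirty = standardize(contaminated, w)
        assert m_dirty == pytest.approx(m_clean, abs=1e-9)
        assert s_dirty == pytest.approx(s_clean, rel=1e-12)


class TestWeightedGls:
    def test_constant_column_gives_weighted_mean(self, rng):
        y = rng.standard_normal(50)
        X = np.ones((50, 1))
        beta, rank, _ = weighted_gls_fit(X, y, np.ones(50))
        assert beta[0] == pytest.approx(y.mean())
        assert rank == 1

    def test_exact_generative_model_recovered(self, rng):
        z = rng.standard_normal((2, 400))
        X = build_design_matrix(z).values
        y = 0.3 - 1.2 * z[0] + 0.7 * z[0] ** 3 + 0.4 * z[0] * z[1]
        w = rng.uniform(0.1, 1.0, 400)
        beta, rank, rss = weighted_gls_fit(X, y, w)
        expected = np.zeros(8)
        expected[[0, 1, 3, 7]] = [0.3, -1.2, 0.7, 0.4]
        np.testing.assert_allclose(beta, expected, atol=1e-8)
        assert rss <= 1e-8

    def test_spike_in_zero_weight_samples_has_no_effect(self, rng):
        z = rng.standard_normal((3, 500))
        X = build_design_matrix(z).values
        y = z[0] - 0.5 * z[1] ** 2 + 0.2 * z[2] ** 3
        w = rng.uniform(0.2, 1.0, 500)
        w[200:260] = 0.0
        dirty = y.copy()
        dirty[200:260] += rng.uniform(-500, 500, 60)
        b_clean, *_ = weighted_gls_fit(X, y, w)
        b_dirty, *_ = weighted_gls_fit(X, dirty, w)
        np.testing.assert_allclose(b_dirty, b_clean, rtol=1e-10, atol=1e-12)

    def test_oracle_equivalence_batch(self):
        """Column-pivoted QR matches brute-force weighted normal equations."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(30, 501))
            k = int(rng.integers(1, 5))
            X = build_design_matrix(rng.standard_normal((k, n))).values
            w = rng.uniform(0, 1, n)
            w[rng.random(n) < 0.2] = 0.0
            if (w > 0).sum() <= X.shape[1]:
                continue
            y = X @ rng.standard_normal(X.shape[1]) + 0.1 * rng.standard_normal(n)
            sw = np.sqrt(w[w > 0])
            A = X[w > 0] * sw[:, None]
            if np.linalg.cond(A) >= 1e6:
                continue
            beta, *_ = weighted_gls_fit(X, y, w)
            oracle = np.linalg.solve(A.T @ A, A.T @ (y[w > 0] * sw))
            worst = max(worst, np.linalg.norm(beta - oracle) / np.linalg.norm(oracle))
        assert worst <= 1e-7

    def test_insufficient_samples_rejected(self, rng):
        X = build_design_matrix(rng.standard_normal((2, 10))).values
        with pytest.raises(ValueError, match="positive-weight"):
            weighted_gls_fit(X, rng.standard_normal(10), np.r_[np.ones(5), np.zeros(5)])

    def test_rank_deficiency_warns_and_reports(self, rng):
        z = rng.standard_normal(200)
        X = np.column_stack([np.ones(200), z, 2 * z])  # duplicated direction
        with pytest.warns(UserWarning, match="rank-deficient"):
            _, rank, _ = weighted_gls_fit(X, z.copy(), np.ones(200))
        assert rank == 2


class TestWaveformRecovery:
    def make_exact(self, seed=3, duration=4.0):
        cfg = SynthConfig(duration_s=duration, seed=seed)
        return synth_exact_model(cfg, spike_channel=3, reference_channels=[6, 8, 10])

    def test_exact_model_null_residual(self):
        rec, _ = self.make_exact()
        cfg = RegressionConfig(reference_channels=[6, 8, 10])
        est, fits = estimate_spike_waveform(rec, 3, np.array([1.5, 2.5]), cfg)
        assert np.sqrt(np.nanmean(est.per_spike_traces_uv**2)) <= 1e-6
        assert all(f.effective_rank == 13 for f in fits)

    def test_exact_model_template_recovered(self):
        rec, _ = self.make_exact()
        tpl = make_template_biphasic(100.0, 0.5, FS, n_channels=16, channel=3)
        rec2, gt = insert_spikes(rec, tpl, times_s=np.array([1.0, 2.0, 3.0]))
        cfg = RegressionConfig(reference_channels=[6, 8, 10])
        est, _ = estimate_spike_waveform(rec2, 3, gt.inserted_times_s, cfg)
        half = est.time_axis_ms.size // 2
        for i in range(est.n_spikes):
            # re-anchoring may settle anywhere in the flat square trough
            shift = int(round((est.spike_times_s[i] - gt.inserted_times_s[i]) * FS))
            ref = template_on_grid(tpl, est.time_axis_ms.size, half - shift)
            err = est.per_spike_traces_uv[i] - ref
            assert np.sqrt(np.nanmean(err**2)) <= 1e-6

    def test_artifact_inside_notch_does_not_change_fit(self):
        rec, _ = self.make_exact()
        cfg = RegressionConfig(reference_channels=[6, 8, 10], trough_refine_ms=0.0)
        t_spike = 2.0
        _, fits_clean = estimate_spike_waveform(rec, 3, np.array([t_spike]), cfg)
        rec_dirty, _ = self.make_exact()
        i0 = rec_dirty.sample_index(t_spike)
        span = int(0.004 * FS)  # strictly inside the +/-5 ms zero plateau
        rng = np.random.default_rng(9)
        rec_dirty.samples[3, i0 - span : i0 + span] += rng.uniform(-300, 300, 2 * span)
        _, fits_dirty = estimate_spike_waveform(rec_dirty, 3, np.array([t_spike]), cfg)
        np.testing.assert_allclose(
            fits_dirty[0].beta, fits_clean[0].beta, rtol=1e-10, atol=1e-13
        )

    def test_window_truncated_at_edge_still_fits(self):
        rec, _ = self.make_exact()
        cfg = RegressionConfig(reference_channels=[6, 8, 10])
        est, fits = estimate_spike_waveform(rec, 3, np.array([0.05]), cfg)
        assert est.n_spikes == 1
        # leading part of the window is NaN-padded, the rest is recovered
        assert np.isnan(est.per_spike_traces_uv[0][0])
        assert np.sqrt(np.nanmean(est.per_spike_traces_uv[0] ** 2)) <= 1e-6

    def test_window_outside_recording_skipped(self):
        rec, _ = self.make_exact()
        cfg = RegressionConfig(reference_channels=[6, 8, 10])
        with pytest.warns(UserWarning, match="outside recording"):
            est, _ = estimate_spike_waveform(rec, 3, np.array([2.0, 99.0]), cfg)
        assert est.n_spikes == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegressionConfig(notch_ms=300.0).validate()
        with pytest.raises(ValueError):
            RegressionConfig(reference_channels=[1, 1]).validate()
        with pytest.raises(ValueError):
            RegressionConfig(reference_channels=[3]).validate(spike_channel=3)


class TestRealisticRecovery:
    def test_window_size_dependence_is_u_shaped(self):
        """Estimate error vs window width has an interior minimum: too-short
        windows starve the fit, too-long windows span LFP state changes."""
        tpl = make_template_ec_spike(peak_uv=100.0)
        rec = synth_lfp(SynthConfig(duration_s=12.0, seed=21))
        rec2, gt = insert_spikes(
            rec, tpl, times_s=np.arange(1.0, 11.0, 0.7), amplitudes_uv=100.0
        )
        errs = []
        for T in [15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0]:
            cfg = RegressionConfig(window_ms=T, reference_channels=list(range(9, 16)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est, _ = estimate_spike_waveform(rec2, 3, gt.inserted_times_s, cfg)
            L = est.time_axis_ms.size
            ref = template_on_grid(tpl, L, L // 2)
            m = np.abs(est.time_axis_ms) <= 5.0
            errs.append(
                float(np.sqrt(np.nanmean((est.per_spike_traces_uv[:, m] - ref[m]) ** 2)))
            )
        best = int(np.argmin(errs))
        assert 0 < best < len(errs) - 1
        assert errs[0] > errs[best] and errs[-1] > errs[best]
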