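"""Analytic-signal preprocessing, carrier extraction, demodulation, whitening."""

import numpy as np
import pytest
from scipy import signal as sps

from timbre import preprocess as pp


class TestPreprocessLFP:
    def test_pure_cosine_becomes_unit_phasor(self):
        fs, fs_out, f = 1250.0, 25.0, 8.0
        t = np.arange(int(10 * fs)) / fs
        raw = pp.RawLFP(np.cos(2 * np.pi * f * t)[:, None], fs)
        lfp = pp.preprocess_lfp(raw, fs_out)
        mid = slice(50, lfp.n_samples - 50)
        assert np.allclose(np.abs(lfp.z[mid, 0]), 1.0, atol=0.02)
        dphase = np.angle(lfp.z[1:, 0] * np.conj(lfp.z[:-1, 0]))
        assert np.allclose(dphase[mid], 2 * np.pi * f / fs_out, atol=0.01)

    def test_dc_offset_rejected_by_highpass(self):
        raw = pp.RawLFP(np.full((5000, 2), 3.7), 250.0)
        lfp = pp.preprocess_lfp(raw)
        assert np.all(np.abs(lfp.z) < 1e-6)

    def test_matches_independent_reference_chain(self, rng):
        """Broadband noise through an independently composed
        decimate -> filtfilt -> hilbert chain."""
        fs, fs_out, q = 250.0, 25.0, 10
        x = rng.standard_normal((int(20 * fs), 3))
        lfp = pp.preprocess_lfp(pp.RawLFP(x, fs), fs_out)
        # reference: explicit Chebyshev-I anti-alias, stride, Butterworth, Hilbert
        b, a = sps.cheby1(8, 0.05, 0.8 / q)
        ref = sps.filtfilt(b, a, x, axis=0)[::q]
        bb, ab = sps.butter(2, 2.0, btype="highpass", fs=fs_out)
        ref = sps.filtfilt(bb, ab, ref, axis=0)
        ref = sps.hilbert(ref, axis=0)
        err = np.abs(lfp.z - ref).max() / np.abs(ref).max()
        assert err < 1e-6

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="non-finite"):
            pp.RawLFP(np.array([[np.nan, 1.0], [0.0, 1.0]]), 100.0)
        with pytest.raises(ValueError, match="2 s"):
            pp.preprocess_lfp(pp.RawLFP(np.zeros((50, 2)), 1250.0))
        with pytest.raises(ValueError, match="integer multiple"):
            pp.preprocess_lfp(pp.RawLFP(np.zeros((5000, 2)), 1000.0), 30.0)


class TestCarrier:
    def test_rank1_input_fully_explained(self, rng):
        u = np.exp(1j * np.linspace(0, 20, 300))
        w = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        lfp = pp.AnalyticLFP(np.outer(u, np.conj(w)), 25.0)
        carrier = pp.extract_carrier(lfp)
        assert carrier.explained_variance_fraction == pytest.approx(1.0)
        # carrier proportional to u (up to the deterministic gauge)
        corr = np.abs(np.vdot(carrier.theta, u)) / (
            np.linalg.norm(carrier.theta) * np.linalg.norm(u))
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_two_equal_components_split_evenly(self):
        t = np.arange(400)
        u1 = np.exp(2j * np.pi * 0.05 * t) / np.sqrt(400)
        u2 = np.exp(2j * np.pi * 0.11 * t) / np.sqrt(400)
        z = np.outer(u1, [1.0, 0.0]) + np.outer(u2, [0.0, 1.0])
        carrier = pp.extract_carrier(pp.AnalyticLFP(z, 25.0))
        assert carrier.explained_variance_fraction == pytest.approx(0.5, abs=1e-9)

    def test_explained_fraction_matches_eigendecomposition(self, rng):
        z = rng.standard_normal((200, 16)) + 1j * rng.standard_normal((200, 16))
        carrier = pp.extract_carrier(pp.AnalyticLFP(z, 25.0))
        evals = np.linalg.eigvalsh(z.conj().T @ z)
        assert carrier.explained_variance_fraction == pytest.approx(
            evals[-1] / evals.sum(), rel=1e-10)

    def test_gauge_is_deterministic(self, rng):
        z = rng.standard_normal((100, 6)) + 1j * rng.standard_normal((100, 6))
        c1 = pp.extract_carrier(pp.AnalyticLFP(z, 25.0))
        c2 = pp.extract_carrier(pp.AnalyticLFP(z.copy(), 25.0))
        assert np.array_equal(c1.theta, c2.theta)


class TestDemodulate:
    def test_carrier_demodulates_itself_to_zero_phase(self, rng):
        theta = (1 + rng.uniform(0, 1, 100)) * np.exp(
            1j * rng.uniform(-np.pi, np.pi, 100))
        out = pp.demodulate(theta[:, None], pp.Carrier(theta, 1.0))
        assert np.allclose(np.angle(out), 0.0, atol=1e-12)
        assert np.allclose(np.abs(out[:, 0]), np.abs(theta))

    def test_constant_offset_channel(self, rng):
        theta = np.exp(1j * rng.uniform(-np.pi, np.pi, 50))
        z = (theta * np.exp(1j * np.pi / 2))[:, None]
        out = pp.demodulate(z, pp.Carrier(theta, 1.0))
        assert np.allclose(np.angle(out), np.pi / 2)

    def test_matches_algebraic_oracle(self, rng):
        z = rng.standard_normal((80, 5)) + 1j * rng.standard_normal((80, 5))
        theta = rng.standard_normal(80) + 1j * rng.standard_normal(80)
        out = pp.demodulate(z, theta)
        oracle = z * (np.conj(theta) / np.abs(theta))[:, None]
        assert np.allclose(out, oracle, atol=1e-12)

    def test_magnitudes_preserved(self, rng):
        z = rng.standard_normal((60, 4)) + 1j * rng.standard_normal((60, 4))
        theta = rng.standard_normal(60) + 1j * rng.standard_normal(60)
        out = pp.demodulate(z, theta)
        assert np.abs(np.abs(out) - np.abs(z)).max() < 1e-13

    def test_shared_phase_invariance(self, rng):
        z = rng.standard_normal((60, 4)) + 1j * rng.standard_normal((60, 4))
        theta = rng.standard_normal(60) + 1j * rng.standard_normal(60)
        alpha = rng.uniform(-np.pi, np.pi, 60)
        rot = np.exp(1j * alpha)
        out1 = pp.demodulate(z, theta)
        out2 = pp.demodulate(z * rot[:, None], theta * rot)
        assert np.allclose(out1, out2, atol=1e-12)

    def test_zero_carrier_sample_convention(self):
        theta = np.array([1.0 + 0j, 0.0 + 0j])
        z = np.array([[1j], [1j]])
        out = pp.demodulate(z, theta)
        assert out[1, 0] == 1j   # phase 0 convention: channel passes through


class TestSplitComplex:
    def test_halves_and_roundtrip(self, rng):
        m = rng.standard_normal((10, 3)) + 1j * rng.standard_normal((10, 3))
        s = pp.split_complex(m)
        assert s.shape == (10, 6)
        assert np.array_equal(pp.split_complex(m.real + 0j)[:, 3:], np.zeros((10, 3)))
        assert np.array_equal(pp.split_complex(1j * m.real)[:, :3], np.zeros((10, 3)))
        assert np.array_equal(pp.combine_complex(s), m)


class TestWhiten:
    @staticmethod
    def _orthogonal_columns(t, variances, rng):
        # zero-mean orthonormal time courses scaled to target variances
        q, _ = np.linalg.qr(rng.standard_normal((t, len(variances)))
                            + 1j * rng.standard_normal((t, len(variances))))
        q = q - q.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(q)
        return q * np.sqrt(np.asarray(variances) * t)

    def test_small_component_is_shrunk_per_formula(self, rng):
        z = self._orthogonal_columns(500, [1.0, 1e-8], rng)
        out = pp.whiten(z, epsilon=1e-5).v
        var = np.mean(np.abs(out - out.mean(0)) ** 2, axis=0)
        expected = 1e-8 / (1e-8 + 1e-5 * (1 + 1e-8))
        assert var[1] == pytest.approx(expected, rel=1e-3)

    def test_epsilon_zero_gives_unit_variance(self, rng):
        z = self._orthogonal_columns(300, [2.0, 0.5, 0.1], rng)
        out = pp.whiten(z, epsilon=0.0).v
        var = np.mean(np.abs(out - out.mean(0)) ** 2, axis=0)
        assert np.allclose(var, 1.0, rtol=1e-6)

    def test_dominant_component_approaches_unit_variance(self, rng):
        z = self._orthogonal_columns(300, [1e4, 1.0], rng)
        out = pp.whiten(z, epsilon=1e-5).v
        var0 = np.mean(np.abs(out[:, 0] - out[:, 0].mean()) ** 2)
        assert var0 == pytest.approx(1.0, rel=0.01)

    def test_scale_equivariance(self, rng):
        z = rng.standard_normal((120, 6)) + 1j * rng.standard_normal((120, 6))
        base = pp.whiten(z).v
        for c in (0.1, 10.0):
            assert np.allclose(pp.whiten(c * z).v, base, rtol=1e-9, atol=1e-12)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            pp.whiten(np.zeros((10, 2), dtype=complex))


class TestThetaPower:
    def test_rank1_data_has_unit_ratio(self, rng):
        u = np.exp(1j * np.linspace(0, 30, 200)) * (1 + rng.uniform(0, 1, 200))
        w = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        lfp = pp.AnalyticLFP(np.outer(u, np.conj(w)), 25.0)
        carrier = pp.extract_carrier(lfp)
        ratio, deciles = pp.relative_theta_power(lfp, carrier)
        assert np.allclose(ratio, 1.0, atol=1e-9)
        # rank-1 oracle: carrier power reconstructs the total power
        recon = np.abs(carrier.theta) ** 2 * np.sum(np.abs(carrier.channel_weights) ** 2)
        assert np.allclose(recon / np.linalg.norm(w) ** 2,
                           np.abs(u) ** 2, rtol=1e-9)

    def test_decile_occupancy_balanced(self, rng):
        values = rng.uniform(0, 1, 1003)
        labels = pp.equal_count_bins(values, 10)
        counts = np.bincount(labels)[1:]
        assert counts.max() - counts.min() <= 1
        assert labels.min() == 1 and labels.max() == 10

    def test_ties_assigned_to_lowest_bin(self):
        labels = pp.equal_count_bins(np.zeros(40), 10)
        assert np.all(labels == 1)


class TestSWR:
    @staticmethod
    def _pink_noise(n, rng):
        white = rng.standard_normal(n)
        f = np.fft.rfftfreq(n, 1e-3)
        f[0] = f[1]
        spectrum = np.fft.rfft(white) / np.sqrt(f)
        return np.fft.irfft(spectrum, n)

    @staticmethod
    def _burst(fs, t0, n, duration=0.08, freq=200.0):
        t = np.arange(n) / fs
        env = np.exp(-((t - t0) ** 2) / (2 * (duration / 4) ** 2))
        return env * np.cos(2 * np.pi * freq * (t - t0))

    def test_constant_power_signal_has_no_events(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        raw = pp.RawLFP(np.sin(2 * np.pi * 200 * t)[:, None], fs)
        events = pp.detect_swr(raw)
        assert len(events.event_indices) == 0

    def test_single_burst_detected(self, rng):
        fs, n = 1000.0, 10000
        x = self._pink_noise(n, rng)
        x = x / x.std() * 0.2 + self._burst(fs, 5.0, n)
        events = pp.detect_swr(pp.RawLFP(x[:, None], fs))
        assert len(events.event_indices) == 1
        assert abs(events.event_indices[0] - 5000) < 100

    def test_two_bursts_counted_with_rate(self, rng):
        fs, n = 1000.0, 10000
        x = self._pink_noise(n, rng)
        x = x / x.std() * 0.2 + self._burst(fs, 4.0, n) + self._burst(fs, 5.0, n)
        events = pp.detect_swr(pp.RawLFP(x[:, None], fs))
        assert len(events.event_indices) == 2
        assert events.rate == pytest.approx(2 / 10.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            pp.detect_swr(pp.RawLFP(np.zeros((1000, 1)), 500.0))


def test_edge_mask_flags_first_and_last_second():
    mask = pp.edge_mask(100, 25.0)
    assert mask[:25].all() and mask[-25:].all() and not mask[25:75].any()
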