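"""Classical branch: normalization, filtering, AR and Welch features."""

import numpy as np
import pytest
from scipy import signal as sps

from eeglink.eeg_io import EEGRecording
from eeglink.preproc import (
    CLASSICAL_BANDS,
    DegenerateChannelError,
    ar_coefficients,
    band_powers,
    bandpass,
    extract_features,
    welch_psd,
    zero_mean_normalize,
)
from eeglink.segment import SegmentBatch


def _rec(data, fs=160.0):
    return EEGRecording(np.atleast_2d(np.asarray(data, float)), fs=fs)


class TestNormalize:
    def test_three_point_channel(self):
        out = zero_mean_normalize(_rec([1.0, 2.0, 3.0]))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(out.data[0], expected, atol=1e-12)
        assert out.data[0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = zero_mean_normalize(_rec(rng.normal(3.0, 5.0, size=(4, 500))))
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.data.std(axis=1), 1.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = zero_mean_normalize(_rec(rng.normal(size=(3, 200))))
        twice = zero_mean_normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateChannelError, match="ch1"):
            zero_mean_normalize(_rec([5.0, 5.0, 5.0]))


class TestBandpass:
    fs = 160.0

    def _rms(self, x):
        return np.sqrt(np.mean(x**2))

    def test_in_band_tone_preserved(self):
        t = np.arange(8 * 160) / self.fs
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(_rec(x, self.fs)).data[0]
        trim = slice(160, -160)  # discard filter edges
        assert self._rms(out[trim]) == pytest.approx(self._rms(x[trim]), rel=0.05)

    def test_stop_band_tone_attenuated(self):
        t = np.arange(8 * 160) / self.fs
        x = np.sin(2 * np.pi * 60 * t)
        out = bandpass(_rec(x, self.fs)).data[0]
        assert self._rms(out[160:-160]) <= 0.1 * self._rms(x)

    def test_dc_removed(self):
        x = np.ones(8 * 160)
        out = bandpass(_rec(x, self.fs)).data[0]
        assert self._rms(out[160:-160]) <= 0.05

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_rec(np.random.default_rng(0).normal(size=300), fs=80.0), high=45.0)


class TestAR:
    def _simulate_ar2(self, a, n, seed=0):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=n + 500)
        x = sps.lfilter([1.0], np.concatenate([[1.0], -np.asarray(a)]), e)
        return x[500:]

    def test_recovers_ar2(self):
        x = self._simulate_ar2([0.5, -0.3], 10_000, seed=42)
        model = ar_coefficients(x, p=2)
        assert model.coefficients == pytest.approx([0.5, -0.3], abs=0.05)

    def test_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(7).normal(size=10_000)
        model = ar_coefficients(x, p=2)
        assert np.all(np.abs(model.coefficients) < 0.05)

    def test_order_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        model = ar_coefficients(x, p=0)
        assert model.coefficients.size == 0
        assert model.intercept == pytest.approx(2.5)

    def test_consistency_error_shrinks(self):
        """Yule-Walker estimates tighten with sample size on a fixed AR(2)."""
        true = np.array([0.5, -0.3])
        errs = []
        for n in (500, 5000, 50_000):
            per_seed = [
                np.abs(ar_coefficients(self._simulate_ar2(true, n, seed=s), 2).coefficients
                       - true).max()
                for s in range(5)
            ]
            errs.append(np.median(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_nonfinite_rejected(self):
        x = np.ones(100)
        x[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            ar_coefficients(x, p=2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.arange(20.0), p=2)


class TestWelch:
    def test_white_noise_integrates_to_variance(self):
        x = np.random.default_rng(3).normal(size=16_384)
        x /= x.std()
        psd = welch_psd(x, fs=160.0, nperseg=256)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_sinusoid_peak_location(self):
        t = np.arange(4096) / 160.0
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), fs=160.0, nperseg=256)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert abs(peak - 10.0) <= psd.resolution

    def test_zero_signal(self):
        psd = welch_psd(np.zeros(1024), fs=160.0, nperseg=256)
        assert np.all(psd.power == 0.0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="nperseg"):
            welch_psd(np.zeros(100), fs=160.0, nperseg=256)

    def test_constant_offset_invariance(self):
        """Detrended Welch: adding a constant leaves the non-DC spectrum."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=4096)
        a = welch_psd(x, fs=160.0, nperseg=256)
        b = welch_psd(x + 100.0, fs=160.0, nperseg=256)
        assert np.allclose(a.power[1:], b.power[1:], rtol=1e-8)


class TestFeatures:
    def _batch(self, segs, subject=1, cls=1):
        return SegmentBatch(segments=segs, labels=[(subject, 1, cls)] * len(segs))

    def test_feature_dimension(self):
        rng = np.random.default_rng(0)
        batch = self._batch([rng.normal(size=(4, 320))])
        feats = extract_features(batch, fs=160.0, p=6)
        assert feats[0].values.size == 4 * (6 + len(CLASSICAL_BANDS))

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        seg = rng.normal(size=(2, 320))
        batch = self._batch([seg, seg.copy()])
        feats = extract_features(batch, fs=160.0, p=4)
        assert np.array_equal(feats[0].values, feats[1].values)

    def test_alpha_feature_monotone_in_amplitude(self):
        t = np.arange(640) / 160.0
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.5, size=640)
        weak = base + 1.0 * np.sin(2 * np.pi * 10 * t)
        strong = base + 2.0 * np.sin(2 * np.pi * 10 * t)
        bp_w = band_powers(weak, fs=160.0)
        bp_s = band_powers(strong, fs=160.0)
        alpha_ix = list(CLASSICAL_BANDS).index("alpha")
        assert bp_s[alpha_ix] > bp_w[alpha_ix]

    def test_blocks_switchable(self):
        rng = np.random.default_rng(3)
        batch = self._batch([rng.normal(size=(2, 320))])
        ar_only = extract_features(batch, fs=160.0, p=6, use_psd=False)
        psd_only = extract_features(batch, fs=160.0, p=6, use_ar=False)
        assert ar_only[0].values.size == 12
        assert psd_only[0].values.size == 10
        with pytest.raises(ValueError):
            extract_features(batch, fs=160.0, use_ar=False, use_psd=False)
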