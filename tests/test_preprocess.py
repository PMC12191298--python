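"""Baseline removal, wavelet denoising, Pan-Tompkins and segmentation."""
import numpy as np
import pytest

from ecgmff import (
    NoiseConfig,
    SynthConfig,
    WaveletDenoiseConfig,
    denoise_wavelet,
    detect_r_peaks,
    generate_record,
    remove_baseline,
    resample_record,
    segment_beats,
)
from ecgmff.preprocess import (
    MAD_CONSTANT,
    level_threshold,
    match_peaks,
    preprocess_record,
    shrink_coefficients,
)
from ecgmff.records import EcgRecord, RPeakList, STANDARD_LEADS


def _record_from(signal, fs=1000.0):
    signal = np.atleast_2d(signal)
    reps = int(np.ceil(12 / signal.shape[0]))
    full = np.tile(signal, (reps, 1))[:12]
    return EcgRecord(full, fs, list(STANDARD_LEADS))


def _band_power(x, fs, lo, hi):
    mags = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return mags[(freqs >= lo) & (freqs <= hi)].sum()


# ---------------------------------------------------------------------------
# Baseline removal
# ---------------------------------------------------------------------------

class TestBaseline:
    def test_constant_offset_removed(self):
        rec = _record_from(np.full(4000, 0.5))
        out = remove_baseline(rec)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_slow_wander_suppressed(self, clean_record):
        t = np.arange(clean_record.n_samples) / clean_record.sampling_rate
        wander = 0.3 * np.sin(2 * np.pi * 0.3 * t)
        drifting = clean_record.with_signal(clean_record.signal + wander)
        out = remove_baseline(drifting)
        fs = clean_record.sampling_rate
        before = _band_power(drifting.lead("II"), fs, 0.05, 0.5)
        after = _band_power(out.lead("II"), fs, 0.05, 0.5)
        assert after < before / 10

    def test_near_identity_on_zero_baseline(self, clean_record):
        out = remove_baseline(clean_record)
        # QRS deflections survive almost untouched
        assert np.max(np.abs(out.signal - clean_record.signal)) < 0.05

    def test_too_short_record_rejected(self):
        rec = _record_from(np.zeros(100))
        with pytest.raises(ValueError):
            remove_baseline(rec)


# ---------------------------------------------------------------------------
# Wavelet denoising
# ---------------------------------------------------------------------------

class TestWaveletDenoise:
    def test_zero_signal_stays_zero(self):
        rec = _record_from(np.zeros(2048))
        out = denoise_wavelet(rec)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_shrinkage_matches_elementwise_rule(self, rng):
        """Shrinkage equals the direct piecewise definition on random data."""
        for _ in range(100):
            d = rng.standard_normal(rng.integers(4, 200)) * rng.uniform(0.1, 5)
            te = float(rng.uniform(0, 2))
            got = shrink_coefficients(d, te)
            expected = np.array(
                [np.sign(c) * (abs(c) - te) if abs(c) > te else 0.0 for c in d]
            )
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_single_coefficient_shrinks_by_threshold(self):
        te = 0.8
        d = np.array([2 * te])
        assert shrink_coefficients(d, te)[0] == pytest.approx(te)

    def test_threshold_nonnegative_even_for_small_norms(self, rng):
        for scale in (1e-4, 1e-2, 1.0, 100.0):
            d = rng.standard_normal(64) * scale
            for level in range(1, 10):
                assert level_threshold(d, level) >= 0.0

    def test_sign_equivariance(self, noisy_record):
        out_pos = denoise_wavelet(noisy_record)
        negated = noisy_record.with_signal(-noisy_record.signal)
        out_neg = denoise_wavelet(negated)
        np.testing.assert_allclose(out_neg.signal, -out_pos.signal, atol=1e-10)

    def test_snr_improves_on_noisy_beats(self):
        """Denoising raises SNR vs the clean reference in >=90% of trials."""
        cfg = SynthConfig(
            duration=4, heart_rate=75, seed=0,
            noise=NoiseConfig(baseline_amp=0, powerline_amp=0, broadband_sd=0),
        )
        clean = generate_record(cfg).lead("II")
        power = np.mean(clean**2)
        target_snr_db = 5.0
        sigma = np.sqrt(power / 10 ** (target_snr_db / 10))
        improved = 0
        n_trials = 50
        for trial in range(n_trials):
            noise = np.random.default_rng(1000 + trial).standard_normal(
                clean.size
            ) * sigma
            rec = _record_from(clean + noise)
            out = denoise_wavelet(rec).signal[0]
            snr_in = power / np.mean((clean + noise - clean) ** 2)
            snr_out = power / np.mean((out - clean) ** 2)
            improved += snr_out > snr_in
        assert improved >= 0.9 * n_trials

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            WaveletDenoiseConfig(wavelet_name="nosuch")
        with pytest.raises(ValueError):
            WaveletDenoiseConfig(n_levels=10)
        rec = _record_from(np.zeros(64))
        with pytest.raises(ValueError):
            denoise_wavelet(rec, WaveletDenoiseConfig(n_levels=9))


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

class TestPanTompkins:
    def test_clean_record_recovers_truth(self, clean_record):
        peaks = detect_r_peaks(clean_record)
        truth = clean_record.meta["true_r_peaks"]
        assert abs(len(peaks) - len(truth)) <= 1
        assert match_peaks(peaks, truth) >= 0.95

    def test_flat_line_gives_no_peaks(self):
        rec = _record_from(np.zeros(5000))
        assert len(detect_r_peaks(rec)) == 0

    def test_noisy_records_recover_95_percent(self):
        total, hit = 0, 0.0
        for seed in range(5):
            cfg = SynthConfig(duration=10, heart_rate=72, rr_jitter=0.05,
                              seed=seed)
            rec = generate_record(cfg)
            clean, peaks, _ = preprocess_record(rec)
            truth = rec.meta["true_r_peaks"]
            hit += match_peaks(peaks, truth) * len(truth)
            total += len(truth)
        assert hit / total >= 0.95

    def test_short_record_rejected(self):
        rec = _record_from(np.zeros(1500))
        with pytest.raises(ValueError):
            detect_r_peaks(rec)

    def test_refractory_invariant(self, noisy_record):
        peaks = detect_r_peaks(denoise_wavelet(remove_baseline(noisy_record)))
        assert np.all(np.diff(peaks.indices) >= 0.2 * noisy_record.sampling_rate)


# ---------------------------------------------------------------------------
# Segmentation and resampling
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_interior_peaks_give_651_sample_beats(self, clean_record):
        peaks = detect_r_peaks(clean_record)
        interior = peaks.indices[
            (peaks.indices >= 250)
            & (peaks.indices + 400 < clean_record.n_samples)
        ]
        beats = segment_beats(clean_record, peaks)
        assert len(beats) == interior.size
        for b in beats:
            assert b.values.shape == (12, 651)

    def test_edge_peak_dropped(self, clean_record):
        peaks = RPeakList(np.array([100, 2000]), clean_record.sampling_rate)
        beats = segment_beats(clean_record, peaks)
        assert len(beats) == 1
        assert beats[0].r_index_in_record == 2000

    def test_degenerate_window(self, clean_record):
        peaks = RPeakList(np.array([1000]), clean_record.sampling_rate)
        beats = segment_beats(clean_record, peaks, pre=0, post=0)
        assert beats[0].values.shape == (12, 1)
        np.testing.assert_array_equal(
            beats[0].values[:, 0], clean_record.signal[:, 1000]
        )

    def test_kept_plus_dropped_equals_peaks(self, clean_record):
        peaks = RPeakList(
            np.array([10, 500, 2500, clean_record.n_samples - 5]),
            clean_record.sampling_rate,
        )
        beats = segment_beats(clean_record, peaks)
        dropped = len(peaks) - len(beats)
        assert len(beats) + dropped == len(peaks)
        assert dropped == 2

    def test_pipeline_is_deterministic(self, noisy_record):
        _, _, beats_a = preprocess_record(noisy_record)
        _, _, beats_b = preprocess_record(noisy_record)
        assert len(beats_a) == len(beats_b)
        for a, b in zip(beats_a, beats_b):
            np.testing.assert_array_equal(a.values, b.values)


class TestResample:
    def test_length_ratio(self):
        rec = _record_from(np.random.default_rng(0).standard_normal(5000),
                           fs=500.0)
        out = resample_record(rec, 1000.0)
        assert out.n_samples == 10000
        assert out.sampling_rate == 1000.0

    def test_sinusoid_frequency_preserved(self):
        fs = 500.0
        t = np.arange(5000) / fs
        rec = _record_from(np.sin(2 * np.pi * 10 * t), fs=fs)
        out = resample_record(rec, 1000.0)
        mags = np.abs(np.fft.rfft(out.lead("II")))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 1000.0)
        assert freqs[np.argmax(mags)] == pytest.approx(10.0, abs=0.2)

    def test_identity_when_rates_match(self, clean_record):
        out = resample_record(clean_record, clean_record.sampling_rate)
        np.testing.assert_array_equal(out.signal, clean_record.signal)

    def test_negative_rate_rejected(self, clean_record):
        with pytest.raises(ValueError):
            resample_record(clean_record, -100.0)


def test_mad_constant_is_standard_normal_quartile():
    import scipy.stats

    assert round(float(scipy.stats.norm.ppf(0.75)), 4) == MAD_CONSTANT
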