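"""Spectral IBI estimation, the filter chain, and fiducial detection."""
import numpy as np
import pytest

from ppgstress.fiducials import (AcSeries, FiducialSet, FilteredSignals,
                                 IbiEstimate, compute_ac, detect_onsets,
                                 detect_peaks, estimate_ibi, extract_ac_series,
                                 filter_chain)

FS = 100.0


def _ibi(f0: float) -> IbiEstimate:
    return IbiEstimate(ibi_seconds=1.0 / f0, peak_frequency=f0)


class TestEstimateIbi:
    def test_pure_sinusoid_recovers_period(self):
        t = np.arange(0, 60, 1 / FS)
        est = estimate_ibi(np.sin(2 * np.pi * 1.25 * t), FS)
        assert est.peak_frequency == pytest.approx(1.25, abs=1 / 60)
        assert est.ibi_seconds == pytest.approx(0.8, abs=0.02)
        assert 0.8 <= est.peak_frequency <= 3.0

    def test_matches_independent_periodogram_argmax_on_noise(self, rng):
        x = rng.standard_normal(3000)
        est = estimate_ibi(x, FS)
        # independent oracle: plain FFT periodogram restricted to the band
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(len(x), d=1 / FS)
        band = (freqs >= 0.8) & (freqs <= 3.0)
        assert est.peak_frequency == pytest.approx(freqs[band][np.argmax(spec[band])])

    def test_short_and_constant_signals_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            estimate_ibi(np.zeros(500), FS)
        with pytest.raises(ValueError, match="heart-rate band"):
            estimate_ibi(np.full(2000, 3.7), FS)


class TestFilterChain:
    def test_constants_preserved(self):
        out = filter_chain(np.full(2000, 2.5), FS, _ibi(1.2))
        for arr in (out.w1, out.w2, out.baseline):
            np.testing.assert_allclose(arr, 2.5, atol=1e-9)

    def test_ramp_baseline_is_ramp_on_interior(self):
        x = np.linspace(0, 10, 2000)
        out = filter_chain(x, FS, _ibi(1.2))
        # zero-phase IIR + centred averages pass an affine trend unchanged;
        # trim generously for the filtfilt edge transients
        trim = 400
        np.testing.assert_allclose(out.baseline[trim:-trim], x[trim:-trim], atol=1e-6)

    def test_butterworth_attenuation_matches_closed_form(self):
        f0 = 1.2
        f_test = 5 * f0  # 6 Hz
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * f_test * t)
        out = filter_chain(x, FS, _ibi(f0))
        # The Butterworth stage maps w1 -> w2, so at any single frequency
        # the spectral ratio equals |H(f)|^2 (zero-phase, applied twice),
        # independent of how the w1 prefilter reshaped the input.
        # closed form with the bilinear design's frequency prewarping
        ratio = np.tan(np.pi * f_test / FS) / np.tan(np.pi * 1.5 * f0 / FS)
        expected = 1.0 / (1.0 + ratio ** 6)
        inner = slice(1000, 5000)  # 40 s interior: 6 Hz falls on bin 240
        spec_w1 = np.abs(np.fft.rfft(out.w1[inner]))
        spec_w2 = np.abs(np.fft.rfft(out.w2[inner]))
        k = int(f_test * 40)
        assert spec_w2[k] / spec_w1[k] == pytest.approx(expected, rel=0.05)

    def test_scaling_linearity(self, rng):
        x = rng.standard_normal(1500)
        one = filter_chain(x, FS, _ibi(1.0))
        three = filter_chain(3.0 * x, FS, _ibi(1.0))
        np.testing.assert_allclose(three.w2, 3.0 * one.w2, atol=1e-9)
        np.testing.assert_allclose(three.baseline, 3.0 * one.baseline, atol=1e-9)

    def test_implausibly_small_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            filter_chain(np.zeros(100), fs=10.0, ibi=_ibi(3.0))


class TestDetectPeaksOnsets:
    def test_clean_subject_recovers_every_true_fiducial(self, clean_subject):
        truth, cfg = clean_subject["truth"], clean_subject["config"]
        fid = clean_subject["fiducials"]
        true_peaks = np.round(truth.true_peak_times * cfg.fs).astype(int)
        true_onsets = np.round(truth.true_onset_times * cfg.fs).astype(int)
        d_peak = np.abs(fid.peak_indices[:, None] - true_peaks[None, :])
        d_onset = np.abs(fid.onset_indices[:, None] - true_onsets[None, :])
        assert (d_peak.min(axis=0) <= 3).all()   # recall within +-30 ms
        assert (d_peak.min(axis=1) <= 3).all()   # precision
        assert (d_onset.min(axis=0) <= 3).all()
        assert (d_onset.min(axis=1) <= 3).all()

    def test_constant_signal_yields_no_peaks(self):
        n = 2000
        flat = FilteredSignals(w1=np.zeros(n), w2=np.zeros(n), baseline=np.zeros(n))
        with pytest.warns(UserWarning, match="no peak"):
            peaks = detect_peaks(flat, FS, _ibi(1.2))
        assert len(peaks) == 0

    def test_low_prominence_bump_rejected(self):
        # pulse train at 1.2 Hz plus one bump at 10% of pulse height,
        # well under the 30%-of-running-median criterion
        t = np.arange(0, 60, 1 / FS)
        x = np.clip(np.sin(2 * np.pi * 1.2 * t), 0, None)
        bump_at = int(29.6 * FS)  # mid-diastole
        x[bump_at - 2:bump_at + 3] += 0.1 * np.array([0.3, 0.8, 1.0, 0.8, 0.3])
        filt = FilteredSignals(w1=x, w2=x, baseline=np.zeros_like(x))
        peaks = detect_peaks(filt, FS, _ibi(1.2))
        assert len(peaks) == pytest.approx(72, abs=1)
        assert np.abs(peaks - bump_at).min() > 10

    def test_onset_is_valley_between_two_peaks(self):
        x = np.array([0.0, 1.0, 0.5, 0.2, 0.6, 1.2, 0.0])
        filt = FilteredSignals(w1=x, w2=x, baseline=np.zeros_like(x))
        onsets = detect_onsets(filt, np.array([1, 5]))
        np.testing.assert_array_equal(onsets, [3])

    def test_flat_valley_tie_breaks_to_earliest(self):
        x = np.array([0.0, 1.0, 0.3, 0.3, 0.3, 1.0, 0.0])
        filt = FilteredSignals(w1=x, w2=x, baseline=np.zeros_like(x))
        onsets = detect_onsets(filt, np.array([1, 5]))
        np.testing.assert_array_equal(onsets, [2])

    def test_fewer_than_two_peaks_gives_no_onsets(self):
        x = np.zeros(10)
        filt = FilteredSignals(w1=x, w2=x, baseline=x)
        assert len(detect_onsets(filt, np.array([4]))) == 0


class TestComputeAc:
    @staticmethod
    def _fiducials_from(w2, peaks, onsets):
        filt = FilteredSignals(w1=w2, w2=w2, baseline=np.zeros_like(w2))
        fid = FiducialSet(peak_indices=np.asarray(peaks),
                          onset_indices=np.asarray(onsets),
                          ibi=_ibi(1.2))
        return filt, fid

    def test_amplitude_is_peak_minus_preceding_onset(self):
        w2 = np.array([0.1, 2.0, 0.5, 0.1, 2.0, 0.1])
        filt, fid = self._fiducials_from(w2, peaks=[1, 4], onsets=[2])
        ac = compute_ac(filt, fid, FS)
        assert ac.ac_values == pytest.approx([1.5])
        assert ac.beat_times == pytest.approx([0.04])

    def test_gross_outlier_beat_masked(self, rng):
        n_beats = 100
        values = 1.0 + 0.01 * rng.standard_normal(n_beats + 1)
        w2 = np.zeros(2 * n_beats + 2)
        w2[1::2] = values  # peaks at odd indices, onsets (0) at even
        outlier_beat = 50
        w2[1 + 2 * outlier_beat] = 20.0 * np.median(values)
        peaks = np.arange(1, 2 * n_beats + 2, 2)
        onsets = np.arange(2, 2 * n_beats + 1, 2)
        filt, fid = self._fiducials_from(w2, peaks, onsets)
        ac = compute_ac(filt, fid, FS)
        assert not ac.kept_mask[outlier_beat - 1]
        assert ac.kept_mask.sum() == n_beats - 1

    def test_identical_beats_all_kept_with_zero_spread(self):
        w2 = np.tile([0.0, 1.0], 50)
        peaks = np.arange(1, 100, 2)
        onsets = np.arange(2, 99, 2)
        filt, fid = self._fiducials_from(w2, peaks, onsets)
        ac = compute_ac(filt, fid, FS)
        assert ac.kept_mask.all()
        assert np.std(ac.kept_values) == 0.0

    def test_alternation_violation_rejected(self):
        w2 = np.zeros(10)
        filt, fid = self._fiducials_from(w2, peaks=[1, 2], onsets=[5])
        with pytest.raises(ValueError, match="alternate"):
            compute_ac(filt, fid, FS)


def test_end_to_end_ac_tracks_ground_truth_rank(clean_subject):
    """Noise-free chain: beat count matches truth and AC rank-correlates
    with the true per-beat amplitude above 0.95."""
    from scipy.stats import spearmanr
    truth, cfg, ac = (clean_subject["truth"], clean_subject["config"],
                      clean_subject["ac"])
    assert len(ac.ac_values) == len(truth.true_ac_series)
    rho = spearmanr(ac.ac_values, truth.true_ac_series).statistic
    assert rho > 0.95
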