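"""Filtering, channel selection, resampling, epoching and baseline tests."""

import numpy as np
import pytest

from brainfog_eeg import preprocess, synth
from brainfog_eeg.containers import Recording
from brainfog_eeg.io import load_bundled_montage


def tone_recording(freqs_hz, fs=250.0, duration_s=20.0, n_channels=2):
    t = np.arange(int(fs * duration_s)) / fs
    wave = sum(np.sin(2 * np.pi * f * t) for f in np.atleast_1d(freqs_hz))
    data = np.tile(wave, (n_channels, 1))
    return Recording(data=data, fs=fs,
                     channel_names=[f"c{i}" for i in range(n_channels)])


def tone_amplitude(rec, freq_hz):
    """Amplitude of one tone read off the periodogram peak."""
    n = rec.n_samples
    spec = np.abs(np.fft.rfft(rec.data[0])) * 2 / n
    freqs = np.fft.rfftfreq(n, 1 / rec.fs)
    return spec[np.argmin(np.abs(freqs - freq_hz))]


class TestBandpass:
    def test_passband_preserved(self):
        rec = preprocess.bandpass_filter(tone_recording(10.0), 0.1, 30.0)
        assert 0.95 <= tone_amplitude(rec, 10.0) <= 1.05

    def test_stopband_attenuated(self):
        rec = preprocess.bandpass_filter(tone_recording(50.0), 0.1, 30.0)
        assert tone_amplitude(rec, 50.0) <= 0.1

    def test_dc_rejected(self):
        rec = tone_recording(10.0)
        rec = rec.copy_with(data=np.full_like(rec.data, 7.0))
        out = preprocess.highpass_filter(rec, 0.5)
        assert abs(out.data.mean()) < 1e-6

    def test_cutoff_at_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess.bandpass_filter(tone_recording(10.0), 0.1, 125.0)


class TestLineNoise:
    def test_notch_removes_line_keeps_signal(self):
        rec = tone_recording([10.0, 50.0])
        out = preprocess.remove_line_noise(rec, (45.0, 55.0))
        # 50 Hz power down >= 20 dB, 10 Hz power within 5%
        before, after = tone_amplitude(rec, 50.0), tone_amplitude(out, 50.0)
        assert 20 * np.log10(before / after) >= 20
        assert abs(tone_amplitude(out, 10.0) - tone_amplitude(rec, 10.0)) < 0.05

    def test_zero_signal_stays_zero(self):
        rec = tone_recording(10.0)
        rec = rec.copy_with(data=np.zeros_like(rec.data))
        out = preprocess.remove_line_noise(rec)
        assert np.allclose(out.data, 0.0)

    def test_broadband_power_outside_band_preserved(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((2, 50_000)), fs=250.0,
                        channel_names=["a", "b"])
        out = preprocess.remove_line_noise(rec)
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        outside = (freqs < 40) | (freqs > 60)
        p_in = np.mean(np.abs(np.fft.rfft(rec.data[0])[outside]) ** 2)
        p_out = np.mean(np.abs(np.fft.rfft(out.data[0])[outside]) ** 2)
        assert abs(p_out - p_in) / p_in < 0.05

    def test_inverted_band_raises(self):
        with pytest.raises(ValueError, match="inverted"):
            preprocess.remove_line_noise(tone_recording(10.0), (55.0, 45.0))


class TestScalpSelection:
    def test_bundled_montage_keeps_137(self):
        montage = load_bundled_montage()
        rec = Recording(np.zeros((256, 100)) + np.arange(100), fs=250.0,
                        channel_names=montage.names, montage=montage)
        out = preprocess.select_scalp_channels(rec, 0.5)
        assert out.n_channels == 137
        assert len(out.montage) == 137

    def test_infinite_radius_keeps_all(self):
        montage = load_bundled_montage()
        rec = Recording(np.ones((256, 10)), fs=250.0,
                        channel_names=montage.names, montage=montage)
        assert preprocess.select_scalp_channels(rec, np.inf).n_channels == 256

    def test_negative_radius_raises(self):
        montage = load_bundled_montage()
        rec = Recording(np.ones((256, 10)), fs=250.0,
                        channel_names=montage.names, montage=montage)
        with pytest.raises(ValueError, match="no channels"):
            preprocess.select_scalp_channels(rec, -1.0)

    def test_missing_montage_raises(self):
        rec = tone_recording(10.0)
        with pytest.raises(ValueError, match="montage"):
            preprocess.select_scalp_channels(rec)


class TestResample:
    def test_count_arithmetic_250_to_125(self):
        rec = Recording(np.random.default_rng(0).standard_normal((3, 1000)),
                        fs=250.0, channel_names=list("abc"))
        out = preprocess.resample(rec, 125.0)
        assert out.n_samples == 500 and out.fs == 125.0

    def test_below_nyquist_tone_preserved(self):
        rec = tone_recording(20.0)
        out = preprocess.resample(rec, 125.0)
        assert abs(tone_amplitude(out, 20.0) - 1.0) < 0.05

    def test_identity_and_upsampling_error(self):
        rec = tone_recording(10.0)
        assert preprocess.resample(rec, rec.fs) is rec
        with pytest.raises(ValueError, match="upsampling"):
            preprocess.resample(rec, 500.0)


class TestRereference:
    def test_zero_mean_and_idempotence(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.standard_normal((5, 200)), fs=100.0,
                        channel_names=list("abcde"))
        out = preprocess.rereference_to_mean(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        out2 = preprocess.rereference_to_mean(out)
        np.testing.assert_allclose(out2.data, out.data, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        v = np.sin(np.linspace(0, 5, 100))
        rec = Recording(np.stack([v, -v]), fs=100.0, channel_names=["p", "n"])
        out = preprocess.rereference_to_mean(rec)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-12)

    def test_single_channel_raises(self):
        rec = Recording(np.ones((1, 10)), fs=100.0, channel_names=["only"])
        with pytest.raises(ValueError):
            preprocess.rereference_to_mean(rec)


class TestArtifactRejection:
    def test_clean_noise_empty_mask(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.standard_normal((2, 1000)), fs=250.0,
                        channel_names=["a", "b"])
        _, mask = preprocess.reject_artifact_segments(rec, 500.0, 200.0)
        assert not mask.any()

    def test_square_pulse_masks_overlapping_windows(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 2000))
        data[1, 700:750] += 1000.0
        rec = Recording(data, fs=250.0, channel_names=["a", "b"])
        _, mask = preprocess.reject_artifact_segments(rec, 500.0, 200.0)
        assert not mask[0].any()
        # 50-sample windows at 200 ms = 50 samples: windows 14 (and 15 if the
        # pulse spans the boundary) on channel 1 only
        assert mask[1, 700:750].all()
        assert not mask[1, :650].any() and not mask[1, 800:].any()

    def test_zero_threshold_masks_everything(self):
        rec = Recording(np.random.default_rng(4).standard_normal((2, 500)),
                        fs=250.0, channel_names=["a", "b"])
        with pytest.raises(ValueError, match="entire recording"):
            preprocess.reject_artifact_segments(rec, 0.0, 100.0)

    def test_nonpositive_window_raises(self):
        rec = tone_recording(10.0)
        with pytest.raises(ValueError):
            preprocess.reject_artifact_segments(rec, 100.0, 0.0)


class TestEpoching:
    def _schedule(self, onsets_ms):
        import pandas as pd

        from brainfog_eeg.synth import TrialSchedule
        return TrialSchedule("digit_span", pd.DataFrame({
            "trial_index": range(len(onsets_ms)),
            "condition_code": ["len3"] * len(onsets_ms),
            "stimulus_payload": ["1-2-3"] * len(onsets_ms),
            "onset_ms": onsets_ms,
        }))

    def test_interior_onsets_all_kept(self):
        rec = tone_recording(5.0, duration_s=60.0)
        onsets = [3000.0 + 4000.0 * i for i in range(10)]
        ep = preprocess.epoch(rec, self._schedule(onsets))
        assert ep.n_trials == 10
        assert ep.n_times == round(1.2 * rec.fs)  # 300 samples at 250 Hz

    def test_boundary_onset_dropped(self):
        rec = tone_recording(5.0, duration_s=60.0)
        onsets = [50.0] + [3000.0 + 4000.0 * i for i in range(9)]
        ep = preprocess.epoch(rec, self._schedule(onsets))
        assert ep.n_trials == 9

    def test_impulse_alignment_at_t0(self):
        rec = tone_recording(5.0, duration_s=10.0)
        data = np.zeros_like(rec.data)
        onset_sample = int(round(4.0 * rec.fs))
        data[:, onset_sample] = 42.0
        rec = rec.copy_with(data=data)
        ep = preprocess.epoch(rec, self._schedule([4000.0]))
        t0_index = int(round(-ep.tmin_ms * ep.fs / 1000.0))
        assert ep.data[0, 0, t0_index] == 42.0
        assert abs(ep.times_ms[t0_index]) < 1e-9


class TestBaseline:
    def test_baseline_mean_zero_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        from brainfog_eeg.containers import Epochs
        data = rng.standard_normal((4, 3, 300))
        ep = Epochs(data=data, fs=250.0, tmin_ms=-200.0, tmax_ms=1000.0,
                    channel_names=list("abc"), condition_codes=["s"] * 4)
        out = preprocess.baseline_correct(ep)
        t = out.times_ms
        sel = (t >= -200) & (t < 0)
        assert np.abs(out.data[:, :, sel].mean(axis=2)).max() < 1e-9
        shifted = preprocess.baseline_correct(
            Epochs(data=data + 3.5, fs=250.0, tmin_ms=-200.0, tmax_ms=1000.0,
                   channel_names=list("abc"), condition_codes=["s"] * 4))
        np.testing.assert_allclose(shifted.data, out.data, atol=1e-9)

    def test_empty_window_raises(self):
        from brainfog_eeg.containers import Epochs
        ep = Epochs(data=np.zeros((1, 1, 300)), fs=250.0, tmin_ms=-200.0,
                    tmax_ms=1000.0, channel_names=["a"], condition_codes=["s"])
        with pytest.raises(ValueError):
            preprocess.baseline_correct(ep, (-100.0, -100.0))


class TestPipelines:
    def test_rerun_bit_identical(self):
        cs = synth.simulate_branching_cascades(8, 0.8, 20, seed=1)
        rec, _ = synth.render_resting_recording(
            cs, fs=250.0, duration_s=20.0, seed=2,
            channel_names=[f"c{i}" for i in range(8)])
        a = preprocess.run_classification_pipeline(rec, select_channels=False)
        b = preprocess.run_classification_pipeline(rec, select_channels=False)
        np.testing.assert_array_equal(a.data, b.data)

    def test_filtering_commutes_with_channel_selection(self):
        montage = load_bundled_montage()
        rng = np.random.default_rng(6)
        rec = Recording(rng.standard_normal((256, 2000)), fs=250.0,
                        channel_names=montage.names, montage=montage)
        filter_then_select = preprocess.select_scalp_channels(
            preprocess.highpass_filter(rec, 1.0), 0.5)
        select_then_filter = preprocess.highpass_filter(
            preprocess.select_scalp_channels(rec, 0.5), 1.0)
        assert filter_then_select.channel_names == select_then_filter.channel_names
        np.testing.assert_allclose(filter_then_select.data,
                                   select_then_filter.data, rtol=1e-6)

    def test_erp_pipeline_recovers_template_shape(self):
        """A clean repeated template embedded in low noise survives the ERP
        chain with its peak structure intact."""
        fs = 250.0
        template = synth.erp_template("digit_span", ["c0"], fs=fs)[0]
        n = int(fs * 120)
        rng = np.random.default_rng(7)
        data = rng.standard_normal((2, n)) * 0.5
        onsets = [5000.0 + 3000.0 * i for i in range(30)]
        for onset in onsets:
            s0 = int(round(onset * fs / 1000.0)) - 50
            data[:, s0:s0 + 300] += template
        rec = Recording(data, fs=fs, channel_names=["c0", "c1"])
        import pandas as pd

        from brainfog_eeg.synth import TrialSchedule
        sched = TrialSchedule("digit_span", pd.DataFrame({
            "trial_index": range(30), "condition_code": ["len3"] * 30,
            "stimulus_payload": ["x"] * 30, "onset_ms": onsets,
        }))
        ep = preprocess.run_erp_pipeline(rec, sched)
        avg = ep.average()[0]
        # positive working-memory peak near 300 ms survives
        t = ep.times_ms
        peak_t = t[np.argmax(avg)]
        assert 250 <= peak_t <= 350
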