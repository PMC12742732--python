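"""Filtering, ICA screening, pooling, segmentation, downsampling."""

import numpy as np
import pytest

from topobind.preprocessing import (
    ConditionSegment,
    DegenerateChannelError,
    FilterSpec,
    bandpass_notch,
    downsample,
    extract_segments,
    pool_channels,
    remove_muscle_components,
    screen_components,
)
from topobind.recording import EEGRecording
from topobind.synthetic import EEGSimConfig, generate_eeg, generate_session


def _sinusoid_rec(freq, fs=256.0, duration=60.0, n_ch=1):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return EEGRecording(np.tile(x, (n_ch, 1)), fs=fs,
                        channel_names=tuple(f"ch{i}" for i in range(n_ch)))


def _central_rms(x, frac=0.5):
    n = len(x)
    lo = int(n * (1 - frac) / 2)
    return float(np.sqrt(np.mean(x[lo:n - lo] ** 2)))


class TestBandpassNotch:
    def test_line_noise_attenuated(self):
        """A pure 50 Hz input loses at least 20 dB (spec asks <=0.1x RMS)."""
        rec = _sinusoid_rec(50.0)
        out = bandpass_notch(rec)
        assert _central_rms(out.data[0]) <= 0.1 * _central_rms(rec.data[0])

    def test_passband_preserved(self):
        """A 10 Hz sinusoid passes with RMS within 11%."""
        rec = _sinusoid_rec(10.0)
        out = bandpass_notch(rec)
        ratio = _central_rms(out.data[0]) / _central_rms(rec.data[0])
        assert abs(ratio - 1.0) < 0.11

    @pytest.mark.parametrize("freq", [2.0, 20.0, 40.0])
    def test_passband_flatness(self, freq):
        rec = _sinusoid_rec(freq)
        out = bandpass_notch(rec)
        ratio = _central_rms(out.data[0]) / _central_rms(rec.data[0])
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)  # within +-1 dB

    def test_zeros_in_zeros_out(self):
        rec = EEGRecording(np.zeros((2, 2560)), fs=256.0,
                           channel_names=("a", "b"))
        out = bandpass_notch(rec)
        assert np.allclose(out.data, 0.0)

    def test_linearity(self, rng):
        a = rng.standard_normal(2560)
        b = rng.standard_normal(2560)
        mk = lambda x: EEGRecording(x[None, :], fs=256.0, channel_names=("c",))
        fa = bandpass_notch(mk(a)).data[0]
        fb = bandpass_notch(mk(b)).data[0]
        fab = bandpass_notch(mk(a + b)).data[0]
        assert np.allclose(fab, fa + fb, atol=1e-9)

    def test_filter_pool_commute(self):
        """Filtering and pooling are both linear, so their order is free."""
        rec = generate_eeg(EEGSimConfig(duration_s=10.0, seed=2))
        a = pool_channels(bandpass_notch(rec))
        b = bandpass_notch(pool_channels(rec))
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_fs_too_low_rejected(self):
        rec = _sinusoid_rec(10.0, fs=64.0)
        with pytest.raises(ValueError):
            bandpass_notch(rec, FilterSpec(lowpass_hz=45.0, notch_hz=None))


class TestScreenComponents:
    def test_injected_artifact_flagged(self):
        """The focal broadband component is found; its channel is the one
        carrying the injected mixing weight."""
        cfg = EEGSimConfig(duration_s=30.0, seed=6, line_noise_amp=0.0,
                           muscle_artifact=True, muscle_amp=10.0)
        rec = bandpass_notch(generate_eeg(cfg), FilterSpec(notch_hz=None))
        reports = screen_components(rec, seed=0)
        flagged = [r for r in reports if r.flagged]
        assert len(flagged) == 1

    def test_clean_recording_not_flagged(self):
        cfg = EEGSimConfig(duration_s=30.0, seed=6, line_noise_amp=0.0,
                           band_weights={"alpha": 1.0})
        rec = bandpass_notch(generate_eeg(cfg), FilterSpec(notch_hz=None))
        reports = screen_components(rec, seed=0)
        assert not any(r.flagged for r in reports)

    @pytest.mark.parametrize("seed", range(10))
    def test_flagging_over_seeds(self, seed):
        """Amplitude >= 5x background flags; amplitude 0 never flags."""
        noisy = EEGSimConfig(duration_s=20.0, seed=seed, line_noise_amp=0.0,
                             muscle_artifact=True, muscle_amp=10.0)
        clean = EEGSimConfig(duration_s=20.0, seed=seed, line_noise_amp=0.0)
        spec = FilterSpec(notch_hz=None)
        rec = bandpass_notch(generate_eeg(noisy), spec)
        assert any(r.flagged for r in screen_components(rec, seed=0))
        rec = bandpass_notch(generate_eeg(clean), spec)
        assert not any(r.flagged for r in screen_components(rec, seed=0))

    def test_removal_reduces_artifact_channel_power(self):
        cfg = EEGSimConfig(duration_s=30.0, seed=1, line_noise_amp=0.0,
                           muscle_artifact=True, muscle_amp=10.0)
        rec = bandpass_notch(generate_eeg(cfg), FilterSpec(notch_hz=None))
        cleaned, reports = remove_muscle_components(rec, seed=0)
        assert any(r.flagged for r in reports)
        assert cleaned.data[-1].var() < 0.5 * rec.data[-1].var()

    def test_no_flag_means_identity(self):
        cfg = EEGSimConfig(duration_s=20.0, seed=2, line_noise_amp=0.0)
        rec = bandpass_notch(generate_eeg(cfg), FilterSpec(notch_hz=None))
        cleaned, reports = remove_muscle_components(rec, seed=0)
        assert not any(r.flagged for r in reports)
        assert np.allclose(cleaned.data, rec.data)

    def test_rank_deficient_names_channel(self):
        x = np.random.default_rng(0).standard_normal((3, 2000))
        data = np.vstack([x, x[2]])  # TP10 duplicates AF8
        rec = EEGRecording(data, fs=256.0)
        with pytest.raises(DegenerateChannelError):
            screen_components(rec, seed=0)

    def test_constant_channel_named(self):
        data = np.random.default_rng(0).standard_normal((4, 2000))
        data[1] = 3.14
        rec = EEGRecording(data, fs=256.0)
        with pytest.raises(DegenerateChannelError, match="AF7"):
            screen_components(rec, seed=0)


class TestPooling:
    def test_arithmetic(self):
        data = np.array([[1.0, 2.0], [0.0, 0.0], [2.0, 2.0], [3.0, 4.0]])
        rec = EEGRecording(data, fs=10.0,
                           channel_names=("TP9", "AF7", "AF8", "TP10"))
        out = pool_channels(rec)
        assert out.channel_names == ("TP", "AF")
        assert np.allclose(out.channel("TP"), [2.0, 3.0])
        assert np.allclose(out.channel("AF"), [1.0, 1.0])

    def test_idempotent_on_equal_pairs(self):
        data = np.random.default_rng(1).standard_normal((4, 100))
        data[3] = data[0]  # TP10 = TP9
        rec = EEGRecording(data, fs=10.0,
                           channel_names=("TP9", "AF7", "AF8", "TP10"))
        assert np.allclose(pool_channels(rec).channel("TP"), data[0])

    def test_missing_channel_named(self):
        rec = EEGRecording(np.zeros((3, 10)), fs=10.0,
                           channel_names=("TP9", "AF7", "AF8"))
        with pytest.raises(ValueError, match="TP10"):
            pool_channels(rec)


class TestSegments:
    def test_scr_last_25s_of_each_question(self):
        rec = generate_session("SCR", EEGSimConfig(seed=0), n_questions=8)
        rec = pool_channels(rec)
        segs = extract_segments(rec, "SCR")
        assert len(segs) == 16  # 8 questions x 2 pooled channels
        fs = rec.fs
        seg = [s for s in segs if s.channel == "TP" and s.question_index == 1][0]
        expected = rec.channel("TP")[int(5 * fs):int(30 * fs)]
        assert np.array_equal(seg.samples, expected)
        assert all(len(s.samples) == int(25 * fs) for s in segs)

    def test_ctr_central_window(self):
        rec = generate_session("CTR", EEGSimConfig(seed=0), ctr_duration_s=240.0)
        rec = pool_channels(rec)
        segs = extract_segments(rec, "CTR")
        assert len(segs) == 2
        start = int(107.5 * 256)
        assert start == 27520
        expected = rec.channel("TP")[start:start + 6400]
        tp = [s for s in segs if s.channel == "TP"][0]
        assert np.array_equal(tp.samples, expected)

    def test_short_question_rejected(self):
        rec = generate_session("SCR", EEGSimConfig(seed=0), n_questions=2,
                               question_s=20.0)
        with pytest.raises(ValueError, match="shorter"):
            extract_segments(rec, "SCR")

    def test_missing_markers_rejected(self):
        rec = generate_eeg(EEGSimConfig(duration_s=30.0, seed=0))
        with pytest.raises(ValueError):
            extract_segments(rec, "SCR")
        with pytest.raises(ValueError):
            extract_segments(rec, "CTR")


class TestDownsample:
    def _seg(self, x, fs=256.0):
        return ConditionSegment("CTR", "TP", None, np.asarray(x, float), fs)

    def test_factor_4_counts(self):
        seg = self._seg(np.random.default_rng(0).standard_normal(6400))
        out = downsample(seg, 4)
        assert len(out.samples) == 1600
        assert out.fs == 64.0

    def test_factor_1_identity(self):
        seg = self._seg(np.arange(100.0))
        out = downsample(seg, 1)
        assert np.array_equal(out.samples, seg.samples)

    def test_passband_tone_survives(self):
        t = np.arange(6400) / 256.0
        seg = self._seg(np.sin(2 * np.pi * 10 * t))
        out = downsample(seg, 4)
        rms_in = np.sqrt(np.mean(seg.samples ** 2))
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            downsample(self._seg(np.zeros(100)), 0)
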