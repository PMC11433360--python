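"""Unit tests for the acoustic front end."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pdnet.features import FeatureSeries, ValidationError
from pdnet.speech import (
    SpeechConfig,
    Waveform,
    detect_voice_activity,
    frame_signal,
    load_audio,
    loudness_series,
    nasality_series,
    phonatory_frequency_range,
    pitch_series,
    save_audio,
    tremor_series,
    voice_break_features,
    wiener_denoise,
    zero_crossing_series,
)

RATE = 44100


def _tone(freq, dur=1.0, rate=RATE, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


class TestWaveformIO:
    def test_wav_round_trip_mono(self, tmp_path):
        w = _tone(220)
        path = tmp_path / "tone.wav"
        save_audio(path, w)
        back = load_audio(path)
        assert back.rate == RATE
        assert back.samples.size == RATE
        assert np.allclose(back.samples, w.samples, atol=1e-6)

    def test_stereo_downmix_channel_mean(self, tmp_path):
        from scipy.io import wavfile

        left = np.linspace(-0.5, 0.5, 1000).astype(np.float32)
        right = np.zeros(1000, dtype=np.float32)
        wavfile.write(tmp_path / "st.wav", 8000, np.stack([left, right], axis=1))
        w = load_audio(tmp_path / "st.wav")
        assert w.samples.size == 1000
        assert np.allclose(w.samples, left / 2, atol=1e-6)

    def test_empty_audio_rejected(self, tmp_path):
        from scipy.io import wavfile

        wavfile.write(tmp_path / "empty.wav", 8000, np.zeros(0, dtype=np.float32))
        with pytest.raises(ValidationError):
            load_audio(tmp_path / "empty.wav")

    def test_zero_length_waveform_rejected(self):
        with pytest.raises(ValidationError):
            Waveform(np.empty(0), RATE)


class TestFraming:
    def test_one_second_reference_counts(self):
        fs = frame_signal(_tone(220))
        assert fs.win_samples == 2205
        assert fs.hop_samples == 1102
        assert fs.n_frames == 39

    def test_exactly_one_window(self):
        w = Waveform(np.ones(2205), RATE)
        assert frame_signal(w).n_frames == 1

    def test_ten_windows_gives_nineteen_frames(self):
        # even window so that 50% overlap is exact
        w = Waveform(np.ones(10 * 1000), 20000)  # win=1000, hop=500
        assert frame_signal(w).n_frames == 19

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            frame_signal(Waveform(np.ones(100), RATE))

    @given(n=st.integers(min_value=2205, max_value=30000))
    def test_count_matches_window_placement_enumeration(self, n):
        fs = frame_signal(Waveform(np.zeros(n), RATE))
        brute = sum(
            1 for start in range(0, n, fs.hop_samples) if start + fs.win_samples <= n
        )
        assert fs.n_frames == brute


class TestLoudness:
    def test_constant_frame(self):
        w = Waveform(np.full(4410, 0.3), RATE)
        sq, tke = loudness_series(frame_signal(w))
        assert np.allclose(sq.values, 0.09)
        assert np.allclose(tke.values, 0.0, atol=1e-15)

    @pytest.mark.parametrize("omega", [0.05, 0.1, 0.2, 0.35, 0.5])
    def test_tke_of_cosine_matches_closed_form(self, omega):
        n = np.arange(4410)
        w = Waveform(np.cos(omega * n), RATE)
        _, tke = loudness_series(frame_signal(w))
        expected = np.sin(omega) ** 2
        assert np.all(np.abs(tke.values - expected) / expected < 0.05)

    def test_zero_frame(self):
        sq, tke = loudness_series(frame_signal(Waveform(np.zeros(4410), RATE)))
        assert np.all(sq.values == 0) and np.all(tke.values == 0)


class TestZeroCrossing:
    def test_alternating_signal_rate_one(self):
        from pdnet.speech import FrameSeries

        frames = np.tile(np.array([1.0, -1.0]), 50)[None, :]
        fs = FrameSeries(frames, 100, 50, RATE)
        assert zero_crossing_series(fs).values[0] == 1.0

    def test_constant_positive_zero(self):
        w = Waveform(np.ones(4410), RATE)
        assert np.all(zero_crossing_series(frame_signal(w)).values == 0)

    def test_sine_rate_two_f0_over_rate(self):
        # crossing counts quantize by +-1 per frame, so assert on the median
        zcr = zero_crossing_series(frame_signal(_tone(100)))
        expected = 2 * 100 / RATE
        assert abs(np.median(zcr.values) - expected) / expected < 0.05


class TestVAD:
    def test_silence_has_no_segments(self):
        seg = detect_voice_activity(Waveform(np.zeros(RATE), RATE))
        assert seg.segments == []

    def test_tone_between_silences_found_within_one_frame(self):
        x = np.concatenate(
            [np.zeros(int(0.5 * RATE)), _tone(220).samples, np.zeros(int(0.5 * RATE))]
        )
        seg = detect_voice_activity(Waveform(x, RATE))
        assert len(seg.segments) == 1
        s, e = seg.segments[0]
        frame = int(0.025 * RATE)
        assert abs(s - int(0.5 * RATE)) <= frame
        assert abs(e - int(1.5 * RATE)) <= frame

    def test_constant_amplitude_single_full_segment(self):
        seg = detect_voice_activity(_tone(220))
        assert len(seg.segments) == 1
        assert seg.segments[0][0] == 0
        assert seg.segments[0][1] == RATE

    @pytest.mark.parametrize("scale", [1e-4, 0.1, 3.0, 1e4])
    def test_amplitude_scale_invariance(self, scale):
        x = np.concatenate(
            [np.zeros(int(0.3 * RATE)), _tone(220, 0.7).samples, np.zeros(int(0.3 * RATE))]
        )
        ref = detect_voice_activity(Waveform(x, RATE)).segments
        scaled = detect_voice_activity(Waveform(scale * x, RATE)).segments
        assert ref == scaled


class TestWiener:
    def test_zero_noise_psd_is_identity(self, tone_waveform):
        win = 2206  # analysis window rounded up to even
        out = wiener_denoise(tone_waveform, noise_profile=np.zeros(win // 2 + 1))
        rms = np.sqrt(np.mean((out.samples - tone_waveform.samples) ** 2))
        assert rms < 1e-6

    def test_snr_gain_on_sine_in_white_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(2 * RATE) / RATE
        clean = np.sin(2 * np.pi * 440 * t)
        noise = rng.normal(0, np.sqrt(0.5), t.size)  # 0 dB SNR
        out = wiener_denoise(
            Waveform(clean + noise, RATE), noise_profile=Waveform(noise, RATE)
        )
        def snr(x):
            return 10 * np.log10(np.mean(clean**2) / np.mean((x - clean) ** 2))
        assert snr(out.samples) - snr(clean + noise) >= 6.0

    def test_noise_with_own_psd_mostly_removed(self):
        rng = np.random.default_rng(1)
        noise = Waveform(rng.normal(0, 1, 2 * RATE), RATE)
        out = wiener_denoise(noise, noise_profile=noise)
        assert np.mean(out.samples**2) <= 0.10 * np.mean(noise.samples**2)

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            wiener_denoise(Waveform(np.ones(100), RATE))


class TestPitch:
    def test_sine_220_recovered(self, tone_waveform):
        p = pitch_series(frame_signal(tone_waveform))
        assert p.valid_mask.all()
        assert np.all(np.abs(p.values - 220) < 2)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(2)
        p = pitch_series(frame_signal(Waveform(rng.normal(0, 1, RATE), RATE)))
        assert (~p.valid_mask).mean() >= 0.9

    def test_silence_all_unvoiced(self):
        p = pitch_series(frame_signal(Waveform(np.zeros(RATE), RATE)))
        assert not p.valid_mask.any()

    def test_fmin_fmax_order_enforced(self, tone_waveform):
        with pytest.raises(ValidationError):
            pitch_series(frame_signal(tone_waveform), fmin=300, fmax=100)

    @pytest.mark.parametrize("f0", [80, 150, 220, 350])
    def test_clean_harmonic_within_two_percent(self, f0):
        from scipy import signal as sps
        from pdnet.synth import _resonator_sos

        exc = np.zeros(RATE)
        exc[np.arange(0, RATE, RATE / f0).astype(int)] = 1.0
        v = sps.sosfilt(_resonator_sos(500, 120, RATE)[None, :], exc)
        p = pitch_series(frame_signal(Waveform(v, RATE)))
        assert abs(np.nanmedian(p.values) - f0) / f0 < 0.02


class TestPhonatoryRange:
    def test_constant_pitch_zero_range(self):
        p = FeatureSeries("pitch", np.full(100, 200.0), "Hz")
        total, rolling = phonatory_frequency_range(p)
        assert total == 0
        assert np.all(rolling.values == 0)

    def test_linear_sweep_matches_percentile_arithmetic(self):
        p = FeatureSeries("pitch", np.linspace(180, 260, 400), "Hz")
        total, _ = phonatory_frequency_range(p)
        assert abs(total - 72.0) / 72.0 < 0.10

    def test_single_voiced_frame(self):
        p = FeatureSeries("pitch", np.array([150.0]), "Hz")
        total, rolling = phonatory_frequency_range(p)
        assert total == 0 and rolling.values[0] == 0


class TestTremor:
    def test_periodic_pulse_train_zero_perturbation(self):
        exc = np.zeros(2 * RATE)
        exc[np.arange(0, exc.size, 441)] = 1.0  # exactly 100 Hz
        w = Waveform(exc, RATE)
        seg = detect_voice_activity(w, energy_threshold_rel=0.001)
        jit, shim = tremor_series(w, seg)
        assert np.all(jit.values < 0.2)
        assert np.all(shim.values < 0.2)

    def test_alternating_periods_give_twenty_percent_local_jitter(self):
        # periods alternating 9 ms / 11 ms: mean |dT| = 2, mean T = 10 -> 20%
        marks = np.cumsum(np.tile([int(0.009 * RATE), int(0.011 * RATE)], 60))
        exc = np.zeros(marks[-1] + 100)
        exc[marks] = 1.0
        w = Waveform(exc, RATE)
        seg = detect_voice_activity(w, energy_threshold_rel=0.001)
        jit, _ = tremor_series(w, seg)
        assert jit.values.size > 0
        assert np.all(np.abs(jit.values - 20.0) < 1.0)


class TestNasality:
    def test_tone_in_nasal_band_ratio_near_one(self):
        nas = nasality_series(frame_signal(_tone(300)))
        assert np.all(nas.values > 0.95)

    def test_tone_outside_band_ratio_near_zero(self):
        nas = nasality_series(frame_signal(_tone(2000)))
        assert np.all(nas.values < 0.05)

    def test_zero_frame_reports_zero(self):
        nas = nasality_series(frame_signal(Waveform(np.zeros(RATE), RATE)))
        assert np.all(nas.values == 0)


class TestVoiceBreaks:
    def test_sustained_tone_two_transitions(self, tone_waveform):
        seg = detect_voice_activity(tone_waveform)
        trans, series = voice_break_features(tone_waveform, seg)
        assert len(trans.records) == 2
        types = [r["transition_type"] for r in trans.records]
        assert types == ["silence_to_speech", "speech_to_silence"]

    def test_tone_gap_tone_pitch_near_tone_frequency(self, tone_gap_tone):
        seg = detect_voice_activity(tone_gap_tone)
        trans, series = voice_break_features(tone_gap_tone, seg)
        assert len(trans.records) == 4  # 2 edges + 2 internal
        voiced_pitch = np.concatenate(
            [r["pitch_hz"][np.isfinite(r["pitch_hz"])] for r in trans.records]
        )
        assert np.all(np.abs(voiced_pitch - 180) < 5)

    def test_hnr_separates_tone_from_noise(self):
        from pdnet.speech import _frame_hnr

        cfg = SpeechConfig()
        tone = _tone(180, 0.05).samples
        rng = np.random.default_rng(3)
        assert _frame_hnr(tone, RATE, cfg) >= 30
        assert _frame_hnr(rng.normal(0, 1, tone.size), RATE, cfg) <= 5

    def test_no_transitions_flagged_empty(self):
        from pdnet.speech import VoicedSegmentation

        w = _tone(200)
        seg = VoicedSegmentation([], RATE, RATE)
        trans, series = voice_break_features(w, seg)
        assert trans.records == [] and len(series) == 0


class TestArticulation:
    def test_resonators_recovered(self):
        from scipy import signal as sps
        from pdnet.synth import _resonator_sos

        exc = np.zeros(RATE)
        exc[np.arange(0, RATE, RATE // 120)] = 1.0
        v = sps.sosfilt(_resonator_sos(500, 120, RATE)[None, :], exc)
        v = sps.sosfilt(_resonator_sos(1500, 150, RATE)[None, :], v)
        from pdnet.speech import articulation_series

        f1, f2 = articulation_series(frame_signal(Waveform(v, RATE)))
        assert abs(np.nanmedian(f1.values) - 500) < 50
        assert abs(np.nanmedian(f2.values) - 1500) < 75

    def test_white_noise_mostly_skipped(self):
        from pdnet.speech import articulation_series

        rng = np.random.default_rng(4)
        f1, f2 = articulation_series(frame_signal(Waveform(rng.normal(0, 1, RATE), RATE)))
        assert (~f2.valid_mask).mean() >= 0.8

    def test_silence_all_skipped(self):
        from pdnet.speech import articulation_series

        f1, f2 = articulation_series(frame_signal(Waveform(np.zeros(RATE), RATE)))
        assert not f1.valid_mask.any() and not f2.valid_mask.any()
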