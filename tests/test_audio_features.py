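"""Acoustic/prosodic extraction against independent DSP oracles."""

import numpy as np
import pytest
import scipy.fft
import scipy.linalg
from hypothesis import given, settings, strategies as st

from lonespeech.audio_features import (
    AudioResponse,
    Segmentation,
    compute_mfcc,
    delta_coefficients,
    detect_voice_activity,
    dmfcc_variances,
    estimate_f0_track,
    estimate_formants,
    hz_to_mel,
    levinson_durbin,
    mel_filterbank,
    mel_to_hz,
    pause_duration,
    pitch_variation,
    summarize_response_acoustics,
)

from conftest import RATE, make_audio, pulse_train, sine, vowel


# ---------------------------------------------------------------------------
# voice activity detection


class TestVAD:
    def test_silence_voice_silence_boundaries(self):
        x = np.concatenate([np.zeros(RATE), sine(220, 1.0), np.zeros(RATE)])
        seg = detect_voice_activity(make_audio(x), frame_s=0.025,
                                    energy_floor_db=-30, min_seg_s=0.1)
        labels = [lab for _, _, lab in seg.intervals]
        assert labels == ["silence", "voice", "silence"]
        (_, b1, _), (a2, b2, _), _ = seg.intervals
        assert abs(b1 - 1.0) <= 0.025 + 1e-9
        assert abs(b2 - 2.0) <= 0.025 + 1e-9

    def test_pure_tone_single_voice_interval(self):
        seg = detect_voice_activity(make_audio(sine(220, 3.0)))
        assert seg.intervals == ((0.0, 3.0, "voice"),)

    def test_short_bursts_merged_by_min_segment_rule(self):
        # alternating 50 ms bursts/gaps; every run < 0.2 s gets absorbed
        burst = sine(220, 0.05)
        gap = np.zeros(int(0.05 * RATE))
        x = np.concatenate([burst, gap] * 20)
        seg = detect_voice_activity(make_audio(x), min_seg_s=0.2)
        assert [lab for _, _, lab in seg.intervals] == ["voice"]

    def test_all_zero_audio_raises(self):
        with pytest.raises(ValueError, match="no signal"):
            detect_voice_activity(make_audio(np.zeros(RATE)))

    def test_frame_longer_than_audio_raises(self):
        with pytest.raises(ValueError):
            detect_voice_activity(make_audio(sine(220, 0.01)), frame_s=0.5,
                                  min_seg_s=0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_segmentation_tiles_duration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(RATE, 3 * RATE)
        x = rng.standard_normal(n) * (rng.random(n) > 0.5)
        if not np.any(x):
            x[0] = 1.0
        seg = detect_voice_activity(make_audio(x))
        assert seg.intervals[0][0] == 0.0
        assert abs(seg.duration - n / RATE) < 1e-9
        for (a, b, lab), (a2, b2, lab2) in zip(seg.intervals, seg.intervals[1:]):
            assert b == a2 and lab != lab2


# ---------------------------------------------------------------------------
# MFCC chain


class TestMFCC:
    def test_white_noise_gives_finite_coefficients(self, voiced_tone):
        rng = np.random.default_rng(0)
        audio = make_audio(0.5 * rng.standard_normal(RATE))
        seg = detect_voice_activity(audio)
        mfcc = compute_mfcc(audio, seg)
        assert mfcc.shape[1] == 14
        assert np.all(np.isfinite(mfcc))

    def test_dct_stage_matches_direct_summation(self):
        # orthonormal DCT-II on a hand-specified 8-bin log-energy vector
        v = np.array([1.0, -0.5, 2.0, 0.25, -1.0, 3.0, 0.0, 1.5])
        N = v.size
        direct = np.empty(N)
        for k in range(N):
            s = sum(v[n] * np.cos(np.pi * k * (2 * n + 1) / (2 * N)) for n in range(N))
            scale = np.sqrt(1.0 / N) if k == 0 else np.sqrt(2.0 / N)
            direct[k] = scale * s
        assert np.allclose(scipy.fft.dct(v, type=2, norm="ortho"), direct, atol=1e-10)

    def test_tone_at_filter_center_concentrates_energy(self):
        n_mel, n_fft = 26, 512
        fb = mel_filterbank(n_mel, n_fft, RATE)
        mel_pts = np.linspace(hz_to_mel(0), hz_to_mel(RATE / 2), n_mel + 2)
        k = 10
        center_hz = float(mel_to_hz(mel_pts[k + 1]))
        freqs = np.arange(n_fft // 2 + 1) * RATE / n_fft
        spectrum = np.exp(-0.5 * ((freqs - center_hz) / 30.0) ** 2)
        energies = fb @ spectrum
        assert int(np.argmax(energies)) == k

    def test_full_pipeline_matches_per_stage_oracle(self, voiced_tone):
        """DFT + hand-built triangular filters + direct DCT-II, per frame."""
        audio, seg = voiced_tone
        n_fft, n_mel = 512, 26
        mfcc = compute_mfcc(audio, seg, n_fft=n_fft, n_mel=n_mel)
        frame_len = int(0.025 * RATE)
        hop = int(0.010 * RATE)
        window = np.hanning(frame_len)
        fb = mel_filterbank(n_mel, n_fft, RATE)
        rng = np.random.default_rng(1)
        for i in rng.choice(mfcc.shape[0], size=10, replace=False):
            frame = audio.samples[i * hop : i * hop + frame_len] * window
            spec = np.abs(np.fft.fft(frame, n_fft)[: n_fft // 2 + 1]) ** 2
            log_e = np.log(np.maximum(fb @ spec, 1e-12))
            N = n_mel
            direct = np.empty(N)
            for k in range(N):
                s = sum(log_e[n] * np.cos(np.pi * k * (2 * n + 1) / (2 * N))
                        for n in range(N))
                direct[k] = (np.sqrt(1.0 / N) if k == 0 else np.sqrt(2.0 / N)) * s
            assert np.allclose(mfcc[i], direct[1:15], atol=1e-8)

    def test_no_voiced_frames_raises(self):
        x = np.concatenate([np.zeros(RATE), sine(220, 0.3), np.zeros(RATE)])
        audio = make_audio(x)
        seg = Segmentation(((0.0, audio.duration, "silence"),))
        with pytest.raises(ValueError, match="no voiced"):
            compute_mfcc(audio, seg)


class TestDelta:
    def test_constant_track_gives_zero(self):
        mfcc = np.ones((10, 3)) * 4.2
        assert np.allclose(delta_coefficients(mfcc), 0.0)

    def test_linear_ramp_gives_slope(self):
        a = 0.7
        track = a * np.arange(20)[:, None] * np.ones((1, 2))
        delta = delta_coefficients(track, half_window=2)
        assert np.allclose(delta[2:-2], a)

    def test_hand_computed_spike(self):
        delta = delta_coefficients(np.array([0.0, 1.0, 0.0]), half_window=1)
        assert np.allclose(delta.ravel(), [0.5, 0.0, -0.5])

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            delta_coefficients(np.ones((3, 2)), half_window=2)


class TestDmfccVariances:
    def test_constant_delta_gives_zeros(self):
        assert np.allclose(dmfcc_variances(np.ones((5, 14))), 0.0)

    def test_two_frame_population_variance(self):
        v = dmfcc_variances(np.array([[1.0], [-1.0]]))
        assert v[0] == pytest.approx(1.0)

    def test_invariant_to_frame_permutation(self):
        rng = np.random.default_rng(3)
        delta = rng.standard_normal((40, 14))
        shuffled = delta[rng.permutation(40)]
        assert np.allclose(dmfcc_variances(delta), dmfcc_variances(shuffled))


# ---------------------------------------------------------------------------
# F0 and prosody


class TestF0:
    def test_pulse_train_recovery(self, voiced_tone):
        for f0_true in (80, 150, 200, 350):
            audio = make_audio(pulse_train(f0_true, 1.0))
            seg = Segmentation(((0.0, audio.duration, "voice"),))
            f0, voiced = estimate_f0_track(audio, seg)
            est = np.median(f0[voiced])
            assert abs(est - RATE / round(RATE / f0_true)) < 2.0

    def test_sine_100hz(self):
        audio = make_audio(sine(100, 2.0))
        seg = detect_voice_activity(audio)
        f0, voiced = estimate_f0_track(audio, seg)
        assert abs(np.median(f0[voiced]) - 100.0) < 1.0

    def test_white_noise_flagged_unvoiced(self):
        rng = np.random.default_rng(42)
        audio = make_audio(0.5 * rng.standard_normal(2 * RATE))
        seg = detect_voice_activity(audio)
        _, voiced = estimate_f0_track(audio, seg)
        assert voiced.mean() < 0.2

    def test_empty_band_raises(self, voiced_tone):
        audio, seg = voiced_tone
        with pytest.raises(ValueError):
            estimate_f0_track(audio, seg, f0_min=400, f0_max=60)


class TestProsody:
    def test_constant_track_zero_variation(self):
        track = (np.full(10, 150.0), np.ones(10, dtype=bool))
        assert pitch_variation(track) == 0.0

    def test_two_value_track(self):
        track = (np.array([100.0, 200.0]), np.array([True, True]))
        assert pitch_variation(track) == pytest.approx(50.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        f0 = 150 + 20 * rng.standard_normal(50)
        v = np.ones(50, dtype=bool)
        assert pitch_variation((f0, v)) == pytest.approx(pitch_variation((f0 + 37, v)))

    def test_too_few_voiced_raises(self):
        with pytest.raises(ValueError):
            pitch_variation((np.array([100.0, 120.0]), np.array([True, False])))

    def test_pause_sums_internal_silences(self):
        seg = Segmentation((
            (0.0, 1.0, "voice"), (1.0, 1.4, "silence"), (1.4, 2.0, "voice"),
            (2.0, 2.6, "silence"), (2.6, 3.0, "voice"),
        ))
        assert pause_duration(seg) == pytest.approx(1.0)

    def test_voice_only_zero_pause(self):
        assert pause_duration(Segmentation(((0.0, 2.0, "voice"),))) == 0.0

    def test_leading_silence_excluded(self):
        seg = Segmentation(((0.0, 2.0, "silence"), (2.0, 3.0, "voice")))
        assert pause_duration(seg) == 0.0

    def test_no_voice_raises(self):
        with pytest.raises(ValueError):
            pause_duration(Segmentation(((0.0, 1.0, "silence"),)))


# ---------------------------------------------------------------------------
# formants


class TestFormants:
    def test_known_resonators_500_1500(self, vowel_audio):
        audio, seg = vowel_audio
        f1, f2 = estimate_formants(audio, seg)
        assert abs(f1 - 500) <= 50
        assert abs(f2 - 1500) <= 75

    def test_known_resonators_300_2300(self):
        audio = make_audio(vowel(300, 2300, 2.0))
        seg = detect_voice_activity(audio)
        f1, f2 = estimate_formants(audio, seg)
        assert abs(f1 - 300) <= 0.05 * 300 + 15
        assert abs(f2 - 2300) <= 0.05 * 2300

    def test_recovery_grid_within_5pct(self):
        """Median relative error < 5% across an (F1, F2) grid."""
        errs = []
        for f1_true in (300, 550, 800):
            for f2_true in (900, 1600, 2400):
                if f2_true - f1_true < 300:
                    continue
                audio = make_audio(vowel(f1_true, f2_true, 1.0))
                seg = detect_voice_activity(audio)
                f1, f2 = estimate_formants(audio, seg)
                errs.append(abs(f1 - f1_true) / f1_true)
                errs.append(abs(f2 - f2_true) / f2_true)
        assert np.median(errs) < 0.05

    def test_levinson_matches_toeplitz_solve(self):
        rng = np.random.default_rng(7)
        frame = rng.standard_normal(480)
        order = 18
        r = np.correlate(frame, frame, mode="full")[frame.size - 1 :][: order + 1]
        a_ld = levinson_durbin(r, order)
        a_direct = scipy.linalg.solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
        assert np.allclose(a_ld, a_direct, atol=1e-8)

    def test_unresolved_raises(self):
        rng = np.random.default_rng(0)
        audio = make_audio(0.3 * rng.standard_normal(RATE // 2))
        seg = Segmentation(((0.0, audio.duration, "silence"),))
        with pytest.raises(ValueError, match="no voiced"):
            estimate_formants(audio, seg)


# ---------------------------------------------------------------------------
# composition


class TestSummarize:
    def test_sixteen_finite_values(self, vowel_audio):
        audio, seg = vowel_audio
        summary = summarize_response_acoustics(audio, seg)
        vals = [summary.f1_hz, summary.f2_hz, *summary.dmfcc_var]
        assert len(vals) == 16
        assert np.all(np.isfinite(vals))

    def test_deterministic(self, vowel_audio):
        audio, seg = vowel_audio
        s1 = summarize_response_acoustics(audio, seg)
        s2 = summarize_response_acoustics(audio, seg)
        assert s1.f1_hz == s2.f1_hz and s1.f2_hz == s2.f2_hz
        assert np.array_equal(s1.dmfcc_var, s2.dmfcc_var)

    def test_formants_stable_under_amplitude_scaling(self, vowel_audio):
        audio, seg = vowel_audio
        scaled = AudioResponse(samples=0.5 * audio.samples, rate=audio.rate,
                               question_id=audio.question_id)
        s1 = summarize_response_acoustics(audio, seg)
        s2 = summarize_response_acoustics(scaled, seg)
        assert abs(s1.f1_hz - s2.f1_hz) < 20
        assert abs(s1.f2_hz - s2.f2_hz) < 30

    def test_variance_invariant_to_time_reversal_of_frames(self, voiced_tone):
        audio, seg = voiced_tone
        mfcc = compute_mfcc(audio, seg)
        d_fwd = delta_coefficients(mfcc)
        d_rev = delta_coefficients(mfcc[::-1])
        assert np.allclose(dmfcc_variances(d_fwd), dmfcc_variances(d_rev), rtol=1e-10)
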