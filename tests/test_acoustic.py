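import numpy as np
import pytest

from speechscreen.acoustic import (
    AcousticConfig,
    PulseSequence,
    UndefinedFeatureError,
    detect_pulses,
    estimate_pitch,
    extract_acoustic,
    f0_mid7,
    formant_medians,
    jitter_local,
    mfcc_frames,
    mfcc_stats,
    shimmer_local,
)
from speechscreen.audio import AudioSignal, SegmentSet
from speechscreen.synth import VoiceSpec, gen_voice, synthesize_voice


def impulse_train(f0_hz: float, duration_s: float = 1.0, fs: float = 16000.0) -> AudioSignal:
    """Raw constant-amplitude impulse train (no vocal-tract filtering)."""
    n = int(duration_s * fs)
    x = np.zeros(n)
    period = int(round(fs / f0_hz))
    x[np.arange(period, n - period, period)] = 1.0
    return AudioSignal(x, fs)


def pulses_from_periods(periods_ms, amplitudes=None) -> PulseSequence:
    times = np.concatenate([[0.0], np.cumsum(periods_ms)]) / 1000.0
    if amplitudes is None:
        amplitudes = np.ones(len(periods_ms))
    return PulseSequence(times, np.asarray(amplitudes, dtype=float))


class TestEstimatePitch:
    def test_pure_200hz_train_within_2hz_on_every_voiced_frame(self):
        track = estimate_pitch(impulse_train(200.0, 2.0))
        assert track.voiced.sum() > 50
        assert np.all(np.abs(track.f0_hz[track.voiced] - 200.0) < 2.0)

    def test_white_noise_mostly_unvoiced(self, rng):
        noise = AudioSignal(rng.standard_normal(32000) * 0.3, 16000.0)
        track = estimate_pitch(noise)
        assert track.voiced.mean() < 0.5

    def test_silence_entirely_unvoiced(self):
        track = estimate_pitch(AudioSignal(np.zeros(16000), 16000.0))
        assert not track.voiced.any()

    def test_signal_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            estimate_pitch(AudioSignal(np.zeros(100), 16000.0))

    def test_floor_ceiling_ordering_enforced(self):
        with pytest.raises(ValueError, match="Nyquist"):
            estimate_pitch(AudioSignal(np.zeros(16000), 16000.0), 500.0, 75.0)

    @pytest.mark.parametrize("f0", [100.0, 150.0, 200.0, 300.0])
    def test_clean_voice_mean_f0_within_2hz(self, f0):
        audio = gen_voice(VoiceSpec(f0_hz=f0, duration_s=2.0, seed=1))
        assert abs(estimate_pitch(audio).mean_f0() - f0) < 2.0


class TestF0Mid7:
    def test_exactly_seven_values_is_identity_sorted(self):
        vals = [170, 150, 160, 120, 130, 140, 110]
        np.testing.assert_array_equal(f0_mid7(vals), sorted(vals))

    def test_nine_values_drop_min_and_max(self):
        out = f0_mid7([100, 110, 120, 130, 140, 150, 160, 170, 180])
        np.testing.assert_array_equal(out, [110, 120, 130, 140, 150, 160, 170])

    def test_single_value_padded_to_seven_copies(self):
        np.testing.assert_array_equal(f0_mid7([150.0]), [150.0] * 7)

    def test_window_is_contiguous_and_contains_median(self, rng):
        vals = np.sort(rng.uniform(90, 280, 15))
        out = f0_mid7(vals)
        # contiguous rank window of the sorted input containing the median
        start = np.flatnonzero(vals == out[0])[0]
        np.testing.assert_array_equal(out, vals[start : start + 7])
        assert np.median(vals) in out

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            f0_mid7([])


class TestDetectPulses:
    def test_unperturbed_100hz_intervals_within_one_sample(self, clean_voice_100):
        audio, _, _ = clean_voice_100
        pulses = detect_pulses(audio, estimate_pitch(audio))
        periods = pulses.periods_ms
        assert len(periods) > 150
        assert np.all(np.abs(periods - 10.0) <= 1000.0 / 16000.0 + 1e-9)

    def test_constant_amplitude_train_has_equal_amplitudes(self):
        audio = impulse_train(100.0, 1.0)
        pulses = detect_pulses(audio, estimate_pitch(audio))
        np.testing.assert_allclose(pulses.amplitudes, pulses.amplitudes[0])

    def test_no_voiced_frames_gives_empty_sequence(self):
        silence = AudioSignal(np.zeros(16000), 16000.0)
        pulses = detect_pulses(silence, estimate_pitch(silence))
        assert pulses.n_periods == 0

    @pytest.mark.parametrize("kind", ["jitter", "shimmer"])
    def test_measured_perturbation_increases_with_injected_level(self, kind):
        # monotone in {0, 0.02, 0.05} for at least 9 of 10 seeds
        wins = 0
        for seed in range(10):
            measured = []
            for level in (0.0, 0.02, 0.05):
                spec = VoiceSpec(
                    f0_hz=150.0,
                    jitter_level=level if kind == "jitter" else 0.0,
                    shimmer_level=level if kind == "shimmer" else 0.0,
                    duration_s=2.0,
                    seed=seed,
                )
                audio = gen_voice(spec)
                pulses = detect_pulses(audio, estimate_pitch(audio))
                fn = jitter_local if kind == "jitter" else shimmer_local
                measured.append(fn(pulses))
            wins += measured[0] < measured[1] < measured[2]
        assert wins >= 9


class TestJitterShimmer:
    def test_equal_periods_give_zero_jitter(self):
        assert jitter_local(pulses_from_periods([10, 10, 10, 10])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_evaluated_jitter_example(self):
        # mean|dT| = (1+1+1)/3 = 1; mean T = 42/4 = 10.5
        assert jitter_local(pulses_from_periods([10, 11, 10, 11])) == pytest.approx(
            1.0 / 10.5
        )

    def test_jitter_invariant_to_time_scaling(self, rng):
        periods = rng.uniform(8, 12, 20)
        assert jitter_local(pulses_from_periods(periods)) == pytest.approx(
            jitter_local(pulses_from_periods(2.0 * periods))
        )

    def test_constant_amplitudes_give_zero_shimmer(self):
        p = pulses_from_periods([10, 10, 10], [0.7, 0.7, 0.7])
        assert shimmer_local(p) == 0.0

    def test_hand_evaluated_shimmer_example(self):
        # mean|dA| = 0.1; mean A = 1.6/3
        p = pulses_from_periods([10, 10, 10], [0.5, 0.6, 0.5])
        assert shimmer_local(p) == pytest.approx(0.1875)

    def test_shimmer_invariant_to_amplitude_scaling(self, rng):
        amps = rng.uniform(0.4, 1.0, 15)
        p1 = pulses_from_periods(np.full(15, 10.0), amps)
        p2 = pulses_from_periods(np.full(15, 10.0), 0.5 * amps)
        assert shimmer_local(p1) == pytest.approx(shimmer_local(p2))

    def test_too_few_periods_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            jitter_local(pulses_from_periods([10.0]))

    def test_all_zero_amplitudes_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            shimmer_local(pulses_from_periods([10, 10, 10], [0.0, 0.0, 0.0]))


def mfcc_oracle(x, fs, window_s=0.015, step_s=0.005, n_filters=26, n_coeffs=6):
    """Brute-force MFCC: explicit DFT, explicit triangles, explicit DCT sums."""
    n_win = int(round(window_s * fs))
    hop = int(round(step_s * fs))
    nfft = 1 << (n_win - 1).bit_length()
    nbins = nfft // 2 + 1
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n_win) / n_win)
    dft = np.exp(-2j * np.pi * np.outer(np.arange(nbins), np.arange(nfft)) / nfft)
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
    melinv = lambda m: 700.0 * (10 ** (m / 2595.0) - 1.0)
    pts = melinv(np.linspace(0.0, mel(fs / 2), n_filters + 2))
    freqs = np.arange(nbins) * fs / nfft
    out = []
    for s in range(0, len(x) - n_win + 1, hop):
        frame = np.zeros(nfft)
        frame[:n_win] = x[s : s + n_win] * hann
        power = np.abs(dft @ frame) ** 2
        logs = []
        for i in range(n_filters):
            lo, mid, hi = pts[i], pts[i + 1], pts[i + 2]
            w = np.maximum(0.0, np.minimum((freqs - lo) / (mid - lo), (hi - freqs) / (hi - mid)))
            logs.append(np.log(max(w @ power, 1e-30)))
        coeffs = []
        for k in range(1, n_coeffs + 1):
            c = sum(
                logs[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * n_filters))
                for m in range(n_filters)
            )
            coeffs.append(c * np.sqrt(2.0 / n_filters))  # orthonormal DCT-II scale
        out.append(coeffs)
    return np.array(out)


class TestMfcc:
    def test_single_frame_has_zero_std(self):
        audio = AudioSignal(np.sin(2 * np.pi * 300 * np.arange(240) / 16000), 16000.0)
        _, std = mfcc_stats(audio)
        np.testing.assert_array_equal(std, np.zeros(6))

    def test_self_concatenation_preserves_means(self):
        # 200 Hz sinusoid: the 80-sample period divides the 80-sample hop,
        # so doubling the signal doubles the frame multiset exactly
        t = np.arange(16000) / 16000.0
        x = np.sin(2 * np.pi * 200 * t)
        m1, _ = mfcc_stats(AudioSignal(x, 16000.0))
        m2, _ = mfcc_stats(AudioSignal(np.concatenate([x, x]), 16000.0))
        np.testing.assert_allclose(m2, m1, rtol=1e-6)

    def test_matches_brute_force_oracle_on_synthetic_vowel(self):
        audio = gen_voice(VoiceSpec(f0_hz=120.0, duration_s=0.12, seed=7))
        ours = mfcc_frames(audio)
        oracle = mfcc_oracle(audio.samples, audio.sample_rate_hz)
        np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-8)

    def test_too_short_audio_raises(self):
        with pytest.raises(ValueError, match="window"):
            mfcc_stats(AudioSignal(np.zeros(100), 16000.0))

    def test_std_nonnegative_on_voice(self, clean_voice_150):
        audio, _, _ = clean_voice_150
        _, std = mfcc_stats(audio)
        assert np.all(std >= 0)


class TestFormants:
    def test_roundtrip_within_10pct_of_generator_targets(self, clean_voice_150):
        audio, _, _ = clean_voice_150
        pulses = detect_pulses(audio, estimate_pitch(audio))
        med = formant_medians(audio, pulses)
        targets = np.array([500.0, 1500.0, 2500.0, 3500.0])
        assert np.all(np.abs(med - targets) / targets < 0.10)

    def test_output_always_ascending(self, clean_voice_100):
        audio, _, _ = clean_voice_100
        pulses = detect_pulses(audio, estimate_pitch(audio))
        med = formant_medians(audio, pulses)
        assert np.all(np.diff(med) > 0)

    def test_time_reversed_signal_gives_same_medians(self, clean_voice_150):
        # the autocorrelation method sees identical statistics under reversal
        audio, _, _ = clean_voice_150
        rev = AudioSignal(audio.samples[::-1].copy(), audio.sample_rate_hz)
        med_fwd = formant_medians(audio, detect_pulses(audio, estimate_pitch(audio)))
        med_rev = formant_medians(rev, detect_pulses(rev, estimate_pitch(rev)))
        np.testing.assert_allclose(med_rev, med_fwd, rtol=0.05)

    def test_no_pulses_undefined(self, clean_voice_150):
        audio, _, _ = clean_voice_150
        with pytest.raises(UndefinedFeatureError):
            formant_medians(audio, PulseSequence(np.array([]), np.array([])))


class TestExtractAcoustic:
    @pytest.fixture(scope="class")
    def subject(self):
        audio, _, _ = synthesize_voice(VoiceSpec(f0_hz=160.0, duration_s=2.4, seed=21))
        segments = SegmentSet([(0.0, 0.8), (0.8, 1.6), (1.6, 2.4)])
        return audio, segments

    def test_all_25_values_present_and_finite(self, subject):
        feats = extract_acoustic(*subject)
        vals = feats.to_list()
        assert len(vals) == 25
        assert np.all(np.isfinite(vals))

    def test_three_segments_pad_the_f0_window(self, subject):
        feats = extract_acoustic(*subject)
        # 3 segment means + 4 median copies: the middle 5 entries coincide
        mid = feats.f0_mid7[1:6]
        assert np.all(mid == mid[0])

    def test_identical_inputs_give_identical_features(self, subject):
        v1 = extract_acoustic(*subject).to_list()
        v2 = extract_acoustic(*subject).to_list()
        assert v1 == v2

    def test_empty_segment_set_rejected(self, subject):
        audio, _ = subject
        with pytest.raises(ValueError):
            extract_acoustic(audio, SegmentSet([]))
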