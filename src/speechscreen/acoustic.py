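"""Acoustic feature extraction from concatenated utterance audio.

Twenty-five features per subject: the middle seven ranked per-utterance mean
fundamental frequencies (F0), relative local jitter and shimmer of the
joined utterances, mean and standard deviation of frame-level MFCC1-6, and
the median of the first four formants at glottal pulses.

Pitch is estimated by windowed autocorrelation with peak picking inside a
configurable floor/ceiling range.  Glottal pulses are located by
period-synchronous peak search guided by the pitch track; jitter and shimmer
are then exact evaluations of the relative local formulas

    jitter  = mean_i |T_i - T_{i+1}|  /  mean_i T_i
    shimmer = mean_i |A_i - A_{i+1}|  /  mean_i A_i

over the N extracted periods, with T_i the i-th period length (ms) and A_i
the per-period peak amplitude on a 0-1 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import irfft, rfft, rfftfreq
from scipy.fftpack import dct
from scipy.linalg import solve_toeplitz
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioSignal, SegmentSet, concatenate_segments
from .schema import ACOUSTIC_COLUMNS


class UndefinedFeatureError(ValueError):
    """A feature has no defined value on this input (e.g. too few periods)."""


@dataclass(frozen=True)
class AcousticConfig:
    """Tunable extraction parameters (all config-exposed)."""

    pitch_floor_hz: float = 75.0
    pitch_ceiling_hz: float = 500.0
    voicing_threshold: float = 0.45
    pitch_step_s: float = 0.01
    pulse_search_frac: float = 0.45
    mfcc_window_s: float = 0.015
    mfcc_step_s: float = 0.005
    n_mel_filters: int = 26
    n_mfcc: int = 6
    formant_fs_hz: float = 10000.0
    lpc_order: int = 10
    formant_window_s: float = 0.025
    bandwidth_cutoff_hz: float = 400.0


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 estimates; unvoiced frames are NaN."""

    frame_times_s: np.ndarray
    f0_hz: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0_hz)

    def mean_f0(self) -> float:
        """Mean F0 over voiced frames; NaN if nothing is voiced."""
        if not self.voiced.any():
            return float("nan")
        return float(np.nanmean(self.f0_hz))


@dataclass(frozen=True)
class PulseSequence:
    """Glottal pulse times plus per-period peak amplitudes.

    ``amplitudes`` has one entry per period, i.e. ``len(pulse_times_s) - 1``
    entries, each on a 0-1 scale.
    """

    pulse_times_s: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times_s, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if len(amps) != max(len(times) - 1, 0):
            raise ValueError("need one amplitude per period (len(times) - 1)")
        if len(amps) and (amps.min() < 0 or amps.max() > 1 + 1e-9):
            raise ValueError("amplitudes must lie in [0, 1]")
        object.__setattr__(self, "pulse_times_s", times)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def periods_ms(self) -> np.ndarray:
        return np.diff(self.pulse_times_s) * 1000.0

    @property
    def n_periods(self) -> int:
        return max(len(self.pulse_times_s) - 1, 0)


@dataclass(frozen=True)
class AcousticFeatures:
    f0_mid7: np.ndarray
    jitter: float
    shimmer: float
    mfcc_mean: np.ndarray
    mfcc_std: np.ndarray
    formant_median: np.ndarray

    def to_list(self) -> list[float]:
        vals = (
            list(self.f0_mid7)
            + [self.jitter, self.shimmer]
            + list(self.mfcc_mean)
            + list(self.mfcc_std)
            + list(self.formant_median)
        )
        assert len(vals) == len(ACOUSTIC_COLUMNS)
        return [float(v) for v in vals]


# ---------------------------------------------------------------------------
# Pitch


def estimate_pitch(
    audio: AudioSignal,
    floor_hz: float = 75.0,
    ceiling_hz: float = 500.0,
    voicing_threshold: float = 0.45,
    step_s: float = 0.01,
) -> PitchTrack:
    """Frame-wise F0 by normalized autocorrelation peak picking.

    Frames are Hann-windowed, three floor-periods long, stepped by
    ``step_s``.  The frame autocorrelation is normalized by the window's own
    autocorrelation (which removes the taper-induced decay across lags); the
    candidate peaks inside the [floor, ceiling] lag range compete with an
    octave cost (0.1 per octave toward lower frequencies) that breaks the
    near-ties between a period and its multiples; the winning peak is
    refined by parabolic interpolation and accepted as voiced when its
    normalized height exceeds ``voicing_threshold``.
    """
    octave_cost = 0.1
    fs = audio.sample_rate_hz
    if not (0 < floor_hz < ceiling_hz < fs / 2):
        raise ValueError("need 0 < floor < ceiling < Nyquist")
    n_win = int(round(3.0 * fs / floor_hz))
    x = audio.samples
    # low-pass above the ceiling's second harmonic: periodicity detection
    # rides on the low harmonics; formant-band content only decorrelates the
    # autocorrelation when the cycle lengths fluctuate
    cutoff = min(1.9 * ceiling_hz, 0.45 * fs)
    if len(x) > 12:
        sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if len(x) < n_win:
        raise ValueError(
            f"signal of {len(x)} samples shorter than one analysis window ({n_win})"
        )
    hop = max(int(round(step_s * fs)), 1)
    win = sps.get_window("hann", n_win, fftbins=True)
    nfft = 1 << (2 * n_win - 1).bit_length()
    # window autocorrelation, for lag normalization
    rw = irfft(np.abs(rfft(win, nfft)) ** 2, nfft)[:n_win]
    rw /= rw[0]
    lag_min = max(int(math.floor(fs / ceiling_hz)), 2)
    lag_max = min(int(math.ceil(fs / floor_hz)), n_win - 2)

    starts = np.arange(0, len(x) - n_win + 1, hop)
    times = (starts + n_win / 2) / fs
    f0 = np.full(len(starts), np.nan)
    for k, s in enumerate(starts):
        frame = x[s : s + n_win]
        frame = (frame - frame.mean()) * win
        r = irfft(np.abs(rfft(frame, nfft)) ** 2, nfft)[:n_win]
        if r[0] < 1e-12:
            continue  # silence
        rn = (r / r[0]) / np.maximum(rw, 1e-6)
        seg = rn[lag_min : lag_max + 1]
        # local maxima of the normalized autocorrelation in the search range
        interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
        cand = np.flatnonzero(interior) + 1 + lag_min
        if len(cand) == 0:
            cand = np.array([int(np.argmax(seg)) + lag_min])
        # octave cost: prefer the shorter lag among near-equal peaks
        scores = rn[cand] - octave_cost * np.log2(cand * floor_hz / fs)
        i = int(cand[np.argmax(scores)])
        if rn[i] < voicing_threshold:
            continue
        # parabolic refinement around the integer-lag peak
        if 0 < i < n_win - 1:
            y0, y1, y2 = rn[i - 1], rn[i], rn[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        cand = fs / (i + delta)
        if floor_hz <= cand <= ceiling_hz:
            f0[k] = cand
    return PitchTrack(frame_times_s=times, f0_hz=f0)


def f0_mid7(segment_mean_f0s: Sequence[float]) -> np.ndarray:
    """Middle seven of the ascending-ranked per-utterance mean F0s.

    Returns the median plus the three values immediately below and above it.
    With fewer than seven inputs the list is padded with repeats of the
    median so the feature dimensionality stays fixed.  Output is sorted.
    """
    vals = np.sort(np.asarray(list(segment_mean_f0s), dtype=float))
    if len(vals) == 0:
        raise ValueError("no segment mean F0s")
    if np.any(~(vals > 0)):
        raise ValueError("segment mean F0s must be positive and finite")
    n = len(vals)
    if n >= 7:
        mid = (n - 1) // 2
        start = min(max(mid - 3, 0), n - 7)
        return vals[start : start + 7]
    med = vals[(n - 1) // 2]
    return np.sort(np.concatenate([vals, np.full(7 - n, med)]))


# ---------------------------------------------------------------------------
# Pulses


def detect_pulses(
    audio: AudioSignal,
    pitch: PitchTrack,
    search_frac: float = 0.45,
) -> PulseSequence:
    """Period-synchronous glottal pulse marking guided by the pitch track.

    Within each voiced span the search seeds at the largest absolute peak,
    then steps forward and backward by the local period, refining each pulse
    to the absolute-amplitude maximum within +/- ``search_frac`` of a period.
    Amplitudes are per-period peak absolute sample values rescaled by the
    signal's global peak so they lie in [0, 1].
    """
    fs = audio.sample_rate_hz
    x = audio.samples
    voiced = pitch.voiced
    if not voiced.any():
        return PulseSequence(np.array([]), np.array([]))
    global_peak = float(np.max(np.abs(x)))
    if global_peak == 0.0:
        return PulseSequence(np.array([]), np.array([]))

    # contiguous voiced runs of frames
    idx = np.flatnonzero(voiced)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    runs = np.split(idx, splits)

    all_pulses: list[int] = []
    for run in runs:
        t_lo = pitch.frame_times_s[run[0]]
        t_hi = pitch.frame_times_s[run[-1]]
        pad = 0.5 / np.nanmin(pitch.f0_hz[run])
        s_lo = max(int((t_lo - pad) * fs), 0)
        s_hi = min(int((t_hi + pad) * fs) + 1, len(x))
        if s_hi - s_lo < 4:
            continue
        span = np.abs(x[s_lo:s_hi])
        span_peak = span.max()
        if span_peak == 0.0:
            continue
        run_times = pitch.frame_times_s[run]
        run_f0 = pitch.f0_hz[run]

        def local_period(sample: int) -> float:
            t = sample / fs
            j = int(np.argmin(np.abs(run_times - t)))
            return fs / run_f0[j]

        seed = int(np.argmax(span)) + s_lo
        pulses = [seed]
        for direction in (+1, -1):
            cur = seed
            while True:
                period = local_period(cur)
                center = cur + direction * int(round(period))
                half = max(int(round(search_frac * period)), 1)
                w_lo = max(center - half, s_lo)
                w_hi = min(center + half + 1, s_hi)
                if w_hi - w_lo < 1 or not (s_lo <= center < s_hi):
                    break
                cand = int(np.argmax(np.abs(x[w_lo:w_hi]))) + w_lo
                # 10% floor rejects resonator ring-down past the final cycle
                if np.abs(x[cand]) >= 0.10 * span_peak:
                    pulses.append(cand)
                    cur = cand
                else:
                    cur = center  # coast over a weak cycle, keep period sync
        all_pulses.extend(pulses)

    if len(all_pulses) < 2:
        return PulseSequence(np.array(sorted(all_pulses)) / fs, np.array([]))
    samples = np.array(sorted(set(all_pulses)))
    # drop spurious near-duplicates from overlapping runs
    min_gap = int(fs / pitch.f0_hz[voiced].max() * 0.5)
    keep = [samples[0]]
    for s in samples[1:]:
        if s - keep[-1] >= max(min_gap, 1):
            keep.append(s)
    samples = np.array(keep)
    # reject residual ring-down picks at voicing onsets/offsets
    heights = np.abs(x[samples])
    samples = samples[heights >= 0.4 * np.median(heights)]
    if len(samples) < 2:
        return PulseSequence(samples / fs, np.array([]))
    amps = np.array(
        [np.max(np.abs(x[a : b + 1])) for a, b in zip(samples[:-1], samples[1:])]
    )
    return PulseSequence(samples / fs, amps / global_peak)


# ---------------------------------------------------------------------------
# Jitter and shimmer


def jitter_local(pulses: PulseSequence) -> float:
    """Relative local jitter: mean absolute successive period difference
    over the mean period."""
    periods = pulses.periods_ms
    if len(periods) < 2:
        raise UndefinedFeatureError("jitter needs at least 2 periods")
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))


def shimmer_local(pulses: PulseSequence) -> float:
    """Relative local shimmer: mean absolute successive amplitude difference
    over the mean amplitude."""
    amps = pulses.amplitudes
    if len(amps) < 2:
        raise UndefinedFeatureError("shimmer needs at least 2 periods with amplitudes")
    if np.all(amps == 0):
        raise UndefinedFeatureError("shimmer undefined: all period amplitudes are zero")
    return float(np.mean(np.abs(np.diff(amps))) / np.mean(amps))


# ---------------------------------------------------------------------------
# MFCC


def _mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular mel filters spanning 0 to Nyquist, (n_filters, nfft//2+1)."""
    mel_pts = np.linspace(_mel(0.0), _mel(fs / 2.0), n_filters + 2)
    hz_pts = np.asarray(_mel_inv(mel_pts))
    freqs = rfftfreq(nfft, 1.0 / fs)
    bank = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        bank[i] = np.maximum(0.0, np.minimum(up, down))
    return bank


def mfcc_frames(
    audio: AudioSignal,
    window_s: float = 0.015,
    step_s: float = 0.005,
    n_filters: int = 26,
    n_coeffs: int = 6,
) -> np.ndarray:
    """Frame-level MFCC matrix (n_frames, n_coeffs), coefficients 1..n_coeffs.

    Hann-windowed frames, triangular mel filterbank over 0-Nyquist, log
    energies, orthonormal DCT-II; the 0th (energy) coefficient is excluded.
    """
    fs = audio.sample_rate_hz
    x = audio.samples
    n_win = int(round(window_s * fs))
    hop = max(int(round(step_s * fs)), 1)
    if len(x) < n_win:
        raise ValueError("audio shorter than one MFCC window")
    win = sps.get_window("hann", n_win, fftbins=True)
    nfft = 1 << (n_win - 1).bit_length()
    starts = np.arange(0, len(x) - n_win + 1, hop)
    frames = np.stack([x[s : s + n_win] for s in starts]) * win
    power = np.abs(rfft(frames, nfft, axis=1)) ** 2
    bank = mel_filterbank(n_filters, nfft, fs)
    energies = power @ bank.T
    logs = np.log(np.maximum(energies, 1e-30))
    cepstra = dct(logs, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : n_coeffs + 1]


def mfcc_stats(
    audio: AudioSignal,
    window_s: float = 0.015,
    step_s: float = 0.005,
    n_filters: int = 26,
    n_coeffs: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient mean and population std of frame-level MFCCs."""
    c = mfcc_frames(audio, window_s, step_s, n_filters, n_coeffs)
    return c.mean(axis=0), c.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# Formants


def lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear-prediction polynomial [1, a_1 .. a_p]."""
    r = np.array([frame[: len(frame) - k] @ frame[k:] for k in range(order + 1)])
    if r[0] <= 0:
        raise UndefinedFeatureError("zero-energy frame")
    r[0] *= 1.0 + 1e-9  # slight ridge for numerical safety
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate([[1.0], a])


def _resonances(a: np.ndarray, fs: float, bw_cutoff: float) -> np.ndarray:
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / np.pi
    ok = (freqs > 90.0) & (freqs < fs / 2 - 90.0) & (bws < bw_cutoff)
    return np.sort(freqs[ok])


def formant_medians(
    audio: AudioSignal,
    pulses: PulseSequence,
    n_formants: int = 4,
    fs_target: float = 10000.0,
    order: int = 10,
    window_s: float = 0.025,
    bw_cutoff: float = 400.0,
) -> np.ndarray:
    """Median of the first ``n_formants`` formants over glottal pulses.

    The signal is resampled to ``fs_target``, a Gaussian-windowed
    linear-prediction analysis of the given order runs in a short window
    centred on each pulse, and resonances with bandwidth below ``bw_cutoff``
    are kept.  A pulse that resolves fewer than ``n_formants`` resonances
    contributes only to the formants it did resolve.
    """
    if len(pulses.pulse_times_s) < 1:
        raise UndefinedFeatureError("no pulses for formant analysis")
    fs_in = audio.sample_rate_hz
    if fs_in != fs_target:
        frac = Fraction(int(round(fs_target)), int(round(fs_in))).limit_denominator(1000)
        x = sps.resample_poly(audio.samples, frac.numerator, frac.denominator)
    else:
        x = audio.samples
    n_win = int(round(window_s * fs_target))
    half = n_win // 2
    win = sps.windows.gaussian(n_win, std=n_win / 6.0)
    per_pulse = []
    for t in pulses.pulse_times_s:
        c = int(round(t * fs_target))
        if c - half < 0 or c + half + (n_win % 2) > len(x):
            continue
        frame = x[c - half : c - half + n_win]
        frame = (frame - frame.mean()) * win
        try:
            a = lpc_coefficients(frame, order)
        except UndefinedFeatureError:
            continue
        f = _resonances(a, fs_target, bw_cutoff)
        row = np.full(n_formants, np.nan)
        row[: min(len(f), n_formants)] = f[:n_formants]
        per_pulse.append(row)
    if not per_pulse:
        raise UndefinedFeatureError("no pulse resolved any formant")
    mat = np.stack(per_pulse)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(mat, axis=0)
    if np.isnan(med).any():
        raise UndefinedFeatureError(
            f"formants {np.flatnonzero(np.isnan(med)) + 1} unresolved at every pulse"
        )
    return np.sort(med)


# ---------------------------------------------------------------------------
# Full per-subject extraction


def extract_acoustic(
    audio: AudioSignal,
    segments: SegmentSet,
    config: AcousticConfig | None = None,
) -> AcousticFeatures:
    """The 25-value acoustic feature vector for one subject.

    Per-utterance mean F0s feed the middle-seven rank window; jitter,
    shimmer, MFCC statistics and formant medians are computed on the
    peak-normalized concatenation of the utterances.
    """
    cfg = config or AcousticConfig()
    if len(segments) < 1:
        raise ValueError("need at least one utterance segment")
    joined = concatenate_segments(audio, segments).normalized(1.0)

    seg_means = []
    for start_s, end_s in segments:
        seg_audio = concatenate_segments(audio, SegmentSet([(start_s, end_s)]))
        try:
            track = estimate_pitch(
                seg_audio,
                cfg.pitch_floor_hz,
                cfg.pitch_ceiling_hz,
                cfg.voicing_threshold,
                cfg.pitch_step_s,
            )
        except ValueError:
            continue  # segment shorter than one pitch window
        m = track.mean_f0()
        if not math.isnan(m):
            seg_means.append(m)
    if not seg_means:
        raise UndefinedFeatureError("no utterance segment yielded a voiced mean F0")
    mid7 = f0_mid7(seg_means)

    track = estimate_pitch(
        joined, cfg.pitch_floor_hz, cfg.pitch_ceiling_hz, cfg.voicing_threshold, cfg.pitch_step_s
    )
    pulses = detect_pulses(joined, track, cfg.pulse_search_frac)
    jit = jitter_local(pulses)
    shim = shimmer_local(pulses)
    m_mean, m_std = mfcc_stats(
        joined, cfg.mfcc_window_s, cfg.mfcc_step_s, cfg.n_mel_filters, cfg.n_mfcc
    )
    formants = formant_medians(
        joined,
        pulses,
        fs_target=cfg.formant_fs_hz,
        order=cfg.lpc_order,
        window_s=cfg.formant_window_s,
        bw_cutoff=cfg.bandwidth_cutoff_hz,
    )
    return AcousticFeatures(
        f0_mid7=mid7,
        jitter=jit,
        shimmer=shim,
        mfcc_mean=m_mean,
        mfcc_std=m_std,
        formant_median=formants,
    )


class AcousticFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: (subject_id, audio, segments) triples -> feature frame."""

    def __init__(self, config: AcousticConfig | None = None):
        self.config = config

    def fit(self, X, y=None):  # noqa: N803 - sklearn API
        return self

    def transform(self, X) -> pd.DataFrame:  # noqa: N803
        rows = []
        for subject_id, audio, segments in X:
            feats = extract_acoustic(audio, segments, self.config)
            rows.append(
                {"subject_id": subject_id, **dict(zip(ACOUSTIC_COLUMNS, feats.to_list()))}
            )
        return pd.DataFrame(rows)
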