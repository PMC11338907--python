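"""Audio containers, WAV I/O, and utterance-segment concatenation.

Speech arrives as one recording per subject plus a table of utterance
intervals (start/end seconds).  Analysis operates on the concatenation of
those intervals, so that per-subject voice-quality statistics are computed
over speech only, not pauses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform with sample rate.

    Samples are dimensionless floats in [-1, 1]; ``sample_rate_hz`` > 0.
    """

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D sample array)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0

    def normalized(self, peak: float = 1.0) -> "AudioSignal":
        """Rescale so the maximum absolute sample equals ``peak``.

        Silent signals are returned unchanged.
        """
        m = float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0
        if m == 0.0:
            return self
        return AudioSignal(self.samples * (peak / m), self.sample_rate_hz)


@dataclass(frozen=True)
class SegmentSet:
    """Sorted, non-overlapping utterance intervals in recording-relative seconds."""

    intervals: tuple

    def __init__(self, intervals: Sequence[Sequence[float]]):
        ivs = tuple((float(a), float(b)) for a, b in intervals)
        for a, b in ivs:
            if not a < b:
                raise ValueError(f"segment start must precede end: ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("segments must be sorted and non-overlapping")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono float signal in [-1, 1].

    Multi-channel input is averaged across channels with a warning.
    """
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn("multi-channel audio averaged to mono", stacklevel=2)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, float(rate))


def write_wav(path: str | Path, audio: AudioSignal) -> None:
    """Write a 16-bit PCM WAV file."""
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate_hz), pcm)


def concatenate_segments(audio: AudioSignal, segments: SegmentSet) -> AudioSignal:
    """Join the utterance intervals of a recording into one signal.

    Output length equals the sum of the interval lengths in samples; sample
    order is preserved.  An interval extending outside the recording raises.
    """
    fs = audio.sample_rate_hz
    n = len(audio.samples)
    pieces = []
    for start_s, end_s in segments:
        i0 = int(round(start_s * fs))
        i1 = int(round(end_s * fs))
        if i0 < 0 or i1 > n:
            raise ValueError(
                f"segment ({start_s}, {end_s}) s outside recording of {n / fs:.3f} s"
            )
        pieces.append(audio.samples[i0:i1])
    if not pieces:
        raise ValueError("segment set is empty")
    return AudioSignal(np.concatenate(pieces), fs)
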