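"""Seeded synthetic data: voices, tagged transcripts, and feature cohorts.

Three generators make every downstream stage testable without recordings:

* ``gen_voice`` — a glottal pulse-train source (period and amplitude
  perturbed cycle-to-cycle by controllable jitter/shimmer levels) filtered
  through second-order resonators at four formant frequencies.
* ``gen_transcript`` — a POS-tagged token stream with exact tag-class counts
  (largest-remainder allocation) and embedded Cookie-Theft information
  units guaranteed to be credited by the scorer.
* ``gen_feature_cohort`` — per-group Gaussian feature draws around
  reference group means from a 92-subject community screening cohort
  (22 HC / 30 AD / 40 MCI), the statistical structure the permutation tests
  and classifiers assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import AudioSignal
from .linguistic import IULexicon, TaggedTranscript
from .schema import ALL_FEATURE_COLUMNS

# ---------------------------------------------------------------------------
# Voice generation

#: Default resonance bandwidths (Hz) for the four formant filters.
DEFAULT_BANDWIDTHS_HZ = (80.0, 120.0, 160.0, 200.0)


@dataclass(frozen=True)
class VoiceSpec:
    """Parameters of one synthetic voice."""

    f0_hz: float = 150.0
    jitter_level: float = 0.0
    shimmer_level: float = 0.0
    formants_hz: tuple = (500.0, 1500.0, 2500.0, 3500.0)
    duration_s: float = 2.0
    sample_rate_hz: float = 16000.0
    seed: int = 0
    pitch_floor_hz: float = 75.0
    pitch_ceiling_hz: float = 500.0

    def validate(self) -> None:
        if not (self.pitch_floor_hz < self.f0_hz < self.pitch_ceiling_hz):
            raise ValueError(
                f"f0 {self.f0_hz} Hz outside ({self.pitch_floor_hz}, {self.pitch_ceiling_hz})"
            )
        if self.jitter_level < 0 or self.shimmer_level < 0:
            raise ValueError("jitter_level and shimmer_level must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        f = tuple(self.formants_hz)
        if list(f) != sorted(f):
            raise ValueError("formants must be ascending")
        if f[-1] >= self.sample_rate_hz / 2:
            raise ValueError(
                f"formant {f[-1]} Hz at or above Nyquist ({self.sample_rate_hz / 2} Hz)"
            )


def synthesize_voice(spec: VoiceSpec) -> tuple[AudioSignal, np.ndarray, np.ndarray]:
    """Generate a voice and return (audio, true pulse times, true amplitudes).

    Periods are ``(1/f0) * (1 + jitter_level * g_i)`` with standard-normal
    ``g_i`` clipped to +/-3; pulse amplitudes are ``1 + shimmer_level * h_i``
    likewise.  The impulse train is filtered through a cascade of two-pole
    resonators at the formant frequencies and peak-normalized to 0.9.
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    base = 1.0 / spec.f0_hz

    times = []
    t = 0.02  # lead-in before the first pulse
    while t < spec.duration_s - 0.02:
        times.append(t)
        g = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        t += base * (1.0 + spec.jitter_level * g)
    times = np.array(times)
    h = np.clip(rng.standard_normal(len(times)), -3.0, 3.0)
    amps = np.maximum(1.0 + spec.shimmer_level * h, 0.05)

    n = int(round(spec.duration_s * fs))
    x = np.zeros(n)
    idx = np.round(times * fs).astype(int)
    np.add.at(x, idx[idx < n], amps[idx < n])

    for f, bw in zip(spec.formants_hz, DEFAULT_BANDWIDTHS_HZ):
        r = math.exp(-math.pi * bw / fs)
        a = [1.0, -2.0 * r * math.cos(2.0 * math.pi * f / fs), r * r]
        x = sps.lfilter([1.0], a, x)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (0.9 / peak)
    return AudioSignal(x, fs), times, amps


def gen_voice(spec: VoiceSpec) -> AudioSignal:
    """Synthetic voiced audio; see :func:`synthesize_voice`."""
    return synthesize_voice(spec)[0]


# ---------------------------------------------------------------------------
# Transcript generation

TAG_CLASS_ORDER = ("noun", "verb", "pronoun", "adjective", "numeral", "other")

#: One representative tag per class (Penn Chinese Treebank conventions).
CLASS_TAGS = {
    "noun": "NN",
    "verb": "VV",
    "pronoun": "PN",
    "adjective": "JJ",
    "numeral": "CD",
    "other": "AD",
}

_SYLLABLES = ("ka", "lo", "mi", "ne", "pu", "ri", "so", "tu", "ve", "zo", "da", "fe")


def largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer allocation of ``n`` over classes by the largest-remainder rule.

    Floors each quota, then hands the leftover units to the classes with the
    largest fractional remainders; remainder ties go to the earlier class in
    ``TAG_CLASS_ORDER``.
    """
    classes = [c for c in TAG_CLASS_ORDER if c in proportions]
    quotas = {c: n * proportions[c] for c in classes}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        classes, key=lambda c: (-(quotas[c] - counts[c]), classes.index(c))
    )
    for c in by_remainder[:leftover]:
        counts[c] += 1
    return counts


@dataclass(frozen=True)
class TranscriptSpec:
    """Parameters of one synthetic tagged transcript."""

    n_tokens: int = 100
    pos_mixture: dict = field(
        default_factory=lambda: {
            "noun": 0.25,
            "verb": 0.22,
            "pronoun": 0.13,
            "adjective": 0.06,
            "numeral": 0.03,
            "other": 0.31,
        }
    )
    iu_concepts: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be >= 1")
        if not self.pos_mixture:
            raise ValueError("pos_mixture is empty")
        vals = list(self.pos_mixture.values())
        if any(v < 0 for v in vals):
            raise ValueError("pos_mixture proportions must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError("pos_mixture proportions must sum to 1")
        unknown = set(self.pos_mixture) - set(TAG_CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown tag classes in mixture: {sorted(unknown)}")


def _filler_vocab(rng: np.random.Generator, size: int, forbidden: set[str]) -> list[str]:
    vocab: list[str] = []
    while len(vocab) < size:
        w = "".join(rng.choice(_SYLLABLES, size=2))
        if w not in forbidden:
            vocab.append(w)
    return vocab


def gen_transcript(
    spec: TranscriptSpec,
    lexicon: IULexicon | None = None,
    subject_id: str = "synthetic",
) -> TaggedTranscript:
    """Tagged token stream with exact class counts and embedded information units.

    Realized tag-class counts equal the largest-remainder allocation of
    ``n_tokens`` over ``pos_mixture``.  Every concept in ``iu_concepts`` is
    realized through a surface form from the lexicon: entities as one noun
    token, actions as an agent noun immediately followed by an action verb
    (so the windowed co-occurrence matcher credits them).  Raises when the
    embedded concepts need more tokens of a class than the mixture allots.
    """
    spec.validate()
    lex = lexicon or IULexicon.default()
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n_tokens, spec.pos_mixture)

    chunks: list[list[tuple[str, str]]] = []
    need = {c: 0 for c in TAG_CLASS_ORDER}
    for name in spec.iu_concepts:
        if name not in lex.concepts:
            raise ValueError(f"unknown information-unit concept: {name!r}")
        c = lex.concepts[name]
        if c["category"] == "actions":
            agent = str(rng.choice(c["agent_patterns"]))
            action = str(rng.choice(c["action_patterns"]))
            chunks.append([(agent, CLASS_TAGS["noun"]), (action, CLASS_TAGS["verb"])])
            need["noun"] += 1
            need["verb"] += 1
        else:
            surface = str(rng.choice([p for p in c["patterns"] if " " not in p] or c["patterns"]))
            chunks.append([(surface, CLASS_TAGS["noun"])])
            need["noun"] += 1
    for cls, k in need.items():
        if k > counts.get(cls, 0):
            raise ValueError(
                f"information units need {k} {cls} tokens but the mixture allots "
                f"{counts.get(cls, 0)}"
            )

    forbidden = {
        p.lower()
        for c in lex.concepts.values()
        for key in ("patterns", "agent_patterns", "action_patterns")
        for p in c.get(key, [])
    }
    for cls in TAG_CLASS_ORDER:
        remaining = counts.get(cls, 0) - need[cls]
        if remaining <= 0:
            continue
        vocab = _filler_vocab(rng, max(3, remaining // 2), forbidden)
        for w in rng.choice(vocab, size=remaining):
            chunks.append([(str(w), CLASS_TAGS[cls])])

    order = rng.permutation(len(chunks))
    tokens = [tok for i in order for tok in chunks[i]]
    return TaggedTranscript(tokens, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Feature-cohort generation

#: Reference per-group feature means (HC, AD, CI) from a 92-subject community
#: screening cohort of older adults (22 HC, 30 AD, 40 MCI; CI = AD + MCI).
REFERENCE_GROUP_MEANS: dict[str, tuple[float, float, float]] = {
    "f0_1": (140.420, 161.085, 154.817),
    "f0_2": (149.492, 173.266, 163.467),
    "f0_3": (151.826, 182.486, 169.933),
    "f0_4": (156.101, 188.991, 176.081),
    "f0_5": (159.801, 193.094, 181.430),
    "f0_6": (163.012, 200.132, 186.841),
    "f0_7": (166.376, 206.172, 191.496),
    "jitter": (0.038, 0.045, 0.041),
    "shimmer": (0.167, 0.175, 0.171),
    "mfcc1_mean": (234.901, 196.541, 225.899),
    "mfcc2_mean": (24.713, 61.410, 31.532),
    "mfcc3_mean": (53.839, 50.680, 52.700),
    "mfcc4_mean": (-10.847, -1.813, -11.745),
    "mfcc5_mean": (-2.153, 1.151, -3.947),
    "mfcc6_mean": (-19.508, -12.374, -16.963),
    "mfcc1_std": (78.217, 62.003, 71.342),
    "mfcc2_std": (49.469, 41.364, 46.065),
    "mfcc3_std": (39.740, 34.426, 38.318),
    "mfcc4_std": (33.715, 29.314, 31.570),
    "mfcc5_std": (31.452, 31.229, 31.718),
    "mfcc6_std": (27.930, 26.263, 27.480),
    "formant1_med": (445.556, 449.034, 449.117),
    "formant2_med": (1624.625, 1711.090, 1650.245),
    "formant3_med": (2651.637, 2782.151, 2720.257),
    "formant4_med": (3774.587, 3859.464, 3805.747),
    "noun_ratio": (0.251, 0.194, 0.222),
    "verb_ratio": (0.223, 0.271, 0.258),
    "pronoun_ratio": (0.133, 0.183, 0.174),
    "ttr_words": (0.558, 0.586, 0.575),
    "ttr_chars": (0.471, 0.513, 0.499),
    "info_word_ratio": (0.546, 0.531, 0.542),
    "iu_people": (2.545, 2.300, 2.414),
    "iu_objects": (5.773, 2.933, 4.100),
    "iu_places": (0.727, 0.200, 0.557),
    "iu_actions": (3.136, 2.133, 2.700),
}

REFERENCE_N_PER_GROUP = {"HC": 22, "AD": 30, "MCI": 40}
REFERENCE_FEMALE_FRACTION = 52 / 92


def _mci_mean(mean_ad: float, mean_ci: float, n_ad: int = 30, n_mci: int = 40) -> float:
    """MCI mean implied by the AD and pooled-CI means and group sizes."""
    return ((n_ad + n_mci) * mean_ci - n_ad * mean_ad) / n_mci


def _default_sd(mean_hc: float, mean_ad: float) -> float:
    """Default within-group sd: the HC-AD separation (effect size ~1),
    floored at 5% of the HC mean magnitude (0.01 for near-zero means)."""
    return max(abs(mean_hc - mean_ad), 0.05 * abs(mean_hc), 0.01)


@dataclass(frozen=True)
class GroupEffectSpec:
    """Per-feature group means and sds for a Gaussian synthetic cohort.

    ``effects`` maps feature name -> (mean_HC, mean_AD, mean_MCI, sd).
    """

    effects: dict
    n_per_group: dict = field(default_factory=lambda: dict(REFERENCE_N_PER_GROUP))
    gender_probability: float = REFERENCE_FEMALE_FRACTION
    seed: int = 0

    def validate(self) -> None:
        if not self.effects:
            raise ValueError("no feature effects given")
        for name, (mh, ma, mm, sd) in self.effects.items():
            if sd <= 0:
                raise ValueError(f"feature {name!r}: sd must be > 0")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g}: need >= 2 subjects (got {n})")
        if not (0.0 <= self.gender_probability <= 1.0):
            raise ValueError("gender_probability must be in [0, 1]")

    @classmethod
    def reference(
        cls,
        n_per_group: Mapping[str, int] | None = None,
        seed: int = 0,
        features: Sequence[str] | None = None,
        null_features: Sequence[str] = (),
    ) -> "GroupEffectSpec":
        """Spec patterned on the reference cohort means.

        ``null_features`` lists features whose group means are collapsed to
        the HC mean (no group effect) — used for planted-signal experiments.
        """
        feats = list(features) if features is not None else list(ALL_FEATURE_COLUMNS)
        effects = {}
        for name in feats:
            mh, ma, mci_pooled = REFERENCE_GROUP_MEANS[name]
            mm = _mci_mean(ma, mci_pooled)
            sd = _default_sd(mh, ma)
            if name in null_features:
                ma = mm = mh
            effects[name] = (mh, ma, mm, sd)
        return cls(
            effects=effects,
            n_per_group=dict(n_per_group or REFERENCE_N_PER_GROUP),
            seed=seed,
        )

    @classmethod
    def null(
        cls,
        n_per_group: Mapping[str, int] | None = None,
        seed: int = 0,
        features: Sequence[str] | None = None,
    ) -> "GroupEffectSpec":
        """All group means equal (type-I-error conditions)."""
        feats = list(features) if features is not None else list(ALL_FEATURE_COLUMNS)
        return cls.reference(n_per_group=n_per_group, seed=seed, features=feats,
                             null_features=feats)


def gen_feature_cohort(spec: GroupEffectSpec) -> pd.DataFrame:
    """Independent Gaussian feature draws per subject, with labels attached.

    Returns a feature table (schema columns for the features present in the
    spec).  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    mean_index = {"HC": 0, "AD": 1, "MCI": 2}
    for group in ("HC", "MCI", "AD"):
        n = spec.n_per_group.get(group, 0)
        for _ in range(n):
            counter += 1
            row = {
                "subject_id": f"S{counter:03d}",
                "gender": "F" if rng.random() < spec.gender_probability else "M",
                "group": group,
            }
            for name, (mh, ma, mm, sd) in spec.effects.items():
                mu = (mh, ma, mm)[mean_index[group]]
                row[name] = mu + sd * rng.standard_normal()
            rows.append(row)
    ordered = [c for c in ALL_FEATURE_COLUMNS if c in spec.effects]
    extra = [c for c in spec.effects if c not in ordered]
    return pd.DataFrame(rows)[["subject_id", "gender", "group"] + ordered + extra]


# ---------------------------------------------------------------------------
# End-to-end audio/transcript cohorts (for the pipeline's self-contained mode)


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str
    gender: str
    voice: VoiceSpec
    transcript: TranscriptSpec
    iu_concepts: tuple


#: Group-level generative profiles for the self-contained demo cohort:
#: mean F0 and perturbation levels rise with impairment, POS mixtures follow
#: the reference group means, and the number of mentioned information units
#: per category shrinks with impairment.
GROUP_VOICE_PROFILES = {
    "HC": {"f0": (150.0, 18.0), "jitter": 0.020, "shimmer": 0.040},
    "MCI": {"f0": (165.0, 20.0), "jitter": 0.028, "shimmer": 0.050},
    "AD": {"f0": (180.0, 22.0), "jitter": 0.036, "shimmer": 0.060},
}

GROUP_POS_MIXTURES = {
    "HC": {"noun": 0.251, "verb": 0.223, "pronoun": 0.133, "adjective": 0.06,
           "numeral": 0.03, "other": 0.303},
    "MCI": {"noun": 0.222, "verb": 0.258, "pronoun": 0.174, "adjective": 0.055,
            "numeral": 0.025, "other": 0.266},
    "AD": {"noun": 0.194, "verb": 0.271, "pronoun": 0.183, "adjective": 0.05,
           "numeral": 0.02, "other": 0.282},
}

#: Mean number of mentioned concepts per IU category, by group.
GROUP_IU_RATES = {
    "HC": {"people": 2.5, "objects": 5.8, "places": 0.7, "actions": 3.1},
    "MCI": {"people": 2.4, "objects": 4.1, "places": 0.55, "actions": 2.7},
    "AD": {"people": 2.3, "objects": 2.9, "places": 0.2, "actions": 2.1},
}


def gen_subject_cohort(
    n_per_group: Mapping[str, int] | None = None,
    seed: int = 0,
    duration_s: float = 2.5,
    sample_rate_hz: float = 16000.0,
    n_tokens: int = 120,
    lexicon: IULexicon | None = None,
) -> list[SubjectSpec]:
    """Subject-level voice and transcript specs with group-dependent profiles."""
    lex = lexicon or IULexicon.default()
    rng = np.random.default_rng(seed)
    n_per_group = dict(n_per_group or {"HC": 4, "MCI": 4, "AD": 4})
    by_cat: dict[str, list[str]] = {}
    for name, c in lex.concepts.items():
        by_cat.setdefault(c["category"], []).append(name)

    subjects = []
    counter = 0
    for group in ("HC", "MCI", "AD"):
        prof_v = GROUP_VOICE_PROFILES[group]
        rates = GROUP_IU_RATES[group]
        for _ in range(n_per_group.get(group, 0)):
            counter += 1
            f0 = float(np.clip(rng.normal(*prof_v["f0"]), 100.0, 300.0))
            base_formants = np.array([500.0, 1500.0, 2500.0, 3500.0])
            formants = tuple(np.sort(base_formants * (1 + 0.04 * rng.standard_normal(4))))
            voice = VoiceSpec(
                f0_hz=f0,
                jitter_level=prof_v["jitter"],
                shimmer_level=prof_v["shimmer"],
                formants_hz=formants,
                duration_s=duration_s,
                sample_rate_hz=sample_rate_hz,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            concepts: list[str] = []
            for cat, pool in by_cat.items():
                k = int(np.clip(rng.poisson(rates[cat]), 0, len(pool)))
                concepts.extend(rng.choice(pool, size=k, replace=False))
            transcript = TranscriptSpec(
                n_tokens=n_tokens,
                pos_mixture=dict(GROUP_POS_MIXTURES[group]),
                iu_concepts=tuple(concepts),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            subjects.append(
                SubjectSpec(
                    subject_id=f"S{counter:03d}",
                    group=group,
                    gender="F" if rng.random() < REFERENCE_FEMALE_FRACTION else "M",
                    voice=voice,
                    transcript=transcript,
                    iu_concepts=tuple(concepts),
                )
            )
    return subjects
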