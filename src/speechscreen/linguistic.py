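"""Linguistic features from POS-tagged picture-description transcripts.

Ten features per subject: part-of-speech ratios (nouns, verbs, pronouns),
type-token ratios over words and characters, the information-word ratio
(nouns + verbs + adjectives + numerals), and the four Cookie-Theft
information-unit counts (people, objects, places, actions).

The contract starts at tagged tokens: transcripts arrive pre-tokenized and
pre-tagged, which keeps the scorer language-agnostic.  The default tag-class
mapping covers Penn Chinese Treebank tags and is configurable.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import LINGUISTIC_COLUMNS

#: Tag classes -> Penn Chinese Treebank tags (configurable; unknown tags -> "other").
DEFAULT_TAG_CLASSES: dict[str, tuple[str, ...]] = {
    "noun": ("NN", "NR", "NT"),
    "verb": ("VV", "VC", "VE"),
    "pronoun": ("PN",),
    "adjective": ("JJ", "VA"),
    "numeral": ("CD", "OD"),
}

INFO_WORD_CLASSES = frozenset({"noun", "verb", "adjective", "numeral"})

IU_CATEGORIES = ("people", "objects", "places", "actions")


def _tag_to_class(tag: str, tag_classes: Mapping[str, Sequence[str]]) -> str:
    for cls, tags in tag_classes.items():
        if tag in tags:
            return cls
    return "other"


def _norm(surface: str) -> str:
    """Case- and width-normalize a surface form (NFKC, lowercase)."""
    return unicodedata.normalize("NFKC", surface).lower()


@dataclass(frozen=True)
class Token:
    surface: str
    tag: str

    @property
    def characters(self) -> tuple[str, ...]:
        return tuple(self.surface)


@dataclass(frozen=True)
class TaggedTranscript:
    """Ordered (surface, POS-tag) tokens for one subject."""

    tokens: tuple
    subject_id: str = ""

    def __init__(self, tokens: Iterable, subject_id: str = ""):
        toks = tuple(
            t if isinstance(t, Token) else Token(str(t[0]), str(t[1])) for t in tokens
        )
        object.__setattr__(self, "tokens", toks)
        object.__setattr__(self, "subject_id", subject_id)

    def __len__(self) -> int:
        return len(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def tag_classes(self, tag_classes: Mapping[str, Sequence[str]] | None = None) -> list[str]:
        tc = DEFAULT_TAG_CLASSES if tag_classes is None else tag_classes
        return [_tag_to_class(t.tag, tc) for t in self.tokens]


@dataclass(frozen=True)
class LinguisticFeatures:
    noun_ratio: float
    verb_ratio: float
    pronoun_ratio: float
    ttr_words: float
    ttr_chars: float
    info_word_ratio: float
    iu_people: int
    iu_objects: int
    iu_places: int
    iu_actions: int

    def to_list(self) -> list[float]:
        return [getattr(self, name) for name in LINGUISTIC_COLUMNS]


# ---------------------------------------------------------------------------
# Information-unit lexicon


@dataclass(frozen=True)
class IULexicon:
    """Cookie-Theft concept inventory grouped into people/objects/places/actions.

    Entity concepts (people, objects, places) carry literal surface patterns;
    a pattern with spaces matches a run of consecutive tokens.  Action
    concepts carry agent patterns and action patterns, credited when an agent
    token is followed by an action token within ``action_window`` tokens.
    Every concept is credited at most once (presence-based scoring).
    """

    concepts: dict = field(default_factory=dict)
    action_window: int = 10

    def category_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in IU_CATEGORIES}
        for spec in self.concepts.values():
            sizes[spec["category"]] += 1
        return sizes

    def validate(self) -> None:
        for name, spec in self.concepts.items():
            cat = spec.get("category")
            if cat not in IU_CATEGORIES:
                raise ValueError(f"concept {name!r}: unknown category {cat!r}")
            if cat == "actions":
                if not spec.get("agent_patterns") or not spec.get("action_patterns"):
                    raise ValueError(f"action concept {name!r} needs agent and action patterns")
            elif not spec.get("patterns"):
                raise ValueError(f"entity concept {name!r} needs surface patterns")
        if self.action_window < 1:
            raise ValueError("action_window must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "IULexicon":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        lex = cls(concepts=raw["concepts"], action_window=int(raw.get("action_window", 10)))
        lex.validate()
        return lex

    @classmethod
    def default(cls) -> "IULexicon":
        """The built-in inventory: 3 people, 2 places, 12 objects, 7 actions."""
        ref = resources.files("speechscreen.data").joinpath("iu_lexicon.json")
        with resources.as_file(ref) as path:
            return cls.from_json(path)


def _match_literal(pattern: str, surfaces: Sequence[str]) -> list[int]:
    """Positions where a (possibly multi-token) literal pattern starts."""
    parts = [_norm(p) for p in pattern.split()]
    k = len(parts)
    return [
        i for i in range(len(surfaces) - k + 1) if list(surfaces[i : i + k]) == parts
    ]


def count_info_units(
    t: TaggedTranscript,
    lex: IULexicon | None = None,
    *,
    presence: bool = True,
) -> dict[str, int]:
    """Per-category credited information-unit counts.

    With ``presence=True`` (default) each concept scores at most 1; with
    ``presence=False`` every distinct match occurrence is counted.
    An empty transcript scores zero everywhere.
    """
    lex = lex or IULexicon.default()
    lex.validate()
    surfaces = [_norm(s) for s in t.surfaces()]
    counts = {c: 0 for c in IU_CATEGORIES}
    for spec in lex.concepts.values():
        cat = spec["category"]
        if cat == "actions":
            agent_pos = sorted(
                p for pat in spec["agent_patterns"] for p in _match_literal(pat, surfaces)
            )
            action_pos = sorted(
                p for pat in spec["action_patterns"] for p in _match_literal(pat, surfaces)
            )
            hits = sum(
                1
                for a in agent_pos
                for b in action_pos
                if a < b <= a + lex.action_window
            )
        else:
            hits = sum(len(_match_literal(pat, surfaces)) for pat in spec["patterns"])
        if hits:
            counts[cat] += 1 if presence else hits
    return counts


# ---------------------------------------------------------------------------
# Lexical features


def pos_ratios(
    t: TaggedTranscript, tag_classes: Mapping[str, Sequence[str]] | None = None
) -> tuple[float, float, float]:
    """(noun, verb, pronoun) token-count ratios over all tokens."""
    if len(t) == 0:
        raise ValueError("empty transcript")
    classes = t.tag_classes(tag_classes)
    n = len(classes)
    return (
        classes.count("noun") / n,
        classes.count("verb") / n,
        classes.count("pronoun") / n,
    )


def ttr(t: TaggedTranscript) -> tuple[float, float]:
    """(word TTR, character TTR): distinct forms over total forms.

    Word types are width/case-normalized surfaces; characters are pooled over
    all tokens, including those inside multi-character words.
    """
    if len(t) == 0:
        raise ValueError("empty transcript")
    words = [_norm(s) for s in t.surfaces()]
    chars = [c for w in words for c in w]
    ttr_words = len(set(words)) / len(words)
    ttr_chars = len(set(chars)) / len(chars) if chars else 0.0
    return ttr_words, ttr_chars


def info_word_ratio(
    t: TaggedTranscript, tag_classes: Mapping[str, Sequence[str]] | None = None
) -> float:
    """Fraction of tokens that are nouns, verbs, adjectives or numerals."""
    if len(t) == 0:
        raise ValueError("empty transcript")
    classes = t.tag_classes(tag_classes)
    return sum(c in INFO_WORD_CLASSES for c in classes) / len(classes)


def extract_linguistic(
    t: TaggedTranscript,
    lex: IULexicon | None = None,
    tag_classes: Mapping[str, Sequence[str]] | None = None,
) -> LinguisticFeatures:
    """Assemble the 10-value linguistic feature vector for one transcript."""
    if len(t) == 0:
        raise ValueError("empty transcript")
    noun, verb, pron = pos_ratios(t, tag_classes)
    ttr_w, ttr_c = ttr(t)
    iwr = info_word_ratio(t, tag_classes)
    iu = count_info_units(t, lex)
    return LinguisticFeatures(
        noun_ratio=noun,
        verb_ratio=verb,
        pronoun_ratio=pron,
        ttr_words=ttr_w,
        ttr_chars=ttr_c,
        info_word_ratio=iwr,
        iu_people=iu["people"],
        iu_objects=iu["objects"],
        iu_places=iu["places"],
        iu_actions=iu["actions"],
    )


class LinguisticFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: tagged transcripts -> 10-column feature frame."""

    def __init__(self, lexicon: IULexicon | None = None, tag_classes: dict | None = None):
        self.lexicon = lexicon
        self.tag_classes = tag_classes

    def fit(self, X: Sequence[TaggedTranscript], y=None):  # noqa: N803 - sklearn API
        return self

    def transform(self, X: Sequence[TaggedTranscript]) -> pd.DataFrame:  # noqa: N803
        lex = self.lexicon or IULexicon.default()
        rows = []
        for t in X:
            feats = extract_linguistic(t, lex, self.tag_classes)
            rows.append({"subject_id": t.subject_id, **dict(zip(LINGUISTIC_COLUMNS, feats.to_list()))})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transcript I/O: JSON-lines (one utterance per line) and two-column text


def read_transcripts_jsonl(path: str | Path) -> list[TaggedTranscript]:
    """Read JSON-lines transcripts: {"subject_id": ..., "tokens": [[surface, tag], ...]}.

    Lines sharing a subject_id are concatenated in file order.
    """
    per_subject: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            per_subject.setdefault(str(rec["subject_id"]), []).extend(rec["tokens"])
    return [TaggedTranscript(toks, subject_id=sid) for sid, toks in per_subject.items()]


def write_transcripts_jsonl(path: str | Path, transcripts: Iterable[TaggedTranscript]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in transcripts:
            rec = {"subject_id": t.subject_id, "tokens": [[tok.surface, tok.tag] for tok in t.tokens]}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_transcript_conll(path: str | Path, subject_id: str = "") -> TaggedTranscript:
    """Read a CoNLL-like two-column file (surface<TAB>tag, blank lines ignored)."""
    toks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed transcript line: {line!r}")
            toks.append((parts[0], parts[1]))
    return TaggedTranscript(toks, subject_id=subject_id or Path(path).stem)
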