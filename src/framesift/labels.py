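"""Canonical emotion vocabulary and label canonicalization.

Frame labels live in a closed vocabulary: the six Ekman universal
emotions that survive the anger/contempt merge, plus a neutral class.
Rater files and commercial classifier responses use divergent vocabularies
(``happiness``, ``fear``, ``CALM`` ...); every label entering the system
passes through a :class:`LabelMapping` that either canonicalizes it or
marks it for discard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Union


class VocabularyError(ValueError):
    """A label term has no canonical mapping."""


class SchemaError(ValueError):
    """An input file violates its documented schema."""


class EmotionLabel(str, enum.Enum):
    """The seven canonical frame-label classes."""

    NEUTRAL = "neutral"
    HAPPY = "happy"
    SAD = "sad"
    SURPRISED = "surprised"
    SCARED = "scared"
    DISGUSTED = "disgusted"
    ANGRY = "angry"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical label order used for reports and confusion matrices.
CANONICAL_EMOTIONS: tuple[EmotionLabel, ...] = tuple(EmotionLabel)


class _Discard:
    """Sentinel: the term is recognized but its frames are dropped."""

    _instance = None

    def __new__(cls) -> "_Discard":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DISCARD"


DISCARD = _Discard()

MappedLabel = Union[EmotionLabel, _Discard]


def _default_entries() -> dict[str, MappedLabel]:
    entries: dict[str, MappedLabel] = {e.value: e for e in EmotionLabel}
    entries.update(
        {
            # anger and contempt are merged into a single class; confusion
            # is dropped (not supported by every classifier, never prompted)
            "anger": EmotionLabel.ANGRY,
            "contempt": EmotionLabel.ANGRY,
            "confusion": DISCARD,
            "confused": DISCARD,
            # common provider/rater synonyms
            "calm": EmotionLabel.NEUTRAL,
            "happiness": EmotionLabel.HAPPY,
            "joy": EmotionLabel.HAPPY,
            "sadness": EmotionLabel.SAD,
            "surprise": EmotionLabel.SURPRISED,
            "fear": EmotionLabel.SCARED,
            "afraid": EmotionLabel.SCARED,
            "disgust": EmotionLabel.DISGUSTED,
        }
    )
    return entries


@dataclass(frozen=True)
class LabelMapping:
    """Mapping from raw vocabulary terms to canonical labels (or DISCARD).

    Lookup is case- and whitespace-insensitive. The mapping is idempotent:
    every canonical value maps to itself.
    """

    entries: Mapping[str, MappedLabel] = field(default_factory=_default_entries)

    def __post_init__(self) -> None:
        normalized = {k.strip().lower(): v for k, v in self.entries.items()}
        for emotion in EmotionLabel:  # identity on canonical values
            normalized.setdefault(emotion.value, emotion)
        object.__setattr__(self, "entries", normalized)

    def canonical(self, term: str | EmotionLabel) -> MappedLabel:
        """Map *term* to its canonical label, raising on unknown terms."""
        if isinstance(term, EmotionLabel):
            return term
        key = term.strip().lower()
        try:
            return self.entries[key]
        except KeyError:
            raise VocabularyError(f"unknown emotion term: {term!r}") from None

    def contains(self, term: str) -> bool:
        return term.strip().lower() in self.entries

    def with_entries(self, extra: Mapping[str, MappedLabel]) -> "LabelMapping":
        merged = dict(self.entries)
        merged.update({k.strip().lower(): v for k, v in extra.items()})
        return LabelMapping(merged)


def default_mapping() -> LabelMapping:
    """The mapping used throughout unless a caller supplies its own."""
    return LabelMapping()
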