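"""Sentence screening for PTL-evaluation indicators and NegEx-style context
classification.

A sentence is screened against the five keyword categories (preterm labor,
fetal fibronectin, transvaginal ultrasound, abdominal pain, uterine
contraction).  Each match is then classified as affirmed, negated, historical,
uncertain or general by scanning for context triggers whose forward scope
window covers the match; only affirmed matches become
:class:`IndicatorHit` evidence.

Phrases from the explicit-description list (e.g. "ruled out ptl") bypass
context classification entirely: grammatically negative or not, they record
that a PTL evaluation took place and are affirmed evidence by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .lexicon import CATEGORY_TO_INDICATOR, KEYWORD_CATEGORIES, ContextTriggerSet, Lexicon
from .preprocess import Sentence

__all__ = [
    "SentenceMatch",
    "IndicatorHit",
    "ContextLabelValue",
    "screen_sentence",
    "classify_context",
    "detect_note_indicators",
    "find_phrase_matches",
]

ContextLabelValue = Literal["affirmed", "negated", "historical", "uncertain", "general"]

_PUNCT = {",", ":", "."}


@dataclass(frozen=True)
class SentenceMatch:
    """A keyword-category phrase matched token-aligned in a sentence."""

    sentence: Sentence
    category: str
    phrase: str
    token_pos: int

    def __post_init__(self) -> None:
        if not 0 <= self.token_pos < len(self.sentence.tokens):
            raise ValueError("token_pos outside sentence")


@dataclass(frozen=True)
class IndicatorHit:
    """An affirmed PTL-evaluation indicator found in a note sentence."""

    note_id: str
    indicator: str
    evidence: SentenceMatch
    context: ContextLabelValue = "affirmed"


def find_phrase_matches(
    tokens: Sequence[str], phrases: Iterable[str]
) -> list[tuple[int, str]]:
    """Token-aligned greedy longest-match scan for *phrases* over *tokens*.

    At each position the longest matching phrase (split on whitespace) wins
    and consumes its tokens; returns ``(start_position, phrase)`` pairs in
    sentence order.  Tokenized phrase comparison makes matching word-boundary
    safe ("cl" never matches inside "clear").
    """
    split = sorted((p.split(), p) for p in phrases)
    split.sort(key=lambda sp: len(sp[0]), reverse=True)
    matches: list[tuple[int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        for phrase_tokens, phrase in split:
            if list(tokens[i : i + len(phrase_tokens)]) == phrase_tokens:
                matches.append((i, phrase))
                i += len(phrase_tokens)
                break
        else:
            i += 1
    return matches


def screen_sentence(sentence: Sentence, lexicon: Lexicon) -> list[SentenceMatch]:
    """All keyword-category matches in a sentence, in (position, category) order.

    An empty list means the sentence carries no predefined keyword and is not
    passed on for further processing.
    """
    out: list[SentenceMatch] = []
    for category in KEYWORD_CATEGORIES:
        for pos, phrase in find_phrase_matches(
            sentence.tokens, lexicon.keywords[category].phrases
        ):
            out.append(SentenceMatch(sentence, category, phrase, pos))
    out.sort(key=lambda m: (m.token_pos, m.category))
    return out


def classify_context(
    match: SentenceMatch, triggers: ContextTriggerSet
) -> ContextLabelValue:
    """Label a match by the nearest trigger whose scope covers it.

    A pre-trigger governs the ``scope_window`` tokens after its last token; a
    post-trigger (a qualifier following the finding, e.g. "uninterpretable")
    governs the ``scope_window`` tokens before its first token.  Scopes stop
    early at a comma, colon or period.  When several triggers cover the match,
    the nearest one wins; on equal distance the preceding trigger wins.  With
    no covering trigger the match is affirmed.
    """
    tokens = match.sentence.tokens
    directory: dict[str, tuple[ContextLabelValue, str]] = {}
    for phrase, label, direction in triggers.labelled():
        directory.setdefault(phrase, (label, direction))  # type: ignore[arg-type]
    best: tuple[int, int, ContextLabelValue] | None = None
    for pos, phrase in find_phrase_matches(tokens, directory):
        label, direction = directory[phrase]
        if direction == "pre":
            end = pos + len(phrase.split()) - 1
            if end >= match.token_pos:
                continue
            covered_to = min(end + triggers.scope_window, len(tokens) - 1)
            for j in range(end + 1, covered_to + 1):
                if tokens[j] in _PUNCT:
                    covered_to = j - 1
                    break
            if match.token_pos > covered_to:
                continue
            candidate = (match.token_pos - end, 0, label)
        else:
            if pos <= match.token_pos:
                continue
            covered_from = max(pos - triggers.scope_window, 0)
            for j in range(pos - 1, covered_from - 1, -1):
                if tokens[j] in _PUNCT:
                    covered_from = j + 1
                    break
            if match.token_pos < covered_from:
                continue
            candidate = (pos - match.token_pos, 1, label)
        if best is None or candidate[:2] < best[:2]:
            best = candidate
    return best[2] if best else "affirmed"


def detect_note_indicators(
    sentences: Sequence[Sentence], lexicon: Lexicon
) -> list[IndicatorHit]:
    """Affirmed indicator hits for one preprocessed note.

    Emits at most one hit per (sentence, indicator), ordered by sentence index
    then token position.  Explicit-description phrases are emitted as affirmed
    ``explicit_ptl_description`` evidence without context classification.
    """
    hits: list[IndicatorHit] = []
    for sentence in sentences:
        seen: set[str] = set()
        explicit = find_phrase_matches(sentence.tokens, lexicon.explicit_descriptions)
        if explicit:
            pos, phrase = explicit[0]
            hits.append(
                IndicatorHit(
                    note_id=sentence.note_id,
                    indicator="explicit_ptl_description",
                    evidence=SentenceMatch(sentence, "preterm_labor", phrase, pos),
                )
            )
            seen.add("explicit_ptl_description")
        for match in screen_sentence(sentence, lexicon):
            indicator = CATEGORY_TO_INDICATOR[match.category]
            if indicator in seen:
                continue
            if classify_context(match, lexicon.context_triggers) == "affirmed":
                hits.append(IndicatorHit(sentence.note_id, indicator, match))
                seen.add(indicator)
    return hits
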