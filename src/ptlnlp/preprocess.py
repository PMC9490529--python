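"""Note-text preprocessing: normalization, sentence segmentation, tokenization
and term standardization.

The chain is deliberately regex-rule based (no statistical models) so every
downstream match is auditable and deterministic.  Normalization lowercases and
reduces the character set to letters, digits, spaces, periods, commas and
colons; a hyphen survives only between two digits, because range expressions
like ``2.6-2.7`` carry measurement information while all other hyphens are
noise.  Removed characters become spaces so token boundaries are never fused.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .lexicon import CorrectionMap

__all__ = [
    "Sentence",
    "normalize_text",
    "segment_sentences",
    "tokenize",
    "standardize_terms",
    "preprocess_text",
]

_KEEP = set("abcdefghijklmnopqrstuvwxyz0123456789 .,:")

# letters | numeric literal (one optional internal decimal point) | punctuation
_TOKEN_RE = re.compile(r"[a-z]+|\d+(?:\.\d+)?|[.,:\-]")

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Sentence:
    """A segmented sentence of a normalized note."""

    note_id: str
    index: int
    tokens: tuple[str, ...]
    char_span: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.char_span
        if start > end:
            raise ValueError("char_span start exceeds end")


def normalize_text(raw: str) -> str:
    """Lowercase *raw* and restrict it to the kept character set.

    Kept: letters, digits, space, period, comma, colon, and hyphens flanked by
    digits.  Every removed character becomes a single space; whitespace runs
    collapse to one space; the result is stripped.  Idempotent.
    """
    lowered = raw.lower()
    out = []
    for i, ch in enumerate(lowered):
        if ch in _KEEP:
            out.append(ch)
        elif ch == "-" and 0 < i < len(lowered) - 1 and lowered[i - 1].isdigit() and lowered[i + 1].isdigit():
            out.append(ch)
        else:
            out.append(" ")
    return _WS_RE.sub(" ", "".join(out)).strip()


def segment_sentences(normalized: str) -> list[tuple[int, int]]:
    """Split normalized text into sentence character spans.

    A period followed by whitespace and a letter ends a sentence; a period
    between two digits is a decimal point and never splits.  Text without a
    terminator is a single sentence.  Spans cover the text completely except
    for the inter-sentence whitespace.
    """
    if not normalized:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(normalized)
    while i < n:
        if normalized[i] == ".":
            prev_digit = i > 0 and normalized[i - 1].isdigit()
            next_digit = i + 1 < n and normalized[i + 1].isdigit()
            if prev_digit and next_digit:
                i += 1
                continue
            # look past the period for whitespace + letter
            j = i + 1
            while j < n and normalized[j].isspace():
                j += 1
            if j > i + 1 and j < n and normalized[j].isalpha():
                spans.append((start, i + 1))
                start = j
                i = j
                continue
        i += 1
    if start < n:
        spans.append((start, n))
    return spans


def tokenize(sentence_text: str) -> list[str]:
    """Tokenize normalized sentence text.

    Tokens are maximal letter runs, numeric literals (digits with at most one
    internal decimal point) and standalone punctuation (period, comma, colon,
    hyphen).  A sentence-final period is its own token and is never absorbed
    into a preceding number.
    """
    return _TOKEN_RE.findall(sentence_text)


def standardize_terms(tokens: list[str], corrections: CorrectionMap) -> list[str]:
    """Apply phrase-level corrections with leftmost longest-match semantics.

    Idempotent for any validated :class:`~ptlnlp.lexicon.CorrectionMap` (map
    values are fixpoints by construction).
    """
    if not corrections.entries:
        return list(tokens)
    keyed = [(k.split(), v.split()) for k, v in corrections.entries.items()]
    keyed.sort(key=lambda kv: len(kv[0]), reverse=True)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        for key, value in keyed:
            if tokens[i : i + len(key)] == key:
                out.extend(value)
                i += len(key)
                break
        else:
            out.append(tokens[i])
            i += 1
    return out


def preprocess_text(
    raw: str, corrections: CorrectionMap, note_id: str = ""
) -> list[Sentence]:
    """Full chain: normalize, segment, tokenize, standardize.

    Returns :class:`Sentence` objects whose ``char_span`` indexes into the
    normalized note text and whose tokens are post-standardization.  Sentences
    that tokenize to nothing are dropped.
    """
    normalized = normalize_text(raw)
    sentences: list[Sentence] = []
    for start, end in segment_sentences(normalized):
        tokens = standardize_terms(tokenize(normalized[start:end]), corrections)
        if not tokens:
            continue
        sentences.append(
            Sentence(
                note_id=note_id,
                index=len(sentences),
                tokens=tuple(tokens),
                char_span=(start, end),
            )
        )
    return sentences
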