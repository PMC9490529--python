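"""Cervical-length (CL) extraction from clinical notes of identified PTL visits.

The extractor searches preprocessed sentences for CL keywords in three
priority tiers, captures numeric value expressions near each keyword (forward
within 10 tokens, else backward within 5), rejects values bound to non-CL
concepts (dilation, effacement, station, fluid pockets, heart rate), resolves
one measurement per note by keyword priority and the shortest-value rule, and
standardizes to centimeters: a missing unit means cm, millimeter values are
divided by 10, and ranges or multiple values collapse to their arithmetic
mean.  Per visit, a delivery encounter keeps the first measurement and any
other encounter keeps the measurement closest to discharge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

from .indicators import find_phrase_matches
from .lexicon import Lexicon
from .preprocess import Sentence, preprocess_text
from .visits import ClinicalNote, PTLVisit

__all__ = [
    "RawMeasurement",
    "NoteCL",
    "VisitCL",
    "find_cl_keywords",
    "search_values",
    "standardize_cl",
    "select_note_cl",
    "select_visit_cl",
    "extract_note_cl",
    "extract_visit_cl",
]

logger = logging.getLogger(__name__)

UNIT_TOKENS = {
    "cm": "cm",
    "centimeter": "cm",
    "centimeters": "cm",
    "mm": "mm",
    "millimeter": "mm",
    "millimeters": "mm",
}

FORWARD_WINDOW = 10   # tokens after the keyword's last token
BACKWARD_WINDOW = 5   # tokens before the keyword's first token


@dataclass(frozen=True)
class RawMeasurement:
    """A captured numeric value expression, prior to standardization."""

    note_id: str
    keyword: str
    priority: int
    direction: str                  # "forward" | "backward"
    values: tuple[float, ...]
    unit: str | None                # "cm" | "mm" | None
    token_pos: int                  # position of the first captured value
    is_range: bool = False

    def __post_init__(self) -> None:
        if not self.values or any(v <= 0 for v in self.values):
            raise ValueError("values must be non-empty and positive")
        if self.is_range and len(self.values) != 2:
            raise ValueError("a range must have exactly 2 values")


@dataclass(frozen=True)
class NoteCL:
    note_id: str
    note_datetime: datetime
    cl_cm: float
    provenance: RawMeasurement

    def __post_init__(self) -> None:
        if self.cl_cm <= 0:
            raise ValueError("cl_cm must be positive")


@dataclass(frozen=True)
class VisitCL:
    visit_id: str
    pregnancy_id: str
    cl_cm: float
    selection_rule: str             # "first_measure" | "closest_to_discharge"
    note_id: str


def find_cl_keywords(
    sentence: Sentence, lexicon: Lexicon
) -> list[tuple[str, int, int]]:
    """All CL keyword matches in a sentence as ``(phrase, priority, token_pos)``.

    Matching is token-aligned and longest-match over the union of the three
    priority groups, so "cl" never fires inside "clear" and "cervical length"
    outranks a bare "cervix" at the same position.
    """
    priority_of = {
        phrase: group.priority
        for group in lexicon.cl_priority_groups
        for phrase in group.phrases
    }
    return [
        (phrase, priority_of[phrase], pos)
        for pos, phrase in find_phrase_matches(sentence.tokens, priority_of)
    ]


def _is_number(token: str) -> bool:
    return bool(token) and token[0].isdigit()


def _parse_expression(
    tokens: Sequence[str], i: int
) -> tuple[tuple[float, ...], bool, str | None, int]:
    """Parse a value expression starting at numeric token *i*.

    Returns ``(values, is_range, unit, end_index_exclusive)``.  Grammar:
    ``N (- N | to N | N*) unit?`` — a hyphen or "to" joins two numbers into a
    range; bare adjacent numbers accumulate as multiple values; a trailing
    unit token binds to the expression.
    """
    values = [float(tokens[i])]
    j = i + 1
    is_range = False
    if j + 1 < len(tokens) and tokens[j] in ("-", "to") and _is_number(tokens[j + 1]):
        values.append(float(tokens[j + 1]))
        is_range = True
        j += 2
    else:
        while j < len(tokens) and _is_number(tokens[j]):
            values.append(float(tokens[j]))
            j += 1
    unit = None
    if j < len(tokens) and tokens[j] in UNIT_TOKENS:
        unit = UNIT_TOKENS[tokens[j]]
        j += 1
    return tuple(values), is_range, unit, j


def _excluded(tokens: Sequence[str], start: int, end: int, lexicon: Lexicon) -> bool:
    """True if the expression spanning ``tokens[start:end]`` sits within the
    configured neighborhood of an exclusion term (dilation, effacement, ...)."""
    w = lexicon.cl_exclusion_window
    lo = max(0, start - w)
    hi = min(len(tokens), end + w)
    return bool(find_phrase_matches(tokens[lo:hi], lexicon.cl_exclusion_terms))


def search_values(
    sentence: Sentence,
    keyword_pos: int,
    keyword_len: int,
    keyword: str,
    priority: int,
    lexicon: Lexicon,
) -> RawMeasurement | None:
    """Capture the value expression associated with a CL keyword match.

    Scans forward from the token after the keyword, starting within
    ``FORWARD_WINDOW`` tokens; if no admissible expression is found (including
    when every candidate was rejected as a non-CL measure), scans backward
    within ``BACKWARD_WINDOW`` tokens before the keyword and keeps the
    expression nearest the keyword.  Returns ``None`` when both scans fail.
    """
    tokens = sentence.tokens
    k_end = keyword_pos + keyword_len - 1

    # forward
    i = k_end + 1
    limit = min(len(tokens), k_end + 1 + FORWARD_WINDOW)
    while i < limit:
        if _is_number(tokens[i]):
            values, is_range, unit, j = _parse_expression(tokens, i)
            if not _excluded(tokens, i, j, lexicon):
                return RawMeasurement(
                    note_id=sentence.note_id,
                    keyword=keyword,
                    priority=priority,
                    direction="forward",
                    values=values,
                    unit=unit,
                    token_pos=i,
                    is_range=is_range,
                )
            i = j
        else:
            i += 1

    # backward
    lo = max(0, keyword_pos - BACKWARD_WINDOW)
    found: RawMeasurement | None = None
    i = lo
    while i < keyword_pos:
        if _is_number(tokens[i]):
            values, is_range, unit, j = _parse_expression(tokens, i)
            if not _excluded(tokens, i, j, lexicon):
                found = RawMeasurement(
                    note_id=sentence.note_id,
                    keyword=keyword,
                    priority=priority,
                    direction="backward",
                    values=values,
                    unit=unit,
                    token_pos=i,
                    is_range=is_range,
                )
            i = j
        else:
            i += 1
    return found


def standardize_cl(m: RawMeasurement) -> float:
    """Standardize a raw measurement to centimeters.

    No unit defaults to cm; mm values are divided by 10; a range or multiple
    values collapse to their arithmetic mean.  Rounded to 2 decimals, the
    resolution at which values are compared for distinctness.
    """
    scale = 0.1 if m.unit == "mm" else 1.0
    converted = [v * scale for v in m.values]
    return round(sum(converted) / len(converted), 2)


def select_note_cl(
    measurements: Sequence[RawMeasurement],
    note_id: str,
    note_datetime: datetime,
    lexicon: Lexicon,
) -> NoteCL | None:
    """Resolve one CL per note: highest keyword priority wins; among distinct
    standardized values in that tier the shortest is kept.

    Standardized values outside the plausible range are logged and dropped.
    """
    lo, hi = lexicon.cl_plausible_range_cm
    plausible: list[tuple[float, RawMeasurement]] = []
    for m in measurements:
        cl = standardize_cl(m)
        if lo < cl <= hi:
            plausible.append((cl, m))
        else:
            logger.warning(
                "note %s: dropped implausible CL %.2f cm (keyword %r)",
                note_id, cl, m.keyword,
            )
    if not plausible:
        return None
    top = min(m.priority for _, m in plausible)
    tier = [(cl, m) for cl, m in plausible if m.priority == top]
    cl, m = min(tier, key=lambda cm: (cm[0], cm[1].token_pos))
    return NoteCL(note_id=note_id, note_datetime=note_datetime, cl_cm=cl, provenance=m)


def select_visit_cl(
    note_cls: Sequence[NoteCL], visit: PTLVisit
) -> VisitCL | None:
    """Resolve one CL per visit from its notes' CLs.

    Delivery visits keep the first (earliest-note) measurement; other visits
    keep the measurement closest to discharge, preferring measurements at or
    before discharge, then later timestamps, then lower note ids.
    """
    if not note_cls:
        return None
    if visit.is_delivery:
        rule = "first_measure"
        chosen = min(note_cls, key=lambda n: (n.note_datetime, n.note_id))
    else:
        rule = "closest_to_discharge"
        chosen = min(
            note_cls,
            key=lambda n: (
                n.note_datetime > visit.discharge,
                abs(visit.discharge - n.note_datetime),
                -n.note_datetime.timestamp(),
                n.note_id,
            ),
        )
    return VisitCL(
        visit_id=visit.visit_id,
        pregnancy_id=visit.pregnancy_id,
        cl_cm=chosen.cl_cm,
        selection_rule=rule,
        note_id=chosen.note_id,
    )


def extract_note_cl(
    note: ClinicalNote, lexicon: Lexicon
) -> tuple[NoteCL | None, list[RawMeasurement]]:
    """Run keyword search, value capture and per-note selection on one note."""
    measurements: list[RawMeasurement] = []
    for sentence in preprocess_text(note.text, lexicon.corrections, note.note_id):
        for phrase, priority, pos in find_cl_keywords(sentence, lexicon):
            m = search_values(sentence, pos, len(phrase.split()), phrase, priority, lexicon)
            if m is not None:
                measurements.append(m)
    note_cl = select_note_cl(measurements, note.note_id, note.note_datetime, lexicon)
    return note_cl, measurements


def extract_visit_cl(
    visit: PTLVisit, notes: Sequence[ClinicalNote], lexicon: Lexicon
) -> tuple[VisitCL | None, list[NoteCL], list[RawMeasurement]]:
    """Extract the final standardized CL for one visit.

    *notes* may be the full note table; only notes of the visit's member
    encounters with an allowed note type are searched.
    """
    members = set(visit.member_encounters)
    note_cls: list[NoteCL] = []
    raws: list[RawMeasurement] = []
    for note in sorted(notes, key=lambda n: (n.note_datetime, n.note_id)):
        if note.encounter_id not in members:
            continue
        if not lexicon.note_filter.allows(note.note_type):
            continue
        note_cl, measurements = extract_note_cl(note, lexicon)
        raws.extend(measurements)
        if note_cl is not None:
            note_cls.append(note_cl)
    return select_visit_cl(note_cls, visit), note_cls, raws
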