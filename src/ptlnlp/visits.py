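"""Identification of preterm-labor evaluation visits.

Combines four stages: structured-code screening of triage/hospital encounters
inside the gestational window (24\\ :sup:`0/7`\\ –34\\ :sup:`6/7` weeks, days
168–244), note-derived indicator evidence, exclusion rules (diagnosis-code-only
encounters; delivery encounters with a pre-eclampsia/eclampsia diagnosis), and
consolidation of time-overlapping encounters into single visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

from .indicators import IndicatorHit, detect_note_indicators
from .lexicon import Lexicon, match_code
from .preprocess import preprocess_text

__all__ = [
    "PregnancyEpisode",
    "Encounter",
    "ClinicalNote",
    "CandidateFlags",
    "EncounterDecision",
    "PTLVisit",
    "GESTATIONAL_WINDOW_DAYS",
    "gestational_age_days",
    "in_gestational_window",
    "screen_structured",
    "classify_encounter",
    "consolidate_visits",
    "first_visit_per_pregnancy",
    "identify_visits",
]

#: default gestational window, inclusive day bounds (24^0/7 .. 34^6/7 weeks)
GESTATIONAL_WINDOW_DAYS = (168, 244)

#: encounter settings whose notes count as PTL-evaluation settings
ELIGIBLE_SETTINGS = ("triage", "hospital")

FLAG_EVIDENCE = {
    "has_ffn_order": "ffn_order",
    "has_tvus_proc": "tvus_proc",
    "has_ptl_dx": "ptl_dx",
    "has_ptl_med": "ptl_med",
}


@dataclass(frozen=True)
class PregnancyEpisode:
    pregnancy_id: str
    start_date: date          # gestational day 0
    delivery_datetime: datetime
    outcome: str = "livebirth"

    def __post_init__(self) -> None:
        if self.delivery_datetime.date() <= self.start_date:
            raise ValueError(f"pregnancy {self.pregnancy_id}: delivery precedes start")
        if (self.delivery_datetime.date() - self.start_date).days >= 350:
            raise ValueError(
                f"pregnancy {self.pregnancy_id}: gestational age at delivery >= 350 days"
            )


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    pregnancy_id: str
    admit: datetime
    discharge: datetime
    setting: str              # triage | hospital | other
    is_delivery: bool = False
    dx_codes: tuple[str, ...] = ()
    proc_codes: tuple[str, ...] = ()
    lab_codes: tuple[str, ...] = ()
    med_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.admit > self.discharge:
            raise ValueError(f"encounter {self.encounter_id}: admit after discharge")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    encounter_id: str
    note_type: str
    note_datetime: datetime
    text: str


@dataclass(frozen=True)
class CandidateFlags:
    """Structured-data screening flags for one encounter."""

    has_ffn_order: bool = False
    has_tvus_proc: bool = False
    has_ptl_dx: bool = False
    has_ptl_med: bool = False

    def any(self) -> bool:
        return self.has_ffn_order or self.has_tvus_proc or self.has_ptl_dx or self.has_ptl_med

    def evidence(self) -> frozenset[str]:
        return frozenset(
            label for attr, label in FLAG_EVIDENCE.items() if getattr(self, attr)
        )


@dataclass(frozen=True)
class EncounterDecision:
    encounter: Encounter
    decision: str             # ptl_visit | excluded_dx_only | excluded_preeclampsia_delivery | not_ptl
    flags: CandidateFlags
    hits: tuple[IndicatorHit, ...] = ()

    @property
    def evidence(self) -> frozenset[str]:
        return self.flags.evidence() | {h.indicator for h in self.hits}


@dataclass(frozen=True)
class PTLVisit:
    """A consolidated PTL evaluation visit (one or more merged encounters)."""

    pregnancy_id: str
    admit: datetime
    discharge: datetime
    member_encounters: tuple[str, ...]
    evidence: frozenset[str]
    is_delivery: bool
    gestational_age_days: int
    hits: tuple[IndicatorHit, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("PTLVisit requires at least one evidence item")

    @property
    def visit_id(self) -> str:
        return min(self.member_encounters)

    def has_ffn(self) -> bool:
        return bool(self.evidence & {"ffn_order", "ffn_performed"})

    def has_tvus(self) -> bool:
        return bool(self.evidence & {"tvus_proc", "tvus_performed"})


def gestational_age_days(event: datetime | date, episode: PregnancyEpisode) -> int:
    """Whole days from pregnancy start (gestational day 0) to *event*."""
    event_date = event.date() if isinstance(event, datetime) else event
    days = (event_date - episode.start_date).days
    if days < 0:
        raise ValueError(
            f"event {event_date} precedes pregnancy start {episode.start_date}"
        )
    return days


def in_gestational_window(
    days: int, window: tuple[int, int] = GESTATIONAL_WINDOW_DAYS
) -> bool:
    return window[0] <= days <= window[1]


def screen_structured(encounter: Encounter, lexicon: Lexicon) -> CandidateFlags:
    """Four structured-evidence booleans from the encounter's code lists."""

    def hit(codes: tuple[str, ...], set_name: str) -> bool:
        cs = lexicon.code_sets[set_name]
        return any(match_code(c, cs) for c in codes if c)

    return CandidateFlags(
        has_ffn_order=hit(encounter.lab_codes, "ffn_lab"),
        has_tvus_proc=hit(encounter.proc_codes, "tvus_proc"),
        has_ptl_dx=hit(encounter.dx_codes, "ptl_dx"),
        has_ptl_med=hit(encounter.med_codes, "ptl_med"),
    )


def classify_encounter(
    encounter: Encounter,
    flags: CandidateFlags,
    hits: Sequence[IndicatorHit],
    lexicon: Lexicon,
) -> EncounterDecision:
    """Apply the combination and exclusion rules to one candidate encounter.

    ``ptl_visit`` requires any structured flag or affirmed indicator hit, and
    survives two exclusions: a delivery encounter carrying a
    pre-eclampsia/eclampsia diagnosis, and an encounter whose only evidence is
    the PTL diagnosis code.
    """
    hits = tuple(hits)
    if not flags.any() and not hits:
        decision = "not_ptl"
    elif encounter.is_delivery and _has_preeclampsia(encounter, lexicon):
        decision = "excluded_preeclampsia_delivery"
    elif (
        flags.has_ptl_dx
        and not (flags.has_ffn_order or flags.has_tvus_proc or flags.has_ptl_med)
        and not hits
    ):
        decision = "excluded_dx_only"
    else:
        decision = "ptl_visit"
    return EncounterDecision(encounter, decision, flags, hits)


def _has_preeclampsia(encounter: Encounter, lexicon: Lexicon) -> bool:
    cs = lexicon.code_sets["preeclampsia_dx"]
    return any(match_code(c, cs) for c in encounter.dx_codes if c)


def consolidate_visits(
    decisions: Iterable[EncounterDecision],
    episodes: Mapping[str, PregnancyEpisode],
) -> list[PTLVisit]:
    """Merge time-overlapping ``ptl_visit`` encounters per pregnancy.

    Overlap is closed-interval (a shared boundary instant merges) and
    transitive.  The merged visit takes the earliest admit, the latest
    discharge, the union of evidence, and is a delivery visit if any member
    is.  Output is sorted by (pregnancy, admit) and pairwise disjoint within
    each pregnancy; idempotent and input-order invariant.
    """
    accepted = sorted(
        (d for d in decisions if d.decision == "ptl_visit"),
        key=lambda d: (d.encounter.pregnancy_id, d.encounter.admit, d.encounter.encounter_id),
    )
    visits: list[PTLVisit] = []
    group: list[EncounterDecision] = []

    def flush() -> None:
        if not group:
            return
        admit = min(d.encounter.admit for d in group)
        discharge = max(d.encounter.discharge for d in group)
        pregnancy_id = group[0].encounter.pregnancy_id
        evidence: frozenset[str] = frozenset().union(*(d.evidence for d in group))
        visits.append(
            PTLVisit(
                pregnancy_id=pregnancy_id,
                admit=admit,
                discharge=discharge,
                member_encounters=tuple(
                    sorted(d.encounter.encounter_id for d in group)
                ),
                evidence=evidence,
                is_delivery=any(d.encounter.is_delivery for d in group),
                gestational_age_days=gestational_age_days(admit, episodes[pregnancy_id]),
                hits=tuple(h for d in group for h in d.hits),
            )
        )

    current_end: datetime | None = None
    current_pid: str | None = None
    for d in accepted:
        e = d.encounter
        if group and e.pregnancy_id == current_pid and e.admit <= current_end:
            group.append(d)
            current_end = max(current_end, e.discharge)
        else:
            flush()
            group = [d]
            current_pid = e.pregnancy_id
            current_end = e.discharge
    flush()
    return visits


def first_visit_per_pregnancy(visits: Iterable[PTLVisit]) -> list[PTLVisit]:
    """Earliest visit per pregnancy; ties broken by lowest member encounter id."""
    best: dict[str, PTLVisit] = {}
    for v in visits:
        cur = best.get(v.pregnancy_id)
        if cur is None or (v.admit, v.visit_id) < (cur.admit, cur.visit_id):
            best[v.pregnancy_id] = v
    return sorted(best.values(), key=lambda v: (v.pregnancy_id, v.admit))


def identify_visits(
    episodes: Sequence[PregnancyEpisode],
    encounters: Sequence[Encounter],
    notes: Sequence[ClinicalNote],
    lexicon: Lexicon,
    window: tuple[int, int] = GESTATIONAL_WINDOW_DAYS,
) -> tuple[list[PTLVisit], list[EncounterDecision]]:
    """Run the full visit-identification pipeline.

    Returns the consolidated :class:`PTLVisit` list and the per-encounter
    audit trail.  Encounters outside the gestational window or outside
    triage/hospital settings are screened out before any evidence is gathered
    and appear in the audit with decision ``not_ptl``.
    """
    episode_map = {ep.pregnancy_id: ep for ep in episodes}
    notes_by_encounter: dict[str, list[ClinicalNote]] = {}
    for note in notes:
        notes_by_encounter.setdefault(note.encounter_id, []).append(note)

    decisions: list[EncounterDecision] = []
    for enc in sorted(encounters, key=lambda e: (e.pregnancy_id, e.admit, e.encounter_id)):
        episode = episode_map.get(enc.pregnancy_id)
        if episode is None:
            raise KeyError(f"encounter {enc.encounter_id}: unknown pregnancy {enc.pregnancy_id}")
        if enc.setting not in ELIGIBLE_SETTINGS or not in_gestational_window(
            gestational_age_days(enc.admit, episode), window
        ):
            decisions.append(
                EncounterDecision(enc, "not_ptl", CandidateFlags(), ())
            )
            continue
        flags = screen_structured(enc, lexicon)
        hits: list[IndicatorHit] = []
        for note in sorted(
            notes_by_encounter.get(enc.encounter_id, ()),
            key=lambda n: (n.note_datetime, n.note_id),
        ):
            if not lexicon.note_filter.allows(note.note_type):
                continue
            sentences = preprocess_text(note.text, lexicon.corrections, note.note_id)
            hits.extend(detect_note_indicators(sentences, lexicon))
        decisions.append(classify_encounter(enc, flags, hits, lexicon))

    visits = consolidate_visits(decisions, episode_map)
    return visits, decisions
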