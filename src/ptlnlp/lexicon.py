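"""Configurable lexicon bundle: code sets, corrections, keywords, CL priority
groups, context triggers and note-type filters.

Every behavioural list used by the pipeline lives in one human-editable YAML
file so that sites can substitute their own terminology.  A versioned default
ships with the package (:func:`default_lexicon_path`).  Loading validates the
schema and the cross-list invariants and fails loudly, naming the offending
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CodeSet",
    "CorrectionMap",
    "KeywordSet",
    "PriorityGroup",
    "NoteTypeFilter",
    "ContextTriggerSet",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "default_lexicon_path",
    "match_code",
]

KEYWORD_CATEGORIES = (
    "preterm_labor",
    "fetal_fibronectin",
    "transvaginal_ultrasound",
    "abdominal_pain",
    "uterine_contraction",
)

#: indicator label emitted for an affirmed match in each keyword category
CATEGORY_TO_INDICATOR = {
    "preterm_labor": "explicit_ptl_description",
    "fetal_fibronectin": "ffn_performed",
    "transvaginal_ultrasound": "tvus_performed",
    "abdominal_pain": "abdominal_pain",
    "uterine_contraction": "uterine_contraction",
}

CODE_SYSTEMS = ("diagnosis", "procedure", "lab", "medication")

#: code-set roles the pipeline requires from every lexicon
REQUIRED_CODE_SETS = {
    "ptl_dx": "diagnosis",
    "ffn_lab": "lab",
    "tvus_proc": "procedure",
    "ptl_med": "medication",
    "preeclampsia_dx": "diagnosis",
}

WILDCARD = "*"


class LexiconError(ValueError):
    """Raised when a lexicon file is missing, unparseable or violates the schema."""


@dataclass(frozen=True)
class CodeSet:
    """A named set of structured codes; entries ending in ``*`` are prefixes."""

    name: str
    system: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconError("code_sets: empty set name")
        if self.system not in CODE_SYSTEMS:
            raise LexiconError(
                f"code_sets.{self.name}.system: {self.system!r} not one of {CODE_SYSTEMS}"
            )
        if not self.codes:
            raise LexiconError(f"code_sets.{self.name}.codes: must be non-empty")
        for c in self.codes:
            if not c or c == WILDCARD:
                raise LexiconError(f"code_sets.{self.name}.codes: invalid entry {c!r}")


def match_code(code: str, code_set: CodeSet) -> bool:
    """True iff *code* equals a listed code or matches a listed ``*`` prefix.

    Comparison is case-insensitive; structured EHR extracts are inconsistent
    about case in order mnemonics.
    """
    if not code:
        raise ValueError("code must be non-empty")
    code = code.strip().upper()
    for entry in code_set.codes:
        entry = entry.upper()
        if entry.endswith(WILDCARD):
            if code.startswith(entry[:-1]):
                return True
        elif code == entry:
            return True
    return False


@dataclass(frozen=True)
class CorrectionMap:
    """Phrase-level misspelling/abbreviation corrections.

    Keys and values are space-joined normalized token phrases.  Validation
    requires every value to be a fixpoint of the map, which makes application
    idempotent by construction.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if key != key.lower():
                raise LexiconError(f"corrections: key {key!r} must be lowercase")
            if key == value:
                raise LexiconError(f"corrections: key {key!r} maps to itself")
            if not key or not value:
                raise LexiconError("corrections: empty key or value")

    def validate_idempotent(self, apply) -> None:
        """Check each value survives *apply* (the standardizer) unchanged."""
        for key, value in self.entries.items():
            tokens = value.split()
            if apply(tokens, self) != tokens:
                raise LexiconError(
                    f"corrections: value {value!r} (for key {key!r}) is itself "
                    "rewritten by the map; chained rewrites break idempotence"
                )


@dataclass(frozen=True)
class KeywordSet:
    category: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in KEYWORD_CATEGORIES:
            raise LexiconError(f"keywords: unknown category {self.category!r}")
        _check_phrases(f"keywords.{self.category}", self.phrases)


@dataclass(frozen=True)
class PriorityGroup:
    priority: int
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.priority not in (1, 2, 3):
            raise LexiconError(f"cl_priority_groups: priority {self.priority} not in 1..3")
        _check_phrases(f"cl_priority_groups.{self.priority}", self.phrases)


@dataclass(frozen=True)
class NoteTypeFilter:
    allowed_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.allowed_types:
            raise LexiconError("note_types: must be non-empty")

    def allows(self, note_type: str) -> bool:
        return note_type.strip().lower() in self.allowed_types


@dataclass(frozen=True)
class ContextTriggerSet:
    """Pre-triggers govern the following tokens; post-triggers (qualifiers
    that follow a finding, e.g. "uninterpretable") govern the preceding
    tokens.  Both scopes span ``scope_window`` tokens and stop at
    comma/colon/period."""

    negation_triggers: tuple[str, ...]
    historical_triggers: tuple[str, ...]
    uncertainty_triggers: tuple[str, ...]
    general_triggers: tuple[str, ...]
    post_negation_triggers: tuple[str, ...] = ()
    post_uncertainty_triggers: tuple[str, ...] = ()
    scope_window: int = 6

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise LexiconError("context_triggers.scope_window: must be >= 1")
        for name in (
            "negation", "historical", "uncertainty", "general",
            "post_negation", "post_uncertainty",
        ):
            phrases = getattr(self, f"{name}_triggers")
            for p in phrases:
                if p != p.lower() or not p:
                    raise LexiconError(
                        f"context_triggers.{name}: phrase {p!r} must be lowercase, non-empty"
                    )

    def labelled(self) -> list[tuple[str, str, str]]:
        """(phrase, label, direction) for all trigger types."""
        out: list[tuple[str, str, str]] = []
        for label, attr, direction in (
            ("negated", "negation_triggers", "pre"),
            ("historical", "historical_triggers", "pre"),
            ("uncertain", "uncertainty_triggers", "pre"),
            ("general", "general_triggers", "pre"),
            ("negated", "post_negation_triggers", "post"),
            ("uncertain", "post_uncertainty_triggers", "post"),
        ):
            out.extend((p, label, direction) for p in getattr(self, attr))
        return out


def _check_phrases(where: str, phrases) -> None:
    if not phrases:
        raise LexiconError(f"{where}: must be non-empty")
    for p in phrases:
        if not p:
            raise LexiconError(f"{where}: empty phrase")
        if p != p.lower():
            raise LexiconError(f"{where}: phrase {p!r} must be lowercase")


@dataclass(frozen=True)
class Lexicon:
    """The full validated lexicon bundle served to every pipeline stage."""

    code_sets: Mapping[str, CodeSet]
    corrections: CorrectionMap
    keywords: Mapping[str, KeywordSet]
    explicit_descriptions: tuple[str, ...]
    context_triggers: ContextTriggerSet
    cl_priority_groups: tuple[PriorityGroup, ...]
    cl_exclusion_terms: tuple[str, ...]
    cl_exclusion_window: int = 3
    cl_plausible_range_cm: tuple[float, float] = (0.0, 10.0)
    note_filter: NoteTypeFilter = field(
        default_factory=lambda: NoteTypeFilter(frozenset({"triage note"}))
    )
    version: int = 1

    def __post_init__(self) -> None:
        for role, system in REQUIRED_CODE_SETS.items():
            if role not in self.code_sets:
                raise LexiconError(f"code_sets: missing required set {role!r}")
            if self.code_sets[role].system != system:
                raise LexiconError(
                    f"code_sets.{role}.system: expected {system!r}, "
                    f"got {self.code_sets[role].system!r}"
                )
        missing = set(KEYWORD_CATEGORIES) - set(self.keywords)
        if missing:
            raise LexiconError(f"keywords: missing categories {sorted(missing)}")
        if len(self.cl_priority_groups) != 3:
            raise LexiconError("cl_priority_groups: exactly 3 groups required")
        seen: dict[str, int] = {}
        for group in self.cl_priority_groups:
            for phrase in group.phrases:
                if phrase in seen:
                    raise LexiconError(
                        f"cl_priority_groups: phrase {phrase!r} appears in "
                        f"priorities {seen[phrase]} and {group.priority}"
                    )
                seen[phrase] = group.priority
        if self.cl_exclusion_window < 1:
            raise LexiconError("cl_exclusion_window: must be >= 1")
        lo, hi = self.cl_plausible_range_cm
        if not lo < hi:
            raise LexiconError("cl_plausible_range_cm: lower bound must be < upper")
        _check_phrases("explicit_descriptions", self.explicit_descriptions)

    def to_dict(self) -> dict:
        """Serialize back to the (normalized) config structure."""
        return {
            "version": self.version,
            "code_sets": {
                name: {"system": cs.system, "codes": sorted(cs.codes)}
                for name, cs in sorted(self.code_sets.items())
            },
            "corrections": dict(sorted(self.corrections.entries.items())),
            "keywords": {c: list(self.keywords[c].phrases) for c in KEYWORD_CATEGORIES},
            "explicit_descriptions": list(self.explicit_descriptions),
            "context_triggers": {
                "negation": list(self.context_triggers.negation_triggers),
                "historical": list(self.context_triggers.historical_triggers),
                "uncertainty": list(self.context_triggers.uncertainty_triggers),
                "general": list(self.context_triggers.general_triggers),
                "post_negation": list(self.context_triggers.post_negation_triggers),
                "post_uncertainty": list(self.context_triggers.post_uncertainty_triggers),
                "scope_window": self.context_triggers.scope_window,
            },
            "cl_priority_groups": {
                g.priority: list(g.phrases) for g in self.cl_priority_groups
            },
            "cl_exclusion_terms": list(self.cl_exclusion_terms),
            "cl_exclusion_window": self.cl_exclusion_window,
            "cl_plausible_range_cm": list(self.cl_plausible_range_cm),
            "note_types": sorted(self.note_filter.allowed_types),
        }


def default_lexicon_path() -> Path:
    """Path of the default lexicon YAML shipped with the package."""
    return Path(resources.files("ptlnlp").joinpath("data/default_lexicon.yaml"))


def load_lexicon(config_path: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon bundle from YAML.

    Parameters
    ----------
    config_path
        Path to a lexicon YAML file; ``None`` loads the shipped default.

    Raises
    ------
    LexiconError
        Missing file, unparseable YAML, or any schema/invariant violation
        (the message names the offending field).
    """
    path = Path(config_path) if config_path is not None else default_lexicon_path()
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough message
        raise LexiconError(f"lexicon file {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise LexiconError(f"lexicon file {path}: top level must be a mapping")
    return _build(raw)


def _build(raw: dict) -> Lexicon:
    def section(name: str, typ=dict):
        if name not in raw:
            raise LexiconError(f"missing section {name!r}")
        value = raw[name]
        if not isinstance(value, typ):
            raise LexiconError(f"section {name!r}: expected {typ.__name__}")
        return value

    code_sets = {
        str(name): CodeSet(
            name=str(name),
            system=str(body.get("system", "")),
            codes=frozenset(str(c) for c in body.get("codes", [])),
        )
        for name, body in section("code_sets").items()
    }
    corrections = CorrectionMap(
        {str(k): str(v) for k, v in section("corrections").items()}
    )
    keywords = {
        str(cat): KeywordSet(str(cat), tuple(str(p) for p in phrases))
        for cat, phrases in section("keywords").items()
    }
    triggers_raw = section("context_triggers")
    triggers = ContextTriggerSet(
        negation_triggers=tuple(str(p) for p in triggers_raw.get("negation", [])),
        historical_triggers=tuple(str(p) for p in triggers_raw.get("historical", [])),
        uncertainty_triggers=tuple(str(p) for p in triggers_raw.get("uncertainty", [])),
        general_triggers=tuple(str(p) for p in triggers_raw.get("general", [])),
        post_negation_triggers=tuple(str(p) for p in triggers_raw.get("post_negation", [])),
        post_uncertainty_triggers=tuple(
            str(p) for p in triggers_raw.get("post_uncertainty", [])
        ),
        scope_window=int(triggers_raw.get("scope_window", 6)),
    )
    groups = tuple(
        PriorityGroup(int(priority), tuple(str(p) for p in phrases))
        for priority, phrases in sorted(section("cl_priority_groups").items())
    )
    rng = raw.get("cl_plausible_range_cm", [0.0, 10.0])
    lexicon = Lexicon(
        code_sets=code_sets,
        corrections=corrections,
        keywords=keywords,
        explicit_descriptions=tuple(str(p) for p in section("explicit_descriptions", list)),
        context_triggers=triggers,
        cl_priority_groups=groups,
        cl_exclusion_terms=tuple(str(p) for p in section("cl_exclusion_terms", list)),
        cl_exclusion_window=int(raw.get("cl_exclusion_window", 3)),
        cl_plausible_range_cm=(float(rng[0]), float(rng[1])),
        note_filter=NoteTypeFilter(
            frozenset(str(t).lower() for t in section("note_types", list))
        ),
        version=int(raw.get("version", 1)),
    )
    # corrections idempotence needs the standardizer; import deferred to avoid
    # a module cycle (preprocess imports CorrectionMap for type hints only).
    from .preprocess import standardize_terms

    lexicon.corrections.validate_idempotent(standardize_terms)
    return lexicon
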