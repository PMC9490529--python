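"""Seeded synthetic corpus generator with known gold labels.

Generates pregnancy episodes, structured encounters and free-text clinical
notes that exercise every pipeline stage: the five indicator categories with
negated/historical/general variants, structured codes, dx-only and
pre-eclampsia-delivery confounders, encounters on both sides of the
gestational window, overlapping encounter pairs, and cervical-length mentions
in the observed formats.  Every planted fact is recorded in a
:class:`GoldRecord`, so recovery can be scored without any real data.

The generator derives gold truth from what it planted (eligibility window,
setting, exclusion rules, CL selection), independently of the pipeline code.
All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .validation import GoldLabel, Prediction, build_confusion, metrics_row
from .visits import ClinicalNote, Encounter, PregnancyEpisode, PTLVisit
from .cervical_length import VisitCL

__all__ = ["CorpusSpec", "GoldRecord", "Corpus", "generate_corpus", "score_recovery"]

CL_FORMATS = (
    "single_cm",
    "single_mm",
    "hyphen_range",
    "to_range",
    "unitless",
    "backward_phrasing",
)

INDICATOR_CATEGORIES = (
    "preterm_labor",
    "fetal_fibronectin",
    "transvaginal_ultrasound",
    "abdominal_pain",
    "uterine_contraction",
)

# structured codes matching the default lexicon's code sets
CODES = {
    "ffn_lab": "82731",
    "tvus_proc": "76817",
    "ptl_dx": "O60.02",
    "ptl_med": "NIFEDIPINE 10MG CAPSULE",
    "preeclampsia_dx": "O14.12",
}
FILLER_CODES = {
    "dx": "Z34.83",
    "proc": "59025",
    "lab": "CBC",
    "med": "PRENATAL VITAMIN",
}

_EPOCH = date(2015, 1, 1)


def _load_templates() -> dict:
    path = resources.files("ptlnlp").joinpath("data/templates.yaml")
    return yaml.safe_load(path.read_text())


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults emulate the published cohort where a value is reported there:
    23% of pregnancies with a PTL evaluation visit, ~20% preterm deliveries,
    CL drawn around mean 3.66 cm (SD 0.99), ~40% of visits with a CL.
    """

    n_pregnancies: int = 500
    ptl_visit_prevalence: float = 0.23
    indicator_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "preterm_labor": 0.50,
            "fetal_fibronectin": 0.30,
            "transvaginal_ultrasound": 0.45,
            "abdominal_pain": 0.50,
            "uterine_contraction": 0.60,
        }
    )
    negation_rate: float = 0.0      # probability a planted indicator sentence is negated
    historical_rate: float = 0.0    # ... rendered as historical/general context
    cl_format_mix: Mapping[str, float] = field(
        default_factory=lambda: {f: 1.0 / len(CL_FORMATS) for f in CL_FORMATS}
    )
    cl_rate: float = 0.40           # probability a true visit has a CL note
    structured_rate: float = 0.60   # probability a true visit carries structured codes
    preterm_rate: float = 0.20
    overlap_rate: float = 0.15      # true visit split into two overlapping encounters
    dx_only_rate: float = 0.10
    negated_only_rate: float = 0.12
    out_of_window_rate: float = 0.12
    other_setting_rate: float = 0.05
    preeclampsia_delivery_rate: float = 0.08
    noise: float = 0.0              # typo/abbreviation injection rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pregnancies < 0:
            raise ValueError("n_pregnancies must be >= 0")
        rates = {
            "ptl_visit_prevalence": self.ptl_visit_prevalence,
            "negation_rate": self.negation_rate,
            "historical_rate": self.historical_rate,
            "cl_rate": self.cl_rate,
            "structured_rate": self.structured_rate,
            "preterm_rate": self.preterm_rate,
            "overlap_rate": self.overlap_rate,
            "noise": self.noise,
            **dict(self.indicator_mix),
            **dict(self.cl_format_mix),
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
        if self.negation_rate + self.historical_rate > 1.0:
            raise ValueError("negation_rate + historical_rate must be <= 1")
        if set(self.cl_format_mix) != set(CL_FORMATS):
            raise ValueError(f"cl_format_mix must cover exactly {CL_FORMATS}")
        total = sum(self.cl_format_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cl_format_mix must sum to 1, got {total}")
        if set(self.indicator_mix) != set(INDICATOR_CATEGORIES):
            raise ValueError(f"indicator_mix must cover exactly {INDICATOR_CATEGORIES}")


@dataclass(frozen=True)
class GoldRecord:
    """Planted truth for one visit-group (one encounter, or an overlapping pair)."""

    record_id: str
    pregnancy_id: str
    encounter_ids: tuple[str, ...]
    is_ptl_visit: bool
    ffn_performed: bool = False
    tvus_performed: bool = False
    is_delivery: bool = False
    cl_true_cm: float | None = None
    planted: tuple[str, ...] = ()


@dataclass
class Corpus:
    episodes: list[PregnancyEpisode]
    encounters: list[Encounter]
    notes: list[ClinicalNote]
    gold: list[GoldRecord]


# ---------------------------------------------------------------------------
# generation


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a full corpus; byte-identical for equal specs."""
    rng = np.random.default_rng(spec.seed)
    bank = _load_templates()
    corpus = Corpus([], [], [], [])
    for p in range(spec.n_pregnancies):
        _generate_pregnancy(f"P{p:05d}", spec, rng, bank, corpus)
    return corpus


def _generate_pregnancy(
    pid: str, spec: CorpusSpec, rng: np.random.Generator, bank: dict, corpus: Corpus
) -> None:
    start = _EPOCH + timedelta(days=int(rng.integers(0, 1461)))
    if rng.random() < spec.preterm_rate:
        ga_delivery = int(rng.integers(185, 259))
    else:
        ga_delivery = int(rng.integers(259, 294))
    delivery_dt = _dt(start, ga_delivery, int(rng.integers(0, 24)))
    corpus.episodes.append(
        PregnancyEpisode(pid, start, delivery_dt, "livebirth")
    )

    # candidate admit days on a 3-day grid so distinct groups never overlap
    hi_day = ga_delivery - 4
    in_window = [d for d in range(168, min(244, hi_day) + 1, 3)]
    out_window = [d for d in range(140, min(167, hi_day) + 1, 3)] + [
        d for d in range(245, min(258, hi_day) + 1, 3)
    ]
    rng.shuffle(in_window)
    rng.shuffle(out_window)

    def next_day(pool: list[int]) -> int | None:
        return pool.pop() if pool else None

    # true PTL visit(s)
    if rng.random() < spec.ptl_visit_prevalence:
        n_true = 2 if rng.random() < 0.15 else 1
        for _ in range(n_true):
            day = next_day(in_window)
            if day is not None:
                _plant_visit_group(pid, day, "true", spec, rng, bank, corpus)

    # confounders
    for kind, rate, pool in (
        ("dx_only", spec.dx_only_rate, in_window),
        ("negated_only", spec.negated_only_rate, in_window),
        ("other_setting", spec.other_setting_rate, in_window),
        ("out_of_window", spec.out_of_window_rate, out_window),
    ):
        if rng.random() < rate:
            day = next_day(pool)
            if day is not None:
                _plant_visit_group(pid, day, kind, spec, rng, bank, corpus)

    # delivery encounter
    _plant_delivery(pid, ga_delivery, delivery_dt, spec, rng, bank, corpus)


def _dt(start: date, ga_days: int, hour: int, minute: int = 0) -> datetime:
    return datetime.combine(start, datetime.min.time()) + timedelta(
        days=ga_days, hours=hour, minutes=minute
    )


def _draw_cl_value(rng: np.random.Generator) -> float:
    while True:
        v = rng.normal(3.66, 0.99)
        if 0.8 <= v <= 6.9:
            return round(float(v), 1)


def _realize_cl(fmt: str, rng: np.random.Generator, bank: dict) -> tuple[str, float]:
    """Pick a CL sentence template and value(s); return (sentence, true cm)."""
    v = _draw_cl_value(rng)
    template = bank["cl_formats"][fmt][int(rng.integers(len(bank["cl_formats"][fmt])))]
    if fmt in ("single_cm", "unitless"):
        return template.format(v=v), round(v, 2)
    if fmt == "single_mm":
        mm = int(round(v * 10))
        return template.format(mm=mm), round(mm / 10, 2)
    if fmt == "backward_phrasing":
        if "{mm}" in template:
            mm = int(round(v * 10))
            return template.format(mm=mm), round(mm / 10, 2)
        return template.format(v=v), round(v, 2)
    a, b = round(max(v - 0.1, 0.1), 1), round(v + 0.1, 1)
    return template.format(a=a, b=b), round((a + b) / 2, 2)


def _apply_noise(sentence: str, spec: CorpusSpec, rng: np.random.Generator, bank: dict) -> str:
    """Corrupt a sentence: invertible abbreviation (the correction map undoes
    it) or an irreversible typo, each with probability noise/2."""
    r = rng.random()
    if r < spec.noise / 2:
        table = bank["noise_invertible"]
    elif r < spec.noise:
        table = bank["noise_typos"]
    else:
        return sentence
    for term, variant in table.items():
        if term in sentence:
            return sentence.replace(term, variant, 1)
    return sentence


def _roughen(sentences: Sequence[str], rng: np.random.Generator) -> str:
    """Assemble raw note text with realistic case/punctuation variation.

    Only the final sentence may end in "!" — normalization deletes the
    exclamation mark, and a non-final one would fuse two sentences.
    """
    out = []
    last = len(sentences) - 1
    for i, s in enumerate(sentences):
        if rng.random() < 0.5:
            s = s.capitalize()
        if i == last and rng.random() < 0.15:
            out.append(s + "!")
        else:
            out.append(s + ".")
    return "  ".join(out)


def _plant_visit_group(
    pid: str,
    day: int,
    kind: str,
    spec: CorpusSpec,
    rng: np.random.Generator,
    bank: dict,
    corpus: Corpus,
) -> None:
    start = corpus.episodes[-1].start_date
    admit = _dt(start, day, int(rng.integers(6, 18)))
    discharge = admit + timedelta(hours=int(rng.integers(4, 20)))
    setting = "other" if kind == "other_setting" else (
        "triage" if rng.random() < 0.7 else "hospital"
    )
    base_id = f"E{len(corpus.encounters):06d}"

    planted: list[str] = []
    sentences_by_note: list[list[str]] = []
    affirmed: set[str] = set()          # affirmed in the primary encounter's notes
    affirmed_extra: set[str] = set()    # affirmed in the overlap partner's note
    structured: set[str] = set()
    cl_notes: list[tuple[int, float]] = []  # (note slot, true value)

    def render_indicator(cat: str, into_affirmed: set[str]) -> str:
        """One indicator sentence, rendered per the context-rate mix."""
        r = rng.random()
        if r < spec.negation_rate:
            planted.append(f"negated:{cat}")
            return _context_sentence(cat, "negated", rng, bank)
        if r < spec.negation_rate + spec.historical_rate:
            variant = "historical" if rng.random() < 0.5 else "general"
            planted.append(f"{variant}:{cat}")
            return _context_sentence(cat, variant, rng, bank)
        into_affirmed.add(cat)
        planted.append(f"affirmed:{cat}")
        return _affirmed_sentence(cat, rng, bank)

    if kind == "dx_only":
        structured.add("ptl_dx")
        sentences_by_note.append(_fillers(rng, bank, 3))
    elif kind == "negated_only":
        sents = []
        for _ in range(int(rng.integers(1, 3))):
            cat = INDICATOR_CATEGORIES[int(rng.integers(len(INDICATOR_CATEGORIES)))]
            sents.append(_context_sentence(cat, "negated", rng, bank))
            planted.append(f"negated:{cat}")
        sentences_by_note.append(sents + _fillers(rng, bank, 2))
    else:  # true visit (possibly in an ineligible setting/window)
        if rng.random() < spec.structured_rate:
            for key, prob in (("ffn_lab", 0.4), ("tvus_proc", 0.5), ("ptl_med", 0.4)):
                if rng.random() < prob:
                    structured.add(key)
        if rng.random() < 0.5:
            structured.add("ptl_dx")
        sents = []
        for cat in INDICATOR_CATEGORIES:
            if rng.random() < spec.indicator_mix[cat]:
                sents.append(render_indicator(cat, affirmed))
        if not sents and not structured - {"ptl_dx"}:
            # guarantee the group is a candidate of some kind
            sents.append(render_indicator("uterine_contraction", affirmed))
        sentences_by_note.append(sents + _fillers(rng, bank, 2))
        # a CL is only measured in the course of an actual evaluation, so CL
        # notes are planted only alongside affirmed or structured evidence
        if (affirmed or structured - {"ptl_dx"}) and rng.random() < spec.cl_rate:
            fmt = str(
                rng.choice(list(spec.cl_format_mix), p=list(spec.cl_format_mix.values()))
            )
            sentence, value = _realize_cl(fmt, rng, bank)
            if "tvus" in sentence or "transvaginal ultrasound" in sentence:
                affirmed.add("transvaginal_ultrasound")
            slot = len(sentences_by_note)
            sentences_by_note.append([sentence] + _fillers(rng, bank, 1))
            cl_notes.append((slot, value))
            planted.append(f"cl:{fmt}:{value}")
            if rng.random() < 0.3:  # second, later CL note: selection is exercised
                fmt2 = str(
                    rng.choice(
                        list(spec.cl_format_mix), p=list(spec.cl_format_mix.values())
                    )
                )
                sentence2, value2 = _realize_cl(fmt2, rng, bank)
                if "tvus" in sentence2 or "transvaginal ultrasound" in sentence2:
                    affirmed.add("transvaginal_ultrasound")
                slot2 = len(sentences_by_note)
                sentences_by_note.append([sentence2] + _fillers(rng, bank, 1))
                cl_notes.append((slot2, value2))
                planted.append(f"cl:{fmt2}:{value2}")

    if not sentences_by_note:
        sentences_by_note.append(_fillers(rng, bank, 2))

    # split into two overlapping encounters occasionally (true visits only);
    # the partner carries its own indicator note so it is identifiable and
    # the pipeline's interval consolidation merges the pair
    encounter_ids: list[str]
    overlap_note: tuple[datetime, str] | None = None
    if kind == "true" and rng.random() < spec.overlap_rate:
        mid = admit + (discharge - admit) / 2
        second_discharge = discharge + timedelta(hours=int(rng.integers(2, 12)))
        e1 = Encounter(
            base_id, pid, admit, discharge, setting, False,
            dx_codes=_codes(structured, "dx"), proc_codes=_codes(structured, "proc"),
            lab_codes=_codes(structured, "lab"), med_codes=_codes(structured, "med"),
        )
        e2 = Encounter(
            base_id + "b", pid, mid, second_discharge, setting, False,
            dx_codes=(FILLER_CODES["dx"],),
        )
        corpus.encounters.extend([e1, e2])
        encounter_ids = [e1.encounter_id, e2.encounter_id]
        cat = INDICATOR_CATEGORIES[int(rng.integers(len(INDICATOR_CATEGORIES)))]
        overlap_note = (
            mid + timedelta(minutes=30), render_indicator(cat, affirmed_extra)
        )
    else:
        enc = Encounter(
            base_id, pid, admit, discharge, setting, False,
            dx_codes=_codes(structured, "dx"), proc_codes=_codes(structured, "proc"),
            lab_codes=_codes(structured, "lab"), med_codes=_codes(structured, "med"),
        )
        corpus.encounters.append(enc)
        encounter_ids = [enc.encounter_id]

    # notes: spread across the primary encounter's stay, chronological by slot
    note_times: list[datetime] = []
    span_minutes = max(int((discharge - admit).total_seconds() // 60) - 30, 60)
    offsets = sorted(
        int(rng.integers(0, span_minutes)) for _ in sentences_by_note
    )
    for i, sents in enumerate(sentences_by_note):
        t = admit + timedelta(minutes=offsets[i] + i)  # +i keeps times distinct
        note_times.append(t)
        noisy = [_apply_noise(s, spec, rng, bank) for s in sents]
        corpus.notes.append(
            ClinicalNote(
                note_id=f"N{len(corpus.notes):06d}",
                encounter_id=encounter_ids[0],
                note_type="triage note" if setting == "triage" else "progress note",
                note_datetime=t,
                text=_roughen(noisy, rng),
            )
        )

    if overlap_note is not None:
        t2, sentence = overlap_note
        corpus.notes.append(
            ClinicalNote(
                note_id=f"N{len(corpus.notes):06d}",
                encounter_id=encounter_ids[1],
                note_type="triage note" if setting == "triage" else "progress note",
                note_datetime=t2,
                text=_roughen([_apply_noise(sentence, spec, rng, bank)], rng),
            )
        )

    # occasionally an ineligible-type note with a decoy CL (must be ignored)
    if kind == "true" and rng.random() < 0.1:
        sentence, _ = _realize_cl("single_cm", rng, bank)
        corpus.notes.append(
            ClinicalNote(
                note_id=f"N{len(corpus.notes):06d}",
                encounter_id=encounter_ids[0],
                note_type="office visit",
                note_datetime=admit + timedelta(minutes=5),
                text=_roughen([sentence], rng),
            )
        )

    # gold truth, derived from the planted facts and the stated rules
    eligible = setting in ("triage", "hospital") and 168 <= day <= 244
    non_dx_structured = bool(structured - {"ptl_dx"})
    primary_identified = non_dx_structured or bool(affirmed)
    is_ptl = eligible and (primary_identified or bool(affirmed_extra))
    any_affirmed = affirmed | affirmed_extra
    cl_true: float | None = None
    if is_ptl and cl_notes and primary_identified:
        # non-delivery visit: the measurement closest to discharge wins
        cl_true = max(cl_notes, key=lambda sv: note_times[sv[0]])[1]
    corpus.gold.append(
        GoldRecord(
            record_id=f"G{len(corpus.gold):06d}",
            pregnancy_id=pid,
            encounter_ids=tuple(encounter_ids),
            is_ptl_visit=is_ptl,
            ffn_performed=is_ptl
            and ("ffn_lab" in structured or "fetal_fibronectin" in any_affirmed),
            tvus_performed=is_ptl
            and ("tvus_proc" in structured or "transvaginal_ultrasound" in any_affirmed),
            is_delivery=False,
            cl_true_cm=cl_true,
            planted=tuple(planted),
        )
    )


def _plant_delivery(
    pid: str,
    ga_delivery: int,
    delivery_dt: datetime,
    spec: CorpusSpec,
    rng: np.random.Generator,
    bank: dict,
    corpus: Corpus,
) -> None:
    admit = delivery_dt - timedelta(hours=6)
    discharge = delivery_dt + timedelta(hours=24)
    preeclampsia = rng.random() < spec.preeclampsia_delivery_rate
    with_contractions = rng.random() < 0.5
    dx = [FILLER_CODES["dx"]]
    if preeclampsia:
        dx.append(CODES["preeclampsia_dx"])
    enc = Encounter(
        f"E{len(corpus.encounters):06d}", pid, admit, discharge,
        "hospital", True, dx_codes=tuple(dx),
    )
    corpus.encounters.append(enc)
    sentences = list(bank["delivery"]["plain"])
    planted: list[str] = []
    affirmed_contraction = False
    if preeclampsia:
        sentences.append(bank["delivery"]["preeclampsia"][0])
        planted.append("preeclampsia_delivery")
    if with_contractions:
        r = rng.random()
        if r < spec.negation_rate:
            sentences.append(_context_sentence("uterine_contraction", "negated", rng, bank))
            planted.append("negated:uterine_contraction")
        elif r < spec.negation_rate + spec.historical_rate:
            sentences.append(_context_sentence("uterine_contraction", "historical", rng, bank))
            planted.append("historical:uterine_contraction")
        else:
            sentences.append(bank["delivery"]["contractions"][0])
            affirmed_contraction = True
            planted.append("affirmed:uterine_contraction")
    corpus.notes.append(
        ClinicalNote(
            note_id=f"N{len(corpus.notes):06d}",
            encounter_id=enc.encounter_id,
            note_type="labor and delivery note",
            note_datetime=admit + timedelta(hours=1),
            text=_roughen([_apply_noise(s, spec, rng, bank) for s in sentences], rng),
        )
    )
    in_window = 168 <= (admit.date() - corpus.episodes[-1].start_date).days <= 244
    is_ptl = in_window and affirmed_contraction and not preeclampsia
    corpus.gold.append(
        GoldRecord(
            record_id=f"G{len(corpus.gold):06d}",
            pregnancy_id=pid,
            encounter_ids=(enc.encounter_id,),
            is_ptl_visit=is_ptl,
            is_delivery=True,
            planted=tuple(planted),
        )
    )


def _fillers(rng: np.random.Generator, bank: dict, n: int) -> list[str]:
    pool = bank["filler"]
    return [pool[int(rng.integers(len(pool)))] for _ in range(n)]


def _affirmed_sentence(category: str, rng: np.random.Generator, bank: dict) -> str:
    pool = bank["affirmed"][category]
    return pool[int(rng.integers(len(pool)))]


def _context_sentence(
    category: str, variant: str, rng: np.random.Generator, bank: dict
) -> str:
    # fill the template with a phrase the lexicon screens for
    phrases = {
        "preterm_labor": "preterm labor",
        "fetal_fibronectin": "fetal fibronectin",
        "transvaginal_ultrasound": "transvaginal ultrasound",
        "abdominal_pain": "abdominal pain",
        "uterine_contraction": "uterine contractions",
    }
    pool = bank[variant]
    template = pool[int(rng.integers(len(pool)))]
    return template.format(phrase=phrases[category])


def _codes(structured: set[str], kind: str) -> tuple[str, ...]:
    mapping = {"dx": "ptl_dx", "proc": "tvus_proc", "lab": "ffn_lab", "med": "ptl_med"}
    out = []
    if mapping[kind] in structured:
        out.append(CODES[mapping[kind]])
    return tuple(out)


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    visits: Sequence[PTLVisit],
    visit_cls: Sequence[VisitCL],
    gold: Sequence[GoldRecord],
) -> dict:
    """Score pipeline output against planted truth.

    Per-target PPV / sensitivity / specificity (percent) for visit
    identification, fFN and TVUS, plus the CL confusion and mean absolute
    error (cm) against the planted values.  Returns ``{}`` for an empty
    corpus.
    """
    if not gold:
        return {}
    by_encounter = {eid: g for g in gold for eid in g.encounter_ids}
    cl_by_visit = {vc.visit_id: vc.cl_cm for vc in visit_cls}

    matched: dict[str, list[PTLVisit]] = {}
    unmatched_visits = 0
    for v in visits:
        records = {by_encounter[eid].record_id for eid in v.member_encounters if eid in by_encounter}
        if not records:
            unmatched_visits += 1
            continue
        for rid in records:
            matched.setdefault(rid, []).append(v)

    predictions: list[Prediction] = []
    labels: list[GoldLabel] = []
    abs_errors: list[float] = []
    for g in gold:
        vs = matched.get(g.record_id, [])
        pred_cl = None
        for v in vs:
            if v.visit_id in cl_by_visit:
                pred_cl = cl_by_visit[v.visit_id]
        predictions.append(
            Prediction(
                visit_id=g.record_id,
                ptl=bool(vs),
                ffn=any(v.has_ffn() for v in vs),
                tvus=any(v.has_tvus() for v in vs),
                cl_cm=pred_cl,
            )
        )
        labels.append(
            GoldLabel(
                visit_id=g.record_id,
                ptl_confirmed=g.is_ptl_visit,
                ffn_confirmed=g.ffn_performed,
                tvus_confirmed=g.tvus_performed,
                cl_gold_cm=g.cl_true_cm,
            )
        )
        if pred_cl is not None and g.cl_true_cm is not None:
            abs_errors.append(abs(pred_cl - g.cl_true_cm))

    report: dict = {}
    for target in ("ptl", "ffn", "tvus", "cl"):
        counts = build_confusion(predictions, labels, target)
        row = metrics_row(counts)
        row["counts"] = counts
        report[target] = row
    report["cl"]["mae_cm"] = float(np.mean(abs_errors)) if abs_errors else 0.0
    report["cl"]["n_compared"] = len(abs_errors)
    report["n_gold_records"] = len(gold)
    report["n_predicted_visits"] = len(visits)
    report["n_unmatched_predicted_visits"] = unmatched_visits
    return report
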