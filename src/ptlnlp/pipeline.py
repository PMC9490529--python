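"""End-to-end orchestration: delimited-table I/O, stage running, manifests.

Input tables are plain CSV with ISO-8601 timestamps; code lists are
semicolon-joined within a cell.  Every run writes a machine-readable manifest
with input checksums, lexicon version and per-stage counts so that reruns can
be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cervical_length import NoteCL, RawMeasurement, VisitCL, extract_visit_cl
from .lexicon import Lexicon, default_lexicon_path, load_lexicon
from .synth import Corpus, CorpusSpec, GoldRecord, generate_corpus, score_recovery
from .validation import (
    GoldLabel,
    Prediction,
    build_confusion,
    format_metric,
    metrics_row,
)
from .visits import (
    ClinicalNote,
    Encounter,
    EncounterDecision,
    GESTATIONAL_WINDOW_DAYS,
    PregnancyEpisode,
    PTLVisit,
    identify_visits,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_episodes",
    "read_encounters",
    "read_notes",
    "read_gold_records",
    "read_gold_labels",
    "write_corpus",
    "visits_frame",
    "audit_frame",
    "validation_report",
]

_SEP = ";"


# ---------------------------------------------------------------------------
# readers / writers


def _codes(cell) -> tuple[str, ...]:
    if pd.isna(cell) or cell == "":
        return ()
    return tuple(str(cell).split(_SEP))


def read_episodes(path: str | Path) -> list[PregnancyEpisode]:
    df = pd.read_csv(path, dtype={"pregnancy_id": str})
    return [
        PregnancyEpisode(
            pregnancy_id=row.pregnancy_id,
            start_date=date.fromisoformat(row.start_date),
            delivery_datetime=datetime.fromisoformat(row.delivery_datetime),
            outcome=row.outcome,
        )
        for row in df.itertuples()
    ]


def read_encounters(path: str | Path) -> list[Encounter]:
    df = pd.read_csv(
        path,
        dtype={
            "encounter_id": str, "pregnancy_id": str, "dx_codes": str,
            "proc_codes": str, "lab_codes": str, "med_codes": str,
        },
    )
    return [
        Encounter(
            encounter_id=row.encounter_id,
            pregnancy_id=row.pregnancy_id,
            admit=datetime.fromisoformat(row.admit),
            discharge=datetime.fromisoformat(row.discharge),
            setting=row.setting,
            is_delivery=bool(row.is_delivery),
            dx_codes=_codes(row.dx_codes),
            proc_codes=_codes(row.proc_codes),
            lab_codes=_codes(row.lab_codes),
            med_codes=_codes(row.med_codes),
        )
        for row in df.itertuples()
    ]


def read_notes(path: str | Path) -> list[ClinicalNote]:
    df = pd.read_csv(path, dtype={"note_id": str, "encounter_id": str}, keep_default_na=False)
    return [
        ClinicalNote(
            note_id=row.note_id,
            encounter_id=row.encounter_id,
            note_type=row.note_type,
            note_datetime=datetime.fromisoformat(row.note_datetime),
            text=row.text,
        )
        for row in df.itertuples()
    ]


def read_gold_records(path: str | Path) -> list[GoldRecord]:
    df = pd.read_csv(
        path,
        dtype={
            "record_id": str, "pregnancy_id": str,
            "encounter_ids": str, "planted": str,
        },
    )
    return [
        GoldRecord(
            record_id=row.record_id,
            pregnancy_id=row.pregnancy_id,
            encounter_ids=tuple(str(row.encounter_ids).split(_SEP)),
            is_ptl_visit=bool(row.is_ptl_visit),
            ffn_performed=bool(row.ffn_performed),
            tvus_performed=bool(row.tvus_performed),
            is_delivery=bool(row.is_delivery),
            cl_true_cm=None if pd.isna(row.cl_true_cm) else float(row.cl_true_cm),
            planted=_codes(row.planted),
        )
        for row in df.itertuples()
    ]


def read_gold_labels(path: str | Path) -> list[GoldLabel]:
    """Chart-review adjudication file: one row per sampled visit."""
    df = pd.read_csv(path, dtype={"visit_id": str})
    return [
        GoldLabel(
            visit_id=row.visit_id,
            ptl_confirmed=bool(row.ptl_confirmed),
            ffn_confirmed=bool(row.ffn_confirmed),
            tvus_confirmed=bool(row.tvus_confirmed),
            cl_gold_cm=None if pd.isna(row.cl_gold_cm) else float(row.cl_gold_cm),
        )
        for row in df.itertuples()
    ]


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "episodes": out / "episodes.csv",
        "encounters": out / "encounters.csv",
        "notes": out / "notes.csv",
        "gold": out / "gold.csv",
    }
    pd.DataFrame(
        [
            {
                "pregnancy_id": e.pregnancy_id,
                "start_date": e.start_date.isoformat(),
                "delivery_datetime": e.delivery_datetime.isoformat(),
                "outcome": e.outcome,
            }
            for e in corpus.episodes
        ]
    ).to_csv(paths["episodes"], index=False)
    pd.DataFrame(
        [
            {
                "encounter_id": e.encounter_id,
                "pregnancy_id": e.pregnancy_id,
                "admit": e.admit.isoformat(),
                "discharge": e.discharge.isoformat(),
                "setting": e.setting,
                "is_delivery": e.is_delivery,
                "dx_codes": _SEP.join(e.dx_codes),
                "proc_codes": _SEP.join(e.proc_codes),
                "lab_codes": _SEP.join(e.lab_codes),
                "med_codes": _SEP.join(e.med_codes),
            }
            for e in corpus.encounters
        ]
    ).to_csv(paths["encounters"], index=False)
    pd.DataFrame(
        [
            {
                "note_id": n.note_id,
                "encounter_id": n.encounter_id,
                "note_type": n.note_type,
                "note_datetime": n.note_datetime.isoformat(),
                "text": n.text,
            }
            for n in corpus.notes
        ]
    ).to_csv(paths["notes"], index=False)
    pd.DataFrame(
        [
            {
                "record_id": g.record_id,
                "pregnancy_id": g.pregnancy_id,
                "encounter_ids": _SEP.join(g.encounter_ids),
                "is_ptl_visit": g.is_ptl_visit,
                "ffn_performed": g.ffn_performed,
                "tvus_performed": g.tvus_performed,
                "is_delivery": g.is_delivery,
                "cl_true_cm": g.cl_true_cm,
                "planted": _SEP.join(g.planted),
            }
            for g in corpus.gold
        ]
    ).to_csv(paths["gold"], index=False)
    return paths


def visits_frame(visits: Sequence[PTLVisit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "visit_id": v.visit_id,
                "pregnancy_id": v.pregnancy_id,
                "admit": v.admit.isoformat(),
                "discharge": v.discharge.isoformat(),
                "gestational_age_days": v.gestational_age_days,
                "is_delivery": v.is_delivery,
                "member_encounters": _SEP.join(v.member_encounters),
                "evidence": _SEP.join(sorted(v.evidence)),
                "has_ffn": v.has_ffn(),
                "has_tvus": v.has_tvus(),
            }
            for v in visits
        ],
        columns=[
            "visit_id", "pregnancy_id", "admit", "discharge",
            "gestational_age_days", "is_delivery", "member_encounters",
            "evidence", "has_ffn", "has_tvus",
        ],
    )


def audit_frame(decisions: Sequence[EncounterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "encounter_id": d.encounter.encounter_id,
                "pregnancy_id": d.encounter.pregnancy_id,
                "decision": d.decision,
                "has_ffn_order": d.flags.has_ffn_order,
                "has_tvus_proc": d.flags.has_tvus_proc,
                "has_ptl_dx": d.flags.has_ptl_dx,
                "has_ptl_med": d.flags.has_ptl_med,
                "n_indicator_hits": len(d.hits),
                "evidence": _SEP.join(sorted(d.evidence)),
            }
            for d in decisions
        ]
    )


def note_cl_frame(note_cls: Sequence[NoteCL], raws: Sequence[RawMeasurement]) -> pd.DataFrame:
    raw_by_id = {(m.note_id, m.token_pos): m for m in raws}
    rows = []
    for n in note_cls:
        m = n.provenance
        rows.append(
            {
                "note_id": n.note_id,
                "note_datetime": n.note_datetime.isoformat(),
                "cl_cm": n.cl_cm,
                "keyword": m.keyword,
                "priority": m.priority,
                "direction": m.direction,
                "unit": m.unit or "",
                "raw_values": _SEP.join(repr(v) for v in m.values),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "note_id", "note_datetime", "cl_cm", "keyword", "priority",
            "direction", "unit", "raw_values",
        ],
    )


def visit_cl_frame(visit_cls: Sequence[VisitCL]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "visit_id": vc.visit_id,
                "pregnancy_id": vc.pregnancy_id,
                "cl_cm": vc.cl_cm,
                "selection_rule": vc.selection_rule,
                "note_id": vc.note_id,
            }
            for vc in visit_cls
        ],
        columns=["visit_id", "pregnancy_id", "cl_cm", "selection_rule", "note_id"],
    )


# ---------------------------------------------------------------------------
# validation report (Table-5 / Table-6 style)


def validation_report(
    visits: Sequence[PTLVisit],
    visit_cls: Sequence[VisitCL],
    gold: Sequence[GoldLabel],
) -> dict:
    """Cross-tabulate identified visits against a chart-review gold file.

    Gold rows are keyed by visit id; a gold visit with no corresponding
    identified visit is an all-negative prediction.
    """
    by_id = {v.visit_id: v for v in visits}
    cl_by_id = {vc.visit_id: vc.cl_cm for vc in visit_cls}
    predictions = []
    for g in gold:
        v = by_id.get(g.visit_id)
        predictions.append(
            Prediction(
                visit_id=g.visit_id,
                ptl=v is not None,
                ffn=v.has_ffn() if v else False,
                tvus=v.has_tvus() if v else False,
                cl_cm=cl_by_id.get(g.visit_id),
            )
        )
    report: dict = {}
    for target in ("ptl", "ffn", "tvus", "cl"):
        counts = build_confusion(predictions, gold, target)
        row = metrics_row(counts)
        report[target] = {
            "counts": {
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "value_mismatch": counts.value_mismatch,
            },
            "metrics": {k: format_metric(v) for k, v in row.items()},
        }
    return report


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class RunConfig:
    """Configuration for an end-to-end run."""

    out_dir: Path
    episodes_path: Path | None = None
    encounters_path: Path | None = None
    notes_path: Path | None = None
    lexicon_path: Path | None = None
    gold_path: Path | None = None
    window: tuple[int, int] = GESTATIONAL_WINDOW_DAYS
    synth_spec: CorpusSpec | None = None

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("gestational window lower bound must be < upper bound")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run synth (optional) -> identify -> extract-cl -> score, write outputs.

    Returns the manifest.  Raises on unreadable inputs or lexicon failure; no
    stage outputs are written past a failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = load_lexicon(config.lexicon_path)
    manifest: dict = {
        "lexicon": str(config.lexicon_path or default_lexicon_path()),
        "lexicon_version": lexicon.version,
        "inputs": {},
        "counts": {},
        "outputs": {},
    }

    if config.synth_spec is not None:
        corpus = generate_corpus(config.synth_spec)
        paths = write_corpus(corpus, out / "corpus")
        episodes, encounters, notes = corpus.episodes, corpus.encounters, corpus.notes
        gold_records: list[GoldRecord] | None = corpus.gold
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
        manifest["counts"]["synth_seed"] = config.synth_spec.seed
    else:
        for name, path in (
            ("episodes", config.episodes_path),
            ("encounters", config.encounters_path),
            ("notes", config.notes_path),
        ):
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input table missing: {name} ({path})")
            manifest["inputs"][name] = _sha256(Path(path))
        episodes = read_episodes(config.episodes_path)
        encounters = read_encounters(config.encounters_path)
        notes = read_notes(config.notes_path)
        gold_records = None

    manifest["counts"]["pregnancies"] = len(episodes)
    manifest["counts"]["encounters"] = len(encounters)
    manifest["counts"]["notes"] = len(notes)

    visits, decisions = identify_visits(episodes, encounters, notes, lexicon, config.window)
    manifest["counts"]["candidate_encounters"] = sum(
        1 for d in decisions if d.decision != "not_ptl"
    )
    manifest["counts"]["ptl_encounters"] = sum(
        1 for d in decisions if d.decision == "ptl_visit"
    )
    manifest["counts"]["excluded_dx_only"] = sum(
        1 for d in decisions if d.decision == "excluded_dx_only"
    )
    manifest["counts"]["excluded_preeclampsia_delivery"] = sum(
        1 for d in decisions if d.decision == "excluded_preeclampsia_delivery"
    )
    manifest["counts"]["consolidated_visits"] = len(visits)

    visit_cls: list[VisitCL] = []
    note_cls: list[NoteCL] = []
    raws: list[RawMeasurement] = []
    for v in visits:
        vc, ncls, ms = extract_visit_cl(v, notes, lexicon)
        if vc is not None:
            visit_cls.append(vc)
        note_cls.extend(ncls)
        raws.extend(ms)
    manifest["counts"]["visits_with_cl"] = len(visit_cls)

    frames = {
        "visits": visits_frame(visits),
        "audit": audit_frame(decisions),
        "note_cl": note_cl_frame(note_cls, raws),
        "visit_cl": visit_cl_frame(visit_cls),
    }
    for name, frame in frames.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = _sha256(path)

    if gold_records is not None:
        report = score_recovery(visits, visit_cls, gold_records)
        for target in ("ptl", "ffn", "tvus", "cl"):
            if target in report:
                report[target] = {
                    k: (v if not hasattr(v, "tp") else {
                        "tp": v.tp, "fp": v.fp, "fn": v.fn, "tn": v.tn,
                        "value_mismatch": v.value_mismatch,
                    })
                    for k, v in report[target].items()
                }
        (out / "recovery.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"]["recovery"] = _sha256(out / "recovery.json")
    elif config.gold_path is not None:
        gold = read_gold_labels(config.gold_path)
        report = validation_report(visits, visit_cls, gold)
        (out / "validation.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"]["validation"] = _sha256(out / "validation.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
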