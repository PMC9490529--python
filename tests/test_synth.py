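"""Synthetic corpus generation: determinism, planted-truth consistency,
confounders, recovery scoring."""

import pickle

import numpy as np
import pytest

from ptlnlp.cervical_length import extract_visit_cl
from ptlnlp.synth import CL_FORMATS, Corpus, CorpusSpec, generate_corpus, score_recovery
from ptlnlp.visits import identify_visits


def _run(corpus, lexicon):
    visits, _ = identify_visits(
        corpus.episodes, corpus.encounters, corpus.notes, lexicon
    )
    visit_cls = []
    for v in visits:
        vc, _, _ = extract_visit_cl(v, corpus.notes, lexicon)
        if vc is not None:
            visit_cls.append(vc)
    return visits, visit_cls


def test_generation_is_deterministic():
    spec = CorpusSpec(n_pregnancies=40, noise=0.3, negation_rate=0.2, seed=11)
    a, b = generate_corpus(spec), generate_corpus(spec)
    assert pickle.dumps(a.episodes) == pickle.dumps(b.episodes)
    assert pickle.dumps(a.encounters) == pickle.dumps(b.encounters)
    assert pickle.dumps(a.notes) == pickle.dumps(b.notes)
    assert pickle.dumps(a.gold) == pickle.dumps(b.gold)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_pregnancies=-1),
        dict(noise=1.2),
        dict(negation_rate=0.8, historical_rate=0.5),
        dict(cl_format_mix={f: (0.5 if f == "single_cm" else 0.2) for f in CL_FORMATS}),
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(ValueError):
        CorpusSpec(**kwargs)


def test_planted_indicators_literally_present():
    """Gold consistency: every planted affirmed phrase category appears in
    the group's note text (noise-free)."""
    corpus = generate_corpus(CorpusSpec(n_pregnancies=60, seed=3))
    notes_by_enc = {}
    for n in corpus.notes:
        notes_by_enc.setdefault(n.encounter_id, []).append(n)
    probes = {
        "fetal_fibronectin": ("ffn", "fibronectin"),
        "transvaginal_ultrasound": ("tvus", "transvaginal ultrasound"),
        "abdominal_pain": ("abdominal pain", "cramping"),
        "uterine_contraction": ("contraction",),
        "preterm_labor": ("preterm labor", "ptl"),
    }
    checked = 0
    for g in corpus.gold:
        text = " ".join(
            n.text.lower()
            for eid in g.encounter_ids
            for n in notes_by_enc.get(eid, [])
        )
        for item in g.planted:
            if item.startswith("affirmed:"):
                cat = item.split(":", 1)[1]
                assert any(p in text for p in probes[cat]), (g.record_id, cat)
                checked += 1
    assert checked > 10


def test_full_negation_without_structured_yields_zero_gold_visits():
    lexicon = __import__("ptlnlp").load_lexicon()
    corpus = generate_corpus(
        CorpusSpec(n_pregnancies=80, negation_rate=1.0, structured_rate=0.0, seed=7)
    )
    assert sum(g.is_ptl_visit for g in corpus.gold) == 0
    visits, _ = _run(corpus, lexicon)
    assert visits == []


def test_single_mm_format_plants_tenfold_token():
    corpus = generate_corpus(
        CorpusSpec(
            n_pregnancies=80,
            cl_format_mix={f: (1.0 if f == "single_mm" else 0.0) for f in CL_FORMATS},
            cl_rate=1.0,
            seed=9,
        )
    )
    notes_by_enc = {}
    for n in corpus.notes:
        notes_by_enc.setdefault(n.encounter_id, []).append(n)
    planted = 0
    for g in corpus.gold:
        if g.cl_true_cm is None:
            continue
        mm = int(round(g.cl_true_cm * 10))
        text = " ".join(
            n.text for eid in g.encounter_ids for n in notes_by_enc.get(eid, [])
        )
        assert f"{mm} mm" in text
        planted += 1
    assert planted > 5


def test_noise_free_recovery_is_perfect():
    lexicon = __import__("ptlnlp").load_lexicon()
    corpus = generate_corpus(CorpusSpec(n_pregnancies=150, seed=2))
    visits, visit_cls = _run(corpus, lexicon)
    report = score_recovery(visits, visit_cls, corpus.gold)
    for target in ("ptl", "ffn", "tvus", "cl"):
        assert report[target]["ppv"] == 100.0, target
        assert report[target]["sensitivity"] == 100.0, target
    assert report["cl"]["mae_cm"] == 0.0
    assert report["cl"]["n_compared"] > 0


def test_dx_only_confounders_never_predicted():
    lexicon = __import__("ptlnlp").load_lexicon()
    corpus = generate_corpus(
        CorpusSpec(
            n_pregnancies=80, ptl_visit_prevalence=0.0, dx_only_rate=1.0,
            negated_only_rate=0.0, out_of_window_rate=0.0,
            other_setting_rate=0.0, preeclampsia_delivery_rate=0.0,
            negation_rate=1.0, seed=13,
        )
    )
    assert sum(g.is_ptl_visit for g in corpus.gold) == 0
    visits, _ = _run(corpus, lexicon)
    assert visits == []


def test_empty_corpus_empty_report():
    corpus = generate_corpus(CorpusSpec(n_pregnancies=0, seed=1))
    assert corpus.gold == []
    assert score_recovery([], [], corpus.gold) == {}


def test_recovery_not_increasing_with_noise():
    """Statistical property over 5 seeds: heavier typo noise can only hurt."""
    lexicon = __import__("ptlnlp").load_lexicon()

    def mean_sens(noise):
        vals = []
        for seed in range(5):
            corpus = generate_corpus(
                CorpusSpec(n_pregnancies=60, noise=noise, seed=seed)
            )
            visits, visit_cls = _run(corpus, lexicon)
            report = score_recovery(visits, visit_cls, corpus.gold)
            vals.append(report["ptl"]["sensitivity"])
        return float(np.mean(vals))

    s0, s_mid, s_hi = mean_sens(0.0), mean_sens(0.5), mean_sens(1.0)
    assert s0 >= s_mid >= s_hi
    assert s0 == 100.0
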