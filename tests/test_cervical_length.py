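"""Cervical-length keyword search, value capture, standardization, selection."""

from datetime import date, datetime, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptlnlp.cervical_length import (
    RawMeasurement,
    extract_note_cl,
    extract_visit_cl,
    find_cl_keywords,
    search_values,
    select_note_cl,
    select_visit_cl,
    standardize_cl,
)
from ptlnlp.visits import ClinicalNote, Encounter, PregnancyEpisode, PTLVisit

# the four narrative formats the extractor must handle end to end
WORKED_EXAMPLES = [
    ("cervical length measures 1.6 cm", 1.6),
    ("tvus cl 2.6-2.7 cm no funneling", 2.65),
    ("cervical length 3.3 to 4.4", 3.85),
    ("transvaginal ultrasound at bedside 41 mm long cervical length", 4.1),
]


@pytest.mark.parametrize("text,expected", WORKED_EXAMPLES)
def test_worked_examples_end_to_end(text, expected, lexicon, make_note):
    note_cl, _ = extract_note_cl(make_note(text), lexicon)
    assert note_cl is not None
    assert note_cl.cl_cm == pytest.approx(expected)


def test_worked_example_set_is_exact(lexicon, make_note):
    values = {
        extract_note_cl(make_note(t), lexicon)[0].cl_cm for t, _ in WORKED_EXAMPLES
    }
    assert values == {1.6, 2.65, 3.85, 4.1}


def test_keyword_matching_is_token_aligned(lexicon, make_sentence):
    assert find_cl_keywords(make_sentence("lungs clear bilaterally"), lexicon) == []
    matches = find_cl_keywords(make_sentence("tvus cl 2.6-2.7 cm no funneling"), lexicon)
    assert [(m[0], m[1]) for m in matches] == [("cl", 1)]


def test_keyword_priorities(lexicon, make_sentence):
    s = make_sentence("cervix appears closed cervical length 3.0 cm")
    found = {phrase: prio for phrase, prio, _ in find_cl_keywords(s, lexicon)}
    assert found == {"cervix": 3, "cervical length": 1}


def test_no_value_in_window_returns_none(lexicon, make_sentence):
    s = make_sentence("cervical length funneling noted")
    assert search_values(s, 0, 2, "cervical length", 1, lexicon) is None


def test_backward_search_captures_preceding_value(lexicon, make_sentence):
    s = make_sentence("transvaginal ultrasound at bedside 41 mm long cervical length")
    m = search_values(s, 7, 2, "cervical length", 1, lexicon)
    assert m is not None
    assert m.direction == "backward"
    assert m.values == (41.0,)
    assert m.unit == "mm"


def test_dilation_value_excluded_cl_kept(lexicon, make_note):
    note_cl, _ = extract_note_cl(
        make_note("cervix dilated 2 cm, cervical length 3.0 cm"), lexicon
    )
    assert note_cl.cl_cm == pytest.approx(3.0)


def test_fluid_pocket_value_excluded(lexicon, make_note):
    note_cl, _ = extract_note_cl(
        make_note("cervix with deepest vertical amniotic fluid pocket 4.2 cm"), lexicon
    )
    assert note_cl is None


def test_plain_cl_value_kept(lexicon, make_note):
    note_cl, _ = extract_note_cl(make_note("cervical length 3.0 cm"), lexicon)
    assert note_cl.cl_cm == pytest.approx(3.0)


def _raw(values, unit=None, priority=1, is_range=False, pos=2, keyword="cervical length"):
    return RawMeasurement(
        note_id="n1", keyword=keyword, priority=priority, direction="forward",
        values=tuple(values), unit=unit, token_pos=pos, is_range=is_range,
    )


@pytest.mark.parametrize(
    "measurement,expected",
    [
        (_raw([1.6], unit="cm"), 1.6),
        (_raw([41], unit="mm"), 4.1),
        (_raw([3.3, 4.4], is_range=True), 3.85),
        (_raw([2.6, 2.7], unit="cm", is_range=True), 2.65),
        (_raw([30, 34], unit="mm", is_range=True), 3.2),
        (_raw([3.0]), 3.0),  # unitless defaults to cm
    ],
)
def test_standardize_cl(measurement, expected):
    assert standardize_cl(measurement) == pytest.approx(expected)


@given(st.integers(5, 95))
def test_unit_consistency_mm_equals_cm_over_ten(mm):
    in_mm = standardize_cl(_raw([mm], unit="mm"))
    in_cm = standardize_cl(_raw([mm / 10], unit="cm"))
    assert in_mm == pytest.approx(in_cm)


NOW = datetime(2020, 7, 20, 12, 0)


def test_priority_dominates_magnitude(lexicon):
    chosen = select_note_cl(
        [_raw([3.0], priority=1), _raw([2.0], priority=2)], "n1", NOW, lexicon
    )
    assert chosen.cl_cm == pytest.approx(3.0)


def test_shortest_value_within_top_priority(lexicon):
    chosen = select_note_cl(
        [_raw([3.0], priority=1), _raw([2.5], priority=1)], "n1", NOW, lexicon
    )
    assert chosen.cl_cm == pytest.approx(2.5)


def test_single_measurement_selected_as_is(lexicon):
    chosen = select_note_cl([_raw([2.2])], "n1", NOW, lexicon)
    assert chosen.cl_cm == pytest.approx(2.2)


def test_no_measurements_returns_none(lexicon):
    assert select_note_cl([], "n1", NOW, lexicon) is None


def test_implausible_values_dropped(lexicon):
    assert select_note_cl([_raw([140], unit=None)], "n1", NOW, lexicon) is None
    kept = select_note_cl([_raw([140]), _raw([3.1])], "n1", NOW, lexicon)
    assert kept.cl_cm == pytest.approx(3.1)


@given(
    st.lists(
        st.tuples(st.integers(5, 95), st.sampled_from([None, "cm", "mm"]),
                  st.integers(1, 3)),
        min_size=1, max_size=6,
    )
)
def test_note_selection_bounded_by_candidates(entries):
    lexicon = __import__("ptlnlp").load_lexicon()
    measurements = [
        _raw([v / 10 if unit != "mm" else v], unit=unit, priority=p)
        for v, unit, p in entries
    ]
    standardized = [standardize_cl(m) for m in measurements]
    chosen = select_note_cl(measurements, "n1", NOW, lexicon)
    if chosen is not None:
        assert min(standardized) <= chosen.cl_cm <= max(standardized)


def _visit(is_delivery=False, discharge=NOW + timedelta(hours=3)):
    return PTLVisit(
        pregnancy_id="p1", admit=NOW - timedelta(hours=4), discharge=discharge,
        member_encounters=("e1",), evidence=frozenset({"tvus_performed"}),
        is_delivery=is_delivery, gestational_age_days=200,
    )


def _note_cl(cl, hours_offset, note_id="n1"):
    from ptlnlp.cervical_length import NoteCL

    return NoteCL(
        note_id=note_id, note_datetime=NOW + timedelta(hours=hours_offset),
        cl_cm=cl, provenance=_raw([cl]),
    )


def test_delivery_visit_keeps_first_measure():
    chosen = select_visit_cl(
        [_note_cl(3.2, -3, "a"), _note_cl(2.1, 2, "b")], _visit(is_delivery=True)
    )
    assert chosen.cl_cm == pytest.approx(3.2)
    assert chosen.selection_rule == "first_measure"


def test_non_delivery_visit_keeps_measure_closest_to_discharge():
    chosen = select_visit_cl(
        [_note_cl(3.2, -3, "a"), _note_cl(2.1, 2, "b")], _visit()
    )
    assert chosen.cl_cm == pytest.approx(2.1)
    assert chosen.selection_rule == "closest_to_discharge"


def test_measure_before_discharge_preferred_over_after():
    # 1h before discharge beats 30min after discharge
    chosen = select_visit_cl(
        [_note_cl(3.0, 2, "a"), _note_cl(2.0, 3.5, "b")], _visit()
    )
    assert chosen.cl_cm == pytest.approx(3.0)


def test_zero_note_cls_returns_none():
    assert select_visit_cl([], _visit()) is None


def test_end_to_end_determinism(lexicon, make_note):
    """Identical note text always yields the identical visit-level CL."""
    episode = PregnancyEpisode("p1", date(2020, 1, 1), datetime(2020, 10, 7), "livebirth")
    admit = datetime(2020, 7, 19, 8, 0)
    enc = Encounter("e1", "p1", admit, admit + timedelta(hours=8), "triage",
                    proc_codes=("76817",))
    notes = [
        make_note("TVUS performed.  Cervical length 3.3 to 4.4!", note_id="nA"),
        make_note("cl 2.6-2.7 cm no funneling", note_id="nB",
                  when=admit + timedelta(hours=5)),
    ]
    visit = PTLVisit("p1", admit, admit + timedelta(hours=8), ("e1",),
                     frozenset({"tvus_proc"}), False, 200)
    results = {extract_visit_cl(visit, notes, lexicon)[0].cl_cm for _ in range(3)}
    assert len(results) == 1
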