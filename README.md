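# ptlnlp

Rule-based NLP identification of **preterm-labor (PTL) evaluation visits** and
extraction of **cervical-length (CL) measurements** from electronic-health-record
tables and free-text clinical notes.

## The problem

Preterm birth research starts from finding the triage and hospital encounters
at which a pregnant patient was evaluated for suspected preterm labor.  Those
evaluations — fetal fibronectin (fFN) swabs, transvaginal ultrasound (TVUS),
documented contractions or abdominal pain, explicit clinician statements like
"ruled out PTL" — live partly in structured codes and partly in narrative
notes, and the cervical length that anchors sPTB risk stratification is
almost always narrative ("tvus cl 2.6-2.7 cm no funneling").  `ptlnlp`
implements a deterministic, auditable phenotyping pipeline for this task:

1. **Structured screening** — encounters between 24^0/7 and 34^6/7 weeks of
   gestation (days 168–244 from pregnancy start) in triage/hospital settings
   are flagged for fFN lab orders, TVUS procedures, PTL diagnoses and PTL
   medications, via configurable code sets.
2. **Note evidence** — eligible notes are lowercased, reduced to a restricted
   character set, segmented, tokenized and term-standardized; sentences
   containing any of five keyword categories (preterm labor, fetal
   fibronectin, transvaginal ultrasound, abdominal pain, uterine contraction)
   are screened, and each mention is classified NegEx-style as affirmed /
   negated / historical / uncertain / general.  Only affirmed mentions count.
3. **Exclusions and consolidation** — encounters whose only evidence is a PTL
   diagnosis code, and delivery encounters with a pre-eclampsia/eclampsia
   diagnosis, are excluded; time-overlapping PTL encounters merge into single
   visits (earliest admit, latest discharge).
4. **CL extraction** — CL keywords in three priority tiers; numeric capture
   forward within 10 tokens, else backward within 5; non-CL values (dilation,
   effacement, station, fluid pockets, heart rate) rejected; per note the
   highest-priority, then shortest, value wins; per visit the first measure
   (delivery) or the measure closest to discharge is kept; standardization:
   no unit ⇒ cm, mm ⇒ ÷10, ranges/multiple values ⇒ arithmetic mean.
5. **Validation metrics** — PPV, sensitivity and specificity (percent)
   against chart-review gold labels, with CL "detected but different value"
   records treated as precision errors and excluded from the sensitivity
   denominator.

A seeded synthetic-corpus generator (`ptlnlp.synth`) produces pregnancies,
encounters, codes and note text with known planted truth, so the whole
pipeline is testable without any real patient data.

All term lists, code sets, context triggers and thresholds ship as an
editable YAML lexicon (`src/ptlnlp/data/default_lexicon.yaml`) — defaults are
plausible stand-ins, not any health system's proprietary lists.

## Worked example

```python
from datetime import datetime
from ptlnlp import load_lexicon, ClinicalNote
from ptlnlp.cervical_length import extract_note_cl

lexicon = load_lexicon()
for text in [
    "cervical length measures 1.6 cm",
    "tvus cl 2.6-2.7 cm no funneling",
    "cervical length 3.3 to 4.4",
    "transvaginal ultrasound at bedside 41 mm long cervical length",
]:
    note = ClinicalNote("n1", "e1", "triage note", datetime(2020, 1, 1), text)
    note_cl, raw = extract_note_cl(note, lexicon)
    print(f"{text!r:65s} -> {note_cl.cl_cm} cm")
```

prints

```
'cervical length measures 1.6 cm'                                 -> 1.6 cm
'tvus cl 2.6-2.7 cm no funneling'                                 -> 2.65 cm
'cervical length 3.3 to 4.4'                                      -> 3.85 cm
'transvaginal ultrasound at bedside 41 mm long cervical length'   -> 4.1 cm
```

— the single value is kept as cm, the hyphen and "to" ranges collapse to
their means (2.65, 3.85), and the backward-phrased 41 mm capture becomes
4.1 cm.

End to end, from a shell:

```bash
ptlnlp run-all --seed 1 --n-pregnancies 500 --out-dir out/
```

writes the synthetic input tables, the identified-visit and CL tables, a
recovery report (`out/recovery.json`, 100% PPV/sensitivity and CL mean
absolute error 0.0 on the noise-free corpus) and a checksummed run manifest.
`ptlnlp identify / extract-cl / validate` run the stages separately on your
own CSV tables; see `ptlnlp --help`.

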