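# Phrase bank for the synthetic clinical-note generator.
#
# Sentences emulate obstetric triage / labor-and-delivery note language around
# the five PTL-evaluation indicator categories, their negated / historical /
# general variants, and the observed cervical-length (CL) reporting formats
# (single value with or without unit, mm values, hyphen ranges, "X to Y"
# ranges, and backward-ordered phrasing).  All synthetic; no real note text.

affirmed:
  preterm_labor:
    - "patient admitted in preterm labor"
    - "assessment: preterm labor"
    - "ruled out ptl after observation period"
    - "evaluation for preterm labor completed tonight"
  fetal_fibronectin:
    - "ffn specimen collected and sent to lab"
    - "fetal fibronectin test performed in triage"
    - "ffn swab obtained prior to exam"
  transvaginal_ultrasound:
    - "transvaginal ultrasound performed at bedside"
    - "tvus completed to assess cervix"
    - "transvaginal ultrasound done by sonographer"
  abdominal_pain:
    - "patient reports abdominal pain since this morning"
    - "abdominal pain rated 6 of 10"
    - "presents with cramping and back pressure"
  uterine_contraction:
    - "uterine contractions every 4 minutes on monitor"
    - "contractions palpated q5 minutes"
    - "regular uterine contractions on tocometer"

# {phrase} is filled with a keyword phrase of the chosen category
negated:
  - "no {phrase} at this time"
  - "denies {phrase}"
  - "without {phrase} currently"
historical:
  - "history of {phrase} in 2012"
  - "hx of {phrase} with last pregnancy"
general:
  - "risk of {phrase} reviewed with patient"
  - "risk for {phrase} education provided"

filler:
  - "patient resting comfortably in room"
  - "plan reviewed with attending physician"
  - "vital signs stable throughout the visit"
  - "fetal heart rate 140 bpm reassuring"
  - "ambulating without difficulty"
  - "call light within reach"
  - "spouse at bedside for support"

# value placeholders: {v} single value, {mm} integer millimeters,
# {a}/{b} range endpoints
cl_formats:
  single_cm:
    - "cervical length measures {v} cm"
    - "cervical length {v} cm noted on scan"
    - "cl {v} cm"
  single_mm:
    - "cervical length {mm} mm"
    - "cl measured {mm} mm today"
  hyphen_range:
    - "tvus cl {a}-{b} cm no funneling"
    - "cervical length {a}-{b} cm"
  to_range:
    - "cervical length {a} to {b}"
    - "cl ranges {a} to {b} cm"
  unitless:
    - "cervical length {v}"
    - "cl today {v}"
  backward_phrasing:
    - "transvaginal ultrasound at bedside {mm} mm long cervical length"
    - "measured {v} cm cervical length on tvus"

# delivery-encounter sentences
delivery:
  plain:
    - "patient admitted for delivery"
    - "delivery note dictated"
  contractions:
    - "regular uterine contractions with cervical change"
  preeclampsia:
    - "severe preeclampsia with delivery indicated"

# invertible abbreviation noise (fixed by the default correction map)
noise_invertible:
  "cervical length": "cerv length"
  "abdominal pain": "abd pain"
  "transvaginal ultrasound": "transvag us"
  "uterine contractions": "uterine ctx"
  "preterm": "pre term"
# irreversible typo noise (outside any correction list)
noise_typos:
  "contractions": "contracshuns"
  "fibronectin": "fibronektin"
  "ultrasound": "ultrsound"
  "labor": "labr"
  "pain": "pian"
  "ffn": "fn"
  "tvus": "tvs"
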