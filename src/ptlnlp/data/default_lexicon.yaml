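# Default lexicon bundle for the preterm-labor (PTL) visit identification and
# cervical-length (CL) extraction pipeline.
#
# These lists are editable site configuration.  They are plausible defaults
# assembled from standard obstetric terminology and the published description
# of the algorithm; they are NOT the originating health system's proprietary
# code and term lists, which were never made public.  Sites should review and
# replace every section before production use.
#
# All phrases are stated in post-normalization form: lowercase, containing only
# letters, digits, spaces, periods, commas and colons (hyphens only between
# digits).  Phrase matching is token-aligned and longest-match.

version: 1

code_sets:
  # PTL diagnosis codes (ICD-9 644.0x/644.1x, ICD-10 O60.0x; trailing '*' is a
  # prefix wildcard).
  ptl_dx:
    system: diagnosis
    codes: ["644.0*", "644.1*", "O60.0*"]
  # Fetal fibronectin lab orders/results (CPT 82731 plus common order mnemonics).
  ffn_lab:
    system: lab
    codes: ["82731", "FFN*", "FETAL FIBRONECTIN*"]
  # Transvaginal ultrasound procedures (CPT 76817 plus descriptive order text).
  tvus_proc:
    system: procedure
    codes: ["76817", "TVUS*", "US TRANSVAGINAL*", "ULTRASOUND TRANSVAGINAL*"]
  # Tocolytics and antenatal corticosteroids used in PTL management.
  ptl_med:
    system: medication
    codes:
      - "NIFEDIPINE*"
      - "INDOMETHACIN*"
      - "TERBUTALINE*"
      - "MAGNESIUM SULFATE*"
      - "BETAMETHASONE*"
      - "DEXAMETHASONE*"
  # Pre-eclampsia / eclampsia diagnoses (delivery-encounter exclusion).
  preeclampsia_dx:
    system: diagnosis
    codes: ["642.4*", "642.5*", "642.6*", "O14*", "O15*"]

# Misspelling / abbreviation corrections applied after tokenization.  Keys and
# values are phrases over normalized tokens; every value must be a fixpoint of
# the map (no chained rewrites), which makes application idempotent.
corrections:
  "cerv length": "cervical length"
  "cerv lgth": "cervical length"
  "cervicl": "cervical"
  "cervial": "cervical"
  "fibronectn": "fibronectin"
  "fibronectrin": "fibronectin"
  "pre term": "preterm"
  "premature labor": "preterm labor"
  "transvag ultrasound": "transvaginal ultrasound"
  "transvag us": "transvaginal ultrasound"
  "abd pain": "abdominal pain"
  "uterine ctx": "uterine contractions"

# The five indicator keyword categories screened in clinical-note sentences.
keywords:
  preterm_labor:
    - "preterm labor"
    - "ptl"
  fetal_fibronectin:
    - "fetal fibronectin"
    - "ffn"
  transvaginal_ultrasound:
    - "transvaginal ultrasound"
    - "tvus"
    - "endovaginal ultrasound"
  abdominal_pain:
    - "abdominal pain"
    - "pelvic pain"
    - "cramping"
  uterine_contraction:
    - "uterine contraction"
    - "uterine contractions"
    - "contraction"
    - "contractions"

# Explicit descriptions of a PTL evaluation.  These phrases are affirmed
# evidence by definition and bypass context classification ("ruled out ptl"
# records that an evaluation took place even though the grammar is negative).
explicit_descriptions:
  - "in preterm labor"
  - "ruled out ptl"
  - "ruled out preterm labor"
  - "ptl ruled out"
  - "preterm labor ruled out"
  - "assessment: preterm labor"
  - "assessment: ptl"
  - "preterm labor evaluation"
  - "ptl evaluation"

# Context triggers (NegEx-style).  A trigger in the four main lists governs
# the following `scope_window` tokens; a post_* trigger governs the preceding
# `scope_window` tokens (for qualifiers that follow the finding, e.g.
# "ffn uninterpretable").  Scopes stop early at a comma, colon or period.
context_triggers:
  negation:
    - "no"
    - "not"
    - "denies"
    - "denied"
    - "without"
    - "negative for"
    - "free of"
  historical:
    - "history of"
    - "hx of"
    - "prior history of"
  uncertainty:
    - "rule out"
    - "possible"
    - "possibly"
    - "questionable"
    - "uncertain"
  general:
    - "risk of"
    - "risk for"
    - "discussed"
    - "education"
    - "counseled"
    - "precautions"
  post_negation:
    - "resolved"
    - "ruled out"
  post_uncertainty:
    - "uninterpretable"
    - "unlikely"
  scope_window: 6

# CL keyword phrases in three priority tiers (1 = highest).
cl_priority_groups:
  1:
    - "cervical length"
    - "cl"
  2:
    - "cervix measures"
    - "cervix measured"
    - "cervical measurement"
  3:
    - "cervix"

# A captured numeric value adjacent (within `cl_exclusion_window` tokens) to
# one of these terms describes something other than the cervical length and is
# dropped (dilation, effacement, station, amniotic fluid, fetal heart rate,
# gestational age).
cl_exclusion_terms:
  - "dilated"
  - "dilation"
  - "dilatation"
  - "effaced"
  - "effacement"
  - "station"
  - "fluid pocket"
  - "vertical pocket"
  - "afi"
  - "bpm"
  - "heart rate"
  - "week"
  - "weeks"
cl_exclusion_window: 3

# Standardized CL values outside this range (cm) are logged and dropped.
cl_plausible_range_cm: [0.0, 10.0]

# Note types eligible for indicator and CL extraction.
note_types:
  - "triage note"
  - "ob triage note"
  - "progress note"
  - "labor and delivery note"
  - "history and physical"
  - "nursing note"
  - "radiology report"
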