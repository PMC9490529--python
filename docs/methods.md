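# Methods

This note documents the algorithmic choices behind `ptlnlp`: what each stage
computes, where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Scope and inputs

The pipeline consumes three tables: pregnancy episodes (pregnancy id, start
date = gestational day 0, delivery datetime, outcome), encounters (admit /
discharge timestamps, setting, delivery flag, diagnosis / procedure / lab /
medication codes) and clinical notes (typed, timestamped free text tied to an
encounter).  Gestational age is **taken as given** via the episode start
date; estimating it from ultrasound or LMP is out of scope.  The gestational
window is days 168–244 inclusive (24^0/7–34^6/7 weeks), anchored on the
encounter **admit** timestamp; weeks 20^0/7–23^6/7 and 35^0/7–36^6/7 are
excluded because fFN testing is not indicated there.  For a long
hospitalization spanning the upper boundary the admit anchor decides; this is
a documented choice, not a clinical claim, and is configurable via the window
bounds.

## Lexicon

Every behavioral list is configuration (`data/default_lexicon.yaml`):

* **Code sets** — PTL diagnoses (ICD-9 644.0x/644.1x, ICD-10 O60.0x), fFN lab
  orders (CPT 82731 + mnemonics), TVUS procedures (CPT 76817 + order text),
  PTL medications (tocolytics, antenatal corticosteroids, magnesium sulfate),
  pre-eclampsia/eclampsia diagnoses.  Entries ending in `*` are prefixes;
  matching is case-insensitive.  These defaults are plausible but are **not**
  the originating study's proprietary lists, which were never published;
  sites must review them.
* **Correction map** — phrase-level misspelling/abbreviation fixes applied
  after tokenization with leftmost-longest-match semantics.  Validation
  requires every value to be a fixpoint of the map, which makes application
  provably idempotent (no rewrite chains).
* **Keyword sets** — exactly the five indicator categories.  Keyword phrases
  are stated in post-normalization form and matched token-aligned, so "cl"
  can never fire inside "clear".
* **Explicit descriptions** — phrases such as "ruled out ptl" or
  "assessment: preterm labor" that record an evaluation having occurred.
  They are affirmed evidence **by definition** and bypass context
  classification: "ruled out PTL" is grammatically negative but documents a
  completed evaluation.
* **Context triggers** — NegEx-style lists for negation, historical,
  uncertainty and general (education/counseling) contexts, plus small
  post-trigger lists ("uninterpretable", "resolved") for qualifiers that
  follow the finding.  A pre-trigger governs the 6 tokens after it, a
  post-trigger the 6 tokens before it; both scopes stop at a comma, colon or
  period.  When several triggers cover a match the nearest wins, ties going
  to the preceding trigger.  The 6-token scope is deliberately small and
  fixed: auditable behavior was preferred over recall.  "uninterpretable" is
  included because an uninterpretable fFN swab is not an affirmed result —
  this deliberately differs from behavior that would count such sentences.
* **CL priority groups** — three tiers ("cervical length"/"cl" ≻ "cervix
  measures" ≻ "cervix"); a phrase may appear in only one tier.
* **CL exclusion terms** — dilation/effacement/station vocabulary, amniotic
  fluid pockets, heart-rate units, and "week(s)" (gestational-age numbers are
  the most common non-CL numerals near "cervix").

## Text preprocessing

Normalization lowercases and keeps only letters, digits, spaces, periods,
commas and colons.  Two refinements were required to keep the worked formats
intact: a **hyphen survives only between two digits** (so the range
"2.6-2.7" is preserved while prose hyphens become spaces), and removed
characters become spaces rather than deletions (so "3.3cm!" cannot fuse with
a neighbor).  Sentence segmentation is a single rule — a period followed by
whitespace and a letter splits; a period between digits is a decimal point —
with no statistical model, for determinism.  Tokens are maximal letter runs,
numeric literals with at most one internal decimal point, and standalone
punctuation; a sentence-final period is never absorbed into a number.  One
shared preprocessing pass feeds both the indicator and the CL stages.

## Visit identification

An encounter is a candidate if structured screening raises any of four flags
(fFN order, TVUS procedure, PTL diagnosis, PTL medication) or any note
sentence yields an affirmed indicator.  Two exclusions follow: delivery
encounters carrying a pre-eclampsia/eclampsia code (confounded by medically
indicated delivery; applied **only** when the delivery flag is set), and
encounters whose sole evidence is the PTL diagnosis code (chart review in the
source study confirmed only ~35% of such encounters).  Identified encounters
with closed-interval time overlap merge transitively: earliest admit, latest
discharge, union of evidence, delivery if any member is.  Consolidation is
idempotent and order-invariant and its output intervals are pairwise disjoint
per pregnancy; the test suite checks it against an O(n²) union-find oracle.
Encounters in settings other than triage/hospital are ignored even when codes
match.  A merged visit's gestational age uses the merged admit.

## CL extraction

For each CL keyword match the extractor scans **forward up to 10 tokens**
after the keyword for the start of a value expression — a number, a
hyphen/"to" range, or adjacent numbers, with an optional trailing unit token
("cm"/"centimeter(s)"/"mm"/"millimeter(s)" binding to the nearest preceding
expression).  If the forward scan yields nothing admissible — including when
every candidate was rejected as a non-CL measure — a **backward scan of the 5
tokens before the keyword** runs, keeping the expression nearest the keyword.
A value adjacent (within 3 tokens) to an exclusion term is rejected.

Per note: highest-priority keyword tier wins; if distinct standardized values
remain in that tier, the shortest is kept (distinctness at 2 decimals).
Ranges are collapsed to their arithmetic mean **at standardization time**, so
the "shortest" rule compares scalars — this resolves the apparent tension
between the shortest-value rule and the average-the-range rule: the averaging
rule governs within one expression, the shortest rule across competing
expressions.  Per visit: delivery encounters keep the first (earliest-note)
measure; all others keep the measure closest to discharge, preferring
measures at or before discharge, then later timestamps, then lower note ids.
Standardization: unitless ⇒ cm; mm ⇒ ÷10; multiple values ⇒ mean; results
rounded to 2 decimals.  A plausibility guard drops (and logs) standardized
values outside (0, 10] cm — the population mean CL is ≈3.7 cm with SD ≈1 cm,
so anything outside that interval is a capture error, most often a fused
heart rate or gestational age.  Office-visit measurements leaking into triage
notes are a known error mode; the note-type filter removes ineligible note
types, and anything beyond that is logged rather than silently filtered.

## Validation metrics

PPV = 100·tp/(tp+fp), sensitivity = 100·tp/(tp+fn), specificity =
100·tn/(tn+fp), rounded half-up to 2 decimals.  Two asymmetries deserve
mention.  First, when a review sample contains **no predicted-negative
records** (a positives-only validation sample), sensitivity and specificity
are reported as not-estimated (NE) rather than the degenerate 100/0 the raw
formulas would give.  Second, CL has a third outcome — measurement detected
but with the wrong value — which counts against PPV and specificity (an fp)
but is excluded from the sensitivity denominator, because the measurement
itself was found.  This accounting is the only one consistent with reporting
a detected-but-different record separately from misses, and it is what the
`cl` target implements.  Predicted and gold CL values within 0.05 cm are "the
same value".

## Synthetic corpus

The generator emulates the study conditions: ~23% of pregnancies get a true
PTL evaluation visit, ~20% of deliveries are preterm, ~40% of true visits
carry a CL note, CL values are drawn from N(3.66, 0.99²) truncated to
[0.8, 6.9] cm and rounded to 1 decimal, and encounter admits are spread over
gestational days 140–258 so the window filter is exercised on both sides.
Six CL formats (single cm, single mm, hyphen range, "to" range, unitless,
backward phrasing) are drawn from a configurable mix, uniform by default
since no format distribution was ever published.  Confounders are planted at
fixed rates: diagnosis-code-only encounters, negated/historical-only notes,
out-of-window and non-triage/hospital encounters, pre-eclampsia deliveries.
True visits are occasionally split into two overlapping encounters (the
partner carrying its own indicator note) to exercise consolidation.  The
`negation_rate`/`historical_rate` dials re-render planted indicator sentences
in excluded contexts; `noise` injects abbreviations the correction map can
undo and, separately, typos it cannot.  Gold truth is derived by the
generator from what it planted, applying the eligibility and exclusion rules
independently of the pipeline code.

Passing the noise-free recovery check (100% PPV/sensitivity, CL MAE 0 on 500
pregnancies) demonstrates internal consistency of the whole chain — every
planted phenomenon is recovered and nothing else is — but **not** performance
on real notes: the generator draws from a finite template bank, its
misspellings are exactly invertible by the shipped correction map, and real
clinical narrative (section headers, copy-forward, telegraphic style,
template boilerplate) is far messier.  The published validation figures
(e.g. PPV 97% for visit identification) came from chart review of real
records and cannot be regenerated from synthetic data; the metrics module
reproduces their arithmetic exactly from the published confusion counts.

## Numerical and degenerate-input choices

* Timestamps are ISO-8601; gestational age is whole days from the episode
  start date; the window test is inclusive on both ends.
* Interval overlap is closed (a shared boundary instant merges).
* First-visit selection ties break on the lowest member encounter id.
* Empty notes, keyword-free sentences and measurement-free notes yield empty
  results, never errors; an event before the pregnancy start raises.
* All stages are pure and deterministic; the only randomness in the package
  lives in the corpus generator and is fully seed-controlled.

## Known limitations

* Default lexicon lists are reconstructions; fidelity to any specific health
  system's terminology is not claimed.
* No dependency parsing or learned context classification; the 6-token
  trigger scope will miss long-range negation ("no evidence at this time of
  any regular uterine contractions" is handled, but longer gaps are not).
* fFN *result* values (positive/negative) are not extracted, only that the
  test was performed; likewise funneling, dilation and effacement are out of
  scope.
* One pregnancy episode per record; successive pregnancies are not linked.
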