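# Methods

This note documents the phenotyping rules as implemented, the tunable
parameters, the synthetic-data model used for validation, and the
design choices made where the rules left genuine freedom.

## Selection model

A *candidate* is any insured person with a C33/C34 (trachea /
bronchus-and-lung malignancy) diagnosis billed in the study period
(default 2015-01-01 … 2016-12-31). The index quarter is the earliest
such quarter. The exclusion cascade runs in a fixed order and records
the **first** failing check, so exclusion counts are disjoint and sum,
with the included count, to the candidate count:

1. *Confirmation* — outpatient C33/C34 in ≥ 2 distinct quarters of the
   observation period (M2Q), or ≥ 1 confirmed inpatient C33/C34.
   All outpatient diagnoses count toward M2Q regardless of their
   certainty marker; the `confirmed` flag is only required on the
   inpatient branch, mirroring how the two confirmation routes are
   defined.
2. *Washout* — no C33/C34 in quarters index−8 … index−1.
3. *Pre-observation* — continuous enrollment over the full 8 quarters
   before the index quarter (gaps < 1 day tolerated). This is the
   strictest reading of "sufficient pre-observation time"; it is
   configurable (`CohortConfig.pre_observation_quarters`).
4. *Other primary tumor* — any C00–C75 diagnosis except C33/C34/C44/C61
   within index±8 quarters. The rule is a code-range predicate, not a
   table lookup, so every 4/5-digit child is covered.
5. *Post-observation* — enrollment must reach into the quarter after
   the index quarter. "Insufficient post-observation time" has no
   operational definition in the source material; this is the package's
   own minimal definition and is deliberately the last check.

The observation horizon for M2Q extends to the end of the data period
(default 2018-12-31), because treatment follow-up runs through 2018; a
confirming outpatient coding after the horizon does not count. This
resolves an ambiguity (study period vs data horizon) in favor of the
data horizon.

Stage precedence is distant > lymph-node > none when C77 and C78/C79
co-occur in the index quarter: the cohort definitions are nested and
stage IV dominates clinically.

Age is computed as index year − birth year (claims carry birth year
only), grouped ≤ 60 vs > 60; a missing birth year is reported as
`unknown`, never dropped.

## Treatment lines

"One month" is fixed at 30 calendar days (`TherapyConfig.window_days`);
the source never defines the month. Windows are closed: an event dated
exactly start+30 belongs to the window, and the second-line scan starts
strictly after start+30. Line-relevant events are ATC dispensings and
OPS/EBM procedures with a therapy role in the code registry; the
second-line trigger considers all of these, not only drug dispensings.
A treatment can commence on any calendar day of the index quarter or
the following quarter (dates, not quarters, are the start resolution).

The group hierarchy (Immunotherapy > Inhibitors > Chemotherapy >
Radiotherapy > Study) follows the registry's listing order; assignment
is stated to be hierarchical but the order itself is a design choice.
Generic chemotherapy OPS markers (8-542 … 8-549) map to the
Chemotherapy group but carry no cancer type, so they can open or label
a line yet never classify a patient. "Study" items count only when a
primary study code (EBM 13461/13492) is billed in the same quarter as a
companion service code (EBM 13494, 02100, 02101, 01510–01512); the
pairing window is not specified in the source and same-quarter
co-occurrence is the package's choice.

Conflicting type tags (NSCLC and SCLC drugs in the same deciding
window) yield `unclassifiable` with `conflicting=True` rather than a
majority vote: the classification is meant to be unambiguous or absent.

## Care attribution

Within the office-based "other physician" category the specialty order
is oncologist > pulmonologist > radiologist > internist > primary care >
other office-based. The authoritative supplementary hierarchy is not
published; this order follows the listing in the source text. The same
hierarchy applies in the index quarter and in the line-start quarters.

"Two weeks before the test" is 14 calendar days inclusive: a test is
inpatient iff some hospital stay satisfies admission ≤ test date and
discharge ≥ test date − 14. Moving a discharge from 14 to 15 days
before the test flips the setting, which the tests pin down.

The bundled surgery OPS set (families 5-32/5-33/5-34) is a **synthetic
placeholder** — the authoritative list is unpublished — and is shipped
as a separate, user-replaceable CSV. With an empty surgery set the
detector warns by never flagging.

## Time expenditure

Counts per relative quarter −4 … +8: pharmacy visits are distinct
dispensing dates (claims record dispensings, not footfall); GP vs
specialist visits are distinct (date, provider) contacts with
primary-care vs specialist providers (oncologist, pulmonologist,
radiologist, internist, other office-based); inpatient days count
closed stay intervals, a stay spanning a quarter boundary contributing
its days to each quarter by calendar membership (so per-quarter counts
sum to the stay length, and a discharge day counts). Quarters without
any enrollment overlap are *missing*, not zero, and drop out of the
stratum mean's denominator — zeros would bias means downward for
patients who die or disenroll before +8. Partially enrolled quarters
count as observed.

Eligibility for the burden analysis: included, a first line exists, no
second line, and the *outpatient* M2Q criterion holds (inpatient-only
confirmation does not qualify).

## Synthetic-data model

The generator (`lungclaims.synth`) emulates the structure the rules key
on, with one independent pseudo-random stream per patient derived from
`(seed, patient index)`, so populations are byte-reproducible and
stable under subsetting. Scenario defaults are the package's standing
study conditions:

| parameter | default | rationale |
|---|---|---|
| `type_mixture` | (0.80, 0.20) | canonical NSCLC:SCLC incidence split |
| `treated_fraction` | 0.62 | ≈ 60% standard therapy + 2% study starts |
| `group_mixture` | chemo 0.65, radio 0.16, immuno 0.10, inhibitors 0.06, study 0.03 | chemotherapy-dominated first lines |
| `exclusion_rates` | other-primary 0.309, pre 0.040, post 0.105 | attrition contamination of the candidate pool |
| `off_label_rate` | 0.2 | substantial off-label prescribing is the reason type calls fail |
| `m2q_fraction` | 0.2 | ≈ 80% of initial codings happen in hospital |
| `stage_mixture` | no-mets 0.35, lymph 0.15, distant 0.50 | mostly advanced-stage diagnosis |
| `urban_fraction` | 0.79 | urban-dominated population |
| contact rates | GP 1.0/quarter; specialist 0.4 pre / 3.0 post; hospital-outpatient 0.8; chronic dispensings 0.7 | plausible utilization with a post-index specialist surge |

Ages come from a two-point mixture (25% in 35–60, 75% in 61–88) around
the observed medians; it exists for plausibility only and no
quantitative claim attaches to it. Therapy events sit on a fixed
0/7/14/21-day grid inside the window because the rules constrain
windows, not intra-window timing. Planned exclusions are mutually
exclusive by construction, which is what makes the attrition-recovery
test exact. Untreated patients draw an "other category" subtype whose
events are constructed to land in exactly one branch of the cascade.

With `off_label_rate=0` and `type_specific_only=True` every drug in a
line window carries the patient's true type, so the classifier must
recover the truth exactly; raising the off-label rate degrades accuracy
monotonically. Infeasible combinations (e.g. SCLC mass on the
inhibitor group, whose drugs are all NSCLC-specific, with off-label use
disabled) are rejected at generation time.

**What the generator does not emulate:** real InGef marginal
distributions, comorbidity structure, coding errors, regional coding
practice, costs, or death events. Passing recovery tests therefore
demonstrates that the *rules are implemented correctly and are
mutually consistent*, not that the pipeline's outputs on real SHI data
would match any published count.

## Validation set-up and problem sizes

The suite validates each rule against hand-computed examples, each
boundary with a flip test (washout index−8 vs −9; biomarker discharge
day 14 vs 15; M2Q coding inside vs outside the horizon; window day 30
vs 31), and line construction against an independent brute-force
day-by-day simulator (exact agreement on 260 random trajectories plus
the edge panel). Statistical checks use a 5,000-patient population for
attrition conservation, 300 patients × 4 off-label rates × 3 seeds for
classifier degradation, 2,000 patients × 3 seeds for mixture recovery
(the classified NSCLC share must fall in the exact central binomial
95% interval of 0.80), and 500 patients × 2 seeds for contact-rate
recovery; these sizes give comfortable statistical resolution while
keeping the default suite fast. A committed 300-patient regression
bundle pins the full report byte-for-byte.

## Known limitations

- The pipeline stops at second-line therapy; third and later lines are
  out of scope, as are costs, dosing, regimen cycles, and survival.
- ICD-10-GM cannot express squamous vs non-squamous NSCLC; no attempt
  is made to sub-classify.
- Codes are opaque strings with prefix semantics; no validation against
  the official ICD-10-GM/ATC/OPS/EBM catalogues is performed.
- The run manifest records a configuration hash and code-table version
  but no wall-clock timestamp, keeping report bundles byte-identical
  for identical inputs.
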