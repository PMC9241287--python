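# lungclaims

Claims-database phenotyping of incident lung cancer on German
statutory-health-insurance (SHI) style billing data.

German SHI claims record diagnoses as ICD-10-GM codes billed per
calendar quarter, outpatient drug dispensings as ATC codes, inpatient
procedures as OPS codes, and outpatient services as EBM fee-schedule
items. They contain no histology, so whether a lung cancer patient has
non-small cell (NSCLC) or small cell (SCLC) disease — the single most
treatment-relevant distinction — must be *inferred* from the billing
trail. `lungclaims` implements that inference pipeline end to end:

1. **Incident-cohort selection.** The *index quarter* is the first
   quarter in the study period (2015–2016) with a C33/C34 diagnosis.
   The diagnosis counts as valid if coded in the outpatient setting in
   ≥ 2 different quarters (**M2Q criterion**) or once as a confirmed
   inpatient diagnosis. Incidence requires a *washout*: no C33/C34 in
   the 8 quarters before the index quarter. Patients are excluded for
   other primary solid tumors (C00–C75 without C33, C34, C44, C61)
   within ±8 quarters of the index, or for insufficient pre-/post-index
   enrollment; each excluded patient gets exactly one reason (first
   failing check in a fixed cascade), so the attrition table partitions
   the candidate pool.
2. **Staging** from metastasis codes in the index quarter:
   C78/C79 → distant metastases (stage IV), else C77 → lymph-node
   metastases, else no metastases.
3. **Treatment lines.** First-line therapy is the treatment whose start
   is billed in the index quarter or the following quarter; all
   therapy-relevant billing over one month (30 days) from that start is
   collected, and the episode is assigned hierarchically to
   Immunotherapy > Inhibitors > Chemotherapy > Radiotherapy > Study.
   The first therapy code after the first-line month that was *not*
   billed in the first-line window opens the second line (patients may
   stay in the same group). Untreated patients fall through a rule
   cascade of "other treatment" categories.
4. **Cancer-type call.** Most lung cancer drugs are approved for only
   one type; if the type tags of first-line window drugs are uniformly
   NSCLC or uniformly SCLC, that is the call, otherwise the second line
   is consulted; everything else (no listed drug, drugs outside the
   windows, or both types billed) is unclassifiable.
5. **Care attribution.** The "therapist" is the institution coding the
   diagnosis in a quarter, by hierarchy (inpatient hospital >
   outpatient hospital > office-based specialties); biomarker testing
   and bronchoscopy are detected from their EBM/OPS code sets and
   assigned inpatient status when a hospital stay is documented in the
   14 days before the test.
6. **Time expenditure.** Per relative quarter −4 … +8 around the index:
   pharmacy visits (distinct dispensing dates), primary-care and
   specialist contacts, inpatient hospital days, and outpatient
   hospital treatments, averaged within cancer-type × region strata.

Real SHI extracts are proprietary, so the package includes a
**synthetic claims generator** (`lungclaims.synth`) that emulates the
structural features these rules key on and carries ground-truth labels,
which the test suite uses for exact recovery checks.

## Worked example

```bash
lungclaims synth --out demo --n 500 --seed 7
lungclaims select --in demo --out demo/selection.csv
```

prints the attrition flow of the generated extract:

```
                                  step   n   pct
                            candidates 260 100.0
                excluded_not_confirmed   0   0.0
           excluded_prior_lc_diagnosis   0   0.0
 excluded_insufficient_pre_observation   7   2.7
          excluded_other_primary_tumor  90  34.6
excluded_insufficient_post_observation  28  10.8
                              included 135  51.9
```

Of the 500 insured, 260 had a C33/C34 diagnosis in 2015–2016
(candidates); 90 were excluded for another primary tumor, 35 for
truncated enrollment, and 135 enter the analysis population. Treatment
lines and cancer-type calls follow:

```bash
lungclaims lines --in demo --selection demo/selection.csv \
    --out-lines demo/lines.csv --out-types demo/types.csv
# wrote 115 episodes, 135 type calls
```

Among the 135 included patients, 61 are called NSCLC and 14 SCLC from
their line drugs; 60 remain unclassifiable (no type-specific drug in a
line window, or conflicting types). `lungclaims run-all --in demo
--out demo/report` produces the full bundle: selection, lines, types,
care, burden series, attrition, and crosstab CSVs plus a JSON manifest.

As a library:

```python
from lungclaims import ScenarioConfig, generate_population, select_cohort

records, truth = generate_population(ScenarioConfig(n_patients=500, seed=7))
selection = select_cohort(records)
print(selection["status"].value_counts())
```

## Caveats

The bundled code table covers the drug/procedure registry and the
diagnostic code sets printed in its source; the surgery OPS list and
therapist-specialty codes are *synthetic placeholders* (clearly marked)
and should be replaced with authoritative lists via
`PipelineConfig.surgery_codes` / a custom code table. The synthetic
generator emulates coding structure, not real-world marginals — see
`docs/methods.md` for what passing tests do and do not establish.
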