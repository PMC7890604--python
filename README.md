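# dxlatency

Completeness and timeliness of **structured** EHR diagnoses (ICD-9-CM /
ICD-10-CM codes) compared to **computed** (rule-based) diagnoses for
hypertension (HTN), hyperlipidemia (HLD), and diabetes mellitus (DM), as a
reusable analysis pipeline over PCORnet-CDM-shaped CSV tables — plus a
synthetic-data generator with a ground-truth ledger so every stage is
verifiable without access to real patient data.

## How it works

1. **`cdm_io`** loads `vital`, `lab_result_cm`, `diagnosis`/`condition`,
   `encounter`, and `demographic` CSV tables (PCORnet CDM v3.1 column names
   by default, remappable via config). `DX_SOURCE` values OD/BI/CL become
   provider/billing/claims; malformed rows are dropped and counted, never
   coerced. A study window restricts measurements and diagnoses to separate
   cutoffs (both ends inclusive).
2. **`phenotyping`** collapses measurements to per-day minima (same-day
   minimum = most conservative reading), flags *signal* days — outpatient BP
   ≥ 140 systolic or ≥ 90 diastolic, LDL ≥ 130 mg/dL (LOINC 13457-7,
   18262-6), HbA1c ≥ 6.5 % (LOINC 4548-4) — and derives a *computed
   diagnosis* dated at the second of any two signals ≥ 30 days apart.
3. **`diagnosis_matching`** normalizes code strings (dotless dialects are
   repaired) and matches their first 3 or 5 characters against per-condition
   parent code groups; the first structured diagnosis per patient breaks
   same-date ties by provider > billing > claims.
4. **`classification`** assigns each computed-diagnosis subject one of four
   temporal categories — `pre_existing`, `early`, `eventual`, `never` — and
   produces durations/censoring (censored at the most recent encounter).
5. **`survival`** computes the mean recording delay, mean censoring time,
   and the Kaplan–Meier curve of remaining undiagnosed (product-limit
   implemented directly, exact-rational running product, checked against
   lifelines in the tests).
6. **`synthetic_data`** generates CDM-shaped extracts from a seeded
   configuration (encounter Poisson process, measurement models,
   configurable recording-delay distribution and never-recorded
   probability) together with a truth ledger; degenerate draws (delay
   clipped past the cutoff, healthy false-signal pairs) are flagged so
   end-to-end replay tests can be exact.
7. **`pipeline` / `cli`** orchestrate everything and emit `report.json`,
   per-condition classification and KM CSVs, and optional plots.

## CLI

Generate a synthetic extract, then run the study:

```bash
dxlatency synth generate --config synth.yaml --out data/ [--seed 7]
dxlatency run --config study.yaml --out results/
```

Minimal `synth.yaml`:

```yaml
n_patients: 1000
seed: 7
conditions:
  HTN: {prevalence: 0.4}
  HLD: {prevalence: 0.3}
  DM:  {prevalence: 0.3, delay: {kind: exponential, mean_days: 200}}
```

Minimal `study.yaml`:

```yaml
tables:
  vital: data/vital.csv
  lab_result_cm: data/lab_result_cm.csv
  diagnosis: data/diagnosis.csv
  encounter: data/encounter.csv
data_start: 2012-01-01
measurement_cutoff: 2018-08-11
diagnosis_cutoff: 2019-02-10
conditions: [HTN, HLD, DM]
```

Exit codes: 0 success, 2 configuration error, 3 data error.

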