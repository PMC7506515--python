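# Cohort interchange schema

A cohort is a directory of UTF-8 flat files, one per EMR stream.  All
structured streams are CSV with a header row; clinical notes are JSONL
(one JSON object per line) because free text contains delimiters and
newlines.  Dates are ISO-8601 calendar dates (`YYYY-MM-DD`); time of day is
never stored.  Booleans are written `true`/`false` (readers also accept
`1`/`0`, `t`/`f`, `yes`/`no`; empty means false).  Writers emit a fixed
column order with rows sorted by primary id, so write → read → write is
byte-identical.

## patients.csv

| column | type | notes |
|---|---|---|
| patient_id | string | unique within the cohort |
| age | integer ≥ 0 | years |
| sex | `male` / `female` / `unknown` | |
| race | string | `unknown` when missing |
| ethnicity | string | `unknown` when missing |
| congestive_heart_failure | bool | comorbidity indicator |
| solid_tumor_without_metastasis | bool | |
| coagulopathy | bool | |
| diabetes_uncomplicated | bool | |
| diabetes_complicated | bool | |
| obesity | bool | |
| pulmonary_circulation_disease | bool | |
| renal_failure | bool | |
| death_date | date or empty | |

Comorbidities arrive precomputed (e.g. from a comorbidity-software run);
this package never derives them from diagnosis codes.

## procedures.csv

| column | type | notes |
|---|---|---|
| procedure_id | string | unique; the unit of surveillance |
| patient_id | string | must resolve to patients.csv |
| procedure_date | date | day 0 for every surveillance window |
| facility_id | string | |
| emergent | bool | |

## diagnoses.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| code | string | ICD-10-CM; normalized uppercase, matched prefix-wise with dots ignored |
| event_date | date | |

## pharmacy.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| drug_name | string | matched case-insensitively against the antibiotic config |
| fill_date | date | |
| days_supplied | integer ≥ 1 | |

## micro.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| order_date | date | |
| specimen_class | `blood` / `cardiac` / `miscellaneous` / `other` | |
| culture_positive | bool | |
| susceptibility_tested | bool | |
| result_text | string | free text; scanned for organism keywords |

## vitals.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| measure | `temperature_c` | |
| value | float | °C; values outside 30–45 are rejected at read time |
| measured_at | date | |

## notes.jsonl

One JSON object per line with keys `note_id` (unique), `patient_id`,
`note_title`, `note_date`, `text`.

## truth.csv (review labels)

| column | type | notes |
|---|---|---|
| procedure_id | string | |
| reviewed | bool | |
| infection | bool | implies reviewed |
| infection_type | `pocket` / `endocarditis_or_lead` / `cellulitis_only` / `none` | `none` iff no infection |
| present_on_admission | bool | infection present at the time of the procedure |
| onset_day | integer 0–90 or empty | days postprocedure |

## flags.csv (extractor output)

One row per procedure: `procedure_id`, `died_90d`, `emergent`, the eight
comorbidity columns, `icd_cied_infection`, `icd_ssi`,
`icd_unspecified_infection`, `fever_30d`, `antibiotic_class`
(`none` / `staph_directed` / `non_staph`), `micro_blood_pos`,
`micro_cardiac_pos`, `micro_misc_pos`, `micro_s_aureus`, `micro_cons`,
`micro_order_no_staph`, `note_infection_post`, `note_infection_pre`.
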