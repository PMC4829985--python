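# CSV schemas

All files are plain CSV with a header row; floats are written with
repr round-trip precision and parsed back exactly, so write-then-read
is the identity on every dataset.

## registry.csv

| column | type | notes |
|---|---|---|
| code | str | metabolite short name, unique |
| lod | float > 0 | raw (pre-correction) limit of detection, ug/L |
| correction_factor | float in (0, 1] | 1.0 when no correction applies |
| mol_weight | float > 0 | g/mol (= ug/umol) |
| group | `DEHP` or `single` | exactly four rows carry `DEHP` |

## mothers.csv

One row per mother/child pair. Required columns: `subject_id`,
`creatinine` (mg/dL, > 0), `collection_date` (ISO-8601),
`race_ethnicity` (0 = non-Hispanic white, 1 = non-Hispanic black,
2 = Hispanic/other), `maternal_age` (years), `education`,
`work_status`, `smoking` (each 0/1), `prepreg_bmi` (kg/m^2),
`maternal_height` (m), `first_preg_weight` (kg), `gestational_age`
(weeks), `birth_weight` (g), `child_sex` (0/1, 1 = male). Optional
(empty = missing, imputed inside the MCMC): `last_preg_weight` (kg),
`breastfed` (0/1).

Plus one column per registry code holding the raw concentration in
ug/L, or the literal token `<LOD` for a censored cell. Internally a
censored cell is stored as the pair (raw-LOD placeholder, flag); the
placeholder never enters modeling.

## visits.csv

One row per (subject, visit): `subject_id`, `visit` (1–3),
`age_months`, `weight` (kg), `fat_mass` (kg; empty iff
`outcome_missing` = 1), `height` (m), `active` (0/1, empty = missing),
`outcome_missing` (0/1). `0 <= fat_mass < weight` where observed;
duplicate (subject, visit) pairs are rejected.

## lms.csv

Growth-reference rows for BMI z-scores: `sex` (0/1), `age_months`,
`L`, `M` (> 0), `S` (> 0). The bundled `lms_synthetic.csv` is a
synthetic stand-in with plausible magnitudes, not a published
reference.
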