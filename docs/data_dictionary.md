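# Cohort file formats

One CSV per event type, comma-delimited, UTF-8, ISO-8601 dates
(`YYYY-MM-DD`), header row mandatory.  Optional fields are written as
empty strings.  Booleans are `true`/`false` (also accepted: `1`/`0`,
`yes`/`no`).  Malformed rows are collected into `rejects.csv`
(`file,row,reason`), never silently dropped.

## patients.csv

| column | type | notes |
|---|---|---|
| patient_id | string | unique |
| gender | `female` \| `male` | |
| age_years | int ≥ 0 | at ART initiation; the ≤30 / 31–40 / >40 band is derived |
| married | bool | |
| education | `none` \| `primary` \| `secondary+` | |
| occupation | `employed` \| `self-employed` \| `unemployed` | |
| living | `alone` \| `with_child_only` \| `with_adult` | |
| support_partner | bool | treatment support partner |
| facility_id | string | |
| facility_management | `government` \| `other` | |
| location | `capital` \| `other_urban` \| `rural` | |
| who_stage | 1–4 | WHO clinical stage at initiation |
| tb_at_initiation | bool | |
| pmtct_history | bool | females only |
| prior_art_exposure | bool | PMTCT does not count |
| initiation_date | date | day 0 of all day arithmetic |
| baseline_weight_kg | float > 0 | |
| baseline_cd4 | int ≥ 0 | cells/mm³ |
| baseline_cd4_date | date | must fall within 91 days before initiation for eligibility |
| data_collection_date | date | observation is censored here |
| selfreport_scale | `three_level` \| `two_level` | two-level facilities are excluded from self-report analyses |

## visits.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| actual_date | date | ≥ initiation_date |
| scheduled_date | date, optional | blank when no appointment was recorded |
| weight_kg | float, optional | |
| selfreport_code | 1 \| 2 \| 3, optional | perfect / good / poor |
| regimen_id | string, optional | |
| side_effect_or_oi_flag | bool | side effect or opportunistic infection noted |

## dispensings.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| dispense_date | date | |
| components | `DRUG:days;DRUG:days;...` | per-component days of supply; effective supply is the minimum |
| regimen_id | string, optional | |
| contains_pi | bool | protease-inhibitor regimen |

## cd4.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| test_date | date | |
| count | int ≥ 0 | cells/mm³ |
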