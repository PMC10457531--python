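# Participant table schema

CSV input to the pipeline (`--input`); one row per participant, missing
values as empty fields. The same schema is produced by the synthetic
generator and expected for external-trial tables (`--external`).

| column | type | values / range | description |
|---|---|---|---|
| participant_id | string | free | opaque identifier (optional) |
| trial | categorical | trial_A, trial_B, external | source trial (never missing) |
| arm | categorical | control, intervention | randomized allocation (never missing) |
| gender | binary | female / male | |
| relationship | binary | yes / no | living in a partnership |
| education | binary | >13y / <=13y | more than 13 years of education |
| children | binary | yes / no | |
| lifetime_scid | binary | yes / no | lifetime depressive disorder (structured clinical interview) |
| prev_psychotherapy | binary | yes / no | previous psychotherapy |
| prev_dep_medication | binary | yes / no | previous antidepressant medication |
| prev_pain_medication | binary | yes / no | previous back-pain medication |
| sick_leave | binary | yes / no | currently on sick leave |
| social_support | binary | good / low | (very) good perceived social support |
| internet_affinity | integer | 0–20 | Internet affinity scale |
| recruitment | binary | online / onsite | recruitment channel |
| age | integer | 18–99 | years |
| phq9_baseline | integer | 0–27 (≥5 in generated data) | depressive symptom severity, baseline |
| hamd_baseline | integer | 0–52 | clinician-rated depression, baseline |
| nrs_pain | integer | 0–10 | pain intensity, numerical rating scale |
| aqol | integer | 0–100 | health-related quality of life (AQoL-6D) |
| pseq | integer | 0–60 | pain self-efficacy questionnaire |
| spe | integer | 0–3 | subjective prognosis of employment |
| odi | integer | 0–100 | pain-related disability (Oswestry) |
| phq9_post | integer or empty | 0–27 | depressive symptom severity at post-test (may be missing) |

Binary columns are coded to 0/1 indicators of the first listed (positive)
level wherever a numeric design is built; numeric 0/1 input is accepted
as-is.
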