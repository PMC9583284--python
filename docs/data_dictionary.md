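# Data dictionary

All tabular interfaces are CSV with ISO-8601 timestamps
(`YYYY-MM-DDTHH:MM:SS`). Missing values are empty cells.

## Source record files

One file per source: `nhs111.csv`, `ambulance.csv`, `ed.csv`,
`inpatient.csv`. All share the same columns; fields that do not apply to a
source are always empty.

| column | type | notes |
|---|---|---|
| record_id | string | unique across all sources; sortable |
| source | code | `NHS111`, `AMB`, `ED`, `IP` |
| provider_code | string | supplying organisation |
| provider_patient_id | string | local patient ID; **never present for AMB**; may have lost leading zeros |
| nhs_number | string | 10 digits, mod-11 check digit; validated on ingest |
| dob | date | date of birth; blanked on ingest if outside [activity − 110 y, activity] |
| age_at_activity | integer | completed years at the event |
| first_name, last_name | string | **never present for NHS111**; normalized to A–Z, hyphen, apostrophe |
| sex | code | `male`, `female` |
| postcode | string | normalized `OUT IN` form (e.g. `S10 2HQ`); for AMB this is the **incident location**, not residence |
| start_datetime | timestamp | call start (NHS111, AMB), arrival (ED), episode start (IP); the governing date for period exclusions |
| end_datetime | timestamp | call end / **arrival at conveyance destination (AMB)** / departure (ED) / discharge (IP) |
| site | code | hospital site: destination for conveyed AMB, attending site for ED/IP |
| conveyed | boolean | AMB only: incident ended in conveyance to hospital |
| admission_method | code | IP only: `emergency` or `other` |
| clinical_key | string | treating specialty + primary diagnosis, `SPEC\|Dxx`; used by duplicate detection |
| disposition | code | NHS111 only: `self_care`, `primary_care`, `ed_advised`, `ambulance_dispatched` |

Generator output additionally carries `truth_person_id` (stripped before
the pipeline sees the data) and a separate `truth.csv` with columns
`record_id, person_id`, plus `config.json` recording every generator
parameter.

## Pipeline artefacts (`write_outputs`)

| file | columns |
|---|---|
| `assignments.csv` | record_id, entity_id, step (`S1`…`S7`, `P`) |
| `step_counts.csv` | source × step record counts |
| `candidate_pairs.csv` | amb_record_id, hosp_record_id, hosp_source, `cmp_<field>` (1 agree / 0 disagree / −1 missing), `sim_first_name`, `sim_last_name`, both_nhs_known, nhs_agree, weight |
| `model.json` | fields, m, u, p, agreement_weight, disagreement_weight, log_likelihood_trace, converged |
| `threshold_curve.csv` | threshold, sensitivity, specificity, ppv, f_measure |
| `threshold_curve.png` | the four measures against threshold, chosen threshold marked |
| `accepted_links.csv` | amb_record_id, hosp_record_id, hosp_source, weight |
| `platform/` | final per-source CSVs (layout above) |
| `assembly_report.csv` | per source: total, duplicates, excluded_date, excluded_nonemergency, final |
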