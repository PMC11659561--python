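# Participant–eye table format

Comma-separated, UTF-8, header required, one row per eye. At most one row
per (participant_id, laterality). Canonical column registry:

| column | type | required | values / units |
|---|---|---|---|
| `participant_id` | text | yes | unique per participant; opaque |
| `laterality` | categorical | yes | `left`, `right` |
| `age` | number | no | years |
| `sex` | categorical | no | `male`, `female` |
| `race` | categorical | no | `White`, `American Indian or Alaska Native`, `Asian`, `Black or African American`, `Latino`, `Native Hawaiian or Other Pacific Islander`, `Refuse to provide`, `Unknown`, `Other`, `Mixed Race` |
| `ethnicity` | categorical | no | `Hispanic or Latino`, `Not Hispanic or Latino`, `Unknown or Not Reported` |
| `hba1c` | number | no | percent |
| `etdrs_level1` | text | yes | base code (10, 12, 14, 15, 20, 35, 43, 47, 53, 55, 60, 61, 65, 71, 75, 81, 85, 90) plus optional modifier letter A–F, e.g. `35C` |
| `dme_level1` | boolean | yes | `true`/`false` or `1`/`0` |
| `cidme` | boolean | no | center-involved DME |
| `csdme` | boolean | no | clinically significant DME |
| `centerfield_thickness_um` | number | no | µm, OCT central subfield |
| `level2_grade` | categorical | no | `detected`, `not_detected`, `ungradable` |
| `ai_output` | categorical | no | `detected`, `not_detected`, `insufficient_quality` |
| `dilated` | boolean | no | defaults to `false` |
| `n_attempts` | integer | no | 1–6 (up to 3 undilated + 3 dilated); defaults to 1 |

Demographics are repeated on each of a participant's rows; the first row
read wins. When both `cidme` and `csdme` are present, `dme_level1` must
equal their OR. Malformed rows are rejected with their row number and
column. `drdtrial.read_trial_table` / `write_trial_table` round-trip this
format losslessly.

The packaged reference fixture `src/drdtrial/data/paper_eyes.csv` uses the
required columns plus demographics only; AI outputs and Level II grades are
absent from it by design.
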