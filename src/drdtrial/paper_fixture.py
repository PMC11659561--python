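"""Deterministic reconstruction of the 1073-eye analyzable reference dataset.

The trial's raw data are proprietary, but the printed marginal counts pin down
a reference dataset exactly at the level this package analyzes it:

* 567 participants, 1073 eyes (61 single-eye participants);
* the published ETDRS severity distribution (545 eyes at level 10, …, 1 eye
  at level 90; 275 eyes at level >= 35, 24 at >= 53);
* 43 DME eyes, of which the printed totals force 36 to sit below ETDRS 35 and
  7 at ETDRS >= 53 (so that DRD-positive eyes total 311 and vision-threatening
  DRD eyes total 60);
* 221 DRD-positive participants (90 with both eyes positive, 131 with one).

Within-stratum placement of DME, the pairing of specific eyes into specific
participants, demographics and OCT thickness draws are not identifiable from
the publication; they are fixed by an internal seed so the fixture is
byte-stable.  AI outputs and Level II grades are deliberately absent: the
fixture carries reference labels only.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .trial_data import (
    ETDRSLevel,
    EyeRecord,
    ParticipantRecord,
    TrialDataset,
    read_trial_table,
)

__all__ = ["ETDRS_SEVERITY_COUNTS", "build_reference_dataset", "load_paper_eyes"]

#: Published ETDRS severity distribution of the 1073 analyzable eyes.
ETDRS_SEVERITY_COUNTS: dict[str, int] = {
    "10": 545,
    "12": 95,
    "14B": 5,
    "15": 16,
    "20": 137,
    "35A": 2,
    "35B": 12,
    "35C": 57,
    "35D": 9,
    "35E": 27,
    "35F": 106,
    "43A": 17,
    "43B": 19,
    "47A": 2,
    "60": 4,
    "61A": 5,
    "61B": 9,
    "65A": 1,
    "65B": 1,
    "71A": 1,
    "71C": 1,
    "71D": 1,
    "90": 1,
}

#: DME eye allocation forced by the printed totals (43 DME, 311 DRD+, 60 vtDRD).
N_DME_BELOW_35 = 36
N_DME_AT_53_PLUS = 7

_N_PARTICIPANTS = 567
_N_BOTH_POSITIVE = 90  # 311 positive eyes over 221 positive participants
_N_ONE_POSITIVE = 131
_N_SINGLE_EYE = 61  # 2*567 - 1073

# Single-race assignment summing to 567 (the published multi-select counts sum
# to 579; White absorbs the overlap so the Black count used by the bias audit
# stays at the published 98).
_RACE_COUNTS = {
    "White": 373,
    "American Indian or Alaska Native": 13,
    "Asian": 35,
    "Black or African American": 98,
    "Latino": 34,
    "Native Hawaiian or Other Pacific Islander": 6,
    "Unknown": 1,
    "Other": 2,
    "Mixed Race": 5,
}
_ETHNICITY_COUNTS = {
    "Not Hispanic or Latino": 304,
    "Hispanic or Latino": 259,
    "Unknown or Not Reported": 4,
}
_N_MALE = 288

_FIXTURE_SEED = 20230329  # fixed: the fixture must be byte-stable


def _draw_thickness(rng: np.random.Generator, dme: bool, positive: bool) -> float:
    """OCT central-subfield thickness, µm.  DME eyes come from a shifted
    component (mean 307); non-DME eyes are capped below the 300 µm CIDME
    threshold so the center-involvement rule stays consistent with labels."""
    if dme:
        return float(np.round(rng.normal(307.0, 35.0), 1))
    mean, sd = (245.0, 35.0) if positive else (242.0, 22.0)
    for _ in range(100):
        t = rng.normal(mean, sd)
        if 100.0 < t <= 300.0:
            return float(np.round(t, 1))
    return 300.0


def build_reference_dataset() -> TrialDataset:
    """Build the 1073-eye reference dataset from the published counts."""
    rng = np.random.default_rng(_FIXTURE_SEED)

    # --- eye truth labels -------------------------------------------------
    levels: list[ETDRSLevel] = []
    for label, count in ETDRS_SEVERITY_COUNTS.items():
        levels.extend([ETDRSLevel.from_string(label)] * count)

    below35 = [i for i, lv in enumerate(levels) if lv.base < 35]
    at53plus = [i for i, lv in enumerate(levels) if lv.base >= 53]
    dme_idx = set(rng.choice(below35, size=N_DME_BELOW_35, replace=False))
    dme_idx |= set(rng.choice(at53plus, size=N_DME_AT_53_PLUS, replace=False))

    eyes: list[tuple[ETDRSLevel, bool]] = [(lv, i in dme_idx) for i, lv in enumerate(levels)]
    positives = [e for e in eyes if e[0].base >= 35 or e[1]]
    negatives = [e for e in eyes if not (e[0].base >= 35 or e[1])]
    rng.shuffle(positives)
    rng.shuffle(negatives)

    # --- demographics -----------------------------------------------------
    sexes = ["male"] * _N_MALE + ["female"] * (_N_PARTICIPANTS - _N_MALE)
    races = [r for r, n in _RACE_COUNTS.items() for _ in range(n)]
    ethnicities = [e for e, n in _ETHNICITY_COUNTS.items() for _ in range(n)]
    rng.shuffle(sexes)
    rng.shuffle(races)
    rng.shuffle(ethnicities)
    ages = np.clip(rng.normal(54.1, 12.0, _N_PARTICIPANTS), 22.0, 87.0).round(0)
    hba1c = np.clip(rng.normal(10.0, 1.99, _N_PARTICIPANTS), 4.6, 15.3).round(1)

    # --- pair eyes into participants -------------------------------------
    # 90 both-positive, 131 one-positive, 285 two-eye negative, 61 single-eye
    # negative participants.
    pairs: list[list[tuple[ETDRSLevel, bool]]] = []
    pos = iter(positives)
    neg = iter(negatives)
    for _ in range(_N_BOTH_POSITIVE):
        pairs.append([next(pos), next(pos)])
    for _ in range(_N_ONE_POSITIVE):
        pairs.append([next(pos), next(neg)])
    n_both_negative = _N_PARTICIPANTS - _N_BOTH_POSITIVE - _N_ONE_POSITIVE - _N_SINGLE_EYE
    for _ in range(n_both_negative):
        pairs.append([next(neg), next(neg)])
    for _ in range(_N_SINGLE_EYE):
        pairs.append([next(neg)])
    order = rng.permutation(len(pairs))

    participants = []
    for k, j in enumerate(order):
        pid = f"P{k + 1:04d}"
        eye_records = []
        for slot, (level, dme) in enumerate(pairs[j]):
            thickness = _draw_thickness(rng, dme, level.base >= 35 or dme)
            cidme = thickness > 300.0
            csdme = bool(dme and (not cidme or rng.random() < 0.4))
            eye_records.append(
                EyeRecord(
                    participant_id=pid,
                    laterality=("right", "left")[slot],
                    etdrs_level1=level,
                    dme_level1=dme,
                    cidme=cidme,
                    csdme=csdme,
                    centerfield_thickness=thickness,
                    dilated=bool(rng.random() < 0.155),
                    n_attempts=int(rng.integers(1, 4)),
                )
            )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=float(ages[k]),
                sex=sexes[k],
                race=races[k],
                ethnicity=ethnicities[k],
                hba1c=float(hba1c[k]),
                eyes=tuple(eye_records),
            )
        )
    return TrialDataset(participants, metadata={"source": "published-counts", "seed": _FIXTURE_SEED})


def write_paper_eyes(path: str | Path) -> None:
    """Write the packaged fixture table: reference labels and demographics
    only (AI outputs, Level II grades and OCT fields are absent from the
    shipped fixture by design)."""
    from .trial_data import to_frame

    frame = to_frame(build_reference_dataset())
    slim = frame[
        ["participant_id", "laterality", "age", "sex", "race", "ethnicity", "etdrs_level1", "dme_level1"]
    ].copy()
    slim["age"] = slim["age"].astype(int)
    slim["dme_level1"] = slim["dme_level1"].astype(int)
    slim["participant_id"] = slim["participant_id"].str.replace("P0", "P", regex=False)
    slim.to_csv(path, index=False)


def load_paper_eyes() -> TrialDataset:
    """Load the packaged ``paper_eyes.csv`` reference fixture."""
    with resources.as_file(resources.files("drdtrial.data") / "paper_eyes.csv") as path:
        ds = read_trial_table(path)
    ds.metadata["source"] = "paper_eyes.csv"
    return ds
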