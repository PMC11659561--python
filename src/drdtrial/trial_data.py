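"""Domain types, case definitions, and tabular I/O for participant–eye trial data.

The analysis unit hierarchy of a paired-eye screening trial: each participant
contributes one or two eyes; each eye carries a Level I prognostic-standard
label (ETDRS severity level plus diabetic macular edema flags graded from
widefield stereo photography and OCT), an optional Level II reading-center
label (graded from the same single-field image the AI consumes), the AI's
output, and imaging-protocol metadata.

Case definitions
----------------
An eye is *DRD-positive* (referable diabetic retinal disease) when its ETDRS
severity level is 35 or higher, or DME is present.  *Vision-threatening DRD*
(vtDRD) raises the severity cut to ETDRS 53.  *Center-involved DME* (CIDME)
is OCT central-subfield thickness strictly greater than 300 µm.  Participants
are classified by a worst-eye rule: positive if any eye is positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ETDRS_BASES",
    "ETDRSLevel",
    "EyeRecord",
    "ParticipantRecord",
    "TrialDataset",
    "TrialDataError",
    "is_drd_positive",
    "is_vtdrd",
    "classify_cidme",
    "participant_reference_positive",
    "participant_ai_output",
    "participant_level2_positive",
    "read_trial_table",
    "write_trial_table",
    "waterfall_summary",
    "COLUMN_REGISTRY",
]

#: Valid ETDRS severity base codes, from no retinopathy (10) to advanced
#: proliferative disease (90).  Ordering of severity follows numeric order.
ETDRS_BASES: tuple[int, ...] = (10, 12, 14, 15, 20, 35, 43, 47, 53, 55, 60, 61, 65, 71, 75, 81, 85, 90)

#: CIDME threshold: OCT central-subfield thickness must strictly exceed this.
CIDME_THICKNESS_UM: float = 300.0

AI_OUTPUTS = ("detected", "not_detected", "insufficient_quality")
LEVEL2_GRADES = ("detected", "not_detected", "ungradable")
SEXES = ("male", "female")
ETHNICITIES = ("Hispanic or Latino", "Not Hispanic or Latino", "Unknown or Not Reported")
RACES = (
    "White",
    "American Indian or Alaska Native",
    "Asian",
    "Black or African American",
    "Latino",
    "Native Hawaiian or Other Pacific Islander",
    "Refuse to provide",
    "Unknown",
    "Other",
    "Mixed Race",
)
LATERALITIES = ("left", "right")


class TrialDataError(ValueError):
    """Invalid or inconsistent trial data."""


@dataclass(frozen=True)
class ETDRSLevel:
    """An ETDRS severity level: integer base code plus optional modifier letter.

    Modifier letters (A–F) subdivide a level for grading detail; they are kept
    for display and stratification but never enter ordinal comparisons, which
    are defined on the base code alone.
    """

    base: int
    modifier: str = ""

    def __post_init__(self) -> None:
        if self.base not in ETDRS_BASES:
            raise TrialDataError(f"unknown ETDRS base code {self.base!r}")
        if self.modifier and not re.fullmatch(r"[A-F]", self.modifier):
            raise TrialDataError(f"invalid ETDRS modifier {self.modifier!r}")

    # Ordinal comparisons use the base code only.
    def __lt__(self, other: "ETDRSLevel") -> bool:
        return self.base < other.base

    def __le__(self, other: "ETDRSLevel") -> bool:
        return self.base <= other.base

    def __gt__(self, other: "ETDRSLevel") -> bool:
        return self.base > other.base

    def __ge__(self, other: "ETDRSLevel") -> bool:
        return self.base >= other.base

    def __str__(self) -> str:
        return f"{self.base}{self.modifier}"

    @classmethod
    def from_string(cls, text: str) -> "ETDRSLevel":
        """Parse labels like ``"35"``, ``"35A"`` or ``"35 A"``."""
        m = re.fullmatch(r"\s*(\d+)\s*([A-F]?)\s*", str(text))
        if not m:
            raise TrialDataError(f"cannot parse ETDRS level {text!r}")
        return cls(int(m.group(1)), m.group(2))


def is_drd_positive(etdrs: ETDRSLevel, dme: bool) -> bool:
    """Referable diabetic retinal disease: ETDRS level >= 35 or DME present."""
    return etdrs.base >= 35 or bool(dme)


def is_vtdrd(etdrs: ETDRSLevel, dme: bool) -> bool:
    """Vision-threatening DRD: ETDRS level >= 53 or DME present."""
    return etdrs.base >= 53 or bool(dme)


def classify_cidme(centerfield_thickness: Optional[float]) -> bool:
    """Center-involved DME: OCT central-subfield thickness strictly > 300 µm.

    Raises :class:`TrialDataError` when thickness is missing or non-positive,
    never silently returning ``False``.
    """
    if centerfield_thickness is None:
        raise TrialDataError("centerfield thickness missing: CIDME indeterminate")
    if centerfield_thickness <= 0:
        raise TrialDataError(f"non-positive centerfield thickness {centerfield_thickness!r}")
    return centerfield_thickness > CIDME_THICKNESS_UM


@dataclass(frozen=True)
class EyeRecord:
    """One eye's reference labels, AI output and protocol metadata.

    ``ai_output`` and ``level2_grade`` are optional because reconstructed
    reference datasets may carry Level I labels only.  ``n_attempts`` counts
    imaging attempts; the protocol allows at most three undilated and three
    dilated attempts.
    """

    participant_id: str
    laterality: str
    etdrs_level1: ETDRSLevel
    dme_level1: bool
    cidme: Optional[bool] = None
    csdme: Optional[bool] = None
    centerfield_thickness: Optional[float] = None
    level2_grade: Optional[str] = None
    ai_output: Optional[str] = None
    dilated: bool = False
    n_attempts: int = 1

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise TrialDataError(f"laterality must be left/right, got {self.laterality!r}")
        if self.ai_output is not None and self.ai_output not in AI_OUTPUTS:
            raise TrialDataError(f"invalid ai_output {self.ai_output!r}")
        if self.level2_grade is not None and self.level2_grade not in LEVEL2_GRADES:
            raise TrialDataError(f"invalid level2_grade {self.level2_grade!r}")
        if not 1 <= self.n_attempts <= 6:
            raise TrialDataError(f"n_attempts must be in 1..6, got {self.n_attempts}")
        if self.cidme is not None and self.csdme is not None:
            if bool(self.dme_level1) != (bool(self.cidme) or bool(self.csdme)):
                raise TrialDataError(
                    f"{self.participant_id}/{self.laterality}: dme_level1 must equal cidme OR csdme"
                )

    @property
    def drd_positive(self) -> bool:
        return is_drd_positive(self.etdrs_level1, self.dme_level1)

    @property
    def vtdrd(self) -> bool:
        return is_vtdrd(self.etdrs_level1, self.dme_level1)

    @property
    def diagnosable(self) -> bool:
        if self.ai_output is None:
            raise TrialDataError(f"{self.participant_id}/{self.laterality}: no AI output")
        return self.ai_output != "insufficient_quality"


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics plus one or two eyes; the cluster unit of the analysis."""

    participant_id: str
    age: float
    sex: str
    race: str
    ethnicity: str
    eyes: tuple[EyeRecord, ...]
    hba1c: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.eyes) <= 2:
            raise TrialDataError(f"{self.participant_id}: participants have 1 or 2 eyes")
        lats = [e.laterality for e in self.eyes]
        if len(set(lats)) != len(lats):
            raise TrialDataError(f"{self.participant_id}: duplicate laterality")
        for e in self.eyes:
            if e.participant_id != self.participant_id:
                raise TrialDataError(
                    f"eye {e.participant_id}/{e.laterality} does not belong to {self.participant_id}"
                )
        if self.sex not in SEXES:
            raise TrialDataError(f"{self.participant_id}: invalid sex {self.sex!r}")


def participant_reference_positive(p: ParticipantRecord) -> bool:
    """Worst-eye rule under the Level I standard: positive if any eye is."""
    return any(e.drd_positive for e in p.eyes)


def participant_level2_positive(p: ParticipantRecord) -> Optional[bool]:
    """Worst-eye rule under the Level II standard.

    Returns ``None`` when no eye has a gradable Level II label.
    """
    grades = [e.level2_grade for e in p.eyes if e.level2_grade in ("detected", "not_detected")]
    if not grades:
        return None
    return "detected" in grades


def participant_ai_output(p: ParticipantRecord) -> str:
    """Participant-level AI output.

    Detected if any diagnosable eye is detected; not detected if at least one
    eye is diagnosable and none detected; insufficient quality only when every
    eye is insufficient.  This any-diagnosable-eye rule is the only aggregation
    under which participant diagnosability can exceed eye-level diagnosability.
    """
    outputs = []
    for e in p.eyes:
        if e.ai_output is None:
            raise TrialDataError(f"{p.participant_id}/{e.laterality}: no AI output")
        outputs.append(e.ai_output)
    diagnosable = [o for o in outputs if o != "insufficient_quality"]
    if not diagnosable:
        return "insufficient_quality"
    return "detected" if "detected" in diagnosable else "not_detected"


@dataclass
class TrialDataset:
    """A collection of participants plus provenance metadata."""

    participants: list[ParticipantRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrialDataError(f"duplicate participant ids: {dupes[:5]}")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_eyes(self) -> int:
        return sum(len(p.eyes) for p in self.participants)

    def eyes(self) -> Iterator[EyeRecord]:
        for p in self.participants:
            yield from p.eyes

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    def subset(self, participant_ids: Iterable[str]) -> "TrialDataset":
        keep = set(participant_ids)
        return TrialDataset(
            [p for p in self.participants if p.participant_id in keep],
            dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Tabular I/O: one row per eye, comma-separated, UTF-8, header required.
# ---------------------------------------------------------------------------

#: Canonical column registry for the participant–eye table (one row per eye).
COLUMN_REGISTRY: tuple[str, ...] = (
    "participant_id",
    "laterality",
    "age",
    "sex",
    "race",
    "ethnicity",
    "hba1c",
    "etdrs_level1",
    "dme_level1",
    "cidme",
    "csdme",
    "centerfield_thickness_um",
    "level2_grade",
    "ai_output",
    "dilated",
    "n_attempts",
)

_REQUIRED_COLUMNS = ("participant_id", "laterality", "etdrs_level1", "dme_level1")

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(value, row: int, column: str, *, optional: bool = False):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        if optional:
            return None
        raise TrialDataError(f"row {row}: missing required value in column {column!r}")
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise TrialDataError(f"row {row}: invalid boolean {value!r} in column {column!r}")
    return _BOOL_MAP[key]


def _parse_float(value, row: int, column: str) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TrialDataError(f"row {row}: invalid number {value!r} in column {column!r}") from None


def _parse_categorical(value, row: int, column: str, allowed: Sequence[str]) -> Optional[str]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text not in allowed:
        raise TrialDataError(f"row {row}: invalid value {text!r} in column {column!r}")
    return text


def read_trial_table(path: str | Path) -> TrialDataset:
    """Read a participant–eye CSV into a :class:`TrialDataset`.

    Malformed rows are reported with their (1-based, header-exclusive) row
    number and offending column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialDataError(f"missing required columns: {missing}")

    by_participant: dict[str, dict] = {}
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        pid = str(rec["participant_id"]).strip()
        if not pid:
            raise TrialDataError(f"row {i}: empty participant_id")
        lat = _parse_categorical(rec["laterality"], i, "laterality", LATERALITIES)
        if lat is None:
            raise TrialDataError(f"row {i}: missing laterality")
        if (pid, lat) in seen:
            raise TrialDataError(f"row {i}: duplicate eye ({pid!r}, {lat!r})")
        seen.add((pid, lat))

        try:
            etdrs = ETDRSLevel.from_string(rec["etdrs_level1"])
        except TrialDataError as err:
            raise TrialDataError(f"row {i}: column 'etdrs_level1': {err}") from None
        eye = EyeRecord(
            participant_id=pid,
            laterality=lat,
            etdrs_level1=etdrs,
            dme_level1=_parse_bool(rec["dme_level1"], i, "dme_level1"),
            cidme=_parse_bool(rec.get("cidme"), i, "cidme", optional=True),
            csdme=_parse_bool(rec.get("csdme"), i, "csdme", optional=True),
            centerfield_thickness=_parse_float(rec.get("centerfield_thickness_um"), i, "centerfield_thickness_um"),
            level2_grade=_parse_categorical(rec.get("level2_grade"), i, "level2_grade", LEVEL2_GRADES),
            ai_output=_parse_categorical(rec.get("ai_output"), i, "ai_output", AI_OUTPUTS),
            dilated=_parse_bool(rec.get("dilated", "false"), i, "dilated", optional=True) or False,
            n_attempts=int(rec.get("n_attempts") or 1),
        )
        demo = by_participant.setdefault(
            pid,
            {
                "age": _parse_float(rec.get("age"), i, "age"),
                "sex": _parse_categorical(rec.get("sex"), i, "sex", SEXES) or "female",
                "race": _parse_categorical(rec.get("race"), i, "race", RACES) or "Unknown",
                "ethnicity": _parse_categorical(rec.get("ethnicity"), i, "ethnicity", ETHNICITIES)
                or "Unknown or Not Reported",
                "hba1c": _parse_float(rec.get("hba1c"), i, "hba1c"),
                "eyes": [],
            },
        )
        demo["eyes"].append(eye)

    participants = [
        ParticipantRecord(
            participant_id=pid,
            age=demo["age"] if demo["age"] is not None else float("nan"),
            sex=demo["sex"],
            race=demo["race"],
            ethnicity=demo["ethnicity"],
            hba1c=demo["hba1c"],
            eyes=tuple(demo["eyes"]),
        )
        for pid, demo in by_participant.items()
    ]
    return TrialDataset(participants, metadata={"source": str(path)})


def to_frame(ds: TrialDataset) -> pd.DataFrame:
    """Flatten a dataset to the canonical one-row-per-eye table."""
    rows = []
    for p in ds.participants:
        for e in p.eyes:
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "laterality": e.laterality,
                    "age": p.age,
                    "sex": p.sex,
                    "race": p.race,
                    "ethnicity": p.ethnicity,
                    "hba1c": "" if p.hba1c is None else p.hba1c,
                    "etdrs_level1": str(e.etdrs_level1),
                    "dme_level1": e.dme_level1,
                    "cidme": "" if e.cidme is None else e.cidme,
                    "csdme": "" if e.csdme is None else e.csdme,
                    "centerfield_thickness_um": ""
                    if e.centerfield_thickness is None
                    else e.centerfield_thickness,
                    "level2_grade": e.level2_grade or "",
                    "ai_output": e.ai_output or "",
                    "dilated": e.dilated,
                    "n_attempts": e.n_attempts,
                }
            )
    return pd.DataFrame(rows, columns=list(COLUMN_REGISTRY))


def write_trial_table(ds: TrialDataset, path: str | Path) -> None:
    """Write a dataset to the canonical participant–eye CSV."""
    to_frame(ds).to_csv(path, index=False)


def waterfall_summary(
    enrolled: TrialDataset, completed: TrialDataset, analyzable: TrialDataset
) -> pd.DataFrame:
    """STARD-style disposition table: counts and exclusions at each stage.

    The three datasets must be nested by participant id
    (analyzable ⊆ completed ⊆ enrolled).
    """
    stages = [("enrolled", enrolled), ("completed", completed), ("analyzable", analyzable)]
    prev_ids: Optional[set[str]] = None
    rows = []
    prev_counts = None
    for name, ds in stages:
        ids = {p.participant_id for p in ds.participants}
        if prev_ids is not None and not ids.issubset(prev_ids):
            raise TrialDataError(f"stage {name!r} is not a subset of the previous stage")
        counts = (ds.n_participants, ds.n_eyes)
        rows.append(
            {
                "stage": name,
                "participants": counts[0],
                "eyes": counts[1],
                "participants_excluded": 0 if prev_counts is None else prev_counts[0] - counts[0],
                "eyes_excluded": 0 if prev_counts is None else prev_counts[1] - counts[1],
            }
        )
        prev_ids, prev_counts = ids, counts
    return pd.DataFrame(rows)
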