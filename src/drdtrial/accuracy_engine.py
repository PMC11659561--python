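"""Confusion tables, accuracy metrics, diagnosability, worst-case imputation.

Units are eyes or participants; the truth standard is either the Level I
prognostic standard (ETDRS >= 35 or DME from widefield stereo photography and
OCT) or the Level II reading-center grade of the single-field image.  Units
whose AI output is insufficient quality never enter the four accuracy cells;
they are tallied separately by true status so the worst-case imputation
(count every insufficient diseased unit as a false negative, every
insufficient non-diseased unit as a false positive) can be applied exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .trial_data import (
    ParticipantRecord,
    TrialDataset,
    TrialDataError,
    participant_ai_output,
    participant_level2_positive,
    participant_reference_positive,
)

__all__ = [
    "ConfusionTable",
    "AccuracySummary",
    "UndefinedMetricError",
    "build_table",
    "sensitivity",
    "specificity",
    "predictive_values",
    "likelihood_ratios",
    "diagnosability",
    "worst_case_impute",
    "summarize",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty; signalled, never silently zero."""


@dataclass(frozen=True)
class ConfusionTable:
    """Counts among diagnosable units plus insufficient-quality counts by truth."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    insufficient_pos: int = 0
    insufficient_neg: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "insufficient_pos", "insufficient_neg"):
            if getattr(self, name) < 0:
                raise TrialDataError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.insufficient_pos + self.insufficient_neg

    @property
    def n_diagnosable(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _eye_truth(eye, reference: str) -> Optional[bool]:
    if reference == "level1":
        return eye.drd_positive
    if reference == "level2":
        if eye.level2_grade in ("detected", "not_detected"):
            return eye.level2_grade == "detected"
        return None  # ungradable or absent: excluded from Level II tables
    raise TrialDataError(f"unknown reference {reference!r}")


def _participant_truth(p: ParticipantRecord, reference: str) -> Optional[bool]:
    if reference == "level1":
        return participant_reference_positive(p)
    if reference == "level2":
        return participant_level2_positive(p)
    raise TrialDataError(f"unknown reference {reference!r}")


def build_table(ds: TrialDataset, unit: str = "eye", reference: str = "level1") -> ConfusionTable:
    """Classify every unit into exactly one of the six confusion cells.

    Level II tables exclude units the reading center could not grade (they
    have no truth label); a missing AI output is an error naming the unit.
    """
    if unit not in ("eye", "participant"):
        raise TrialDataError(f"unknown unit {unit!r}")
    tp = fp = fn = tn = ins_pos = ins_neg = 0

    if unit == "eye":
        items = [(e, _eye_truth(e, reference), e.ai_output) for e in ds.eyes()]
        for e, truth, out in items:
            if out is None:
                raise TrialDataError(f"eye {e.participant_id}/{e.laterality} has no AI output")
    else:
        items = []
        for p in ds.participants:
            items.append((p, _participant_truth(p, reference), participant_ai_output(p)))

    for _, truth, out in items:
        if truth is None:
            continue
        if out == "insufficient_quality":
            if truth:
                ins_pos += 1
            else:
                ins_neg += 1
        elif out == "detected":
            if truth:
                tp += 1
            else:
                fp += 1
        else:
            if truth:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp, fp, fn, tn, ins_pos, ins_neg)


def sensitivity(t: ConfusionTable) -> float:
    """TP / (TP + FN) among diagnosable units."""
    if t.tp + t.fn == 0:
        raise UndefinedMetricError("no diagnosable positive units")
    return t.tp / (t.tp + t.fn)


def specificity(t: ConfusionTable) -> float:
    """TN / (TN + FP) among diagnosable units."""
    if t.tn + t.fp == 0:
        raise UndefinedMetricError("no diagnosable negative units")
    return t.tn / (t.tn + t.fp)


def predictive_values(t: ConfusionTable) -> tuple[float, float]:
    """(PPV, NPV) = (TP/(TP+FP), TN/(TN+FN))."""
    if t.tp + t.fp == 0:
        raise UndefinedMetricError("no test-positive units")
    if t.tn + t.fn == 0:
        raise UndefinedMetricError("no test-negative units")
    return t.tp / (t.tp + t.fp), t.tn / (t.tn + t.fn)


def likelihood_ratios(t: ConfusionTable) -> tuple[float, float]:
    """(PLR, NLR) = (sens/(1-spec), (1-sens)/spec)."""
    sens, spec = sensitivity(t), specificity(t)
    if spec >= 1.0:
        raise UndefinedMetricError("PLR undefined at specificity 1")
    if spec <= 0.0:
        raise UndefinedMetricError("NLR undefined at specificity 0")
    return sens / (1.0 - spec), (1.0 - sens) / spec


def diagnosability(ds: TrialDataset, unit: str = "eye") -> float:
    """Fraction of units with a disease-level AI output (not insufficient)."""
    if unit == "eye":
        outputs = []
        for e in ds.eyes():
            if e.ai_output is None:
                raise TrialDataError(f"eye {e.participant_id}/{e.laterality} has no AI output")
            outputs.append(e.ai_output)
    elif unit == "participant":
        outputs = [participant_ai_output(p) for p in ds.participants]
    else:
        raise TrialDataError(f"unknown unit {unit!r}")
    if not outputs:
        raise UndefinedMetricError("no units")
    return sum(o != "insufficient_quality" for o in outputs) / len(outputs)


def worst_case_impute(t: ConfusionTable) -> ConfusionTable:
    """Assume every insufficient diseased unit is a false negative and every
    insufficient non-diseased unit a false positive; totals are preserved."""
    return ConfusionTable(
        tp=t.tp,
        fp=t.fp + t.insufficient_neg,
        fn=t.fn + t.insufficient_pos,
        tn=t.tn,
        insufficient_pos=0,
        insufficient_neg=0,
    )


@dataclass(frozen=True)
class AccuracySummary:
    """Derived metrics for one unit/reference combination."""

    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    plr: Optional[float]
    nlr: Optional[float]
    diagnosability: float
    n_units: int
    level: str
    reference: str


def summarize(
    ds: TrialDataset,
    unit: str = "eye",
    reference: str = "level1",
    *,
    worst_case: bool = False,
) -> AccuracySummary:
    """Build the confusion table and derive the full metric panel."""
    table = build_table(ds, unit, reference)
    if worst_case:
        table = worst_case_impute(table)

    def _maybe(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    pv = _maybe(predictive_values, table)
    lr = _maybe(likelihood_ratios, table)
    return AccuracySummary(
        sensitivity=sensitivity(table),
        specificity=specificity(table),
        ppv=pv[0] if pv else None,
        npv=pv[1] if pv else None,
        plr=lr[0] if lr else None,
        nlr=lr[1] if lr else None,
        diagnosability=diagnosability(ds, unit),
        n_units=table.total,
        level=unit,
        reference=reference,
    )
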