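"""Subgroup and intersectional accuracy audits with clustered bootstrap tests.

Accuracy parity across demographic subgroups is a pre-specifiable safety
property of a screening AI.  This module computes eye- or participant-level
sensitivity and specificity within two-level demographic partitions (male vs
female, Black vs non-Black, Hispanic vs non-Hispanic, or custom contrasts),
tests the group difference with a participant-clustered bootstrap, and
enforces the minimum-subgroup reporting rule: cells with fewer than ``min_n``
participants are suppressed entirely — no numeric estimate leaks into any
rendered output.

The two-sided p-value is the add-one-smoothed fraction of bootstrap
replicates whose group difference lands on the opposite side of zero from
each tail, doubled and capped at 1.  P-values are unadjusted for multiple
comparisons, matching the pre-specified reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .trial_data import ParticipantRecord, TrialDataset, TrialDataError
from .accuracy_engine import AccuracySummary, summarize
from .inference import BootstrapSettings, _extract_arrays

__all__ = ["SubgroupSpec", "BiasReport", "subgroup_accuracy", "bias_test", "intersectional_audit"]


def _sex_rule(p: ParticipantRecord) -> Optional[bool]:
    return p.sex == "male"


def _race_rule(p: ParticipantRecord) -> Optional[bool]:
    if p.race in ("Unknown", "Refuse to provide"):
        return None
    return p.race == "Black or African American"


def _ethnicity_rule(p: ParticipantRecord) -> Optional[bool]:
    if p.ethnicity == "Unknown or Not Reported":
        return None
    return p.ethnicity == "Hispanic or Latino"


_BUILTIN_CONTRASTS: dict[str, tuple[str, str, Callable[[ParticipantRecord], Optional[bool]]]] = {
    "sex": ("male", "female", _sex_rule),
    "race": ("Black", "non-Black", _race_rule),
    "ethnicity": ("Hispanic", "non-Hispanic", _ethnicity_rule),
}


@dataclass(frozen=True)
class SubgroupSpec:
    """A two-level partition of participants by a demographic attribute.

    ``rule`` maps a participant to True (group A), False (group B) or None
    (attribute unknown: excluded from the contrast).  The built-in attributes
    provide the conventional contrasts; ``custom`` requires an explicit rule.
    """

    attribute: str
    rule: Optional[Callable[[ParticipantRecord], Optional[bool]]] = None
    group_labels: tuple[str, str] = ("group_a", "group_b")
    min_n: int = 10

    def __post_init__(self) -> None:
        if self.min_n < 1:
            raise TrialDataError("min_n must be >= 1")
        if self.rule is None and self.attribute not in _BUILTIN_CONTRASTS:
            raise TrialDataError(f"custom attribute {self.attribute!r} requires an explicit rule")

    def resolve(self) -> tuple[str, str, Callable[[ParticipantRecord], Optional[bool]]]:
        if self.rule is not None:
            return self.group_labels[0], self.group_labels[1], self.rule
        return _BUILTIN_CONTRASTS[self.attribute]


@dataclass
class BiasReport:
    """Group estimates, difference and clustered-bootstrap p-value.

    When a group falls below ``min_n`` participants, ``reported`` is False and
    all numeric fields are None: the suppression rule is total.
    """

    attribute: str
    metric: str
    group_labels: tuple[str, str]
    group_ns: tuple[int, int]
    group_estimates: Optional[tuple[float, float]]
    difference: Optional[float]
    p_value: Optional[float]
    reported: bool
    suppression_reason: Optional[str] = None

    def render(self) -> str:
        if not self.reported:
            return f"{self.attribute}/{self.metric}: not reported (n<{self.suppression_reason or 'min'})"
        a, b = self.group_labels
        ea, eb = self.group_estimates  # type: ignore[misc]
        return (
            f"{self.attribute}/{self.metric}: {a} {100*ea:.1f}% vs {b} {100*eb:.1f}% "
            f"(diff {100*self.difference:+.1f} pp, p = {self.p_value:.3f}, unadjusted)"
        )


def _split(ds: TrialDataset, spec: SubgroupSpec) -> tuple[TrialDataset, TrialDataset]:
    _, _, rule = spec.resolve()
    a = [p for p in ds.participants if rule(p) is True]
    b = [p for p in ds.participants if rule(p) is False]
    return TrialDataset(a, dict(ds.metadata)), TrialDataset(b, dict(ds.metadata))


def subgroup_accuracy(
    ds: TrialDataset,
    spec: SubgroupSpec,
    metric: str = "sensitivity",
    unit: str = "eye",
    reference: str = "level1",
) -> dict[str, Optional[AccuracySummary]]:
    """Per-group accuracy panels; a group below ``min_n`` maps to None."""
    label_a, label_b, _ = spec.resolve()
    ds_a, ds_b = _split(ds, spec)
    out: dict[str, Optional[AccuracySummary]] = {}
    for label, sub in ((label_a, ds_a), (label_b, ds_b)):
        out[label] = summarize(sub, unit, reference) if sub.n_participants >= spec.min_n else None
    return out


def bias_test(
    ds: TrialDataset,
    spec: SubgroupSpec,
    metric: str = "sensitivity",
    unit: str = "eye",
    reference: str = "level1",
    settings: BootstrapSettings = BootstrapSettings(n_replicates=2000),
) -> BiasReport:
    """Two-sided clustered-bootstrap test of the subgroup metric difference.

    Each group's participants are resampled with replacement independently
    (clusters intact); replicates where either group's metric is undefined are
    dropped, with the same 10% tolerance as the primary analysis.
    """
    label_a, label_b, _ = spec.resolve()
    ds_a, ds_b = _split(ds, spec)
    n_a, n_b = ds_a.n_participants, ds_b.n_participants
    if min(n_a, n_b) < spec.min_n:
        return BiasReport(
            attribute=spec.attribute,
            metric=metric,
            group_labels=(label_a, label_b),
            group_ns=(n_a, n_b),
            group_estimates=None,
            difference=None,
            p_value=None,
            reported=False,
            suppression_reason=f"{spec.min_n}",
        )

    arr_a = _extract_arrays(ds_a, metric, unit, reference)
    arr_b = _extract_arrays(ds_b, metric, unit, reference)
    if arr_a.den.sum() == 0 or arr_b.den.sum() == 0:
        return BiasReport(
            attribute=spec.attribute,
            metric=metric,
            group_labels=(label_a, label_b),
            group_ns=(n_a, n_b),
            group_estimates=None,
            difference=None,
            p_value=None,
            reported=False,
            suppression_reason="undefined metric",
        )
    est_a = float(arr_a.num.sum() / arr_a.den.sum())
    est_b = float(arr_b.num.sum() / arr_b.den.sum())

    rng = np.random.default_rng(settings.seed)
    B = settings.n_replicates
    idx_a = rng.integers(0, n_a, size=(B, n_a))
    idx_b = rng.integers(0, n_b, size=(B, n_b))
    num_a, den_a = arr_a.num[idx_a].sum(axis=1), arr_a.den[idx_a].sum(axis=1)
    num_b, den_b = arr_b.num[idx_b].sum(axis=1), arr_b.den[idx_b].sum(axis=1)
    defined = (den_a > 0) & (den_b > 0)
    n_excluded = int(B - defined.sum())
    if n_excluded > 0.10 * B:
        raise TrialDataError(f"{n_excluded}/{B} bias-test replicates degenerate")
    diff = num_a[defined] / den_a[defined] - num_b[defined] / den_b[defined]
    m = len(diff)
    tail_low = (1 + int((diff <= 0).sum())) / (m + 1)
    tail_high = (1 + int((diff >= 0).sum())) / (m + 1)
    p = min(1.0, 2.0 * min(tail_low, tail_high))

    return BiasReport(
        attribute=spec.attribute,
        metric=metric,
        group_labels=(label_a, label_b),
        group_ns=(n_a, n_b),
        group_estimates=(est_a, est_b),
        difference=est_a - est_b,
        p_value=p,
        reported=True,
    )


def intersectional_audit(
    ds: TrialDataset,
    specs: Sequence[SubgroupSpec],
    metrics: Sequence[str] = ("sensitivity", "specificity"),
    unit: str = "eye",
    reference: str = "level1",
    settings: BootstrapSettings = BootstrapSettings(n_replicates=2000),
) -> list[BiasReport]:
    """Marginal and pairwise-intersection bias tests.

    Runs :func:`bias_test` for every attribute and, for every pair of
    attributes, for each of the four intersection cells against its
    complement.  Cells below ``min_n`` are returned suppressed.
    """
    if len(specs) < 2:
        raise TrialDataError("intersectional audit requires >= 2 subgroup specs")
    reports: list[BiasReport] = []
    for spec in specs:
        for metric in metrics:
            reports.append(bias_test(ds, spec, metric, unit, reference, settings))
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            la_i, lb_i, rule_i = specs[i].resolve()
            la_j, lb_j, rule_j = specs[j].resolve()
            min_n = max(specs[i].min_n, specs[j].min_n)
            for flag_i, name_i in ((True, la_i), (False, lb_i)):
                for flag_j, name_j in ((True, la_j), (False, lb_j)):
                    def cell_rule(p, fi=flag_i, fj=flag_j, ri=rule_i, rj=rule_j):
                        vi, vj = ri(p), rj(p)
                        if vi is None or vj is None:
                            return None
                        return vi is fi and vj is fj

                    cell_spec = SubgroupSpec(
                        attribute=f"{specs[i].attribute}×{specs[j].attribute}",
                        rule=cell_rule,
                        group_labels=(f"{name_i}&{name_j}", "complement"),
                        min_n=min_n,
                    )
                    for metric in metrics:
                        reports.append(bias_test(ds, cell_spec, metric, unit, reference, settings))
    return reports
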