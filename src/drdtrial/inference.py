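"""Participant-clustered bootstrap, non-inferiority testing, power simulation.

The primary analysis resamples whole participants (clusters of up to two
eyes) with replacement, so inter-eye correlation is respected; each replicate
may additionally be *spectrum-expanded* by appending resampled participants
who carry at least one ETDRS >= 53 eye until those eyes make up a target
fraction (default 20%) of Level-I-positive eyes, countering disease-spectrum
bias in a cohort recruited without known retinopathy.

Non-inferiority is one-sided: H0: p < p0 against HA: p >= p0, with p0 = 75%
for sensitivity and 77.5% for specificity.  The reported lower bound is the
empirical 2.5th percentile of replicate metrics; the non-inferiority p-value
is the add-one-smoothed bootstrap tail probability
(1 + #{replicates <= p0}) / (B + 1).  Study success requires both endpoints
to reject at one-sided alpha = 0.025.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trial_data import (
    ParticipantRecord,
    TrialDataset,
    TrialDataError,
    participant_ai_output,
)
from .accuracy_engine import _eye_truth, _participant_truth

__all__ = [
    "NIHypothesis",
    "BootstrapSettings",
    "BootstrapResult",
    "DesignSpec",
    "cluster_resample",
    "spectrum_expand",
    "bootstrap_metric",
    "study_success",
    "power_simulation",
    "hierarchical_test",
]


@dataclass(frozen=True)
class NIHypothesis:
    """Non-inferiority margins and the pre-specified point thresholds."""

    p0_sensitivity: float = 0.75
    p0_specificity: float = 0.775
    alpha_one_sided: float = 0.025
    point_thresholds: tuple[float, float] = (0.80, 0.80)

    def __post_init__(self) -> None:
        for p0, thr in zip((self.p0_sensitivity, self.p0_specificity), self.point_thresholds):
            if not 0.0 < p0 < thr < 1.0:
                raise TrialDataError(f"require 0 < p0 ({p0}) < threshold ({thr}) < 1")
        if not 0.0 < self.alpha_one_sided < 0.5:
            raise TrialDataError("alpha must be in (0, 0.5)")

    def p0(self, metric: str) -> float:
        if metric == "sensitivity":
            return self.p0_sensitivity
        if metric == "specificity":
            return self.p0_specificity
        raise TrialDataError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class BootstrapSettings:
    """Replicate count, seed, spectrum-expansion target and bound level."""

    n_replicates: int = 10_000
    seed: int = 0
    spectrum_target: float = 0.20
    expand_spectrum: bool = False
    bound_level: float = 0.975

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise TrialDataError("n_replicates must be >= 100")
        if not 0.0 < self.spectrum_target < 1.0:
            raise TrialDataError("spectrum_target must be in (0, 1)")


@dataclass
class BootstrapResult:
    """Point estimate, replicate distribution, lower bound and NI p-value."""

    metric: str
    point_estimate: float
    replicate_values: np.ndarray
    lower_bound: float
    ni_p_value: float
    n_excluded: int
    settings: BootstrapSettings
    hypothesis: NIHypothesis


# ---------------------------------------------------------------------------
# Object-level resampling operations
# ---------------------------------------------------------------------------


def _renumber(participants: list[ParticipantRecord]) -> list[ParticipantRecord]:
    """Disambiguate duplicated participants drawn with replacement."""
    from dataclasses import replace as _rep

    seen: dict[str, int] = {}
    out = []
    for p in participants:
        k = seen.get(p.participant_id, 0)
        seen[p.participant_id] = k + 1
        if k == 0:
            out.append(p)
        else:
            new_id = f"{p.participant_id}#{k}"
            out.append(
                _rep(p, participant_id=new_id, eyes=tuple(_rep(e, participant_id=new_id) for e in p.eyes))
            )
    return out


def cluster_resample(ds: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    """Resample whole participants with replacement to the original count."""
    if ds.n_participants == 0:
        raise TrialDataError("cannot resample an empty dataset")
    idx = rng.integers(0, ds.n_participants, ds.n_participants)
    drawn = [ds.participants[i] for i in idx]
    return TrialDataset(_renumber(drawn), {**ds.metadata, "resampled": True})


def _severe_fraction(ds: TrialDataset) -> tuple[int, int]:
    """(positive eyes at ETDRS >= 53, all Level-I-positive eyes)."""
    n53 = npos = 0
    for e in ds.eyes():
        if e.drd_positive:
            npos += 1
            if e.etdrs_level1.base >= 53:
                n53 += 1
    return n53, npos


def spectrum_expand(ds: TrialDataset, target: float, rng: np.random.Generator) -> TrialDataset:
    """Append resampled carriers of ETDRS >= 53 eyes until those eyes first
    reach the target fraction of Level-I-positive eyes.  No-op if already
    at or above target."""
    n53, npos = _severe_fraction(ds)
    if npos > 0 and n53 / npos >= target:
        return ds
    carriers = [p for p in ds.participants if any(e.etdrs_level1.base >= 53 for e in p.eyes)]
    if not carriers:
        raise TrialDataError("spectrum target unreachable: no ETDRS >= 53 carriers")
    extra: list[ParticipantRecord] = []
    while npos == 0 or n53 / npos < target:
        p = carriers[int(rng.integers(0, len(carriers)))]
        extra.append(p)
        for e in p.eyes:
            if e.drd_positive:
                npos += 1
                if e.etdrs_level1.base >= 53:
                    n53 += 1
    return TrialDataset(
        _renumber(list(ds.participants) + extra), {**ds.metadata, "spectrum_expanded": True}
    )


# ---------------------------------------------------------------------------
# Array-based bootstrap engine
# ---------------------------------------------------------------------------


@dataclass
class _ClusterArrays:
    """Per-participant counts sufficient for one metric's bootstrap."""

    num: np.ndarray  # numerator contribution (e.g. TP among diagnosable)
    den: np.ndarray  # denominator contribution (e.g. diagnosable positives)
    n53: np.ndarray  # positive eyes at ETDRS >= 53
    npos: np.ndarray  # Level-I-positive eyes
    carriers: np.ndarray  # indices of participants with any ETDRS >= 53 eye


def _extract_arrays(ds: TrialDataset, metric: str, unit: str, reference: str) -> _ClusterArrays:
    n = ds.n_participants
    num = np.zeros(n)
    den = np.zeros(n)
    n53 = np.zeros(n)
    npos = np.zeros(n)
    carrier = np.zeros(n, dtype=bool)
    want_positive = metric == "sensitivity"
    if metric not in ("sensitivity", "specificity"):
        raise TrialDataError(f"unknown metric {metric!r}")

    for i, p in enumerate(ds.participants):
        for e in p.eyes:
            if e.drd_positive:
                npos[i] += 1
                if e.etdrs_level1.base >= 53:
                    n53[i] += 1
            if e.etdrs_level1.base >= 53:
                carrier[i] = True
        if unit == "eye":
            for e in p.eyes:
                truth = _eye_truth(e, reference)
                if truth is None or truth is not want_positive:
                    continue
                if e.ai_output is None:
                    raise TrialDataError(f"eye {e.participant_id}/{e.laterality} has no AI output")
                if e.ai_output == "insufficient_quality":
                    continue
                den[i] += 1
                correct = (e.ai_output == "detected") if want_positive else (e.ai_output == "not_detected")
                num[i] += correct
        else:
            truth = _participant_truth(p, reference)
            out = participant_ai_output(p)
            if truth is None or truth is not want_positive or out == "insufficient_quality":
                continue
            den[i] = 1
            num[i] = (out == "detected") if want_positive else (out == "not_detected")
    return _ClusterArrays(num, den, n53, npos, np.flatnonzero(carrier))


def _bootstrap_from_arrays(
    arrays: _ClusterArrays,
    settings: BootstrapSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Replicate metric values (degenerate replicates excluded) and the
    number excluded."""
    n = len(arrays.num)
    B = settings.n_replicates
    idx = rng.integers(0, n, size=(B, n))
    num = arrays.num[idx].sum(axis=1)
    den = arrays.den[idx].sum(axis=1)

    if settings.expand_spectrum:
        s53 = arrays.n53[idx].sum(axis=1)
        spos = arrays.npos[idx].sum(axis=1)
        carriers = arrays.carriers
        target = settings.spectrum_target
        needs = np.flatnonzero((spos > 0) & (s53 < target * spos))
        if needs.size and carriers.size == 0:
            raise TrialDataError("spectrum target unreachable: no ETDRS >= 53 carriers")
        for b in needs:
            cs53, cspos, cnum, cden = s53[b], spos[b], num[b], den[b]
            while cs53 < target * cspos:
                j = carriers[int(rng.integers(0, carriers.size))]
                cs53 += arrays.n53[j]
                cspos += arrays.npos[j]
                cnum += arrays.num[j]
                cden += arrays.den[j]
            num[b], den[b] = cnum, cden

    defined = den > 0
    n_excluded = int(B - defined.sum())
    if n_excluded > 0.10 * B:
        raise TrialDataError(
            f"{n_excluded}/{B} bootstrap replicates had an undefined metric "
            "(no units in the denominator); the dataset is too sparse for this analysis"
        )
    return num[defined] / den[defined], n_excluded


def bootstrap_metric(
    ds: TrialDataset,
    metric: str,
    unit: str = "eye",
    reference: str = "level1",
    settings: BootstrapSettings = BootstrapSettings(),
    hypothesis: NIHypothesis = NIHypothesis(),
) -> BootstrapResult:
    """Clustered bootstrap of sensitivity or specificity with one-sided
    lower confidence bound and non-inferiority p-value."""
    arrays = _extract_arrays(ds, metric, unit, reference)
    if arrays.den.sum() == 0:
        raise TrialDataError(f"{metric} undefined on the full dataset")
    point = float(arrays.num.sum() / arrays.den.sum())

    rng = np.random.default_rng(settings.seed)
    values, n_excluded = _bootstrap_from_arrays(arrays, settings, rng)
    lower = float(np.quantile(values, 1.0 - settings.bound_level))
    p0 = hypothesis.p0(metric)
    ni_p = float((1 + int((values <= p0).sum())) / (len(values) + 1))
    return BootstrapResult(
        metric=metric,
        point_estimate=point,
        replicate_values=values,
        lower_bound=lower,
        ni_p_value=ni_p,
        n_excluded=n_excluded,
        settings=settings,
        hypothesis=hypothesis,
    )


def study_success(
    sensitivity_result: BootstrapResult,
    specificity_result: BootstrapResult,
    hypothesis: NIHypothesis = NIHypothesis(),
) -> bool:
    """Both one-sided null hypotheses must be rejected."""
    s_set, p_set = sensitivity_result.settings, specificity_result.settings
    if (s_set.n_replicates, s_set.spectrum_target, s_set.expand_spectrum, s_set.bound_level) != (
        p_set.n_replicates,
        p_set.spectrum_target,
        p_set.expand_spectrum,
        p_set.bound_level,
    ):
        raise TrialDataError("sensitivity and specificity results use mismatched settings")
    alpha = hypothesis.alpha_one_sided
    return sensitivity_result.ni_p_value < alpha and specificity_result.ni_p_value < alpha


def hierarchical_test(results: list[BootstrapResult], hypothesis: NIHypothesis = NIHypothesis()) -> list[bool]:
    """Fixed-sequence testing of an ordered endpoint list: each endpoint is
    tested at full alpha only while every earlier endpoint rejected; testing
    stops at the first failure (later endpoints are not tested)."""
    verdicts: list[bool] = []
    alive = True
    for r in results:
        if not alive:
            verdicts.append(False)
            continue
        ok = r.ni_p_value < hypothesis.alpha_one_sided
        verdicts.append(ok)
        alive = ok
    return verdicts


# ---------------------------------------------------------------------------
# Design power simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """The enrollment design: eye counts by stratum and the pairing of eyes
    into participant clusters.

    ``n_discordant_pairs`` participants carry one positive and one negative
    eye; the rest are concordant.  Severe (ETDRS >= 53) eyes are the larger of
    ``n_vtdrd_min`` and 20% of positive eyes, matching the severe fraction the
    design anticipates in screening populations.
    """

    n_pos_eyes: int = 200
    n_vtdrd_min: int = 20
    n_neg_eyes: int = 140
    n_discordant_pairs: int = 60
    q_fail_eye: float = 0.0

    def __post_init__(self) -> None:
        a2 = self.n_pos_eyes - self.n_discordant_pairs
        c2 = self.n_neg_eyes - self.n_discordant_pairs
        if a2 < 0 or c2 < 0 or a2 % 2 or c2 % 2:
            raise TrialDataError("discordant pairs incompatible with eye counts")

    @property
    def n_severe(self) -> int:
        return max(self.n_vtdrd_min, round(0.20 * self.n_pos_eyes))


def _simulate_design_arrays(
    design: DesignSpec,
    true_sensitivity: float,
    true_specificity: float,
    metric: str,
    rng: np.random.Generator,
) -> _ClusterArrays:
    a = (design.n_pos_eyes - design.n_discordant_pairs) // 2  # both-positive clusters
    b = design.n_discordant_pairs
    c = (design.n_neg_eyes - design.n_discordant_pairs) // 2  # both-negative clusters
    n = a + b + c

    npos = np.concatenate([np.full(a, 2.0), np.ones(b), np.zeros(c)])
    # Distribute severe eyes uniformly over positive eye slots.
    pos_owner = np.concatenate([np.repeat(np.arange(a), 2), np.arange(a, a + b)]).astype(int)
    severe_slots = rng.choice(design.n_pos_eyes, size=design.n_severe, replace=False)
    n53 = np.zeros(n)
    np.add.at(n53, pos_owner[severe_slots], 1.0)

    if metric == "sensitivity":
        diag = rng.random(design.n_pos_eyes) >= design.q_fail_eye
        correct = (rng.random(design.n_pos_eyes) < true_sensitivity) & diag
        den = np.zeros(n)
        num = np.zeros(n)
        np.add.at(den, pos_owner[diag], 1.0)
        np.add.at(num, pos_owner[correct], 1.0)
    else:
        neg_owner = np.concatenate([np.arange(a, a + b), np.repeat(np.arange(a + b, n), 2)]).astype(int)
        diag = rng.random(design.n_neg_eyes) >= design.q_fail_eye
        correct = (rng.random(design.n_neg_eyes) < true_specificity) & diag
        den = np.zeros(n)
        num = np.zeros(n)
        np.add.at(den, neg_owner[diag], 1.0)
        np.add.at(num, neg_owner[correct], 1.0)
    return _ClusterArrays(num, den, n53, npos, np.flatnonzero(n53 > 0))


def power_simulation(
    true_sensitivity: float,
    true_specificity: float,
    hypothesis: NIHypothesis = NIHypothesis(),
    settings: BootstrapSettings = BootstrapSettings(n_replicates=300),
    n_trials: int = 200,
    design: DesignSpec = DesignSpec(),
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of simulated design trials achieving study success.

    Returns per-endpoint and study-level power plus Monte-Carlo standard
    errors.  Each simulated trial enrolls the design's eye counts, draws AI
    outputs at the supplied true operating point, and runs the full clustered
    bootstrap on both endpoints.
    """
    if n_trials < 1:
        raise TrialDataError("n_trials must be >= 1")
    root = np.random.SeedSequence(seed)
    sens_hits = spec_hits = both_hits = 0
    for trial_ss in root.spawn(n_trials):
        rng = np.random.default_rng(trial_ss)
        ok = []
        for metric, p0 in (("sensitivity", hypothesis.p0_sensitivity), ("specificity", hypothesis.p0_specificity)):
            arrays = _simulate_design_arrays(design, true_sensitivity, true_specificity, metric, rng)
            values, _ = _bootstrap_from_arrays(arrays, settings, rng)
            ni_p = (1 + int((values <= p0).sum())) / (len(values) + 1)
            ok.append(ni_p < hypothesis.alpha_one_sided)
        sens_hits += ok[0]
        spec_hits += ok[1]
        both_hits += ok[0] and ok[1]

    def _se(k: int) -> float:
        p = k / n_trials
        return math.sqrt(p * (1 - p) / n_trials)

    return {
        "power_sensitivity": sens_hits / n_trials,
        "power_specificity": spec_hits / n_trials,
        "power_study": both_hits / n_trials,
        "mc_se_sensitivity": _se(sens_hits),
        "mc_se_specificity": _se(spec_hits),
        "mc_se_study": _se(both_hits),
        "n_trials": n_trials,
    }
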