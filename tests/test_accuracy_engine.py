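"""Confusion-table construction, derived metrics, worst-case imputation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drdtrial import (
    ConfusionTable,
    ETDRSLevel,
    EyeRecord,
    ParticipantRecord,
    TrialDataError,
    TrialDataset,
    UndefinedMetricError,
    build_table,
    diagnosability,
    likelihood_ratios,
    predictive_values,
    sensitivity,
    specificity,
    summarize,
    worst_case_impute,
)

tables = st.builds(
    ConfusionTable,
    tp=st.integers(0, 500),
    fp=st.integers(0, 500),
    fn=st.integers(0, 500),
    tn=st.integers(0, 500),
    insufficient_pos=st.integers(0, 100),
    insufficient_neg=st.integers(0, 100),
)


def _eye(pid, lat, base, dme, ai, level2=None):
    return EyeRecord(
        participant_id=pid,
        laterality=lat,
        etdrs_level1=ETDRSLevel(base),
        dme_level1=dme,
        ai_output=ai,
        level2_grade=level2,
    )


def _dataset(eye_specs):
    """eye_specs: list of per-participant lists of (base, dme, ai, level2)."""
    participants = []
    for i, spec in enumerate(eye_specs):
        pid = f"P{i}"
        eyes = tuple(
            _eye(pid, ("right", "left")[j], *args) for j, args in enumerate(spec)
        )
        participants.append(
            ParticipantRecord(pid, 50.0, "female", "White", "Not Hispanic or Latino", eyes)
        )
    return TrialDataset(participants)


class TestBuildTable:
    def test_single_positive_detected(self):
        t = build_table(_dataset([[(35, False, "detected", None)]]))
        assert (t.tp, t.fp, t.fn, t.tn, t.insufficient_pos, t.insufficient_neg) == (1, 0, 0, 0, 0, 0)

    def test_single_positive_insufficient(self):
        t = build_table(_dataset([[(35, False, "insufficient_quality", None)]]))
        assert t.insufficient_pos == 1 and t.n_diagnosable == 0

    def test_unit_conservation(self, small_trial):
        for unit in ("eye", "participant"):
            t = build_table(small_trial, unit)
            n = small_trial.n_eyes if unit == "eye" else small_trial.n_participants
            assert t.total == n

    def test_level2_excludes_ungradable(self):
        ds = _dataset(
            [
                [(35, False, "detected", "detected")],
                [(35, False, "detected", "ungradable")],
                [(10, False, "not_detected", None)],
            ]
        )
        t = build_table(ds, "eye", "level2")
        assert t.total == 1 and t.tp == 1

    def test_missing_ai_output_names_unit(self):
        with pytest.raises(TrialDataError, match="P0/right"):
            build_table(_dataset([[(35, False, None, None)]]))

    def test_matches_exhaustive_enumeration_on_tiny_datasets(self):
        outs = ("detected", "not_detected", "insufficient_quality")
        combos = list(itertools.product((10, 35), (False, True), outs))
        for a, b in itertools.product(combos, repeat=2):
            ds = _dataset([[(*a, None), (*b, None)]])
            t = build_table(ds, "eye")
            # oracle: classify each eye independently
            exp = dict(tp=0, fp=0, fn=0, tn=0, ip=0, ig=0)
            for base, dme, ai in (a, b):
                truth = base >= 35 or dme
                if ai == "insufficient_quality":
                    exp["ip" if truth else "ig"] += 1
                elif ai == "detected":
                    exp["tp" if truth else "fp"] += 1
                else:
                    exp["fn" if truth else "tn"] += 1
            assert (t.tp, t.fp, t.fn, t.tn, t.insufficient_pos, t.insufficient_neg) == (
                exp["tp"], exp["fp"], exp["fn"], exp["tn"], exp["ip"], exp["ig"],
            )


class TestMetrics:
    def test_worked_ratios(self):
        assert sensitivity(ConfusionTable(tp=220, fn=121)) == pytest.approx(0.645, abs=5e-4)
        assert specificity(ConfusionTable(tn=696, fp=134)) == pytest.approx(0.839, abs=5e-4)
        assert sensitivity(ConfusionTable(tp=5, fn=0)) == 1.0

    def test_chance_performance(self):
        t = ConfusionTable(tp=25, fp=25, fn=25, tn=25)
        assert predictive_values(t) == (0.5, 0.5)
        assert likelihood_ratios(t) == (1.0, 1.0)

    def test_plr_closed_form(self):
        # sens 0.796, spec 0.884 -> PLR = 0.796/0.116
        t = ConfusionTable(tp=796, fn=204, tn=884, fp=116)
        plr, _ = likelihood_ratios(t)
        assert round(plr, 2) == 6.86

    def test_ppv_one_when_no_false_positives(self):
        ppv, _ = predictive_values(ConfusionTable(tp=10, tn=5, fn=1))
        assert ppv == 1.0

    def test_empty_margins_signalled(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionTable(tn=10, fp=1))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionTable(tp=10, fn=1))
        with pytest.raises(UndefinedMetricError):
            likelihood_ratios(ConfusionTable(tp=1, fn=1, tn=5, fp=0))

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_lr_identities(self, t):
        try:
            plr, nlr = likelihood_ratios(t)
        except UndefinedMetricError:
            return
        sens, spec = sensitivity(t), specificity(t)
        assert abs(plr - sens / (1 - spec)) < 1e-12
        assert abs(nlr - (1 - sens) / spec) < 1e-12


class TestWorstCase:
    def test_identity_without_insufficient(self):
        t = ConfusionTable(tp=3, fp=2, fn=1, tn=4)
        assert worst_case_impute(t) == t

    def test_published_worked_examples(self):
        sens_t = worst_case_impute(ConfusionTable(tp=220, fn=56, insufficient_pos=65))
        assert sensitivity(sens_t) == pytest.approx(220 / 341)
        spec_t = worst_case_impute(ConfusionTable(tn=696, fp=91, insufficient_neg=43))
        assert specificity(spec_t) == pytest.approx(696 / 830)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_never_improves_metrics_and_preserves_total(self, t):
        w = worst_case_impute(t)
        assert w.total == t.total
        assert w.insufficient_pos == w.insufficient_neg == 0
        if t.tp + t.fn > 0:
            assert sensitivity(w) <= sensitivity(t)
        if t.tn + t.fp > 0:
            assert specificity(w) <= specificity(t)


class TestDiagnosability:
    def test_extremes(self):
        all_bad = _dataset([[(35, False, "insufficient_quality", None)]])
        all_good = _dataset([[(35, False, "detected", None)]])
        assert diagnosability(all_bad) == 0.0
        assert diagnosability(all_good) == 1.0

    def test_participant_rule_uses_any_eye(self):
        ds = _dataset([[(35, False, "insufficient_quality", None), (10, False, "not_detected", None)]])
        assert diagnosability(ds, "eye") == 0.5
        assert diagnosability(ds, "participant") == 1.0


def test_summarize_matches_components(small_trial):
    s = summarize(small_trial, "eye", "level1")
    t = build_table(small_trial, "eye", "level1")
    assert s.sensitivity == sensitivity(t)
    assert s.specificity == specificity(t)
    assert s.diagnosability == diagnosability(small_trial, "eye")
    assert s.n_units == small_trial.n_eyes
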