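"""Clustered bootstrap, spectrum expansion, non-inferiority mechanics."""

import numpy as np
import pytest

from drdtrial import (
    BootstrapSettings,
    ETDRSLevel,
    EyeRecord,
    NIHypothesis,
    ParticipantRecord,
    TrialDataError,
    TrialDataset,
    bootstrap_metric,
    cluster_resample,
    spectrum_expand,
    study_success,
)
from drdtrial.inference import BootstrapResult, DesignSpec, hierarchical_test, power_simulation


def _single_eye_ds(n_pos, n_tp, n_neg=0, n_tn=0, base_pos=35, n_severe=0):
    """n_pos single-eye positive participants of which n_tp detected, plus
    negatives; the first n_severe positives carry an ETDRS >= 53 eye."""
    participants = []
    k = 0
    for i in range(n_pos):
        base = 60 if i < n_severe else base_pos
        ai = "detected" if i < n_tp else "not_detected"
        pid = f"P{k}"; k += 1
        participants.append(
            ParticipantRecord(
                pid, 50.0, "female", "White", "Not Hispanic or Latino",
                (EyeRecord(pid, "right", ETDRSLevel(base), False, ai_output=ai),),
            )
        )
    for i in range(n_neg):
        ai = "not_detected" if i < n_tn else "detected"
        pid = f"P{k}"; k += 1
        participants.append(
            ParticipantRecord(
                pid, 50.0, "female", "White", "Not Hispanic or Latino",
                (EyeRecord(pid, "right", ETDRSLevel(10), False, ai_output=ai),),
            )
        )
    return TrialDataset(participants)


class TestClusterResample:
    def test_single_participant_always_itself(self):
        ds = _single_eye_ds(1, 1)
        rs = cluster_resample(ds, np.random.default_rng(0))
        assert rs.n_participants == 1
        assert rs.participants[0].eyes[0].etdrs_level1.base == 35

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrialDataError):
            cluster_resample(TrialDataset([]), np.random.default_rng(0))

    def test_cluster_integrity_over_replicates(self, small_trial):
        eye_counts = {p.participant_id: len(p.eyes) for p in small_trial}
        rng = np.random.default_rng(1)
        for _ in range(100):
            rs = cluster_resample(small_trial, rng)
            assert rs.n_participants == small_trial.n_participants
            for p in rs.participants:
                original = p.participant_id.split("#")[0]
                assert len(p.eyes) == eye_counts[original]
                assert all(e.participant_id == p.participant_id for e in p.eyes)

    def test_reference_fixture_resample_size(self, reference_ds):
        rs = cluster_resample(reference_ds, np.random.default_rng(2))
        assert rs.n_participants == 567


class TestSpectrumExpand:
    def test_noop_when_already_at_target(self):
        ds = _single_eye_ds(20, 10, n_severe=5)  # 25% severe
        out = spectrum_expand(ds, 0.20, np.random.default_rng(0))
        assert out is ds

    def test_first_crossing_property(self):
        ds = _single_eye_ds(100, 50, n_severe=5)  # 5% severe
        out = spectrum_expand(ds, 0.20, np.random.default_rng(3))
        n53 = sum(e.etdrs_level1.base >= 53 for e in out.eyes() if e.drd_positive)
        npos = sum(e.drd_positive for e in out.eyes())
        frac = n53 / npos
        assert 0.20 <= frac <= 0.20 + 1 / npos + 1e-9

    def test_unreachable_target_rejected(self):
        ds = _single_eye_ds(10, 5, n_severe=0)
        with pytest.raises(TrialDataError, match="unreachable"):
            spectrum_expand(ds, 0.2, np.random.default_rng(0))


class TestBootstrapMetric:
    def test_seed_determinism(self, small_trial):
        s = BootstrapSettings(n_replicates=200, seed=5, expand_spectrum=True)
        a = bootstrap_metric(small_trial, "sensitivity", settings=s)
        b = bootstrap_metric(small_trial, "sensitivity", settings=s)
        assert a.lower_bound == b.lower_bound
        assert a.ni_p_value == b.ni_p_value
        assert np.array_equal(a.replicate_values, b.replicate_values)

    def test_degenerate_perfect_metric(self):
        ds = _single_eye_ds(30, 30)
        s = BootstrapSettings(n_replicates=500, seed=0)
        r = bootstrap_metric(ds, "sensitivity", settings=s)
        assert r.point_estimate == 1.0
        assert r.lower_bound == 1.0
        assert r.ni_p_value == pytest.approx(1 / 501)

    def test_ni_p_nonincreasing_in_point_estimate(self):
        # fixed margin of 100 positives, varying correct count
        pvals = []
        for tp in (70, 75, 80, 85, 90):
            ds = _single_eye_ds(100, tp)
            r = bootstrap_metric(ds, "sensitivity", settings=BootstrapSettings(n_replicates=400, seed=7))
            pvals.append(r.ni_p_value)
        assert pvals == sorted(pvals, reverse=True)

    def test_undefined_metric_on_full_dataset_rejected(self):
        ds = _single_eye_ds(0, 0, n_neg=10, n_tn=9)
        with pytest.raises(TrialDataError):
            bootstrap_metric(ds, "sensitivity", settings=BootstrapSettings(n_replicates=100, seed=0))

    def test_expansion_applied_within_replicates(self):
        ds = _single_eye_ds(100, 80, n_severe=5)
        s = BootstrapSettings(n_replicates=200, seed=1, expand_spectrum=True)
        r = bootstrap_metric(ds, "sensitivity", settings=s)
        assert 0 < r.lower_bound <= r.point_estimate + 0.05


class TestStudySuccess:
    def _result(self, metric, p, settings):
        return BootstrapResult(
            metric=metric,
            point_estimate=0.8,
            replicate_values=np.array([0.8]),
            lower_bound=0.78,
            ni_p_value=p,
            n_excluded=0,
            settings=settings,
            hypothesis=NIHypothesis(),
        )

    def test_requires_both_rejections(self):
        s = BootstrapSettings(n_replicates=100, seed=0)
        assert study_success(self._result("sensitivity", 0.021, s), self._result("specificity", 0.0009, s))
        assert not study_success(self._result("sensitivity", 0.021, s), self._result("specificity", 0.5, s))
        assert not study_success(self._result("sensitivity", 0.026, s), self._result("specificity", 0.001, s))

    def test_mismatched_settings_rejected(self):
        a = BootstrapSettings(n_replicates=100, seed=0)
        b = BootstrapSettings(n_replicates=200, seed=0)
        with pytest.raises(TrialDataError, match="mismatched"):
            study_success(self._result("sensitivity", 0.01, a), self._result("specificity", 0.01, b))

    def test_hierarchical_stops_at_first_failure(self):
        s = BootstrapSettings(n_replicates=100, seed=0)
        results = [self._result("sensitivity", p, s) for p in (0.01, 0.5, 0.001)]
        assert hierarchical_test(results) == [True, False, False]


class TestPowerSimulation:
    def test_zero_trials_rejected(self):
        with pytest.raises(TrialDataError):
            power_simulation(0.85, 0.90, n_trials=0)

    def test_design_pairing_validated(self):
        with pytest.raises(TrialDataError):
            DesignSpec(n_pos_eyes=200, n_neg_eyes=140, n_discordant_pairs=141)

    def test_reports_mc_error(self):
        out = power_simulation(
            0.85, 0.90, n_trials=20, settings=BootstrapSettings(n_replicates=150, seed=0), seed=4
        )
        assert set(out) >= {"power_sensitivity", "power_specificity", "power_study", "mc_se_study"}
        assert 0 <= out["power_study"] <= 1


def test_full_pipeline_seed_determinism(small_trial):
    s = BootstrapSettings(n_replicates=150, seed=9, expand_spectrum=True)
    a = bootstrap_metric(small_trial, "specificity", settings=s)
    b = bootstrap_metric(small_trial, "specificity", settings=s)
    assert a.ni_p_value == b.ni_p_value and a.lower_bound == b.lower_bound
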