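"""Case-definition rules, participant aggregation, and tabular I/O."""

import itertools

import pytest

from drdtrial import (
    ETDRSLevel,
    EyeRecord,
    ParticipantRecord,
    TrialDataset,
    TrialDataError,
    classify_cidme,
    is_drd_positive,
    is_vtdrd,
    participant_ai_output,
    participant_reference_positive,
    read_trial_table,
    waterfall_summary,
    write_trial_table,
)
from drdtrial.trial_data import ETDRS_BASES, to_frame


def eye(pid="P1", lat="right", base=10, mod="", dme=False, ai=None, **kw):
    return EyeRecord(
        participant_id=pid,
        laterality=lat,
        etdrs_level1=ETDRSLevel(base, mod),
        dme_level1=dme,
        ai_output=ai,
        **kw,
    )


def participant(pid, *eyes_args):
    eyes = tuple(eye(pid=pid, lat=("right", "left")[i], **kw) for i, kw in enumerate(eyes_args))
    return ParticipantRecord(pid, 50.0, "female", "White", "Not Hispanic or Latino", eyes)


class TestETDRSLevel:
    def test_parse_formats(self):
        assert ETDRSLevel.from_string("35 A") == ETDRSLevel(35, "A")
        assert ETDRSLevel.from_string("43B") == ETDRSLevel(43, "B")
        assert ETDRSLevel.from_string("10") == ETDRSLevel(10)

    @pytest.mark.parametrize("bad", ["34", "9", "x", "35G", "35 AA"])
    def test_invalid_rejected(self, bad):
        with pytest.raises(TrialDataError):
            ETDRSLevel.from_string(bad)

    def test_ordering_ignores_modifier(self):
        assert ETDRSLevel(35, "A") >= ETDRSLevel(35, "F")
        assert ETDRSLevel(35, "F") <= ETDRSLevel(43)
        assert not ETDRSLevel(20) >= ETDRSLevel(35, "A")


class TestCaseDefinitions:
    @pytest.mark.parametrize(
        "base,mod,dme,expected",
        [(35, "A", False, True), (20, "", False, False), (10, "", True, True)],
    )
    def test_drd_cutoff(self, base, mod, dme, expected):
        assert is_drd_positive(ETDRSLevel(base, mod), dme) is expected

    @pytest.mark.parametrize(
        "base,dme,expected",
        [(60, False, True), (47, False, False), (35, True, True)],
    )
    def test_vtdrd_cutoff(self, base, dme, expected):
        assert is_vtdrd(ETDRSLevel(base), dme) is expected

    def test_vtdrd_implies_drd_over_full_level_set(self):
        for base, dme in itertools.product(ETDRS_BASES, (False, True)):
            level = ETDRSLevel(base)
            if is_vtdrd(level, dme):
                assert is_drd_positive(level, dme)

    @pytest.mark.parametrize("thickness,expected", [(307, True), (300, False), (243, False)])
    def test_cidme_strict_threshold(self, thickness, expected):
        assert classify_cidme(thickness) is expected

    def test_cidme_missing_thickness_is_signalled(self):
        with pytest.raises(TrialDataError):
            classify_cidme(None)
        with pytest.raises(TrialDataError):
            classify_cidme(0)


class TestParticipantAggregation:
    def test_worst_eye_rule_examples(self):
        assert participant_reference_positive(participant("P1", dict(base=20), dict(base=35)))
        assert not participant_reference_positive(participant("P2", dict(base=10), dict(base=10)))
        assert participant_reference_positive(participant("P3", dict(base=53)))

    def test_worst_eye_matches_brute_force_or(self):
        bases = (10, 20, 35, 53)
        for combo in itertools.product(itertools.product(bases, (False, True)), repeat=2):
            p = participant("P1", *({"base": b, "dme": d} for b, d in combo))
            expected = any(is_drd_positive(ETDRSLevel(b), d) for b, d in combo)
            assert participant_reference_positive(p) is expected

    @pytest.mark.parametrize(
        "outputs,expected",
        [
            (("detected", "insufficient_quality"), "detected"),
            (("not_detected", "not_detected"), "not_detected"),
            (("insufficient_quality", "insufficient_quality"), "insufficient_quality"),
            (("not_detected", "detected"), "detected"),
            (("not_detected", "insufficient_quality"), "not_detected"),
        ],
    )
    def test_any_diagnosable_eye_rule(self, outputs, expected):
        p = participant("P1", *({"ai": o} for o in outputs))
        assert participant_ai_output(p) == expected

    def test_missing_ai_output_is_an_error(self):
        with pytest.raises(TrialDataError):
            participant_ai_output(participant("P1", dict(ai=None)))


class TestRecordInvariants:
    def test_dme_component_consistency_enforced(self):
        with pytest.raises(TrialDataError):
            eye(dme=True, cidme=False, csdme=False)
        eye(dme=True, cidme=True, csdme=False)  # consistent

    def test_duplicate_laterality_rejected(self):
        with pytest.raises(TrialDataError):
            ParticipantRecord(
                "P1", 50.0, "male", "White", "Not Hispanic or Latino",
                (eye(lat="right"), eye(lat="right")),
            )

    def test_attempt_bounds(self):
        with pytest.raises(TrialDataError):
            eye(n_attempts=7)


class TestTabularIO:
    def test_round_trip_identity(self, small_trial, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial_table(small_trial, path)
        back = read_trial_table(path)
        assert to_frame(small_trial).equals(to_frame(back))

    def test_empty_table_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("participant_id,laterality,etdrs_level1,dme_level1\n")
        assert read_trial_table(path).n_participants == 0

    def test_two_rows_one_participant(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "participant_id,laterality,etdrs_level1,dme_level1\nA,left,10,0\nA,right,35,0\n"
        )
        ds = read_trial_table(path)
        assert ds.n_participants == 1 and ds.n_eyes == 2

    def test_bad_categorical_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "participant_id,laterality,etdrs_level1,dme_level1,ai_output\nA,left,10,0,maybe\n"
        )
        with pytest.raises(TrialDataError, match=r"row 1.*ai_output"):
            read_trial_table(path)

    def test_duplicate_eye_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "participant_id,laterality,etdrs_level1,dme_level1\nA,left,10,0\nA,left,10,0\n"
        )
        with pytest.raises(TrialDataError, match="duplicate"):
            read_trial_table(path)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("participant_id,laterality\nA,left\n")
        with pytest.raises(TrialDataError, match="etdrs_level1"):
            read_trial_table(path)


class TestWaterfall:
    def test_counts_and_exclusions(self, small_trial):
        ids = [p.participant_id for p in small_trial.participants]
        completed = small_trial.subset(ids[:-7])
        analyzable = small_trial.subset(ids[:-59])
        table = waterfall_summary(small_trial, completed, analyzable)
        assert list(table["participants"]) == [800, 793, 741]
        assert list(table["participants_excluded"]) == [0, 7, 52]
        assert table["eyes_excluded"][1] == small_trial.n_eyes - completed.n_eyes

    def test_identical_datasets_no_exclusions(self, small_trial):
        table = waterfall_summary(small_trial, small_trial, small_trial)
        assert table["participants_excluded"].sum() == 0
        assert table["eyes_excluded"].sum() == 0

    def test_non_nested_inputs_rejected(self, small_trial):
        ids = [p.participant_id for p in small_trial.participants]
        completed = small_trial.subset(ids[:400])
        not_subset = small_trial.subset(ids[300:])
        with pytest.raises(TrialDataError, match="subset"):
            waterfall_summary(small_trial, completed, not_subset)
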