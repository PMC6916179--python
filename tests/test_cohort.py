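"""Eligibility cascade, therapy-line derivation and the diagnosis date."""

import numpy as np
import pandas as pd
import pytest

from rxadhere.cohort import (
    apply_exclusions,
    compute_diagnosis_date,
    derive_all_episodes,
    derive_therapy_lines,
    validate_tables,
)
from rxadhere.errors import SchemaError, UndeterminedDiagnosisError


def _patient(pid=1, regstart=-500, regend=2000, gap=0, birth_year=1950):
    return {
        "patient_id": pid,
        "regstart_date": regstart,
        "regend_date": regend,
        "has_registration_gap": gap,
        "sex": "F",
        "birth_year": birth_year,
        "ethnicity": "white",
    }


def _rx(pid, day, cls="MFN", form="tablet", qty=56.0, dose=2.0):
    return {
        "patient_id": pid,
        "issue_date": day,
        "drug_class": cls,
        "formulation": form,
        "quantity": qty,
        "daily_dose": dose,
    }


def _two_line_rx(pid, start=0):
    """A clean eligible record: metformin then a sulfonylurea added."""
    rows = [_rx(pid, start + 30 * k) for k in range(20)]
    rows += [_rx(pid, start + 400 + 30 * k, cls="SU", qty=28.0, dose=1.0) for k in range(14)]
    return rows


def _frames(patients, rx_rows, events=None):
    pat = pd.DataFrame(patients)
    rx = pd.DataFrame(rx_rows)
    ev = pd.DataFrame(
        events or [], columns=["patient_id", "event_date", "category"]
    )
    return pat, rx, ev


class TestSchema:
    def test_missing_column_named(self):
        frame = pd.DataFrame([_rx(1, 0)]).drop(columns=["daily_dose"])
        with pytest.raises(SchemaError, match="daily_dose"):
            validate_tables(prescriptions=frame)


class TestDiagnosisDate:
    def test_minimum_of_three_sources(self):
        ev = pd.DataFrame([{"patient_id": 1, "event_date": 100, "category": "diabetes_code"}])
        rx = pd.DataFrame([_rx(1, 120)])
        obs = pd.DataFrame([{"patient_id": 1, "obs_date": 40, "kind": "hba1c", "value": 60.0}])
        assert compute_diagnosis_date(ev, rx, obs) == 40

    def test_prescription_only(self):
        ev = pd.DataFrame(columns=["patient_id", "event_date", "category"])
        rx = pd.DataFrame([_rx(1, 10)])
        assert compute_diagnosis_date(ev, rx) == 10

    def test_hba1c_below_threshold_does_not_qualify(self):
        ev = pd.DataFrame(columns=["patient_id", "event_date", "category"])
        rx = pd.DataFrame([_rx(1, 90)])
        obs = pd.DataFrame([{"patient_id": 1, "obs_date": 5, "kind": "hba1c", "value": 45.0}])
        assert compute_diagnosis_date(ev, rx, obs) == 90

    def test_no_qualifying_record_raises(self):
        empty_ev = pd.DataFrame(columns=["patient_id", "event_date", "category"])
        empty_rx = pd.DataFrame(columns=["patient_id", "issue_date", "drug_class"])
        with pytest.raises(UndeterminedDiagnosisError):
            compute_diagnosis_date(empty_ev, empty_rx)


class TestTherapyLines:
    def test_canonical_two_lines(self):
        rx = pd.DataFrame(_two_line_rx(1))
        der = derive_therapy_lines(rx, records_end=2000)
        assert not der.dual_start and not der.injectable_line
        assert [e.line for e in der.episodes] == ["first", "second"]
        assert der.episodes[0].drug_class == "MFN"
        assert der.episodes[1].drug_class == "SU"
        assert der.episodes[1].start_date > der.episodes[0].start_date
        # metformin refills continue past a year
        assert der.episodes[0].end_event == "ongoing_at_1yr"

    def test_dual_start_flagged(self):
        rx = pd.DataFrame([_rx(1, 0), _rx(1, 0, cls="SU"), _rx(1, 30), _rx(1, 30, cls="SU")])
        der = derive_therapy_lines(rx, records_end=500)
        assert der.dual_start and not der.episodes

    def test_single_line_yields_one_episode(self):
        rx = pd.DataFrame([_rx(1, 30 * k) for k in range(15)])
        der = derive_therapy_lines(rx, records_end=2000)
        assert len(der.episodes) == 1

    def test_switch_within_year_classified(self):
        rows = [_rx(1, 30 * k) for k in range(5)]  # metformin stops at day 120
        rows += [_rx(1, 150 + 30 * k, cls="SU") for k in range(15)]
        der = derive_therapy_lines(pd.DataFrame(rows), records_end=2000)
        first = der.episodes[0]
        assert first.end_event == "switched"
        assert first.end_event_date == 150

    def test_injectable_first_line_flagged(self):
        rows = [_rx(1, 30 * k, cls="INSULIN", form="injectable") for k in range(15)]
        rows += [_rx(1, 500 + 30 * k, cls="MFN") for k in range(15)]
        der = derive_therapy_lines(pd.DataFrame(rows), records_end=2000)
        assert der.injectable_line and not der.episodes


class TestExclusions:
    def _run(self, patients, rx_rows, events=None):
        pat, rx, ev = _frames(patients, rx_rows, events)
        return apply_exclusions(pat, rx, ev)

    def test_age_at_diagnosis_under_35(self):
        # diagnosis (earliest prescription, day 0) at age ~30
        patients = [_patient(birth_year=1974)]
        eligible, log = self._run(patients, _two_line_rx(1),
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert len(eligible) == 0
        assert log.counts["t1d_age_lt_35"] == 1

    def test_insulin_within_year_of_diagnosis(self):
        patients = [_patient()]
        rx = _two_line_rx(1) + [_rx(1, 180, cls="INSULIN", form="injectable")]
        eligible, log = self._run(patients, rx,
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert len(eligible) == 0
        assert log.counts["t1d_insulin_within_1yr"] == 1

    def test_first_prescription_within_91_days_of_registration(self):
        patients = [_patient(regstart=-50)]
        eligible, log = self._run(patients, _two_line_rx(1),
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert len(eligible) == 0
        assert log.counts["start_within_91d_of_registration"] == 1

    def test_dual_start_excludes_patient(self):
        patients = [_patient()]
        rx = [_rx(1, 0), _rx(1, 0, cls="SU")] + [_rx(1, 30 * k) for k in range(1, 20)]
        eligible, log = self._run(patients, rx,
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert log.counts["dual_start_same_day"] == 1

    def test_no_second_line_excluded(self):
        patients = [_patient()]
        rx = [_rx(1, 30 * k) for k in range(20)]
        eligible, log = self._run(patients, rx,
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert log.counts["no_second_line"] == 1

    def test_no_diabetes_code_takes_precedence(self):
        patients = [_patient(birth_year=1974)]  # would also fail the age rule
        eligible, log = self._run(patients, _two_line_rx(1), [])
        assert log.counts["no_diabetes_code"] == 1
        assert log.counts["t1d_age_lt_35"] == 0

    def test_clean_patient_retained(self):
        patients = [_patient()]
        eligible, log = self._run(patients, _two_line_rx(1),
                                  [{"patient_id": 1, "event_date": 0, "category": "diabetes_code"}])
        assert len(eligible) == 1
        assert log.conserved


class TestExclusionsOnGenerated:
    def test_count_conservation(self, small_tables):
        _, log = apply_exclusions(
            small_tables.patients,
            small_tables.prescriptions,
            small_tables.clinical_events,
            observations=small_tables.observations,
        )
        assert log.n_input == len(small_tables.patients)
        assert log.conserved

    def test_idempotence(self, small_tables):
        eligible, _ = apply_exclusions(
            small_tables.patients,
            small_tables.prescriptions,
            small_tables.clinical_events,
            observations=small_tables.observations,
        )
        again, log2 = apply_exclusions(
            eligible,
            small_tables.prescriptions,
            small_tables.clinical_events,
            observations=small_tables.observations,
        )
        assert len(again) == len(eligible)
        assert sum(log2.counts.values()) == 0

    def test_episode_ordering_for_retained_patients(self, small_tables):
        eligible, _ = apply_exclusions(
            small_tables.patients,
            small_tables.prescriptions,
            small_tables.clinical_events,
            observations=small_tables.observations,
        )
        episodes = derive_all_episodes(eligible, small_tables.prescriptions)
        by_pid = {}
        for e in episodes:
            by_pid.setdefault(e.patient_id, {})[e.line] = e
        assert by_pid  # non-empty
        for eps in by_pid.values():
            assert set(eps) == {"first", "second"}
            assert eps["second"].start_date > eps["first"].start_date
            for e in eps.values():
                assert (np.diff(e.dates) >= 0).all()
                assert e.start_date == e.dates[0]
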