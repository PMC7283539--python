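"""T2DM rules: evidence aggregation, case decision tree, control screen."""

from __future__ import annotations

import itertools

import pytest

from phenofrag.ehr_model import make_view
from phenofrag.t2dm_phenotype import (
    T2DMEvidence,
    classify_t2dm,
    classify_t2dm_case,
    classify_t2dm_control,
    extract_t2dm_evidence,
    load_t2dm_rules,
)

from conftest import ev, frame, roster


@pytest.fixture(scope="module")
def rules():
    return load_t2dm_rules()


# ---------------------------------------------------------------------------
# Independent oracles: direct boolean transcriptions of the decision tree,
# kept separate from the config-driven rule engine they check.
# ---------------------------------------------------------------------------

def oracle_case(e: T2DMEvidence) -> str | None:
    t1, t2 = e.n_t1dm_dx >= 1, e.n_t2dm_dx >= 1
    if not t1 and t2 and e.has_t2dm_med:
        return "P1"
    if not t1 and t2 and not e.has_t2dm_med and e.has_abnormal_lab:
        return "P2"
    if not t1 and not t2 and e.has_t2dm_med and e.has_abnormal_lab:
        return "P3"
    if t1 and t2 and e.has_t1dm_med and e.has_t2dm_med and e.t2dm_med_precedes_t1dm_med is True:
        return "P4"
    if t1 and t2 and e.has_t1dm_med and not e.has_t2dm_med and e.n_t2dm_dx_physician >= 2:
        return "P5"
    return None


def oracle_control(e: T2DMEvidence) -> bool:
    return (
        e.n_inperson_visits >= 2
        and e.n_glucose_measures >= 1
        and not e.has_abnormal_lab
        and not e.has_dm_related_dx
        and not e.has_dm_med_or_supplies
        and not e.family_history_dm
    )


def enumerate_case_evidence():
    """All consistent combinations of the decision-tree inputs."""
    for t1, t2, t1m, t2m, abn, nphys in itertools.product(
        [0, 1], [0, 1], [False, True], [False, True], [False, True], [0, 1, 2]
    ):
        if nphys > 0 and not t2:
            continue  # physician-entered T2DM dx implies a T2DM dx
        precedences = [None] if not (t1m and t2m) else [True, False]
        for prec in precedences:
            yield T2DMEvidence(
                n_t1dm_dx=t1,
                n_t2dm_dx=max(t2, nphys),
                n_t2dm_dx_physician=nphys,
                has_t1dm_med=t1m,
                has_t2dm_med=t2m,
                t2dm_med_precedes_t1dm_med=prec,
                has_abnormal_lab=abn,
            ) if t2 else T2DMEvidence(
                n_t1dm_dx=t1,
                n_t2dm_dx=0,
                n_t2dm_dx_physician=0,
                has_t1dm_med=t1m,
                has_t2dm_med=t2m,
                t2dm_med_precedes_t1dm_med=prec,
                has_abnormal_lab=abn,
            )


class TestEvidenceInvariants:
    def test_precedence_requires_both_meds(self):
        with pytest.raises(ValueError, match="both med flags"):
            T2DMEvidence(has_t2dm_med=True, t2dm_med_precedes_t1dm_med=True)

    def test_counts_non_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            T2DMEvidence(n_t2dm_dx=-1)


class TestCaseTree:
    def test_all_false_is_not_case(self, rules):
        assert classify_t2dm_case(T2DMEvidence(), rules) == ("neither", None)

    def test_classic_path(self, rules):
        e = T2DMEvidence(n_t2dm_dx=2, has_t2dm_med=True)
        assert classify_t2dm_case(e, rules) == ("case", "P1")

    def test_truth_table_matches_oracle(self, rules):
        """Exhaustive enumeration over the decision-tree inputs."""
        n_checked = 0
        for e in enumerate_case_evidence():
            label, path = classify_t2dm_case(e, rules)
            expected = oracle_case(e)
            assert (label == "case") == (expected is not None), e
            assert path == expected, e
            n_checked += 1
        assert n_checked == 80  # full consistent truth table


class TestControlScreen:
    def test_minimal_control(self, rules):
        e = T2DMEvidence(n_inperson_visits=2, n_glucose_measures=1)
        assert classify_t2dm_control(e, rules) == "control"

    def test_family_history_blocks(self, rules):
        e = T2DMEvidence(n_inperson_visits=2, n_glucose_measures=1, family_history_dm=True)
        assert classify_t2dm_control(e, rules) == "neither"

    def test_enumeration_matches_conjunction_oracle(self, rules):
        for abn, dm_dx, supplies, fam in itertools.product([False, True], repeat=4):
            for visits, glucose in itertools.product([0, 1, 2], repeat=2):
                e = T2DMEvidence(
                    has_abnormal_lab=abn,
                    has_dm_related_dx=dm_dx,
                    has_dm_med_or_supplies=supplies,
                    family_history_dm=fam,
                    n_inperson_visits=visits,
                    n_glucose_measures=glucose,
                )
                got = classify_t2dm_control(e, rules)
                assert (got == "control") == oracle_control(e), e

    def test_no_evidence_is_both_case_and_control(self, rules):
        """The case paths and the control screen are mutually exclusive."""
        for e in enumerate_case_evidence():
            # make the control screens as permissive as the case evidence allows
            eligible = T2DMEvidence(
                n_t1dm_dx=e.n_t1dm_dx,
                n_t2dm_dx=e.n_t2dm_dx,
                n_t2dm_dx_physician=e.n_t2dm_dx_physician,
                has_t1dm_med=e.has_t1dm_med,
                has_t2dm_med=e.has_t2dm_med,
                t2dm_med_precedes_t1dm_med=e.t2dm_med_precedes_t1dm_med,
                has_abnormal_lab=e.has_abnormal_lab,
                n_inperson_visits=2,
                n_glucose_measures=1,
                has_dm_related_dx=e.n_t1dm_dx + e.n_t2dm_dx > 0,
                has_dm_med_or_supplies=e.has_t1dm_med or e.has_t2dm_med,
            )
            assert not (oracle_case(eligible) and oracle_control(eligible))
            label, _ = classify_t2dm_case(eligible, rules)
            if label == "case":
                assert classify_t2dm_control(eligible, rules) == "neither"


class TestEvidenceExtraction:
    def test_empty_patient_all_zero(self, pconfig, rules):
        view = make_view(frame([ev("P1")]), roster("P1", "P2"), ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P2", pconfig.codelists, rules)
        assert e == T2DMEvidence()

    @pytest.mark.parametrize("value,expected", [(7.0, True), (6.5, True), (6.4, False)])
    def test_hba1c_threshold(self, pconfig, rules, value, expected):
        events = frame([ev("P1", event_type="lab", code_system="LAB", code="HBA1C", value=value)])
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P1", pconfig.codelists, rules)
        assert e.has_abnormal_lab is expected

    @pytest.mark.parametrize(
        "t2_day,t1_day,expected",
        [("2011-03-01", "2012-01-01", True), ("2012-01-01", "2011-03-01", False)],
    )
    def test_med_precedence_dates(self, pconfig, rules, t2_day, t1_day, expected):
        events = frame(
            [
                ev("P1", event_type="medication", code_system="MED", code="METFORMIN", day=t2_day),
                ev("P1", event_type="medication", code_system="MED", code="INSULIN_GLARGINE", day=t1_day),
            ]
        )
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P1", pconfig.codelists, rules)
        assert e.t2dm_med_precedes_t1dm_med is expected

    def test_precedence_none_with_single_med_class(self, pconfig, rules):
        events = frame(
            [ev("P1", event_type="medication", code_system="MED", code="METFORMIN")]
        )
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P1", pconfig.codelists, rules)
        assert e.t2dm_med_precedes_t1dm_med is None

    def test_physician_and_nlp_diagnoses_counted(self, pconfig, rules):
        events = frame(
            [
                ev("P1", code="E11.9", code_system="ICD10CM", entry_mode="physician"),
                ev("P1", event_type="nlp_diagnosis", code="E11.9", code_system="ICD10CM",
                   entry_mode="nlp"),
                ev("P1", code="E11.9", code_system="ICD10CM", entry_mode="billing"),
            ]
        )
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P1", pconfig.codelists, rules)
        assert e.n_t2dm_dx == 3
        assert e.n_t2dm_dx_physician == 2

    def test_inperson_visits_and_family_history(self, pconfig, rules):
        events = frame(
            [
                ev("P1", event_type="encounter", code_system="NONE", code="INPERSON"),
                ev("P1", event_type="encounter", code_system="NONE", code="VIRTUAL"),
                ev("P1", event_type="lab", code_system="LAB", code="GLU_RANDOM", value=100.0),
            ]
        )
        patients = roster("P1", family_history={"P1": True})
        view = make_view(events, patients, ["Mayo"], "Mayo")
        e = extract_t2dm_evidence(view, "P1", pconfig.codelists, rules)
        assert e.n_inperson_visits == 1
        assert e.n_glucose_measures == 1
        assert e.family_history_dm is True


class TestComposedViewClassification:
    def test_fragmentation_flips_labels(self, pconfig, rules):
        """Missing events can flip case -> neither and neither -> control."""
        events = frame(
            [
                # caseA: dx at Mayo, med at REP -> union case, Mayo neither
                ev("caseA", code="250.00", source_id="Mayo"),
                ev("caseA", event_type="medication", code_system="MED", code="METFORMIN",
                   source_id="REP"),
                # fpB: supplies order only at REP; clean visits/glucose at Mayo
                ev("fpB", event_type="medication", code_system="MED", code="TEST_STRIPS",
                   source_id="REP"),
                ev("fpB", event_type="encounter", code_system="NONE", code="INPERSON",
                   source_id="Mayo"),
                ev("fpB", event_type="encounter", code_system="NONE", code="INPERSON",
                   source_id="Mayo"),
                ev("fpB", event_type="lab", code_system="LAB", code="GLU_FASTING", value=90.0,
                   source_id="Mayo"),
            ]
        )
        patients = roster("caseA", "fpB")
        union = make_view(events, patients, ["Mayo", "REP"], "U")
        mayo = make_view(events, patients, ["Mayo"], "Mayo", known_sources=["Mayo", "REP"])
        u_calls = classify_t2dm(union, pconfig.codelists, rules)
        m_calls = classify_t2dm(mayo, pconfig.codelists, rules)
        assert u_calls.loc["caseA", "label"] == "case"
        assert m_calls.loc["caseA", "label"] == "neither"
        assert u_calls.loc["fpB", "label"] == "neither"  # supplies disqualify
        assert m_calls.loc["fpB", "label"] == "control"  # FP control in Mayo

    def test_labels_partition_roster(self, sim_cohort, pconfig, rules):
        view = make_view(sim_cohort.events, sim_cohort.patients, ["Mayo", "REP"], "U")
        calls = classify_t2dm(view, pconfig.codelists, rules)
        assert len(calls) == len(sim_cohort.patients)
        assert set(calls["label"]) <= {"case", "control", "neither"}


def test_default_rules_paths(rules):
    assert [p.id for p in rules.case_paths] == ["P1", "P2", "P3", "P4", "P5"]
    assert rules.lab_criteria.hba1c_threshold == 6.5


def test_invalid_path_field_rejected():
    from phenofrag.t2dm_phenotype import CasePath

    with pytest.raises(ValueError, match="unknown evidence field"):
        CasePath(id="X", when={"has_wings": True})
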