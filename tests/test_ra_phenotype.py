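"""RA algorithm: inclusion screen, feature extraction, logistic scoring, calls."""

from __future__ import annotations

import random

import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from phenofrag.ehr_model import make_view
from phenofrag.ra_phenotype import (
    RAFeatureVector,
    RAModel,
    classify_ra,
    extract_ra_features,
    ra_feature_table,
    ra_inclusion_cohort,
    ra_score,
    ra_score_table,
)

from conftest import ev, frame, roster


def make_model(**overrides) -> RAModel:
    base = dict(
        intercept=0.0,
        weights={
            "n_ra_dx": 1.0,
            "n_sle_dx": -1e-9,
            "n_pa_dx": -1e-9,
            "n_rf_lab": 1e-9,
            "n_rf_positive": 1.0,
            "n_encounters": -1e-9,
        },
        transform="raw",
        cutoff=0.5,
    )
    base.update(overrides)
    return RAModel(**base)


class TestModelValidation:
    def test_sign_constraints_enforced(self):
        with pytest.raises(ValueError, match="n_ra_dx"):
            make_model(weights={**make_model().weights, "n_ra_dx": -1.0})
        with pytest.raises(ValueError, match="n_encounters"):
            make_model(weights={**make_model().weights, "n_encounters": 0.5})

    def test_weight_coverage_enforced(self):
        with pytest.raises(ValueError, match="unknown feature"):
            make_model(weights={**make_model().weights, "n_bogus": 1.0})
        weights = make_model().weights.copy()
        weights.pop("n_sle_dx")
        with pytest.raises(ValueError, match="missing"):
            make_model(weights=weights)

    def test_cutoff_bounds(self):
        with pytest.raises(ValueError, match="cutoff"):
            make_model(cutoff=1.0)

    def test_feature_vector_invariants(self):
        with pytest.raises(ValueError, match="exceed"):
            RAFeatureVector(n_rf_lab=1, n_rf_positive=2)
        with pytest.raises(ValueError, match="non-negative"):
            RAFeatureVector(n_ra_dx=-1)


class TestInclusionCohort:
    def test_screen_positive_sets_per_view(self, pconfig):
        # P1: RA code in Mayo only; P2: RA codes in both; P3: none
        events = frame(
            [
                ev("P1", code="714.0", source_id="Mayo"),
                ev("P2", code="M05.79", code_system="ICD10CM", source_id="Mayo"),
                ev("P2", code="714.0", source_id="REP"),
                ev("P3", code="250.00", source_id="REP"),
            ]
        )
        patients = roster("P1", "P2", "P3")
        mayo = make_view(events, patients, ["Mayo"], "Mayo", known_sources=["Mayo", "REP"])
        rep = make_view(events, patients, ["REP"], "REP", known_sources=["Mayo", "REP"])
        union = make_view(events, patients, ["Mayo", "REP"], "U")
        assert ra_inclusion_cohort(mayo, pconfig.codelists) == {"P1", "P2"}
        assert ra_inclusion_cohort(rep, pconfig.codelists) == {"P2"}
        assert ra_inclusion_cohort(union, pconfig.codelists) == {"P1", "P2"}

    def test_toy_cohort_matches_bruteforce(self, pconfig):
        rng = random.Random(11)
        rows, with_ra = [], set()
        for i in range(8):
            pid = f"P{i}"
            if rng.random() < 0.4:
                rows.append(ev(pid, code="714.0"))
                with_ra.add(pid)
            rows.append(ev(pid, code="401.9"))  # unrelated dx
        view = make_view(frame(rows), roster(*[f"P{i}" for i in range(8)]), ["Mayo"], "Mayo")
        assert ra_inclusion_cohort(view, pconfig.codelists) == with_ra
        assert 0 < len(with_ra) < 8  # fixture sanity


class TestFeatureExtraction:
    def test_eventless_patient_zero_vector(self, pconfig):
        view = make_view(frame([ev("P1")]), roster("P1", "P2"), ["Mayo"], "Mayo")
        vec = extract_ra_features(view, "P2", pconfig.codelists, pconfig.ra_model)
        assert vec == RAFeatureVector()

    def test_direct_counts(self, pconfig):
        events = frame(
            [
                ev("P1", code="714.0"),
                ev("P1", code="M06.9", code_system="ICD10CM"),
                ev("P1", event_type="lab", code_system="LAB", code="RF", value=60.0),
                *[ev("P1", event_type="encounter", code_system="NONE", code="INPERSON")
                  for _ in range(5)],
            ]
        )
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        vec = extract_ra_features(view, "P1", pconfig.codelists, pconfig.ra_model)
        assert vec == RAFeatureVector(
            n_ra_dx=2, n_sle_dx=0, n_pa_dx=0, n_rf_lab=1, n_rf_positive=1, n_encounters=5
        )

    def test_rf_positive_threshold_boundary(self, pconfig):
        thr = pconfig.ra_model.rf_positive_threshold
        events = frame(
            [
                ev("P1", event_type="lab", code_system="LAB", code="RF", value=thr),
                ev("P1", event_type="lab", code_system="LAB", code="RF", value=thr - 0.1),
            ]
        )
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        vec = extract_ra_features(view, "P1", pconfig.codelists, pconfig.ra_model)
        assert (vec.n_rf_lab, vec.n_rf_positive) == (2, 1)

    def test_union_counts_dominate_source_counts(self, sim_cohort, pconfig):
        """Union-view feature counts are >= any single source's, component-wise."""
        events, patients = sim_cohort.events, sim_cohort.patients
        union = make_view(events, patients, ["Mayo", "REP"], "U")
        tables = {
            src: ra_feature_table(
                make_view(events, patients, [src], src), pconfig.codelists, pconfig.ra_model
            )
            for src in ("Mayo", "REP")
        }
        union_table = ra_feature_table(union, pconfig.codelists, pconfig.ra_model)
        subset = union_table.index[:50]
        for src, table in tables.items():
            assert (union_table.loc[subset] >= table.loc[subset]).all().all(), src


class TestScoring:
    def test_zero_features_zero_intercept_is_half(self):
        assert ra_score(RAFeatureVector(), make_model()) == pytest.approx(0.5)

    def test_logistic_algebra_identity(self):
        # intercept -2, raw weight 1 on RA dx, two diagnoses -> logistic(0) = 0.5
        model = make_model(
            intercept=-2.0, weights={**make_model().weights, "n_ra_dx": 1.0}
        )
        assert ra_score(RAFeatureVector(n_ra_dx=2), model) == pytest.approx(0.5)

    def test_matches_high_precision_sigmoid(self):
        """Scores agree with an arbitrary-precision sigmoid to 1e-12."""
        rng = random.Random(42)
        for _ in range(25):
            weights = {
                "n_ra_dx": rng.uniform(0.1, 3),
                "n_rf_positive": rng.uniform(0.1, 3),
                "n_rf_lab": rng.uniform(-1, 1) or 0.1,
                "n_sle_dx": -rng.uniform(0.1, 3),
                "n_pa_dx": -rng.uniform(0.1, 3),
                "n_encounters": -rng.uniform(0.01, 1),
            }
            transform = rng.choice(["raw", "log1p"])
            intercept = rng.uniform(-4, 4)
            model = make_model(intercept=intercept, weights=weights, transform=transform)
            rf_lab = rng.randint(0, 10)
            vec = RAFeatureVector(
                n_ra_dx=rng.randint(0, 20),
                n_sle_dx=rng.randint(0, 5),
                n_pa_dx=rng.randint(0, 5),
                n_rf_lab=rf_lab,
                n_rf_positive=rng.randint(0, rf_lab),
                n_encounters=rng.randint(0, 100),
            )
            eta = sympy.Float(intercept, 50)
            for name, w in weights.items():
                x = sympy.Integer(getattr(vec, name))
                t = sympy.log(1 + x) if transform == "log1p" else x
                eta += sympy.Float(w, 50) * t
            expected = float(1 / (1 + sympy.exp(-eta)))
            assert abs(ra_score(vec, model) - expected) < 1e-12

    def test_table_scores_match_scalar(self, pconfig):
        vecs = [
            RAFeatureVector(),
            RAFeatureVector(n_ra_dx=3, n_rf_lab=2, n_rf_positive=1, n_encounters=9),
            RAFeatureVector(n_ra_dx=1, n_sle_dx=2, n_pa_dx=1, n_encounters=40),
        ]
        import pandas as pd

        table = pd.DataFrame([v.as_dict() for v in vecs])
        got = ra_score_table(table, pconfig.ra_model)
        for i, v in enumerate(vecs):
            assert got.iloc[i] == pytest.approx(ra_score(v, pconfig.ra_model), abs=1e-12)

    @given(
        base=st.fixed_dictionaries(
            {
                "n_ra_dx": st.integers(0, 10),
                "n_sle_dx": st.integers(0, 5),
                "n_pa_dx": st.integers(0, 5),
                "n_rf_lab": st.integers(0, 6),
                "n_encounters": st.integers(0, 60),
            }
        ),
        pos_extra=st.sampled_from(["n_ra_dx", "n_rf_positive"]),
        neg_extra=st.sampled_from(["n_sle_dx", "n_pa_dx", "n_encounters"]),
    )
    def test_score_monotone_in_evidence(self, pconfig, base, pos_extra, neg_extra):
        """Adding RA-dx/positive-RF evidence never lowers the score; adding
        SLE/PA/encounters never raises it (sign-constrained weights)."""
        model = pconfig.ra_model
        base = dict(base, n_rf_positive=min(base["n_rf_lab"], 1))
        vec = RAFeatureVector(**base)
        more = dict(base)
        more[pos_extra] += 1
        if pos_extra == "n_rf_positive":
            more["n_rf_lab"] += 1
        assert ra_score(RAFeatureVector(**more), model) >= ra_score(vec, model)
        fewer = dict(base)
        fewer[neg_extra] += 1
        assert ra_score(RAFeatureVector(**fewer), model) <= ra_score(vec, model)


class TestClassification:
    def test_hand_built_fixture_matches_rule_table(self, pconfig):
        """Labels equal direct evaluation of the two rules on each patient."""
        cl = pconfig.codelists
        model = pconfig.ra_model
        events = []
        # screened, strong evidence -> case
        for _ in range(4):
            events.append(ev("case1", code="714.0"))
        events.append(ev("case1", event_type="lab", code_system="LAB", code="RF", value=80.0))
        # screened, single code -> neither
        events.append(ev("weak1", code="714.0"))
        # exclusion code only -> neither (not control, not screened)
        events.append(ev("excl1", code="M08.3", code_system="ICD10CM"))
        # unrelated events only -> control
        events.append(ev("ctrl1", code="401.9"))
        view = make_view(
            frame(events), roster("case1", "weak1", "excl1", "ctrl1", "empty1"), ["Mayo"], "Mayo"
        )
        calls = classify_ra(view, cl, model)
        assert calls.loc["case1", "label"] == "case"
        assert calls.loc["weak1", "label"] == "neither"
        assert calls.loc["excl1", "label"] == "neither"
        assert calls.loc["ctrl1", "label"] == "control"
        assert calls.loc["empty1", "label"] == "control"  # no RA dx, no exclusion
        # screened patients carry a probability; others do not
        assert calls.loc["case1", "probability"] > model.cutoff
        assert np.isnan(calls.loc["ctrl1", "probability"])

    def test_probability_exactly_at_cutoff_is_case(self, pconfig):
        # raw model: intercept -2 + 2 * n_ra_dx(=1) * 2.0 ... build eta == 0
        model = make_model(
            intercept=-2.0,
            weights={**make_model().weights, "n_ra_dx": 2.0},
            cutoff=0.5,
        )
        events = frame([ev("P1", code="714.0")])
        view = make_view(events, roster("P1"), ["Mayo"], "Mayo")
        calls = classify_ra(view, pconfig.codelists, model)
        assert calls.loc["P1", "probability"] == pytest.approx(0.5)
        assert calls.loc["P1", "label"] == "case"

    def test_partition_case_control_neither(self, sim_cohort, pconfig):
        """Every patient gets exactly one of the three labels."""
        view = make_view(sim_cohort.events, sim_cohort.patients, ["Mayo", "REP"], "U")
        calls = classify_ra(view, pconfig.codelists, pconfig.ra_model)
        assert set(calls["label"]) <= {"case", "control", "neither"}
        assert len(calls) == len(sim_cohort.patients)
        assert calls.index.is_unique
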