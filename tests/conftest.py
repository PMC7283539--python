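"""Shared fixtures: phenotyping configuration, a simulated cohort, and small
hand-built event fixtures."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import settings

from phenofrag.ehr_model import ClinicalEvent, Patient, events_to_frame, patients_to_frame
from phenofrag.fragmentation_eval import PhenotypeConfig, run_experiment
from phenofrag.synthetic_ehr import SimulationConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def ev(
    patient_id: str,
    event_type: str = "diagnosis",
    code_system: str = "ICD9CM",
    code: str = "714.0",
    value: float | None = None,
    day: str = "2012-06-01",
    source_id: str = "Mayo",
    entry_mode: str = "billing",
    linkage_key: str | None = None,
) -> ClinicalEvent:
    """Terse event constructor for fixtures (unique linkage key by default)."""
    ev.counter = getattr(ev, "counter", 0) + 1
    return ClinicalEvent(
        patient_id=patient_id,
        event_type=event_type,
        code_system=code_system,
        code=code,
        value=value,
        date=date.fromisoformat(day),
        source_id=source_id,
        entry_mode=entry_mode,
        linkage_key=linkage_key or f"K{ev.counter:05d}",
    )


def frame(events) -> pd.DataFrame:
    return events_to_frame(events)


def roster(*patient_ids: str, family_history: dict[str, bool] | None = None) -> pd.DataFrame:
    family_history = family_history or {}
    return patients_to_frame(
        [Patient(p, family_history.get(p, False)) for p in patient_ids]
    )


@pytest.fixture(scope="session")
def pconfig() -> PhenotypeConfig:
    return PhenotypeConfig.default()


@pytest.fixture(scope="session")
def sim_cohort():
    """A 2,000-patient fragmented cohort under default study conditions."""
    return generate_cohort(SimulationConfig(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def sim_report(sim_cohort, pconfig):
    """Full fragmentation evaluation of the session cohort (both algorithms)."""
    return run_experiment(sim_cohort, ["Mayo", "REP"], ["ra", "t2dm"], pconfig)
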