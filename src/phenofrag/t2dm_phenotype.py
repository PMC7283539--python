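"""Rule-based type 2 diabetes mellitus (T2DM) case and control phenotyping.

The case definition is a decision tree over per-patient evidence aggregated
from diagnoses (billing-, physician- and NLP-entered), medication orders,
glucose/HbA1c lab results and a self-reported diabetes family-history flag.
It is expressed here as an ordered disjunction of *paths* — conjunctions of
evidence conditions — declared in configuration (``data/t2dm_rules.yaml``)
so the branch set can be amended without code changes. The default paths:

  P1  no T1DM dx, T2DM dx, T2DM medication
  P2  no T1DM dx, T2DM dx, no T2DM medication, abnormal lab
  P3  no T1DM dx, no T2DM dx, T2DM medication, abnormal lab
  P4  T1DM dx, T2DM dx, both medications, T2DM medication ordered first
  P5  T1DM dx, T2DM dx, T1DM medication, no T2DM medication,
      >= 2 physician-asserted T2DM diagnoses

A control must clear six screens: >= 2 in-person physician visits, >= 1
glucose measurement, no abnormal lab, no diabetes-related diagnosis, no
diabetes medication or supplies order, and no family history of diabetes.
When case and control rules are composed, the case label takes precedence.

"Abnormal lab" means a fasting glucose, random glucose or HbA1c result at or
above standard diagnostic thresholds (126 mg/dL, 200 mg/dL, 6.5%); the
thresholds are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .ehr_model import (
    Codelists,
    ConfigError,
    SourceView,
    match_codes,
    require_codelist,
)

__all__ = [
    "T2DMEvidence",
    "LabCriteria",
    "T2DMRules",
    "load_t2dm_rules",
    "t2dm_evidence_table",
    "extract_t2dm_evidence",
    "classify_t2dm_case",
    "classify_t2dm_control",
    "classify_t2dm",
    "EVIDENCE_FIELDS",
]

EVIDENCE_FIELDS = (
    "n_t1dm_dx",
    "n_t2dm_dx",
    "n_t2dm_dx_physician",
    "has_t1dm_med",
    "has_t2dm_med",
    "t2dm_med_precedes_t1dm_med",
    "has_abnormal_lab",
    "n_inperson_visits",
    "n_glucose_measures",
    "has_dm_related_dx",
    "has_dm_med_or_supplies",
    "family_history_dm",
)

_COUNT_FIELDS = {"n_t1dm_dx", "n_t2dm_dx", "n_t2dm_dx_physician", "n_inperson_visits", "n_glucose_measures"}
_DERIVED_BOOLS = {"has_t1dm_dx": "n_t1dm_dx", "has_t2dm_dx": "n_t2dm_dx"}


@dataclass(frozen=True)
class T2DMEvidence:
    """Aggregated per-patient inputs to the T2DM decision tree.

    ``t2dm_med_precedes_t1dm_med`` is None unless the patient has both
    medication classes; it compares the earliest order dates.
    """

    n_t1dm_dx: int = 0
    n_t2dm_dx: int = 0
    n_t2dm_dx_physician: int = 0
    has_t1dm_med: bool = False
    has_t2dm_med: bool = False
    t2dm_med_precedes_t1dm_med: bool | None = None
    has_abnormal_lab: bool = False
    n_inperson_visits: int = 0
    n_glucose_measures: int = 0
    has_dm_related_dx: bool = False
    has_dm_med_or_supplies: bool = False
    family_history_dm: bool = False

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.t2dm_med_precedes_t1dm_med is not None and not (
            self.has_t1dm_med and self.has_t2dm_med
        ):
            raise ValueError(
                "t2dm_med_precedes_t1dm_med must be None unless both med flags are set"
            )

    @property
    def has_t1dm_dx(self) -> bool:
        return self.n_t1dm_dx >= 1

    @property
    def has_t2dm_dx(self) -> bool:
        return self.n_t2dm_dx >= 1


class LabCriteria(BaseModel):
    fasting_glucose_threshold: float = 126.0  # mg/dL
    random_glucose_threshold: float = 200.0  # mg/dL
    hba1c_threshold: float = 6.5  # percent

    @field_validator(
        "fasting_glucose_threshold", "random_glucose_threshold", "hba1c_threshold"
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("lab thresholds must be positive")
        return v


class CasePath(BaseModel):
    id: str
    when: dict[str, Any]

    @field_validator("when")
    @classmethod
    def _known_fields(cls, v: dict[str, Any]) -> dict[str, Any]:
        known = set(EVIDENCE_FIELDS) | set(_DERIVED_BOOLS)
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown evidence field(s) in path: {sorted(unknown)}")
        return v


class ControlScreen(BaseModel):
    min_inperson_visits: int = 2
    min_glucose_measures: int = 1


class T2DMRules(BaseModel):
    """Complete rule configuration: case paths, lab criteria, control screens."""

    case_paths: list[CasePath]
    lab_criteria: LabCriteria = Field(default_factory=LabCriteria)
    control: ControlScreen = Field(default_factory=ControlScreen)
    inperson_code: str = "INPERSON"
    physician_entry_modes: list[str] = ["physician", "nlp"]


def load_t2dm_rules(path=None) -> T2DMRules:
    """Load T2DM rules from YAML (packaged defaults when ``path`` is None)."""
    if path is None:
        text = resources.files("phenofrag.data").joinpath("t2dm_rules.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"T2DM rules file not found: {path}")
        text = path.read_text()
    try:
        return T2DMRules.model_validate(yaml.safe_load(text))
    except ValueError as exc:
        raise ConfigError(f"invalid T2DM rules: {exc}") from exc


# ---------------------------------------------------------------------------
# Evidence extraction
# ---------------------------------------------------------------------------

def t2dm_evidence_table(
    view: SourceView, codelists: Codelists, rules: T2DMRules
) -> pd.DataFrame:
    """Per-patient evidence over the full roster (vectorized).

    ``t2dm_med_precedes_t1dm_med`` uses pandas nullable booleans (``pd.NA``
    when either medication class is absent).
    """
    events = view.events
    roster = view.roster

    def count(matched: pd.DataFrame) -> pd.Series:
        return matched.groupby("patient_id").size().reindex(roster, fill_value=0).astype(int)

    def earliest(matched: pd.DataFrame) -> pd.Series:
        return matched.groupby("patient_id")["date"].min().reindex(roster)

    t1_dx = match_codes(events, require_codelist(codelists, "t1dm_dx"))
    t2_dx = match_codes(events, require_codelist(codelists, "t2dm_dx"))
    t2_dx_phys = t2_dx[t2_dx["entry_mode"].isin(rules.physician_entry_modes)]

    meds = events[events["event_type"] == "medication"]
    t1_med = match_codes(meds, require_codelist(codelists, "t1dm_med"), event_types=None)
    t2_med = match_codes(meds, require_codelist(codelists, "t2dm_med"), event_types=None)

    labs = events[events["event_type"] == "lab"]
    crit = rules.lab_criteria
    fasting = match_codes(labs, require_codelist(codelists, "fasting_glucose_lab"), event_types=None)
    random_ = match_codes(labs, require_codelist(codelists, "random_glucose_lab"), event_types=None)
    hba1c = match_codes(labs, require_codelist(codelists, "hba1c_lab"), event_types=None)
    abnormal = pd.concat(
        [
            fasting[fasting["value"] >= crit.fasting_glucose_threshold],
            random_[random_["value"] >= crit.random_glucose_threshold],
            hba1c[hba1c["value"] >= crit.hba1c_threshold],
        ]
    )

    glucose = match_codes(labs, require_codelist(codelists, "glucose_lab"), event_types=None)
    encounters = events[events["event_type"] == "encounter"]
    inperson = encounters[
        encounters["code"].astype(str).str.upper() == rules.inperson_code.upper()
    ]

    dm_dx = match_codes(events, require_codelist(codelists, "dm_related_dx"))
    supplies = match_codes(meds, require_codelist(codelists, "dm_supplies"), event_types=None)

    has_t1_med = count(t1_med) > 0
    has_t2_med = count(t2_med) > 0
    t1_first, t2_first = earliest(t1_med), earliest(t2_med)
    precedes = pd.array(
        np.where(
            (has_t1_med & has_t2_med).to_numpy(),
            (t2_first < t1_first).to_numpy(),
            None,
        ),
        dtype="boolean",
    )

    fam = (
        view.patients.set_index("patient_id")["family_history_dm"]
        .reindex(roster, fill_value=False)
        .astype(bool)
    )

    table = pd.DataFrame(
        {
            "n_t1dm_dx": count(t1_dx),
            "n_t2dm_dx": count(t2_dx),
            "n_t2dm_dx_physician": count(t2_dx_phys),
            "has_t1dm_med": has_t1_med,
            "has_t2dm_med": has_t2_med,
            "t2dm_med_precedes_t1dm_med": precedes,
            "has_abnormal_lab": count(abnormal) > 0,
            "n_inperson_visits": count(inperson),
            "n_glucose_measures": count(glucose),
            "has_dm_related_dx": count(dm_dx) > 0,
            "has_dm_med_or_supplies": (count(t1_med) + count(t2_med) + count(supplies)) > 0,
            "family_history_dm": fam,
        },
        index=roster,
    )
    table.index.name = "patient_id"
    return table


def extract_t2dm_evidence(
    view: SourceView, patient_id: str, codelists: Codelists, rules: T2DMRules
) -> T2DMEvidence:
    """Evidence for one patient (all-zero/false when the patient has no events)."""
    if patient_id not in set(view.roster):
        raise ValueError(f"patient {patient_id!r} not in view roster")
    row = t2dm_evidence_table(view, codelists, rules).loc[patient_id]
    precedes = row["t2dm_med_precedes_t1dm_med"]
    return T2DMEvidence(
        n_t1dm_dx=int(row["n_t1dm_dx"]),
        n_t2dm_dx=int(row["n_t2dm_dx"]),
        n_t2dm_dx_physician=int(row["n_t2dm_dx_physician"]),
        has_t1dm_med=bool(row["has_t1dm_med"]),
        has_t2dm_med=bool(row["has_t2dm_med"]),
        t2dm_med_precedes_t1dm_med=None if pd.isna(precedes) else bool(precedes),
        has_abnormal_lab=bool(row["has_abnormal_lab"]),
        n_inperson_visits=int(row["n_inperson_visits"]),
        n_glucose_measures=int(row["n_glucose_measures"]),
        has_dm_related_dx=bool(row["has_dm_related_dx"]),
        has_dm_med_or_supplies=bool(row["has_dm_med_or_supplies"]),
        family_history_dm=bool(row["family_history_dm"]),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _field_series(table: pd.DataFrame, name: str) -> pd.Series:
    if name in _DERIVED_BOOLS:
        return table[_DERIVED_BOOLS[name]] >= 1
    return table[name]


def _condition_mask(table: pd.DataFrame, name: str, spec: Any) -> pd.Series:
    series = _field_series(table, name)
    if isinstance(spec, bool):
        if name == "t2dm_med_precedes_t1dm_med":
            # tri-state: NA (meds not both present) never satisfies
            return (series == spec).fillna(False).astype(bool)
        return series.astype(bool) == spec
    if isinstance(spec, dict):
        if set(spec) == {"ge"}:
            return series >= int(spec["ge"])
        if set(spec) == {"eq"}:
            return series == int(spec["eq"])
        raise ConfigError(f"unsupported condition {spec!r} for field {name!r}")
    if isinstance(spec, int):
        return series == spec
    raise ConfigError(f"unsupported condition {spec!r} for field {name!r}")


def _case_paths_table(table: pd.DataFrame, rules: T2DMRules) -> tuple[pd.Series, pd.Series]:
    """(is_case, first satisfied path id) for an evidence table."""
    is_case = pd.Series(False, index=table.index)
    path_id = pd.Series(None, index=table.index, dtype=object)
    for path in rules.case_paths:
        mask = pd.Series(True, index=table.index)
        for name, spec in path.when.items():
            mask &= _condition_mask(table, name, spec)
        newly = mask & ~is_case
        path_id[newly] = path.id
        is_case |= mask
    return is_case, path_id


def _evidence_to_row(evidence: T2DMEvidence) -> pd.DataFrame:
    row = {name: getattr(evidence, name) for name in EVIDENCE_FIELDS}
    frame = pd.DataFrame([row], index=["_"])
    frame["t2dm_med_precedes_t1dm_med"] = pd.array(
        [evidence.t2dm_med_precedes_t1dm_med], dtype="boolean"
    )
    return frame


def classify_t2dm_case(evidence: T2DMEvidence, rules: T2DMRules) -> tuple[str, str | None]:
    """Case decision for one evidence vector.

    Returns ``("case", path_id)`` for the first satisfied path, else
    ``("neither", None)``.
    """
    is_case, path_id = _case_paths_table(_evidence_to_row(evidence), rules)
    if bool(is_case.iloc[0]):
        return "case", str(path_id.iloc[0])
    return "neither", None


def _control_mask(table: pd.DataFrame, rules: T2DMRules) -> pd.Series:
    c = rules.control
    return (
        (table["n_inperson_visits"] >= c.min_inperson_visits)
        & (table["n_glucose_measures"] >= c.min_glucose_measures)
        & ~table["has_abnormal_lab"].astype(bool)
        & ~table["has_dm_related_dx"].astype(bool)
        & ~table["has_dm_med_or_supplies"].astype(bool)
        & ~table["family_history_dm"].astype(bool)
    )


def classify_t2dm_control(evidence: T2DMEvidence, rules: T2DMRules) -> str:
    """Control screen for one evidence vector: "control" or "neither"."""
    return "control" if bool(_control_mask(_evidence_to_row(evidence), rules).iloc[0]) else "neither"


def classify_t2dm(view: SourceView, codelists: Codelists, rules: T2DMRules) -> pd.DataFrame:
    """Composed per-patient T2DM calls for a view (case precedence over control).

    Returns a frame indexed by patient_id with columns ``label`` and
    ``detail`` (the satisfied case path, or the rule that decided).
    """
    table = t2dm_evidence_table(view, codelists, rules)
    is_case, path_id = _case_paths_table(table, rules)
    is_control = _control_mask(table, rules) & ~is_case

    label = np.where(is_case, "case", np.where(is_control, "control", "neither"))
    detail = np.where(
        is_case, path_id.astype(str), np.where(is_control, "control_screen", "no_rule")
    )
    calls = pd.DataFrame({"label": label, "detail": detail}, index=table.index)
    calls["probability"] = np.nan  # rule-based: no score
    calls.index.name = "patient_id"
    return calls[["label", "probability", "detail"]]
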