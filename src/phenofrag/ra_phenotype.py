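"""Regression-scored rheumatoid arthritis (RA) case/control phenotyping.

The algorithm mirrors the published eMERGE-style RA definition: a
screen-positive *inclusion cohort* (at least one RA diagnosis code) is scored
with a fixed logistic model over per-patient feature counts — RA, SLE and
psoriatic-arthritis (PA) diagnoses, rheumatoid-factor (RF) lab tests and
positives, and total encounter volume — and a screened patient is a case when
the probability reaches the model cutoff (default 0.632). Controls are
patients with no RA diagnosis codes and no exclusion codes; everyone else is
"neither".

The model here is an applied artifact, not a fit: weights are configuration
(see ``data/ra_model.yaml``) constrained to the published sign structure
(RA dx and positive RF positive; SLE, PA and encounters negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, field_validator, model_validator

from .ehr_model import (
    Codelists,
    ConfigError,
    SourceView,
    match_codes,
    require_codelist,
)

__all__ = [
    "RA_FEATURES",
    "RAFeatureVector",
    "RAModel",
    "load_ra_model",
    "ra_inclusion_cohort",
    "ra_feature_table",
    "extract_ra_features",
    "ra_score",
    "ra_score_table",
    "classify_ra",
]

RA_FEATURES = (
    "n_ra_dx",
    "n_sle_dx",
    "n_pa_dx",
    "n_rf_lab",
    "n_rf_positive",
    "n_encounters",
)

_POSITIVE_WEIGHTS = ("n_ra_dx", "n_rf_positive")
_NEGATIVE_WEIGHTS = ("n_sle_dx", "n_pa_dx", "n_encounters")


@dataclass(frozen=True)
class RAFeatureVector:
    n_ra_dx: int = 0
    n_sle_dx: int = 0
    n_pa_dx: int = 0
    n_rf_lab: int = 0
    n_rf_positive: int = 0
    n_encounters: int = 0

    def __post_init__(self) -> None:
        for name in RA_FEATURES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_rf_positive > self.n_rf_lab:
            raise ValueError("n_rf_positive cannot exceed n_rf_lab")

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in RA_FEATURES}


class RAModel(BaseModel):
    """Logistic scoring weights, count transform and case cutoff."""

    intercept: float
    weights: dict[str, float]
    transform: Literal["raw", "log1p"] = "log1p"
    cutoff: float = 0.632
    rf_positive_threshold: float = 15.0

    @field_validator("cutoff")
    @classmethod
    def _cutoff_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")
        return v

    @model_validator(mode="after")
    def _check_weights(self) -> "RAModel":
        extra = set(self.weights) - set(RA_FEATURES)
        if extra:
            raise ValueError(f"unknown feature(s) in model weights: {sorted(extra)}")
        missing = set(RA_FEATURES) - set(self.weights)
        if missing:
            raise ValueError(f"model weights missing feature(s): {sorted(missing)}")
        for name in _POSITIVE_WEIGHTS:
            if self.weights[name] <= 0:
                raise ValueError(f"weight for {name} must be positive")
        for name in _NEGATIVE_WEIGHTS:
            if self.weights[name] >= 0:
                raise ValueError(f"weight for {name} must be negative")
        return self


def load_ra_model(path=None) -> RAModel:
    """Load an RA model from YAML (packaged defaults when ``path`` is None)."""
    from importlib import resources
    from pathlib import Path

    if path is None:
        text = resources.files("phenofrag.data").joinpath("ra_model.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"RA model file not found: {path}")
        text = path.read_text()
    try:
        return RAModel.model_validate(yaml.safe_load(text))
    except ValueError as exc:
        raise ConfigError(f"invalid RA model: {exc}") from exc


def ra_inclusion_cohort(view: SourceView, codelists: Codelists) -> set[str]:
    """Patients with at least one RA diagnosis code in the view (screen-positive set)."""
    ra_dx = require_codelist(codelists, "ra_dx")
    matched = match_codes(view.events, ra_dx)
    return set(matched["patient_id"].unique())


def ra_feature_table(view: SourceView, codelists: Codelists, model: RAModel) -> pd.DataFrame:
    """Per-patient RA feature counts over the full roster (vectorized).

    Patients without events get all-zero rows.
    """
    events = view.events
    roster = view.roster

    def count(matched: pd.DataFrame) -> pd.Series:
        return matched.groupby("patient_id").size().reindex(roster, fill_value=0)

    ra = match_codes(events, require_codelist(codelists, "ra_dx"))
    sle = match_codes(events, require_codelist(codelists, "sle_dx"))
    pa = match_codes(events, require_codelist(codelists, "pa_dx"))
    rf = match_codes(events, require_codelist(codelists, "rf_lab"), event_types=("lab",))
    rf_pos = rf[rf["value"] >= model.rf_positive_threshold]
    enc = events[events["event_type"] == "encounter"]

    table = pd.DataFrame(
        {
            "n_ra_dx": count(ra),
            "n_sle_dx": count(sle),
            "n_pa_dx": count(pa),
            "n_rf_lab": count(rf),
            "n_rf_positive": count(rf_pos),
            "n_encounters": count(enc),
        },
        index=roster,
    ).astype(int)
    table.index.name = "patient_id"
    return table


def extract_ra_features(
    view: SourceView, patient_id: str, codelists: Codelists, model: RAModel
) -> RAFeatureVector:
    """Feature counts for one patient (zero vector when the patient has no events)."""
    if patient_id not in set(view.roster):
        raise ValueError(f"patient {patient_id!r} not in view roster")
    row = ra_feature_table(view, codelists, model).loc[patient_id]
    return RAFeatureVector(**{name: int(row[name]) for name in RA_FEATURES})


def _transform(x: np.ndarray | float, kind: str):
    return np.log1p(x) if kind == "log1p" else x


def ra_score(features: RAFeatureVector, model: RAModel) -> float:
    """Logistic probability for one feature vector."""
    eta = model.intercept + sum(
        model.weights[name] * float(_transform(getattr(features, name), model.transform))
        for name in RA_FEATURES
    )
    return 1.0 / (1.0 + math.exp(-eta))


def ra_score_table(features: pd.DataFrame, model: RAModel) -> pd.Series:
    """Vectorized logistic probabilities for a feature table."""
    eta = np.full(len(features), model.intercept)
    for name in RA_FEATURES:
        eta += model.weights[name] * _transform(features[name].to_numpy(float), model.transform)
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index, name="probability")


def classify_ra(view: SourceView, codelists: Codelists, model: RAModel) -> pd.DataFrame:
    """Per-patient RA phenotype calls for a view.

    Returns a frame indexed by patient_id with columns ``label`` (case /
    control / neither), ``probability`` (the logistic score for screened
    patients, NaN otherwise) and ``detail`` (rule provenance). A screened
    patient whose probability equals the cutoff exactly is a case.
    """
    features = ra_feature_table(view, codelists, model)
    scores = ra_score_table(features, model)
    screened = features["n_ra_dx"] >= 1

    exclusion = match_codes(view.events, require_codelist(codelists, "ra_exclusion"))
    has_exclusion = pd.Series(False, index=features.index)
    if len(exclusion):
        has_exclusion.loc[
            has_exclusion.index.intersection(exclusion["patient_id"].unique())
        ] = True

    case = screened & (scores >= model.cutoff)
    control = ~screened & ~has_exclusion

    label = np.where(case, "case", np.where(control, "control", "neither"))
    detail = np.where(
        case,
        "screened:score>=cutoff",
        np.where(
            control,
            "no_ra_dx:no_exclusion",
            np.where(screened, "screened:score<cutoff", "excluded"),
        ),
    )
    calls = pd.DataFrame(
        {
            "label": label,
            "probability": scores.where(screened),
            "detail": detail,
        },
        index=features.index,
    )
    calls.index.name = "patient_id"
    return calls
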