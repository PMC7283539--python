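"""Domain model for multi-source longitudinal EHR event data.

Patient facts are represented as flat, source-tagged event rows (diagnoses,
labs, medication orders, encounters, NLP-derived physician diagnoses). The
canonical in-memory container for an event collection is a
:class:`pandas.DataFrame` with the columns in :data:`EVENT_COLUMNS`; the
dataclasses :class:`Patient` and :class:`ClinicalEvent` are convenience
wrappers for constructing small fixtures row by row.

A :class:`SourceView` is the slice of a cohort's events visible to one
institution, or the de-duplicated union of several institutions. Events
recorded by more than one institution share a ``linkage_key`` (record linkage
is assumed to have resolved identity already); union views keep exactly one
representative per key.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

__all__ = [
    "EVENT_COLUMNS",
    "EVENT_TYPES",
    "CODE_SYSTEMS",
    "ENTRY_MODES",
    "EventFormatError",
    "ConfigError",
    "Patient",
    "ClinicalEvent",
    "CodeList",
    "SourceView",
    "events_to_frame",
    "patients_to_frame",
    "read_events",
    "write_events",
    "read_patients",
    "write_patients",
    "read_truth",
    "load_codelists",
    "filter_window",
    "make_view",
    "match_codes",
]

EVENT_COLUMNS = [
    "patient_id",
    "event_type",
    "code_system",
    "code",
    "value",
    "date",
    "source_id",
    "entry_mode",
    "linkage_key",
]

EVENT_TYPES = frozenset({"diagnosis", "lab", "medication", "encounter", "nlp_diagnosis"})
CODE_SYSTEMS = frozenset({"ICD9CM", "ICD10CM", "MED", "LAB", "NONE"})
ENTRY_MODES = frozenset({"billing", "physician", "nlp"})

#: event types treated as diagnosis assertions when matching diagnosis code lists
DIAGNOSIS_TYPES = ("diagnosis", "nlp_diagnosis")

_PATTERN_RE = re.compile(r"^[A-Za-z0-9._\- ]+\*?$")


class EventFormatError(ValueError):
    """Raised when an event CSV violates the column or row contract.

    ``errors`` holds ``(row_number, message)`` pairs; row numbers refer to the
    data rows of the file (header = row 0).
    """

    def __init__(self, message: str, errors: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.errors = errors or []


class ConfigError(ValueError):
    """Raised for invalid or missing configuration (code lists, models, rules)."""


@dataclass(frozen=True)
class Patient:
    """A cohort member; ``family_history_dm`` is the self-reported first-degree
    diabetes family history flag collected outside the event stream."""

    patient_id: str
    family_history_dm: bool = False


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated, source-tagged clinical fact about a patient."""

    patient_id: str
    event_type: str
    code_system: str
    code: str
    value: float | None
    date: date
    source_id: str
    entry_mode: str = "billing"
    linkage_key: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.code_system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code_system {self.code_system!r}")
        if self.entry_mode not in ENTRY_MODES:
            raise ValueError(f"unknown entry_mode {self.entry_mode!r}")
        if self.event_type == "lab" and self.value is None:
            raise ValueError("lab events require a value")
        if not self.linkage_key:
            raise ValueError("linkage_key must be non-empty")


def events_to_frame(events: Iterable[ClinicalEvent]) -> pd.DataFrame:
    """Build a canonical event frame from :class:`ClinicalEvent` records."""
    rows = [dataclasses.asdict(e) for e in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame["date"] = pd.to_datetime(frame["date"])
    frame["value"] = pd.to_numeric(frame["value"])
    return frame


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [dataclasses.asdict(p) for p in patients],
        columns=["patient_id", "family_history_dm"],
    )
    frame["family_history_dm"] = frame["family_history_dm"].astype(bool)
    return frame


@dataclass(frozen=True)
class CodeList:
    """A named set of code patterns within one coding system.

    Matching is case-insensitive; ``.`` is literal; a single trailing ``*``
    is a prefix wildcard (``"714.*"`` matches ``"714.0"`` but not ``"7140"``).
    """

    name: str
    system: str
    codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.system not in CODE_SYSTEMS:
            raise ConfigError(f"code list {self.name!r}: unknown system {self.system!r}")
        if not self.codes:
            raise ConfigError(f"code list {self.name!r} is empty")
        for pattern in self.codes:
            if not _PATTERN_RE.match(pattern):
                raise ConfigError(
                    f"code list {self.name!r}: invalid pattern {pattern!r}"
                )
        object.__setattr__(self, "codes", frozenset(c.upper() for c in self.codes))

    def matches(self, code: str) -> bool:
        code = code.upper()
        for pattern in self.codes:
            if pattern.endswith("*"):
                if code.startswith(pattern[:-1]):
                    return True
            elif code == pattern:
                return True
        return False


#: a code-list registry: algorithm role -> lists (possibly one per code system)
Codelists = Mapping[str, tuple[CodeList, ...]]


@dataclass(frozen=True)
class SourceView:
    """The events visible to one institution, or to a union of institutions.

    The patient roster is always the full cohort: a patient with no events in
    the view is still present (their feature vectors are simply empty).
    """

    label: str
    sources: frozenset[str]
    events: pd.DataFrame
    patients: pd.DataFrame

    @property
    def roster(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])

    def events_for(self, patient_id: str) -> pd.DataFrame:
        return self.events[self.events["patient_id"] == patient_id]


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def read_events(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate an events CSV.

    Rows violating the event contract (unparseable date, lab without a value,
    unknown enum value, empty linkage key) are collected with their row
    numbers; in strict mode any such row raises :class:`EventFormatError`,
    otherwise offending rows are dropped with a warning.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventFormatError(f"{path}: missing required column(s) {missing}")
    frame = frame[EVENT_COLUMNS].copy()

    errors: list[tuple[int, str]] = []
    parsed_date = pd.to_datetime(frame["date"], format="ISO8601", errors="coerce")
    parsed_value = pd.to_numeric(frame["value"].replace("", None), errors="coerce")

    checks = [
        (parsed_date.isna(), "unparseable date"),
        (~frame["event_type"].isin(EVENT_TYPES), "unknown event_type"),
        (~frame["code_system"].isin(CODE_SYSTEMS), "unknown code_system"),
        (~frame["entry_mode"].isin(ENTRY_MODES), "unknown entry_mode"),
        ((frame["event_type"] == "lab") & parsed_value.isna(), "lab event without value"),
        ((frame["value"] != "") & parsed_value.isna(), "non-numeric value"),
        (frame["linkage_key"] == "", "empty linkage_key"),
        (frame["patient_id"] == "", "empty patient_id"),
    ]
    bad = pd.Series(False, index=frame.index)
    for mask, message in checks:
        for idx in frame.index[mask & ~bad]:
            errors.append((int(idx) + 1, message))
        bad |= mask

    if errors:
        errors.sort()
        if strict:
            detail = "; ".join(f"row {r}: {m}" for r, m in errors[:20])
            raise EventFormatError(
                f"{path}: {len(errors)} malformed row(s): {detail}", errors
            )
        warnings.warn(f"{path}: dropping {len(errors)} malformed row(s)", stacklevel=2)

    frame = frame[~bad]
    out = frame.assign(value=parsed_value[~bad], date=parsed_date[~bad])
    return out.reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event frame as the canonical CSV (ISO-8601 dates)."""
    out = events[EVENT_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%g")


def read_patients(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in ("patient_id", "family_history_dm") if c not in frame.columns]
    if missing:
        raise EventFormatError(f"{path}: missing required column(s) {missing}")
    flag = frame["family_history_dm"].str.strip().str.lower()
    valid = flag.isin(["true", "false", "1", "0"])
    if not valid.all():
        rows = [(int(i) + 1, "invalid family_history_dm") for i in frame.index[~valid]]
        raise EventFormatError(f"{path}: invalid family_history_dm values", rows)
    frame["family_history_dm"] = flag.isin(["true", "1"])
    if frame["patient_id"].duplicated().any():
        raise EventFormatError(f"{path}: duplicate patient_id")
    return frame[["patient_id", "family_history_dm"]]


def write_patients(patients: pd.DataFrame, path: str | Path) -> None:
    out = patients[["patient_id", "family_history_dm"]].copy()
    out["family_history_dm"] = out["family_history_dm"].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a latent-truth table (simulation ground truth; never a classifier input)."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    frame["ra_status"] = frame["ra_status"].astype(bool) if frame["ra_status"].dtype != bool else frame["ra_status"]
    return frame


def load_codelists(path: str | Path | None = None) -> dict[str, tuple[CodeList, ...]]:
    """Load a code-list registry from YAML (packaged defaults when ``path`` is None)."""
    if path is None:
        text = resources.files("phenofrag.data").joinpath("codelists.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"code list file not found: {path}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("codelists YAML must map role names to lists")
    registry: dict[str, tuple[CodeList, ...]] = {}
    for role, entries in raw.items():
        if not isinstance(entries, list):
            raise ConfigError(f"code list role {role!r}: expected a list of entries")
        lists = []
        for entry in entries:
            try:
                lists.append(
                    CodeList(name=role, system=entry["system"], codes=frozenset(entry["codes"]))
                )
            except (KeyError, TypeError) as exc:
                raise ConfigError(f"code list role {role!r}: malformed entry ({exc})") from exc
        registry[role] = tuple(lists)
    return registry


def require_codelist(codelists: Codelists, role: str) -> tuple[CodeList, ...]:
    try:
        return tuple(codelists[role])
    except KeyError:
        raise ConfigError(f"missing code list role {role!r}") from None


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def filter_window(
    events: pd.DataFrame,
    start: Union[str, date, pd.Timestamp],
    end: Union[str, date, pd.Timestamp],
) -> pd.DataFrame:
    """Keep events whose date lies in the closed interval [start, end]."""
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    if start_ts > end_ts:
        raise ValueError(f"window start {start_ts.date()} after end {end_ts.date()}")
    dates = pd.to_datetime(events["date"])
    return events[(dates >= start_ts) & (dates <= end_ts)].reset_index(drop=True)


def make_view(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    sources: Iterable[str],
    label: str,
    known_sources: Iterable[str] | None = None,
) -> SourceView:
    """Build the view of a cohort visible to ``sources``.

    Single-source views keep that source's events as-is. Multi-source (union)
    views de-duplicate cross-recorded events by ``linkage_key``, keeping the
    earliest-dated representative (ties broken by lexicographically smallest
    ``source_id``). The patient roster is the full cohort regardless of the
    sources chosen.
    """
    sources = frozenset(sources)
    if not sources:
        raise ValueError("sources must be non-empty")
    known = frozenset(known_sources) if known_sources is not None else frozenset(
        events["source_id"].unique()
    )
    unknown = sources - known
    if unknown:
        raise ValueError(f"unknown source_id(s): {sorted(unknown)}")

    subset = events[events["source_id"].isin(sources)]
    if len(sources) > 1:
        subset = (
            subset.sort_values(["date", "source_id"], kind="stable")
            .drop_duplicates(subset="linkage_key", keep="first")
        )
    subset = subset.sort_values(
        ["patient_id", "date", "linkage_key"], kind="stable"
    ).reset_index(drop=True)
    return SourceView(
        label=label,
        sources=sources,
        events=subset,
        patients=patients.reset_index(drop=True),
    )


def _match_mask(
    events: pd.DataFrame,
    code_lists: Iterable[CodeList],
    event_types: Iterable[str] | None,
) -> pd.Series:
    mask = pd.Series(False, index=events.index)
    if event_types is not None:
        type_mask = events["event_type"].isin(set(event_types))
    else:
        type_mask = pd.Series(True, index=events.index)
    codes_upper = events["code"].astype(str).str.upper()
    for cl in code_lists:
        system_mask = events["code_system"] == cl.system
        exact = frozenset(p for p in cl.codes if not p.endswith("*"))
        prefixes = tuple(p[:-1] for p in cl.codes if p.endswith("*"))
        code_mask = codes_upper.isin(exact)
        if prefixes:
            code_mask |= codes_upper.str.startswith(prefixes)
        mask |= system_mask & code_mask
    return mask & type_mask


def match_codes(
    events: pd.DataFrame,
    code_list: CodeList | Iterable[CodeList],
    event_types: Iterable[str] | None = DIAGNOSIS_TYPES,
) -> pd.DataFrame:
    """Return the events whose (system, code) matches any pattern.

    By default only diagnosis-type events (including NLP-derived diagnoses)
    are considered; pass ``event_types`` explicitly for labs, medications or
    encounters, or ``None`` to match across all event types.
    """
    lists = [code_list] if isinstance(code_list, CodeList) else list(code_list)
    return events[_match_mask(events, lists, event_types)]
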