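"""Fragmentation evaluation: single-source phenotyping vs. the union benchmark.

In place of a chart-review gold standard, phenotype calls computed on the
de-duplicated union of all sources serve as the benchmark; each single-source
view is scored against it with confusion counts over the *fixed full cohort
roster* (so TP+FP+TN+FN always equals the cohort size) and the four derived
percentages — sensitivity TP/(TP+FN), specificity TN/(FP+TN), positive
predictive value TP/(TP+FP) and false-negative rate FN/(TP+FN). Errors are
then attributed to missing information: for every false-negative case or
false-positive control the per-factor evidence is compared between the erring
source view and the union view, counting subjects whose evidence exists in
the union but not in the source (plus, for RA, the aggregate encounter-count
shortfall).
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ehr_model import Codelists, SourceView, filter_window, load_codelists, make_view
from .ra_phenotype import (
    RAModel,
    classify_ra,
    load_ra_model,
    ra_feature_table,
    ra_score_table,
)
from .synthetic_ehr import Cohort
from .t2dm_phenotype import T2DMRules, classify_t2dm, load_t2dm_rules, t2dm_evidence_table

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "MissingInfoRow",
    "FactorSpec",
    "PhenotypeConfig",
    "ExperimentReport",
    "calls_for_view",
    "benchmark_calls",
    "confusion",
    "compute_metrics",
    "round_half_up",
    "attribute_missing_info",
    "ra_factor_specs",
    "t2dm_case_factor_specs",
    "t2dm_control_factor_specs",
    "run_experiment",
]

TARGETS = ("case", "control")


@dataclass(frozen=True)
class ConfusionCounts:
    """Agreement cells between a source call set and the benchmark over a
    fixed patient universe."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """The four percentages (raw, unrounded); None where a denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    fnr: float | None

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        return {
            name: None if value is None else round_half_up(value, ndigits)
            for name, value in self.__dict__.items()
        }


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (report-layer only; computations stay raw)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """Percentages from confusion counts; zero denominators yield None with a warning."""

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return None
        return 100.0 * num / den

    return PerformanceMetrics(
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.fp + c.tn, "specificity"),
        ppv=ratio(c.tp, c.tp + c.fp, "ppv"),
        fnr=ratio(c.fn, c.tp + c.fn, "fnr"),
    )


# ---------------------------------------------------------------------------
# Phenotype calls per view
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeConfig:
    """Code lists plus both algorithm configurations."""

    codelists: Codelists
    ra_model: RAModel
    t2dm_rules: T2DMRules

    @classmethod
    def default(cls) -> "PhenotypeConfig":
        return cls(
            codelists=load_codelists(),
            ra_model=load_ra_model(),
            t2dm_rules=load_t2dm_rules(),
        )


def calls_for_view(view: SourceView, algorithm: str, config: PhenotypeConfig) -> pd.DataFrame:
    if algorithm == "ra":
        return classify_ra(view, config.codelists, config.ra_model)
    if algorithm == "t2dm":
        return classify_t2dm(view, config.codelists, config.t2dm_rules)
    raise ValueError(f"unknown algorithm {algorithm!r} (expected 'ra' or 't2dm')")


def benchmark_calls(
    union_view: SourceView,
    algorithm: str,
    config: PhenotypeConfig,
    all_sources: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Calls on the union view, marked as the benchmark.

    Raises if the view does not cover all sources (a single-source view is
    never a valid benchmark).
    """
    if all_sources is not None and union_view.sources != frozenset(all_sources):
        raise ValueError(
            f"benchmark requires the union of {sorted(set(all_sources))}, "
            f"got {sorted(union_view.sources)}"
        )
    if len(union_view.sources) < 2:
        raise ValueError("benchmark requires a union view over >= 2 sources")
    calls = calls_for_view(union_view, algorithm, config).copy()
    calls["benchmark"] = True
    return calls


def _target_set(calls: pd.DataFrame, target: str) -> set[str]:
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    return set(calls.index[calls["label"] == target])


def confusion(
    source_calls: pd.DataFrame, benchmark_calls: pd.DataFrame, target: str
) -> ConfusionCounts:
    """Confusion counts for one target label over the shared roster."""
    roster = set(source_calls.index)
    if roster != set(benchmark_calls.index):
        raise ValueError("source and benchmark calls cover different rosters")
    src = _target_set(source_calls, target)
    bench = _target_set(benchmark_calls, target)
    tp = len(src & bench)
    fp = len(src - bench)
    fn = len(bench - src)
    tn = len(roster) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Missing-information attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpec:
    """One attributable evidence factor.

    ``extract`` maps a view to a per-patient Series (bool or count).
    ``compare`` is "less" (missing iff union value exceeds the source value —
    the monotone case) or "ne" (missing iff the values differ, for derived
    facts such as medication-order precedence that are not monotone in the
    event set).
    """

    name: str
    extract: Callable[[SourceView], pd.Series]
    compare: str = "less"


@dataclass(frozen=True)
class MissingInfoRow:
    """Per-factor missing-information counts for one error cell."""

    error_type: str  # "FN" | "FP"
    source: str
    total_subjects: int
    factor_counts: dict[str, int]
    missing_encounters: int | None = None

    def __post_init__(self) -> None:
        for name, count in self.factor_counts.items():
            if count > self.total_subjects:
                raise ValueError(f"factor {name!r} count exceeds total subjects")


def attribute_missing_info(
    errors: Iterable[str],
    source_view: SourceView,
    union_view: SourceView,
    factor_extractors: Sequence[FactorSpec],
    error_type: str = "FN",
    encounter_extract: Callable[[SourceView], pd.Series] | None = None,
    return_detail: bool = False,
):
    """Count error subjects whose factor evidence exists in the union view but
    not in the erring source view.

    With ``encounter_extract`` the aggregate encounter-count shortfall across
    error subjects is also totalled (the RA layout). ``return_detail``
    additionally yields the per-patient boolean factor diff frame.
    """
    errors = sorted(set(errors))
    roster = set(union_view.roster)
    unknown = set(errors) - roster
    if unknown:
        raise ValueError(f"error subjects outside roster: {sorted(unknown)[:5]}")

    detail = pd.DataFrame(index=pd.Index(errors, name="patient_id"))
    for spec in factor_extractors:
        u = spec.extract(union_view).reindex(errors)
        s = spec.extract(source_view).reindex(errors)
        if spec.compare == "ne":
            u_f = u.astype("float64")
            s_f = s.astype("float64")
            diff = ~((u_f == s_f) | (u_f.isna() & s_f.isna()))
        elif spec.compare == "less":
            diff = s.astype("float64").fillna(0) < u.astype("float64").fillna(0)
        else:
            raise ValueError(f"unknown compare mode {spec.compare!r}")
        detail[spec.name] = diff.astype(bool)

    shortfall = None
    if encounter_extract is not None:
        u = encounter_extract(union_view).reindex(errors).astype("float64").fillna(0)
        s = encounter_extract(source_view).reindex(errors).astype("float64").fillna(0)
        per_patient = (u - s).clip(lower=0)
        detail["_encounter_shortfall"] = per_patient
        shortfall = int(per_patient.sum())

    row = MissingInfoRow(
        error_type=error_type,
        source=source_view.label,
        total_subjects=len(errors),
        factor_counts={
            spec.name: int(detail[spec.name].sum()) for spec in factor_extractors
        },
        missing_encounters=shortfall,
    )
    return (row, detail) if return_detail else row


def _memo(fn: Callable[[SourceView], pd.DataFrame]) -> Callable[[SourceView], pd.DataFrame]:
    cache: dict[int, pd.DataFrame] = {}

    def wrapped(view: SourceView) -> pd.DataFrame:
        key = id(view)
        if key not in cache:
            cache[key] = fn(view)
        return cache[key]

    return wrapped


def ra_factor_specs(
    config: PhenotypeConfig, full: bool = False
) -> tuple[list[FactorSpec], Callable[[SourceView], pd.Series]]:
    """RA attribution factors plus the encounter-count extractor.

    The default layout mirrors the published table: binary "has 1+" factors
    for RA / PA / SLE diagnoses and RF lab tests, with encounters totalled as
    a shortfall. ``full=True`` instead compares every feature count, which is
    complete: any call flip implies at least one differing feature.
    """
    table = _memo(lambda v: ra_feature_table(v, config.codelists, config.ra_model))

    def flag(col: str) -> Callable[[SourceView], pd.Series]:
        return lambda v: table(v)[col] >= 1

    def count(col: str) -> Callable[[SourceView], pd.Series]:
        return lambda v: table(v)[col]

    if full:
        specs = [FactorSpec(c, count(c)) for c in (
            "n_ra_dx", "n_sle_dx", "n_pa_dx", "n_rf_lab", "n_rf_positive", "n_encounters"
        )]
        # exclusion codes decide the control rule but are not scoring features
        from .ehr_model import match_codes, require_codelist

        excl = require_codelist(config.codelists, "ra_exclusion")

        def n_exclusion(view: SourceView) -> pd.Series:
            matched = match_codes(view.events, excl)
            return (
                matched.groupby("patient_id").size().reindex(view.roster, fill_value=0)
            )

        specs.append(FactorSpec("n_exclusion_dx", n_exclusion))
    else:
        specs = [
            FactorSpec("ra_dx_1plus", flag("n_ra_dx")),
            FactorSpec("pa_dx_1plus", flag("n_pa_dx")),
            FactorSpec("sle_dx_1plus", flag("n_sle_dx")),
            FactorSpec("rf_lab_1plus", flag("n_rf_lab")),
        ]
    return specs, count("n_encounters")


def _t2dm_table(config: PhenotypeConfig) -> Callable[[SourceView], pd.DataFrame]:
    return _memo(lambda v: t2dm_evidence_table(v, config.codelists, config.t2dm_rules))


def t2dm_case_factor_specs(config: PhenotypeConfig, full: bool = False) -> list[FactorSpec]:
    """T2DM case attribution factors (published layout; ``full`` adds every
    evidence field, including medication-order precedence)."""
    table = _t2dm_table(config)

    def col(name: str) -> Callable[[SourceView], pd.Series]:
        return lambda v: table(v)[name]

    specs = [
        FactorSpec("t1dm_dx", lambda v: table(v)["n_t1dm_dx"] >= 1),
        FactorSpec("t2dm_dx", lambda v: table(v)["n_t2dm_dx"] >= 1),
        FactorSpec("t1dm_drug", col("has_t1dm_med")),
        FactorSpec("t2dm_drug", col("has_t2dm_med")),
        FactorSpec("abnormal_lab", col("has_abnormal_lab")),
        FactorSpec("t2dm_dx_physician", col("n_t2dm_dx_physician")),
    ]
    if full:
        specs += [
            FactorSpec("t2dm_med_precedence", col("t2dm_med_precedes_t1dm_med"), compare="ne"),
            FactorSpec("n_t1dm_dx", col("n_t1dm_dx")),
            FactorSpec("n_t2dm_dx", col("n_t2dm_dx")),
        ]
    return specs


def t2dm_control_factor_specs(config: PhenotypeConfig, full: bool = False) -> list[FactorSpec]:
    """T2DM control attribution factors (the six control screens)."""
    table = _t2dm_table(config)

    def col(name: str) -> Callable[[SourceView], pd.Series]:
        return lambda v: table(v)[name]

    specs = [
        FactorSpec("inperson_visits_2plus", lambda v: table(v)["n_inperson_visits"] >= 2),
        FactorSpec("glucose_measure_1plus", lambda v: table(v)["n_glucose_measures"] >= 1),
        FactorSpec("abnormal_lab", col("has_abnormal_lab")),
        FactorSpec("dm_related_dx", col("has_dm_related_dx")),
        FactorSpec("dm_med_or_supplies", col("has_dm_med_or_supplies")),
        FactorSpec("family_hx_dm", col("family_history_dm")),
    ]
    if full:
        specs += [
            FactorSpec("n_inperson_visits", col("n_inperson_visits")),
            FactorSpec("n_glucose_measures", col("n_glucose_measures")),
            FactorSpec("n_t2dm_dx", col("n_t2dm_dx")),
            FactorSpec("has_t2dm_med", col("has_t2dm_med")),
            FactorSpec("has_t1dm_med", col("has_t1dm_med")),
        ]
    return specs


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """All tabular outputs of one fragmentation experiment."""

    counts: pd.DataFrame          # positives per algorithm / target / view
    metrics: pd.DataFrame         # confusion counts + percentages per row
    missing_info: pd.DataFrame    # per-factor missing-information counts
    ra_probabilities: pd.DataFrame  # benchmark RA cases scored under every view
    calls: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _union_label(sources: Sequence[str]) -> str:
    return "+".join(sources)


def run_experiment(
    cohort: Cohort,
    sources: Sequence[str],
    algorithms: Sequence[str] = ("ra", "t2dm"),
    config: PhenotypeConfig | None = None,
    window: tuple | None = None,
) -> ExperimentReport:
    """Run both phenotyping algorithms on the union and every single source,
    score each source against the union benchmark, and attribute errors.

    ``window`` optionally restricts events to a closed [start, end] interval
    first. Views are evaluated in the order: union, then each source.
    """
    if len(sources) < 2:
        raise ValueError("fragmentation evaluation requires >= 2 sources")
    config = config or PhenotypeConfig.default()
    events = cohort.events
    if window is not None:
        events = filter_window(events, window[0], window[1])

    union_label = _union_label(sources)
    views: dict[str, SourceView] = {
        union_label: make_view(events, cohort.patients, sources, union_label, known_sources=sources)
    }
    for src in sources:
        views[src] = make_view(events, cohort.patients, [src], src, known_sources=sources)
    view_order = [union_label] + list(sources)

    counts_rows, metrics_rows, missing_rows = [], [], []
    calls: dict[tuple[str, str], pd.DataFrame] = {}
    ra_prob_frames = []

    for algorithm in algorithms:
        bench = benchmark_calls(views[union_label], algorithm, config, all_sources=sources)
        calls[(algorithm, union_label)] = bench
        for src in sources:
            calls[(algorithm, src)] = calls_for_view(views[src], algorithm, config)

        for label in view_order:
            row = {"algorithm": algorithm, "view": label}
            for target in TARGETS:
                row[f"n_{target}"] = len(_target_set(calls[(algorithm, label)], target))
            counts_rows.append(row)

        for target in TARGETS:
            bench_set = _target_set(bench, target)
            for label in view_order:
                c = confusion(calls[(algorithm, label)], bench, target)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = compute_metrics(c)
                metrics_rows.append(
                    {
                        "algorithm": algorithm,
                        "target": target,
                        "view": label,
                        "tp": c.tp,
                        "fp": c.fp,
                        "tn": c.tn,
                        "fn": c.fn,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "ppv": m.ppv,
                        "fnr": m.fnr,
                    }
                )

            # missing-information attribution for the published error cells
            attribute = (
                (algorithm == "ra" and target == "case")
                or (algorithm == "t2dm")
            )
            if not attribute:
                continue
            if algorithm == "ra":
                specs, enc = ra_factor_specs(config)
            elif target == "case":
                specs, enc = t2dm_case_factor_specs(config), None
            else:
                specs, enc = t2dm_control_factor_specs(config), None
            for src in sources:
                src_set = _target_set(calls[(algorithm, src)], target)
                for error_type, subjects in (
                    ("FN", bench_set - src_set),
                    ("FP", src_set - bench_set),
                ):
                    info = attribute_missing_info(
                        subjects, views[src], views[union_label], specs,
                        error_type=error_type, encounter_extract=enc,
                    )
                    missing_rows.append(
                        {
                            "algorithm": algorithm,
                            "target": target,
                            "error_type": info.error_type,
                            "source": info.source,
                            "total_subjects": info.total_subjects,
                            **info.factor_counts,
                            "missing_encounters": info.missing_encounters,
                        }
                    )

        if algorithm == "ra":
            bench_cases = sorted(_target_set(bench, "case"))
            for label in view_order:
                features = ra_feature_table(views[label], config.codelists, config.ra_model)
                probs = ra_score_table(features, config.ra_model).reindex(bench_cases)
                ra_prob_frames.append(
                    pd.DataFrame(
                        {"patient_id": bench_cases, "view": label, "probability": probs.to_numpy()}
                    )
                )

    counts = pd.DataFrame(counts_rows)
    metrics = pd.DataFrame(metrics_rows)
    missing_info = pd.DataFrame(missing_rows)
    for col in missing_info.columns:
        if col not in ("algorithm", "target", "error_type", "source"):
            missing_info[col] = missing_info[col].astype("Int64")
    ra_probabilities = (
        pd.concat(ra_prob_frames, ignore_index=True)
        if ra_prob_frames
        else pd.DataFrame(columns=["patient_id", "view", "probability"])
    )

    summary = {
        "n_patients": int(len(cohort.patients)),
        "sources": list(sources),
        "algorithms": list(algorithms),
        "union_view": union_label,
        "metrics": metrics.to_dict(orient="records"),
    }
    return ExperimentReport(
        counts=counts,
        metrics=metrics,
        missing_info=missing_info,
        ra_probabilities=ra_probabilities,
        calls=calls,
        summary=summary,
    )
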