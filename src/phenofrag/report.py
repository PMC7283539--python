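"""Human-readable rendering of an :class:`ExperimentReport`.

Writes deterministic CSV files (counts, metrics, missing information, RA
probabilities), a full-precision ``summary.json`` and a Markdown summary.
Percentages are rounded half-up at the requested precision only at this
layer; the underlying report keeps raw values.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .fragmentation_eval import ExperimentReport, round_half_up

__all__ = ["render_report"]

_METRIC_COLS = ("sensitivity", "specificity", "ppv", "fnr")


def _format_metrics(metrics: pd.DataFrame, precision: int) -> pd.DataFrame:
    out = metrics.copy()
    for col in _METRIC_COLS:
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else f"{round_half_up(float(v), precision):.{precision}f}"
        )
    return out


def render_report(report: ExperimentReport, outdir: str | Path, precision: int = 1) -> list[Path]:
    """Write the report bundle under ``outdir``; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    counts = report.counts.sort_values(["algorithm", "view"], kind="stable")
    path = outdir / "counts.csv"
    counts.to_csv(path, index=False)
    written.append(path)

    metrics = _format_metrics(
        report.metrics.sort_values(["algorithm", "target", "view"], kind="stable"), precision
    )
    path = outdir / "metrics.csv"
    metrics.to_csv(path, index=False)
    written.append(path)

    missing = report.missing_info
    if len(missing):
        missing = missing.sort_values(
            ["algorithm", "target", "error_type", "source"], kind="stable"
        )
    path = outdir / "missing_info.csv"
    missing.to_csv(path, index=False)
    written.append(path)

    probs = report.ra_probabilities.sort_values(["view", "patient_id"], kind="stable")
    path = outdir / "ra_probabilities.csv"
    probs.to_csv(path, index=False, float_format="%.6f")
    written.append(path)

    path = outdir / "summary.json"
    path.write_text(json.dumps(report.summary, indent=2, sort_keys=True, default=str) + "\n")
    written.append(path)

    path = outdir / "report.md"
    path.write_text(_markdown(report, precision))
    written.append(path)
    return written


def _markdown(report: ExperimentReport, precision: int) -> str:
    lines = ["# Fragmentation evaluation report", ""]
    lines += ["## Phenotype counts by data source", ""]
    lines += _md_table(report.counts.sort_values(["algorithm", "view"], kind="stable"))
    lines += ["", "## Benchmark performance by data source", ""]
    lines += _md_table(
        _format_metrics(
            report.metrics.sort_values(["algorithm", "target", "view"], kind="stable"), precision
        )
    )
    if len(report.missing_info):
        lines += ["", "## Missing information for error subjects", ""]
        lines += _md_table(
            report.missing_info.sort_values(
                ["algorithm", "target", "error_type", "source"], kind="stable"
            )
        )
    lines.append("")
    return "\n".join(lines)


def _md_table(frame: pd.DataFrame) -> list[str]:
    if not len(frame):
        return ["(empty)"]
    cols = list(frame.columns)
    def fmt(v):
        if pd.isna(v):
            return ""
        if isinstance(v, float) and v.is_integer():
            return str(int(v))
        return str(v)
    rows = [" | ".join(cols), " | ".join("---" for _ in cols)]
    for _, row in frame.iterrows():
        rows.append(" | ".join(fmt(row[c]) for c in cols))
    return rows
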