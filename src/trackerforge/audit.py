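"""Audit stage: aggregate validation events into data-quality reports.

The event log and the staged tables together answer the operational
question "where do quality problems come from?": a count matrix of events
by (clinic, reporting period, event code), and per-variable completeness —
the fraction of staged rows carrying a usable value, where sentinel values
never count as observed data. The completeness denominator is all staged
rows of the entity, so columns that are structurally absent in some
template eras (e.g. insulin-type fields before 2024) surface as
incompleteness rather than disappearing from the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import pyarrow.parquet as pq

from .config import Config, load_default_config

__all__ = ["AuditReport", "build_audit", "render_report", "PARSE_ERROR"]

PARSE_ERROR = "PARSE_ERROR"


@dataclass
class AuditReport:
    """Event counts by (clinic, period, code) plus per-variable completeness."""

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)  # "entity.column"
    total_events: int = 0
    rows: dict[str, int] = field(default_factory=dict)

    def count(self, clinic: str, period: str, code: str) -> int:
        return self.counts.get((clinic, period, code), 0)

    def code_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, _, code), n in self.counts.items():
            out[code] = out.get(code, 0) + n
        return dict(sorted(out.items()))

    def to_dict(self) -> dict:
        matrix = [
            {"clinic": c, "period": p, "code": k, "count": n}
            for (c, p, k), n in sorted(self.counts.items())
        ]
        return {
            "total_events": self.total_events,
            "rows": dict(sorted(self.rows.items())),
            "counts": matrix,
            "code_totals": self.code_totals(),
            "completeness": dict(sorted(self.completeness.items())),
        }


def _usable(value: object, sentinels) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and value == sentinels[0]:
        return False
    if isinstance(value, date) and value == sentinels[1]:
        return False
    return True


def build_audit(events_path: Path | str, tables_dir: Path | str,
                config: Optional[Config] = None) -> AuditReport:
    """Aggregate an event log and staged tables into an audit report.

    Malformed event lines are never dropped silently — they count under the
    PARSE_ERROR bucket. Completeness is (#rows with usable value) / (#rows),
    usable excluding both missing values and sentinels.
    """
    events_path, tables_dir = Path(events_path), Path(tables_dir)
    config = config or load_default_config()
    sentinels = (float(config.sentinels.numeric_sentinel),
                 config.sentinels.date_sentinel)
    report = AuditReport()

    with open(events_path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            report.total_events += 1
            try:
                ev = json.loads(line)
                key = (str(ev.get("clinic", "")), str(ev.get("period", "")),
                       str(ev["code"]))
            except Exception:
                key = ("", "", PARSE_ERROR)
            report.counts[key] = report.counts.get(key, 0) + 1

    for entity in ("patient", "product"):
        path = tables_dir / f"{entity}.parquet"
        if not path.exists():
            continue
        table = pq.read_table(path)
        n = table.num_rows
        report.rows[entity] = n
        for col in table.column_names:
            if col.startswith("source_"):
                continue
            values = table.column(col).to_pylist()
            usable = sum(1 for v in values if _usable(v, sentinels))
            report.completeness[f"{entity}.{col}"] = (
                usable / n if n else 0.0)
    return report


def render_report(report: AuditReport, path: Path | str) -> Path:
    """Write the report as JSON plus a human-readable text summary.

    Ordering is stable (clinic, period, code lexicographic); rendering the
    same report twice yields identical bytes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = report.to_dict()
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                    encoding="ascii")

    lines = ["Data-quality audit", "==================", "",
             f"total events: {doc['total_events']}", ""]
    lines.append(f"{'clinic':<8} {'period':<10} {'code':<22} {'count':>6}")
    for row in doc["counts"]:
        lines.append(f"{row['clinic']:<8} {row['period']:<10} "
                     f"{row['code']:<22} {row['count']:>6}")
    lines += ["", "completeness (fraction of usable values per column)", ""]
    for name, frac in doc["completeness"].items():
        lines.append(f"{name:<40} {frac:6.3f}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n",
                                        encoding="ascii")
    return path
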