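"""Load stage: assemble cleaned records into database-ready columnar tables.

Cleaned records are split by entity, projected onto the canonical schema
(the combined blood-pressure field expands into systolic/diastolic columns,
cleaning flags materialize as boolean columns), sorted deterministically —
patients by (identifier, visit date), products by (clinic, record date,
product name), ties broken by provenance — and serialized to Apache Parquet
in a local staging directory. Parquet output carries explicit logical types
(date32 for dates, so the 9999-12-31 sentinel survives) and is byte-for-byte
reproducible for identical inputs.

``run_pipeline`` drives the whole extract-clean-load sequence over a
directory of anonymized workbooks and writes the staged tables, the JSON
Lines event log and a run summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .clean import CanonicalRecord, clean_record
from .config import Config, load_default_config
from .events import ValidationEvent, write_events
from .extract import extract_records

__all__ = ["StagedTable", "assemble_tables", "write_parquet", "run_pipeline",
           "PATIENT_SORT_KEYS", "PRODUCT_SORT_KEYS"]

PATIENT_SORT_KEYS = ("patient_id", "visit_date")
PRODUCT_SORT_KEYS = ("clinic_code", "record_date", "product_name")

_PROVENANCE_COLS = ("source_workbook", "source_sheet", "source_row")


def _entity_columns(config: Config, entity: str) -> list[tuple[str, str]]:
    """(column name, logical type) pairs in canonical-schema order."""
    cols: list[tuple[str, str]] = []
    for var in config.entity_variables(entity):
        if var.dtype == "blood_pressure":
            cols.append((f"{var.name}_systolic", "float"))
            cols.append((f"{var.name}_diastolic", "float"))
        elif var.dtype in ("number", "hba1c", "height"):
            cols.append((var.name, "float"))
        elif var.dtype == "date":
            cols.append((var.name, "date"))
        else:
            cols.append((var.name, "string"))
        # flag columns
        if var.dtype == "hba1c":
            cols.append((f"{var.name}_threshold_exceeded", "bool"))
        elif var.dtype == "height":
            cols.append((f"{var.name}_unit_converted", "bool"))
        elif var.dtype == "date":
            cols.append((f"{var.name}_month_precision", "bool"))
    return cols


@dataclass
class StagedTable:
    """One database-ready table with explicit logical column types."""

    entity: str
    frame: pd.DataFrame
    column_types: dict[str, str]

    def __len__(self) -> int:
        return len(self.frame)

    def to_arrow(self) -> pa.Table:
        fields = []
        arrays = []
        typemap = {"float": pa.float64(), "date": pa.date32(),
                   "string": pa.string(), "bool": pa.bool_(),
                   "int": pa.int64()}
        for col in self.frame.columns:
            t = typemap[self.column_types[col]]
            fields.append(pa.field(col, t))
            arrays.append(pa.array(self.frame[col].tolist(), type=t))
        return pa.Table.from_arrays(arrays, schema=pa.schema(fields))


def _sort_key_patient(rec: CanonicalRecord) -> tuple:
    pid = rec.values.get("patient_id")
    vd = rec.values.get("visit_date")
    pid_s = str(pid.value) if pid is not None and pid.value is not None else ""
    vd_s = (vd.value.isoformat()
            if vd is not None and isinstance(vd.value, date) else "")
    return (pid_s, vd_s, rec.workbook, rec.sheet, rec.row)


def _sort_key_product(rec: CanonicalRecord) -> tuple:
    rd = rec.values.get("record_date")
    pn = rec.values.get("product_name")
    rd_s = (rd.value.isoformat()
            if rd is not None and isinstance(rd.value, date) else "")
    pn_s = str(pn.value) if pn is not None and pn.value is not None else ""
    return (rec.clinic, rd_s, pn_s, rec.workbook, rec.sheet, rec.row)


def assemble_tables(records: list[CanonicalRecord], config: Config,
                    ) -> tuple[StagedTable, StagedTable]:
    """Split cleaned records by entity into sorted, schema-ordered tables.

    Sentinel values pass through unchanged; flags become boolean columns;
    ties in the sort keys are broken by provenance so the order is a total,
    deterministic function of content. Fully empty records are excluded
    (their count is reported by the pipeline summary).
    """
    out: list[StagedTable] = []
    for entity, keyfn in (("patient", _sort_key_patient),
                          ("product", _sort_key_product)):
        cols = _entity_columns(config, entity)
        colnames = [c for c, _ in cols]
        types = dict(cols)
        for c in _PROVENANCE_COLS:
            types[c] = "string" if c != "source_row" else "int"
        subset = sorted((r for r in records if r.entity == entity
                         and any(cv.value is not None
                                 for cv in r.values.values())),
                        key=keyfn)
        data: dict[str, list] = {c: [] for c in colnames}
        for c in _PROVENANCE_COLS:
            data[c] = []
        for rec in subset:
            for cname, ctype in cols:
                if ctype == "bool":
                    for suffix, flagname in (
                            ("_threshold_exceeded", "threshold_exceeded"),
                            ("_unit_converted", "unit_converted"),
                            ("_month_precision", "month_precision")):
                        if cname.endswith(suffix):
                            src = cname[:-len(suffix)]
                            break
                    cv = rec.values.get(src)
                    data[cname].append(bool(cv is not None
                                            and flagname in cv.flags))
                else:
                    cv = rec.values.get(cname)
                    data[cname].append(None if cv is None else cv.value)
            data["source_workbook"].append(rec.workbook)
            data["source_sheet"].append(rec.sheet)
            data["source_row"].append(rec.row)
        frame = pd.DataFrame(data, columns=colnames + list(_PROVENANCE_COLS))
        out.append(StagedTable(entity=entity, frame=frame, column_types=types))
    return out[0], out[1]


def write_parquet(table: StagedTable, path: Path | str) -> Path:
    """Serialize a staged table to Parquet with declared logical types.

    Identical tables yield identical bytes; a read-back equals the table
    exactly (compare via :meth:`StagedTable.to_arrow`).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pq.write_table(table.to_arrow(), path, compression="snappy")
    return path


def run_pipeline(in_dir: Path | str, out_dir: Path | str,
                 config: Optional[Config] = None,
                 seed: Optional[int] = None) -> dict:
    """Extract, clean and load every workbook of a staging input directory.

    Writes ``patient.parquet``, ``product.parquet``, ``events.jsonl`` and
    ``summary.json`` to ``out_dir`` and returns the summary dict. The exit
    status contract is carried by ``summary["unreadable_workbooks"]``.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or load_default_config()

    workbooks = sorted(in_dir.glob("*.xlsx"))
    all_records: list[CanonicalRecord] = []
    all_events: list[ValidationEvent] = []
    unreadable: list[str] = []
    unknown_period_sheets = 0

    for path in workbooks:
        try:
            raw_records, events = extract_records(path, config)
        except Exception:
            unreadable.append(path.name)
            continue
        all_events.extend(events)
        seen_sheets = set()
        for raw in raw_records:
            if raw.period == "unknown" and raw.sheet not in seen_sheets:
                seen_sheets.add(raw.sheet)
                unknown_period_sheets += 1
            rec, evs = clean_record(raw, config)
            all_records.append(rec)
            all_events.extend(evs)

    patient, product = assemble_tables(all_records, config)
    write_parquet(patient, out_dir / "patient.parquet")
    write_parquet(product, out_dir / "product.parquet")
    write_events(all_events, out_dir / "events.jsonl")

    by_code: dict[str, int] = {}
    for ev in all_events:
        by_code[ev.code] = by_code.get(ev.code, 0) + 1
    n_excluded = len(all_records) - len(patient) - len(product)
    summary = {
        "workbooks": [p.name for p in workbooks],
        "unreadable_workbooks": unreadable,
        "records": {"patient": len(patient), "product": len(product),
                    "excluded_empty": n_excluded,
                    "total_cleaned": len(all_records)},
        "events_by_code": dict(sorted(by_code.items())),
        "total_events": len(all_events),
        "clinics": sorted({r.clinic for r in all_records}),
        "periods": sorted({r.period for r in all_records}),
        "unknown_period_sheets": unknown_period_sheets,
        "seed": seed,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="ascii")
    return summary
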