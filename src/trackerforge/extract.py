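"""Extraction stage: locate data regions and map raw columns onto the schema.

Monthly worksheets carry decorative title rows, varying header spellings and
occasional end markers. Region detection finds the header row (the first row
where at least three cells normalize to known synonyms), then takes the data
span from the following row down to the first fully empty row, an ``END``
marker, or the sheet end. Column mapping is purely configuration-driven:
each header is normalized and looked up in the synonym map; unmatched
headers are retained on the record and logged (never silently excluded),
and duplicate mappings keep the first occurrence.

All coordinates are 0-based with half-open spans, consistently across
provenance and logs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from openpyxl import load_workbook

from .config import Config, SynonymMap, normalize_header
from .events import ValidationEvent

__all__ = ["UNMAPPED", "RawSheetRegion", "RawRecord", "detect_region",
           "map_columns", "extract_records", "HeaderNotFound"]

UNMAPPED = "UNMAPPED"
#: minimum synonym hits for a row to qualify as the header
HEADER_MIN_HITS = 3
_END_MARKER = "end"
_PERIOD_RE = re.compile(r"(\d{4})-(\d{2})")
_PATIENT_LIST = "patient list"


class HeaderNotFound(ValueError):
    """No row of the sheet qualifies as a header."""


@dataclass
class RawSheetRegion:
    """Detected data region of one worksheet."""

    sheet: str
    header_row: int                      # 0-based
    data_span: tuple[int, int]           # half-open, 0-based
    headers: list[object] = field(default_factory=list)
    column_map: dict[int, str] = field(default_factory=dict)  # col idx -> canonical/UNMAPPED
    entity: str = "patient"
    period: str = "unknown"


@dataclass
class RawRecord:
    """One extracted data row with provenance and raw cell payloads."""

    entity: str
    workbook: str
    sheet: str
    row: int                              # 0-based absolute sheet row
    clinic: str
    period: str
    values: dict[str, object] = field(default_factory=dict)
    unmapped: dict[str, object] = field(default_factory=dict)  # raw header -> cell


def _row_empty(row: list[object]) -> bool:
    return all(c is None or (isinstance(c, str) and c.strip() == "")
               for c in row)


def _is_end_marker(row: list[object]) -> bool:
    head = next((c for c in row if c is not None
                 and str(c).strip() != ""), None)
    return head is not None and normalize_header(str(head)) == _END_MARKER


def detect_region(sheet_name: str, rows: list[list[object]],
                  synonyms: SynonymMap) -> RawSheetRegion:
    """Find the header row and the half-open data span of one sheet.

    The header is the first row with at least :data:`HEADER_MIN_HITS` cells
    normalizing to known synonyms. The span runs from the next row to the
    first fully empty row, the first ``END`` marker row, or the sheet end —
    whichever comes first. Raises :class:`HeaderNotFound` if no row
    qualifies.
    """
    header_row = None
    for i, row in enumerate(rows):
        hits = sum(1 for c in row
                   if c is not None and synonyms.lookup(str(c)) is not None)
        if hits >= HEADER_MIN_HITS:
            header_row = i
            break
    if header_row is None:
        raise HeaderNotFound(f"sheet {sheet_name!r}: no recognizable header")
    end = len(rows)
    for i in range(header_row + 1, len(rows)):
        if _row_empty(rows[i]) or _is_end_marker(rows[i]):
            end = i
            break
    m = _PERIOD_RE.search(sheet_name)
    period = f"{m.group(1)}-{m.group(2)}" if m else "unknown"
    return RawSheetRegion(sheet=sheet_name, header_row=header_row,
                          data_span=(header_row + 1, end),
                          headers=list(rows[header_row]), period=period)


def map_columns(region: RawSheetRegion, synonyms: SynonymMap,
                config: Config) -> tuple[RawSheetRegion, list[ValidationEvent]]:
    """Map each header cell to a canonical variable via the synonym file.

    Unmatched headers become UNMAPPED with one W_UNMAPPED_COLUMN event per
    (sheet, header); a second header mapping to an already-claimed canonical
    variable is ignored with W_DUPLICATE_MAPPING. The region's entity is the
    one (patient vs product) with more entity-exclusive mapped variables.
    """
    events: list[ValidationEvent] = []
    claimed: set[str] = set()
    for j, header in enumerate(region.headers):
        if header is None or str(header).strip() == "":
            continue
        target = synonyms.lookup(str(header))
        if target is None:
            region.column_map[j] = UNMAPPED
            events.append(ValidationEvent(
                code="W_UNMAPPED_COLUMN", sheet=region.sheet,
                row=region.header_row, column=str(header), raw=str(header)))
            continue
        if target in claimed:
            events.append(ValidationEvent(
                code="W_DUPLICATE_MAPPING", sheet=region.sheet,
                row=region.header_row, column=target, raw=str(header)))
            region.column_map[j] = UNMAPPED
            continue
        claimed.add(target)
        region.column_map[j] = target

    patient_only = {v.name for v in config.entity_variables("patient")} \
        - {v.name for v in config.entity_variables("product")}
    product_only = {v.name for v in config.entity_variables("product")} \
        - {v.name for v in config.entity_variables("patient")}
    p_hits = len(claimed & patient_only)
    q_hits = len(claimed & product_only)
    region.entity = "product" if q_hits > p_hits else "patient"
    return region, events


def extract_records(workbook_path: Path | str, config: Config,
                    clinic: Optional[str] = None,
                    ) -> tuple[list[RawRecord], list[ValidationEvent]]:
    """Extract all raw records from one anonymized workbook.

    Every monthly worksheet is scanned (the Patient List roster sheet is
    excluded from data extraction); per-row records carry provenance and the
    raw cell payload for each mapped column. Sheets without a recognizable
    header are skipped with a W_NO_HEADER event.
    """
    workbook_path = Path(workbook_path)
    clinic = clinic or workbook_path.stem
    wb = load_workbook(workbook_path, read_only=True, data_only=True)
    records: list[RawRecord] = []
    events: list[ValidationEvent] = []
    try:
        for sheet_name in wb.sheetnames:
            if normalize_header(sheet_name) == _PATIENT_LIST:
                continue
            rows = [list(r) for r in wb[sheet_name].iter_rows(values_only=True)]
            try:
                region = detect_region(sheet_name, rows, config.synonyms)
            except HeaderNotFound:
                events.append(ValidationEvent(
                    code="W_NO_HEADER", workbook=workbook_path.name,
                    sheet=sheet_name, raw="", clinic=clinic))
                continue
            region, map_events = map_columns(region, config.synonyms, config)
            for ev in map_events:
                events.append(ValidationEvent(
                    code=ev.code, workbook=workbook_path.name, sheet=ev.sheet,
                    row=ev.row, column=ev.column, raw=ev.raw, clinic=clinic,
                    period=region.period))
            lo, hi = region.data_span
            for i in range(lo, hi):
                row = rows[i]
                rec = RawRecord(entity=region.entity,
                                workbook=workbook_path.name, sheet=sheet_name,
                                row=i, clinic=clinic, period=region.period)
                for j, cell in enumerate(row):
                    target = region.column_map.get(j)
                    if target is None:
                        continue
                    if target == UNMAPPED:
                        rec.unmapped[str(region.headers[j])] = cell
                    else:
                        rec.values[target] = cell
                records.append(rec)
    finally:
        wb.close()
    return records, events
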