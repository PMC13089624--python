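"""Deterministic pseudonymization of tracker workbooks.

Pseudonymization runs before any other processing. Each workbook carries a
"Patient List" roster sheet pairing patient names with structured program
identifiers (two-letter country code + two-letter clinic code + three-digit
zero-padded sequence, e.g. ``LAVT001``). A lookup built from that roster is
applied to every worksheet: any cell whose normalized content equals a roster
name is replaced by the identifier. Cells in name-designated columns that
match no roster entry are redacted to ``[UNRESOLVED]`` (fail closed) and
logged with ``W_NAME_UNMATCHED`` for manual follow-up. Matching is exact
after normalization — no fuzzy or phonetic matching, which could substitute
the wrong patient. Originals are never modified; deidentified copies go to a
separate directory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from openpyxl import load_workbook

from ._xlsx import save_workbook_deterministic
from .config import normalize_header
from .events import ValidationEvent

__all__ = [
    "ID_PATTERN", "REDACTION_TOKEN", "PatientIdentifier", "IdentifierLookup",
    "LookupError_", "validate_identifier", "build_lookup",
    "anonymize_workbook", "normalize_name", "PATIENT_LIST_SHEET",
]

ID_PATTERN = re.compile(r"^[A-Z]{2}[A-Z]{2}[0-9]{3}$")
REDACTION_TOKEN = "[UNRESOLVED]"
PATIENT_LIST_SHEET = "patient list"


def normalize_name(raw: object) -> str:
    """Name normalization: case-fold + whitespace collapse (same rules as
    header normalization)."""
    return normalize_header(str(raw))


class LookupError_(ValueError):
    """Roster problems that cannot be resolved automatically."""


@dataclass(frozen=True)
class PatientIdentifier:
    """Structured program identifier: country + clinic + sequence."""

    country: str
    clinic: str
    sequence: int

    def __post_init__(self) -> None:
        if not (len(self.country) == 2 and self.country.isalpha()
                and self.country.isupper()):
            raise ValueError(f"country code must be 2 uppercase letters: "
                             f"{self.country!r}")
        if not (len(self.clinic) == 2 and self.clinic.isalpha()
                and self.clinic.isupper()):
            raise ValueError(f"clinic code must be 2 uppercase letters: "
                             f"{self.clinic!r}")
        if not 1 <= self.sequence <= 999:
            raise ValueError(f"sequence must be 1-999: {self.sequence}")

    @property
    def rendered(self) -> str:
        return f"{self.country}{self.clinic}{self.sequence:03d}"

    @classmethod
    def parse(cls, candidate: str) -> "PatientIdentifier":
        """Structural parse; raises ValueError if the shape is wrong."""
        if not isinstance(candidate, str) or len(candidate) != 7:
            raise ValueError(f"identifier must be 7 characters: {candidate!r}")
        head, tail = candidate[:4], candidate[4:]
        if not (head.isalpha() and head.isupper() and head.isascii()):
            raise ValueError(f"identifier prefix must be 4 uppercase letters: "
                             f"{candidate!r}")
        if not (tail.isdigit() and tail.isascii()):
            raise ValueError(f"identifier suffix must be 3 digits: {candidate!r}")
        seq = int(tail)
        if seq == 0:
            raise ValueError(f"identifier sequence 000 is reserved: {candidate!r}")
        return cls(country=head[:2], clinic=head[2:], sequence=seq)


def validate_identifier(candidate: str
                        ) -> tuple[bool, Optional[ValidationEvent]]:
    """True iff the candidate has the program identifier shape.

    Failures emit a ``W_ID_PATTERN`` event carrying the candidate, for
    manual review.
    """
    try:
        PatientIdentifier.parse(candidate)
        return True, None
    except ValueError:
        ev = ValidationEvent(code="W_ID_PATTERN", column="patient_id",
                             raw=str(candidate), substituted=None)
        return False, ev


@dataclass
class IdentifierLookup:
    """Normalized name -> identifier mapping built from a Patient List."""

    mapping: dict[str, str] = field(default_factory=dict)
    events: list[ValidationEvent] = field(default_factory=list)
    unmatched_names: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, raw_name: object) -> Optional[str]:
        return self.mapping.get(normalize_name(raw_name))


def _find_patient_list(wb) -> Optional[str]:
    for name in wb.sheetnames:
        if normalize_header(name) == PATIENT_LIST_SHEET:
            return name
    return None


#: headers that designate a patient-name column (exact normalized match;
#: "product name" and the like must never be treated as patient names)
_NAME_HEADERS = frozenset({"patient name", "name", "full name"})


def _is_name_header(header: object) -> bool:
    return normalize_header(str(header)) in _NAME_HEADERS


def build_lookup(workbook_path: Path | str) -> IdentifierLookup:
    """Read the Patient List sheet into a name->identifier lookup.

    The identifier column is recognized by its content (cells matching the
    identifier pattern); the name column is the other text column. Duplicate
    normalized names with conflicting identifiers are a hard error;
    identifiers failing the pattern are ingested but logged W_ID_PATTERN.
    """
    workbook_path = Path(workbook_path)
    wb = load_workbook(workbook_path, read_only=True, data_only=True)
    try:
        sheet_name = _find_patient_list(wb)
        if sheet_name is None:
            raise LookupError_(
                f"{workbook_path.name}: no sheet named 'Patient List'")
        rows = [[c for c in row] for row in wb[sheet_name].iter_rows(
            values_only=True)]
    finally:
        wb.close()
    rows = [r for r in rows if any(c is not None and str(c).strip() != ""
                                   for c in r)]
    if not rows:
        raise LookupError_(f"{workbook_path.name}: Patient List sheet is empty")

    header, data = rows[0], rows[1:]
    name_col = id_col = None
    for j, h in enumerate(header):
        if h is None:
            continue
        norm = normalize_header(str(h))
        if _is_name_header(h):
            name_col = j if name_col is None else name_col
        elif "id" in norm.split() or "identifier" in norm or "code" in norm:
            id_col = j if id_col is None else id_col
    if name_col is None or id_col is None:
        raise LookupError_(
            f"{workbook_path.name}: Patient List needs a name column and an "
            f"identifier column, got headers {header!r}")

    lookup = IdentifierLookup()
    for i, row in enumerate(data, start=1):
        raw_name = row[name_col] if name_col < len(row) else None
        raw_id = row[id_col] if id_col < len(row) else None
        if raw_name is None or str(raw_name).strip() == "":
            continue
        ident = "" if raw_id is None else str(raw_id).strip()
        ok, ev = validate_identifier(ident)
        if not ok and ev is not None:
            lookup.events.append(
                ValidationEvent(code="W_ID_PATTERN",
                                workbook=workbook_path.name, sheet=sheet_name,
                                row=i, column="patient_id", raw=ident))
        key = normalize_name(raw_name)
        if key in lookup.mapping and lookup.mapping[key] != ident:
            raise LookupError_(
                f"{workbook_path.name}: duplicate normalized name {key!r} "
                f"maps to both {lookup.mapping[key]!r} and {ident!r}")
        lookup.mapping[key] = ident
    return lookup


def anonymize_workbook(workbook_path: Path | str, lookup: IdentifierLookup,
                       out_dir: Path | str,
                       ) -> tuple[Path, list[ValidationEvent]]:
    """Replace every roster name with its identifier across all sheets.

    Whole-cell matches only (free text is never rewritten mid-sentence).
    Unmatched non-empty cells in name-designated columns are redacted to
    ``[UNRESOLVED]`` and logged ``W_NAME_UNMATCHED``. The output directory
    must differ from the input directory: originals never leave their
    storage location.
    """
    workbook_path = Path(workbook_path)
    out_dir = Path(out_dir)
    if out_dir.resolve() == workbook_path.parent.resolve():
        raise ValueError("output directory must differ from the input "
                         "directory; originals are never overwritten")
    out_dir.mkdir(parents=True, exist_ok=True)

    wb = load_workbook(workbook_path, data_only=True)
    events: list[ValidationEvent] = []
    for ws in wb.worksheets:
        is_roster = normalize_header(ws.title) == PATIENT_LIST_SHEET
        name_cols: set[int] = set()
        for row in ws.iter_rows():
            for cell in row:
                if cell.value is None:
                    continue
                text = str(cell.value)
                replacement = lookup.get(text)
                if replacement is not None:
                    cell.value = replacement
                    continue
                if is_roster:
                    continue
                if _is_name_header(text):
                    # header cell designates this column as a name column
                    name_cols.add(cell.column)
                    continue
                if normalize_header(text) == "end":
                    continue  # structural end-of-data marker, not a name
                if cell.column in name_cols and text.strip():
                    cell.value = REDACTION_TOKEN
                    events.append(ValidationEvent(
                        code="W_NAME_UNMATCHED", workbook=workbook_path.name,
                        sheet=ws.title, row=cell.row - 1, column="patient_id",
                        raw="", substituted=REDACTION_TOKEN))
    out_path = out_dir / workbook_path.name
    save_workbook_deterministic(wb, out_path)
    return out_path, events
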