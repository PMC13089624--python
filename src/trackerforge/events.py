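"""Structured data-quality events.

Every validation finding anywhere in the pipeline — a conversion failure, an
out-of-range value, an unmatched name — is recorded as one :class:`ValidationEvent`
with a standardized code, cell-level provenance, and the raw/substituted values.
Events serialize to JSON Lines with a stable key order so logs are diffable
and streamable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

#: Warning codes: data lost precision or was substituted / could not be mapped.
WARNING_CODES = frozenset({
    "W_TYPE_NUM", "W_TYPE_DATE", "W_RANGE", "W_CATEGORY", "W_BP_MALFORMED",
    "W_ID_PATTERN", "W_NAME_UNMATCHED", "W_UNMAPPED_COLUMN",
    "W_DUPLICATE_MAPPING", "W_NO_HEADER",
})
#: Info codes: a recoverable transformation was applied and flagged.
INFO_CODES = frozenset({
    "I_HBA1C_THRESHOLD", "I_HEIGHT_CONVERTED", "I_DATE_MONTH_PRECISION",
})
ALL_CODES = WARNING_CODES | INFO_CODES

_KEY_ORDER = ("code", "severity", "workbook", "sheet", "row", "column",
              "raw", "substituted", "clinic", "period")


@dataclass
class ValidationEvent:
    """One coded data-quality finding with cell provenance.

    ``row`` is the 0-based absolute sheet row; ``column`` is the canonical
    variable name (or the raw header for mapping-level events). ``substituted``
    is the sentinel written in place of the raw value, or ``None`` when the
    raw value was retained.
    """

    code: str
    workbook: str = ""
    sheet: str = ""
    row: Optional[int] = None
    column: str = ""
    raw: str = ""
    substituted: Optional[str] = None
    clinic: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown event code: {self.code!r}")

    @property
    def severity(self) -> str:
        return "warning" if self.code in WARNING_CODES else "info"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["severity"] = self.severity
        return {k: d[k] for k in _KEY_ORDER}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationEvent":
        d = {k: v for k, v in d.items() if k != "severity"}
        return cls(**d)


def write_events(events: Iterable[ValidationEvent], path: Path | str) -> Path:
    """Write events as JSON Lines (one event per line, stable key order)."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")
    return path


def read_events(path: Path | str) -> list[ValidationEvent]:
    out = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ValidationEvent.from_dict(json.loads(line)))
    return out
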