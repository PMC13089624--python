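"""Score pipeline output against a generator ground-truth manifest.

The synthetic generator records, for every cell it writes, the intended true
value and the corruption class it injected. This module replays the cleaned
records and the event log against that manifest and measures:

* recovery — recoverable corruption classes (format variants, serials,
  embedded dates, inequality prefixes, combined blood pressure, centimeter
  heights) and clean cells must reproduce the true value exactly;
* accounting — every non-blank unrecoverable corruption must yield exactly
  one warning event; blanks must surface as missing values with no event;
  free-text categoricals must be retained with a W_CATEGORY warning;
* the sentinel/event bijection — sentinel-valued source cells and warning
  events carrying a substitution must match one-to-one on provenance;
* conservation — no generated data row may be lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable

from .clean import CanonicalRecord
from .config import Config
from .events import ValidationEvent
from .synthetic import (GroundTruthManifest, ManifestEntry,
                        RECOVERABLE_CLASSES, RETAINED_CLASSES)

__all__ = ["VerificationSummary", "verify_against_manifest"]

_TOL = 1e-9


@dataclass
class VerificationSummary:
    """Aggregate outcome of a manifest verification pass."""

    recoverable_total: int = 0
    recoverable_recovered: int = 0
    clean_total: int = 0
    clean_recovered: int = 0
    unrecoverable_total: int = 0
    unrecoverable_one_warning: int = 0
    blank_total: int = 0
    blank_missing: int = 0
    freetext_total: int = 0
    freetext_retained: int = 0
    sentinel_cells: int = 0
    substituting_warnings: int = 0
    bijection_mismatches: int = 0
    rows_expected: int = 0
    rows_cleaned: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        total = self.recoverable_total
        return self.recoverable_recovered / total if total else 1.0

    @property
    def clean_rate(self) -> float:
        return self.clean_recovered / self.clean_total if self.clean_total else 1.0

    @property
    def bijection_ok(self) -> bool:
        return (self.bijection_mismatches == 0
                and self.sentinel_cells == self.substituting_warnings)

    @property
    def conservation_ok(self) -> bool:
        return self.rows_expected == self.rows_cleaned

    @property
    def all_ok(self) -> bool:
        return (self.recoverable_recovered == self.recoverable_total
                and self.clean_recovered == self.clean_total
                and self.unrecoverable_one_warning == self.unrecoverable_total
                and self.blank_missing == self.blank_total
                and self.freetext_retained == self.freetext_total
                and self.bijection_ok and self.conservation_ok)


def _values_match(entry: ManifestEntry, record: CanonicalRecord) -> bool:
    col = entry.column
    truth = entry.true_value
    if col == "blood_pressure":
        s = record.values.get("blood_pressure_systolic")
        d = record.values.get("blood_pressure_diastolic")
        if s is None or d is None or s.value is None or d.value is None:
            return False
        return (abs(float(s.value) - truth[0]) < _TOL
                and abs(float(d.value) - truth[1]) < _TOL)
    cv = record.values.get(col)
    if cv is None or cv.value is None:
        return False
    value = cv.value
    if isinstance(value, date):
        return value.isoformat() == truth
    if isinstance(value, float):
        try:
            return abs(value - float(truth)) < _TOL
        except (TypeError, ValueError):
            return False
    return str(value) == str(truth)


def _cell_values(entry: ManifestEntry, record: CanonicalRecord):
    if entry.column == "blood_pressure":
        return [record.values.get("blood_pressure_systolic"),
                record.values.get("blood_pressure_diastolic")]
    return [record.values.get(entry.column)]


def verify_against_manifest(records: Iterable[CanonicalRecord],
                            events: Iterable[ValidationEvent],
                            manifest: GroundTruthManifest,
                            config: Config) -> VerificationSummary:
    """Measure recovery, accounting, bijection and conservation."""
    s = VerificationSummary()
    recs = {r.provenance: r for r in records}
    warn_at: dict[tuple, list[ValidationEvent]] = {}
    for ev in events:
        if ev.severity == "warning":
            key = (ev.workbook, ev.sheet, ev.row, ev.column)
            warn_at.setdefault(key, []).append(ev)

    s.rows_expected = len(manifest.data_rows())
    s.rows_cleaned = len(recs)
    if s.rows_expected != s.rows_cleaned:
        s.failures.append(f"row conservation: {s.rows_expected} generated vs "
                          f"{s.rows_cleaned} cleaned")

    for entry in manifest.entries:
        rec = recs.get((entry.workbook, entry.sheet, entry.row))
        if rec is None:
            s.failures.append(f"missing record for {entry.key}")
            continue
        key = (entry.workbook, entry.sheet, entry.row, entry.column)
        warns = warn_at.get(key, [])
        cls = entry.corruption_class

        if entry.column == "patient_id":
            # the name cell: pseudonymization target, scored separately
            cv = rec.values.get("patient_id")
            if cls == "none":
                s.clean_total += 1
                if cv is not None and cv.value == entry.true_value:
                    s.clean_recovered += 1
                else:
                    s.failures.append(f"identifier mismatch at {entry.key}")
            else:  # injected misspelling: redacted upstream, flagged here
                s.unrecoverable_total += 1
                if (cv is not None and cv.value == "[UNRESOLVED]"
                        and len(warns) == 1
                        and warns[0].code == "W_ID_PATTERN"):
                    s.unrecoverable_one_warning += 1
                else:
                    s.failures.append(f"unresolved-name handling at {entry.key}")
            continue

        if cls == "blank":
            s.blank_total += 1
            missing = all(cv is None or cv.value is None
                          for cv in _cell_values(entry, rec))
            if missing and not warns:
                s.blank_missing += 1
            else:
                s.failures.append(f"blank not missing at {entry.key}")
        elif cls in RETAINED_CLASSES:
            s.freetext_total += 1
            cv = rec.values.get(entry.column)
            retained = (cv is not None and cv.value == entry.rendered_value
                        and not cv.is_sentinel)
            if retained and len(warns) == 1 and warns[0].code == "W_CATEGORY":
                s.freetext_retained += 1
            else:
                s.failures.append(f"freetext handling at {entry.key}")
        elif cls in RECOVERABLE_CLASSES:
            s.recoverable_total += 1
            if _values_match(entry, rec) and not warns:
                s.recoverable_recovered += 1
            else:
                s.failures.append(f"recovery failed at {entry.key} "
                                  f"({cls}: {entry.rendered_value!r})")
        elif cls == "none":
            s.clean_total += 1
            if _values_match(entry, rec):
                s.clean_recovered += 1
            else:
                s.failures.append(f"clean cell mismatch at {entry.key} "
                                  f"({entry.rendered_value!r})")
        else:  # typo_unrecoverable / out_of_range on a data column
            s.unrecoverable_total += 1
            cells = _cell_values(entry, rec)
            sentinel = any(cv is not None and cv.is_sentinel for cv in cells)
            if sentinel and len(warns) == 1:
                s.unrecoverable_one_warning += 1
            else:
                s.failures.append(
                    f"unrecoverable handling at {entry.key} ({cls}: "
                    f"{entry.rendered_value!r}, {len(warns)} warnings)")

    # sentinel <-> substituting-warning bijection, per source cell
    sentinel_keys: set[tuple] = set()
    for rec in recs.values():
        for cname, cv in rec.values.items():
            if cv.is_sentinel:
                col = cname
                if cname.startswith("blood_pressure_"):
                    col = "blood_pressure"
                sentinel_keys.add((rec.workbook, rec.sheet, rec.row, col))
    warning_keys = {k for k, evs in warn_at.items()
                    if any(e.substituted is not None for e in evs)}
    s.sentinel_cells = len(sentinel_keys)
    s.substituting_warnings = len(warning_keys)
    s.bijection_mismatches = len(sentinel_keys ^ warning_keys)
    if s.bijection_mismatches:
        s.failures.append(
            f"sentinel/warning bijection broken at "
            f"{sorted(sentinel_keys ^ warning_keys)[:5]}")
    return s
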