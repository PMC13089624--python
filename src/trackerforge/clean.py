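"""Cleaning stage: type conversion, sentinel substitution, clinical rules.

Every raw cell is converted to its canonical type. Conversion failures never
drop a record; instead the conspicuous sentinel (999999 for numbers,
9999-12-31 for dates) is substituted and a coded warning event is emitted, so
downstream analysts can trace exactly where quality problems originate.

Domain-specific rules:

* **Dates** are attempted in a fixed cascade: spreadsheet serial number,
  ISO ``YYYY-MM-DD``, ``15-Mar-2022`` (day-monthname-year), ``Mar 2022``
  (month precision, completed to day 1 and flagged), numeric day-first
  ``d/m/y``, and finally the first date-like substring embedded in a longer
  string.
* **HbA1c** values may carry a leading inequality (``<7.0``); the symbol is
  stripped, a threshold-exceeded flag retained, and the numeral range-checked
  against the configured 0-25% band.
* **Blood pressure** arrives combined (``120/80 mmHg``) and is split into
  systolic and diastolic components with independent plausibility bands.
* **Height** recorded above 50 is taken as centimeters and converted to
  meters, flagged as a unit conversion.

Range validation uses closed intervals; out-of-range values are replaced by
the numeric sentinel. Categorical values are checked case-insensitively
against the configured allowed values; failures retain the raw text and emit
a warning (free text is analytically valuable). Blank cells are missing
values, not errors: no sentinel, no event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Optional

from .config import (CanonicalVariable, Config, SentinelPolicy,
                     ValidationRuleSet, normalize_header)
from .events import ValidationEvent

__all__ = [
    "CleanValue", "CanonicalRecord", "MISSING",
    "convert_numeric", "parse_date", "clean_hba1c", "split_blood_pressure",
    "normalize_height", "check_range", "check_category", "clean_record",
    "EXCEL_EPOCH", "SERIAL_WINDOW",
]

#: Day 0 of the spreadsheet serial-date system (the 1900 system as
#: implemented, i.e. including its phantom leap day).
EXCEL_EPOCH = date(1899, 12, 30)
#: Serial numbers are only believed inside this window (~1954-2064), so that
#: small integers such as heights or ages are never misread as dates.
SERIAL_WINDOW = (20000, 60000)

#: Marker object distinguishing "cell was blank" from any real payload.
MISSING = None


@dataclass
class CleanValue:
    """One cleaned cell: typed payload, sentinel status, transformation flags."""

    variable: str
    value: object  # float | datetime.date | str | None
    is_sentinel: bool = False
    flags: frozenset[str] = frozenset()

    def with_flag(self, flag: str) -> "CleanValue":
        return replace(self, flags=self.flags | {flag})

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass
class CanonicalRecord:
    """One cleaned patient-month or product row keyed to the canonical schema."""

    entity: str
    workbook: str
    sheet: str
    row: int
    clinic: str
    period: str
    values: dict[str, CleanValue] = field(default_factory=dict)

    @property
    def provenance(self) -> tuple[str, str, int]:
        return (self.workbook, self.sheet, self.row)


def _is_blank(raw: object) -> bool:
    return raw is None or (isinstance(raw, str) and raw.strip() == "")


def _missing(variable: str) -> CleanValue:
    return CleanValue(variable=variable, value=MISSING)


# ---------------------------------------------------------------------------
# numeric conversion

_THOUSANDS = re.compile(r"(?<=\d),(?=\d{3}\b)")


def convert_numeric(raw: object, variable: CanonicalVariable,
                    policy: SentinelPolicy,
                    ) -> tuple[CleanValue, Optional[ValidationEvent]]:
    """Parse a decimal number; failures become the numeric sentinel + W_TYPE_NUM.

    Blank input is a missing value (no sentinel, no event). Thousands
    separators are stripped before parsing.
    """
    if _is_blank(raw):
        return _missing(variable.name), None
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return CleanValue(variable.name, float(raw)), None
    text = _THOUSANDS.sub("", str(raw).strip())
    try:
        value = float(text)
    except ValueError:
        ev = ValidationEvent(code="W_TYPE_NUM", column=variable.name,
                             raw=str(raw),
                             substituted=_fmt_num(policy.numeric_sentinel))
        return CleanValue(variable.name, policy.numeric_sentinel,
                          is_sentinel=True), ev
    return CleanValue(variable.name, value), None


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


# ---------------------------------------------------------------------------
# the date cascade

_MONTHS = {m.casefold(): i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}
_MONTHS.update({m.casefold(): i + 1 for i, m in enumerate(
    ["January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"])})

_MON = r"(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|" \
       r"jul(?:y)?|aug(?:ust)?|sep(?:tember)?|oct(?:ober)?|nov(?:ember)?|" \
       r"dec(?:ember)?)"

_RE_ISO = re.compile(r"(\d{4})-(\d{2})-(\d{2})")
_RE_DMY_NAME = re.compile(rf"(\d{{1,2}})[ \-]({_MON})[ \-,]+(\d{{4}})", re.I)
_RE_MY_NAME = re.compile(rf"({_MON})[ \-,]+(\d{{4}})", re.I)
_RE_DMY_NUM = re.compile(r"(\d{1,2})[/.\-](\d{1,2})[/.\-](\d{4})")
_RE_SERIAL = re.compile(r"\d{5}")


def _month_number(name: str) -> Optional[int]:
    return _MONTHS.get(name.casefold())


def _safe_date(y: int, m: int, d: int) -> Optional[date]:
    try:
        return date(y, m, d)
    except ValueError:
        return None


def _from_serial(n: float) -> Optional[date]:
    if SERIAL_WINDOW[0] <= n <= SERIAL_WINDOW[1]:
        return EXCEL_EPOCH + timedelta(days=int(n))
    return None


def _try_formats(text: str, anchored: bool
                 ) -> Optional[tuple[date, bool]]:
    """Try the string formats of the cascade in fixed order.

    Returns (date, month_precision) or None. ``anchored`` requires the whole
    string to be the date; unanchored finds the first embedded match.
    """
    def match(rx: re.Pattern) -> Optional[re.Match]:
        return rx.fullmatch(text) if anchored else rx.search(text)

    m = match(_RE_ISO)
    if m:
        d = _safe_date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        if d:
            return d, False
    m = match(_RE_DMY_NAME)
    if m:
        mon = _month_number(m.group(2))
        if mon:
            d = _safe_date(int(m.group(3)), mon, int(m.group(1)))
            if d:
                return d, False
    m = match(_RE_MY_NAME)
    if m:
        mon = _month_number(m.group(1))
        if mon:
            d = _safe_date(int(m.group(2)), mon, 1)
            if d:
                return d, True
    m = match(_RE_DMY_NUM)
    if m:
        # day-first convention
        d = _safe_date(int(m.group(3)), int(m.group(2)), int(m.group(1)))
        if d:
            return d, False
    if not anchored:
        m = _RE_SERIAL.search(text)
        if m:
            d = _from_serial(int(m.group(0)))
            if d:
                return d, False
    return None


def parse_date(raw: object, policy: SentinelPolicy,
               ) -> tuple[CleanValue, Optional[ValidationEvent]]:
    """Parse one date cell through the format cascade.

    Order: spreadsheet serial number (numeric payloads inside the plausible
    window), ISO, day-monthname-year, monthname-year (completed to day 1 and
    flagged month-precision), numeric day-first d/m/y, then the first
    embedded date substring. All failures yield the date sentinel plus a
    W_TYPE_DATE warning.
    """
    name = "date"
    if _is_blank(raw):
        return _missing(name), None
    if isinstance(raw, datetime):
        raw = raw.date()
    if isinstance(raw, date):
        return CleanValue(name, raw), None
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        d = _from_serial(float(raw))
        if d is not None:
            return CleanValue(name, d), None
        return _date_failure(raw, policy)
    text = str(raw).strip()
    # a bare numeric string may be a serial too
    try:
        d = _from_serial(float(text))
        if d is not None:
            return CleanValue(name, d), None
    except ValueError:
        pass
    hit = _try_formats(text, anchored=True)
    if hit is None:
        hit = _try_formats(text, anchored=False)  # embedded date
    if hit is None:
        return _date_failure(raw, policy)
    d, month_precision = hit
    cv = CleanValue(name, d)
    if month_precision:
        cv = cv.with_flag("month_precision")
        ev = ValidationEvent(code="I_DATE_MONTH_PRECISION", column=name,
                             raw=str(raw), substituted=None)
        return cv, ev
    return cv, None


def _date_failure(raw: object, policy: SentinelPolicy
                  ) -> tuple[CleanValue, ValidationEvent]:
    ev = ValidationEvent(code="W_TYPE_DATE", column="date", raw=str(raw),
                         substituted=policy.date_sentinel.isoformat())
    return CleanValue("date", policy.date_sentinel, is_sentinel=True), ev


# ---------------------------------------------------------------------------
# clinical field cleaners

_RE_INEQ = re.compile(r"^\s*([<>])\s*")


def clean_hba1c(raw: object, rules: ValidationRuleSet, policy: SentinelPolicy,
                ) -> tuple[CleanValue, list[ValidationEvent]]:
    """Strip a leading inequality symbol, keep a threshold-exceeded flag,
    parse the numeral and range-check against the HbA1c band."""
    name = "hba1c"
    if _is_blank(raw):
        return _missing(name), []
    events: list[ValidationEvent] = []
    flagged = False
    text = str(raw).strip() if isinstance(raw, str) else raw
    if isinstance(text, str):
        m = _RE_INEQ.match(text)
        if m:
            flagged = True
            text = text[m.end():]
            events.append(ValidationEvent(code="I_HBA1C_THRESHOLD", column=name,
                                          raw=str(raw), substituted=None))
    numvar = CanonicalVariable(name=name, entity="patient", dtype="number",
                               bounds=rules.hba1c_bounds)
    cv, ev = convert_numeric(text, numvar, policy)
    if ev is not None:
        events.append(ev)
        return CleanValue(name, cv.value, is_sentinel=True,
                          flags=frozenset({"threshold_exceeded"}) if flagged
                          else frozenset()), events
    cv, ev = check_range(cv.value, numvar, policy)
    if ev is not None:
        events.append(ev)
    if flagged:
        cv = cv.with_flag("threshold_exceeded")
    return cv, events


_RE_BP = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*[a-zA-Z ]*$")


def split_blood_pressure(raw: object, rules: ValidationRuleSet,
                         policy: SentinelPolicy,
                         ) -> tuple[CleanValue, CleanValue,
                                    list[ValidationEvent]]:
    """Split a combined ``systolic/diastolic`` string into two components.

    Tolerates surrounding whitespace and a trailing unit (``mmHg``). Any
    other shape is malformed: both components become the numeric sentinel and
    one W_BP_MALFORMED warning is emitted for the source cell.
    """
    sname, dname = "blood_pressure_systolic", "blood_pressure_diastolic"
    if _is_blank(raw):
        return _missing(sname), _missing(dname), []
    m = _RE_BP.match(str(raw))
    if not m:
        ev = ValidationEvent(code="W_BP_MALFORMED", column="blood_pressure",
                             raw=str(raw),
                             substituted=_fmt_num(policy.numeric_sentinel))
        s = CleanValue(sname, policy.numeric_sentinel, is_sentinel=True)
        d = CleanValue(dname, policy.numeric_sentinel, is_sentinel=True)
        return s, d, [ev]
    events: list[ValidationEvent] = []
    sys_var = CanonicalVariable(name=sname, entity="patient", dtype="number",
                                bounds=rules.bp_systolic_bounds)
    dia_var = CanonicalVariable(name=dname, entity="patient", dtype="number",
                                bounds=rules.bp_diastolic_bounds)
    s, ev = check_range(float(m.group(1)), sys_var, policy)
    if ev is not None:
        events.append(ev)
    d, ev = check_range(float(m.group(2)), dia_var, policy)
    if ev is not None:
        events.append(ev)
    return s, d, events


def normalize_height(raw: object, rules: ValidationRuleSet,
                     policy: SentinelPolicy,
                     variable: Optional[CanonicalVariable] = None,
                     ) -> tuple[CleanValue, list[ValidationEvent]]:
    """Convert centimeter-recorded heights to meters, then range-check.

    A value above the configured threshold (default 50) is taken as
    centimeters, divided by 100 and flagged as a unit conversion; the result
    must fall inside the plausible meter band or it is replaced by the
    numeric sentinel.
    """
    name = variable.name if variable is not None else "height"
    bounds = (variable.bounds if variable is not None and variable.bounds
              else None)
    if _is_blank(raw):
        return _missing(name), []
    numvar = CanonicalVariable(name=name, entity="patient", dtype="number",
                               bounds=bounds or rules.hba1c_bounds)
    cv, ev = convert_numeric(raw, numvar, policy)
    if ev is not None:
        return cv, [ev]
    events: list[ValidationEvent] = []
    value = float(cv.value)
    converted = False
    if value > rules.height_cm_threshold:
        value = value / 100.0
        converted = True
        events.append(ValidationEvent(code="I_HEIGHT_CONVERTED", column=name,
                                      raw=str(raw), substituted=_fmt_num(value)))
    if bounds is not None:
        cv, ev = check_range(value, CanonicalVariable(
            name=name, entity="patient", dtype="number", bounds=bounds), policy)
        if ev is not None:
            events.append(ev)
    else:
        cv = CleanValue(name, value)
    if converted and not cv.is_sentinel:
        cv = cv.with_flag("unit_converted")
    elif converted:
        cv = replace(cv, flags=cv.flags | {"unit_converted"})
    return cv, events


def check_range(value: float, variable: CanonicalVariable,
                policy: SentinelPolicy,
                ) -> tuple[CleanValue, Optional[ValidationEvent]]:
    """Enforce the variable's closed plausibility bounds.

    Outliers are replaced by the numeric sentinel with a W_RANGE warning
    carrying the raw value.
    """
    if variable.bounds is None:
        return CleanValue(variable.name, float(value)), None
    if variable.bounds.contains(value):
        return CleanValue(variable.name, float(value)), None
    ev = ValidationEvent(code="W_RANGE", column=variable.name,
                         raw=_fmt_num(value),
                         substituted=_fmt_num(policy.numeric_sentinel))
    return CleanValue(variable.name, policy.numeric_sentinel,
                      is_sentinel=True), ev


def check_category(raw: object, variable: CanonicalVariable,
                   ) -> tuple[CleanValue, Optional[ValidationEvent]]:
    """Case-insensitive allowed-value check; matches take canonical casing.

    Non-matching values are retained as raw text (no sentinel) with a
    W_CATEGORY warning — free text may carry site-specific observations.
    """
    if _is_blank(raw):
        return _missing(variable.name), None
    text = str(raw).strip()
    norm = normalize_header(text)
    for allowed in (variable.allowed_values or ()):
        if normalize_header(allowed) == norm:
            return CleanValue(variable.name, allowed), None
    ev = ValidationEvent(code="W_CATEGORY", column=variable.name,
                         raw=text, substituted=None)
    return CleanValue(variable.name, text), ev


# ---------------------------------------------------------------------------
# record-level orchestration

def _validate_id(candidate: str):
    from .anonymize import validate_identifier
    return validate_identifier(candidate)


def clean_record(record, config: Config,
                 ) -> tuple[CanonicalRecord, list[ValidationEvent]]:
    """Dispatch every mapped field of a raw record to its dtype cleaner.

    The record is never dropped; every event is stamped with the record's
    provenance (workbook, sheet, 0-based row, canonical column) plus clinic
    and reporting period.
    """
    policy, rules = config.sentinels, config.rules
    out = CanonicalRecord(entity=record.entity, workbook=record.workbook,
                          sheet=record.sheet, row=record.row,
                          clinic=record.clinic, period=record.period)
    events: list[ValidationEvent] = []

    def stamp(evs, column=None):
        for ev in evs:
            events.append(replace(
                ev, workbook=record.workbook, sheet=record.sheet,
                row=record.row, clinic=record.clinic, period=record.period,
                column=column or ev.column))

    for name, raw in record.values.items():
        try:
            var = config.variable(name, record.entity)
        except KeyError:
            var = config.variable(name)
        if var.dtype == "number":
            cv, ev = convert_numeric(raw, var, policy)
            if ev is None and not cv.is_missing:
                cv, ev = check_range(cv.value, var, policy)
            out.values[name] = cv
            stamp([ev] if ev else [], column=name)
        elif var.dtype == "date":
            cv, ev = parse_date(raw, policy)
            out.values[name] = replace(cv, variable=name)
            stamp([ev] if ev else [], column=name)
        elif var.dtype == "hba1c":
            cv, evs = clean_hba1c(raw, rules, policy)
            out.values[name] = replace(cv, variable=name)
            stamp(evs, column=name)
        elif var.dtype == "blood_pressure":
            s, d, evs = split_blood_pressure(raw, rules, policy)
            out.values[s.variable] = s
            out.values[d.variable] = d
            stamp(evs, column=name)
        elif var.dtype == "height":
            cv, evs = normalize_height(raw, rules, policy, variable=var)
            out.values[name] = replace(cv, variable=name)
            stamp(evs, column=name)
        elif var.dtype == "category":
            cv, ev = check_category(raw, var)
            out.values[name] = cv
            stamp([ev] if ev else [], column=name)
        else:  # text
            if _is_blank(raw):
                out.values[name] = _missing(name)
            else:
                out.values[name] = CleanValue(name, str(raw).strip())
            if name == "patient_id" and not _is_blank(raw):
                ok, ev = _validate_id(str(raw).strip())
                if not ok and ev is not None:
                    stamp([ev], column=name)
    return out, events
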