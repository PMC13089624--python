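"""Seeded generator of realistically messy multi-hospital tracker workbooks.

The generator emulates the structural heterogeneity of a multi-country
program exchanging monthly spreadsheet trackers: per-clinic header variants
drawn from the synonym map, mixed date representations (spreadsheet serials,
``15-Mar-2022``, ``Mar 2022``, dates buried in free text), inequality-prefixed
HbA1c values, combined blood-pressure strings, heights recorded in
centimeters or meters, free-text categoricals, typos and blanks, and
template drift over time (insulin-type columns appear only from 2024
onward). Alongside the workbooks it emits a per-cell ground-truth manifest
recording the intended value and the injected corruption class, which the
test suite uses as the oracle for the cleaning stage.

Corruption classes fall into three groups:

* recoverable — a formatting deviation whose true value the cleaner can
  reconstruct (``date_format_variant``, ``excel_serial``, ``embedded_date``,
  ``hba1c_inequality``, ``bp_combined``, ``height_cm``);
* unrecoverable — the value is lost (``typo_unrecoverable``, ``blank``,
  ``out_of_range``);
* retained — ``category_freetext``: kept as raw text with a warning.

Injection is i.i.d. per cell given each class's rate. Identical
(config, seed) pairs reproduce byte-identical workbooks and manifests.
"""

from __future__ import annotations

import itertools
import json
import random
import string
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

from openpyxl import Workbook
from pydantic import BaseModel, ConfigDict, model_validator

from ._names import FIRST_NAMES, LAST_NAMES
from ._xlsx import save_workbook_deterministic
from .clean import EXCEL_EPOCH
from .config import Config, load_default_config, normalize_header

__all__ = [
    "GeneratorConfig", "GroundTruthManifest", "ManifestEntry",
    "generate_program", "generate_patient_list",
    "RECOVERABLE_CLASSES", "UNRECOVERABLE_CLASSES", "RETAINED_CLASSES",
    "DEFAULT_CORRUPTION_RATES",
]

RECOVERABLE_CLASSES = frozenset({
    "date_format_variant", "excel_serial", "embedded_date",
    "hba1c_inequality", "bp_combined", "height_cm",
})
UNRECOVERABLE_CLASSES = frozenset({"typo_unrecoverable", "blank", "out_of_range"})
RETAINED_CLASSES = frozenset({"category_freetext"})
ALL_CLASSES = RECOVERABLE_CLASSES | UNRECOVERABLE_CLASSES | RETAINED_CLASSES | {"none"}

DEFAULT_CORRUPTION_RATES: dict[str, float] = {
    "date_format_variant": 0.30,
    "excel_serial": 0.10,
    "embedded_date": 0.03,
    "hba1c_inequality": 0.08,
    "bp_combined": 0.20,
    "height_cm": 0.40,
    "typo_unrecoverable": 0.02,
    "blank": 0.08,
    "out_of_range": 0.01,
    "category_freetext": 0.05,
    "name_misspelling": 0.02,
}

COUNTRY_CODES = ["LA", "VN", "KH", "MM", "TH", "PH", "ID", "MY", "SG", "BN"]

#: columns every clinic template carries
CORE_PATIENT_VARS = [
    "visit_date", "date_of_birth", "age", "sex", "hba1c", "height", "weight",
    "blood_pressure", "insulin_regimen", "patient_status",
]
#: template drift: these only exist from this period onward
INSULIN_TYPE_VARS = [
    "insulin_type_basal", "insulin_type_bolus",
    "insulin_type_premixed", "insulin_type_other",
]
INSULIN_TYPES_FROM = "2024-01"

PRODUCT_VARS = [
    "product_name", "product_category", "unit", "quantity_received",
    "quantity_distributed", "stock_on_hand", "batch_number", "expiry_date",
    "unit_cost", "currency", "supplier", "clinic_code", "record_date", "notes",
]

_PRODUCT_CATALOG = [
    ("Insulin Glargine 100U/ml", "Insulin", "vial"),
    ("Insulin Aspart 100U/ml", "Insulin", "vial"),
    ("Premixed Insulin 70/30", "Insulin", "vial"),
    ("NPH Insulin", "Insulin", "vial"),
    ("Glucose Test Strips 50ct", "Test Strips", "box"),
    ("Ketone Strips 10ct", "Test Strips", "box"),
    ("Pen Needles 4mm", "Needles", "box"),
    ("Syringes 1ml", "Needles", "box"),
    ("Glucose Meter Kit", "Meter", "unit"),
    ("Lancets 100ct", "Consumable", "box"),
    ("Glucagon Kit", "Other", "kit"),
    ("Alcohol Swabs 100ct", "Consumable", "box"),
]

_SUPPLIERS = ["MedSupply Asia", "PharmaDirect", "Regional Health Co", "Unistock"]
_FREETEXT_CATEGORY = [
    "mixed insulin twice daily", "patient self adjusts", "see notes",
    "moved away?", "regular scheme", "na - follow up",
]
_TYPO_TOKENS = ["n/a", "??", "not recorded", "pending", "tbc"]
_TEXT_TOKENS = ["stable", "doing well", "counselled on diet",
                "missed last visit", "supplies issued", ""]


class GeneratorConfig(BaseModel):
    """Program-scale knobs; defaults mirror the emulated program."""

    model_config = ConfigDict(frozen=True)
    n_countries: int = 7
    n_clinics: int = 42
    n_patients: int = 1400
    year_range: tuple[int, int] = (2017, 2025)
    n_months: Optional[int] = None  # None = every month in year_range
    corruption_rates: dict[str, float] = dict(DEFAULT_CORRUPTION_RATES)
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorConfig":
        if self.n_clinics < self.n_countries:
            raise ValueError("n_clinics must be >= n_countries")
        if self.n_countries < 1 or self.n_countries > len(COUNTRY_CODES):
            raise ValueError(f"n_countries must be 1-{len(COUNTRY_CODES)}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        y0, y1 = self.year_range
        if not (1900 < y0 <= y1 < 9998):
            raise ValueError("year_range must lie within (1900, 9998)")
        for cls, p in self.corruption_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"corruption rate {cls}={p} outside [0,1]")
        return self


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one generated data cell."""

    workbook: str
    sheet: str
    row: int           # 0-based absolute sheet row
    column: str        # canonical variable name
    true_value: object
    rendered_value: str
    corruption_class: str

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.workbook, self.sheet, self.row, self.column)


@dataclass
class GroundTruthManifest:
    """Per-cell true values and injected-corruption labels."""

    entries: list[ManifestEntry] = field(default_factory=list)
    workbooks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple, ManifestEntry] = {e.key: e for e in self.entries}

    def add(self, entry: ManifestEntry) -> None:
        self.entries.append(entry)
        self._index[entry.key] = entry

    def get(self, workbook: str, sheet: str, row: int, column: str
            ) -> Optional[ManifestEntry]:
        return self._index.get((workbook, sheet, row, column))

    def count_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.corruption_class] = out.get(e.corruption_class, 0) + 1
        return dict(sorted(out.items()))

    def data_rows(self) -> set[tuple[str, str, int]]:
        """Distinct generated data rows (workbook, sheet, row)."""
        return {(e.workbook, e.sheet, e.row) for e in self.entries}

    def to_dict(self) -> dict:
        return {
            "workbooks": self.workbooks,
            "entries": [
                {"workbook": e.workbook, "sheet": e.sheet, "row": e.row,
                 "column": e.column, "true_value": e.true_value,
                 "rendered_value": e.rendered_value,
                 "corruption_class": e.corruption_class}
                for e in self.entries
            ],
        }

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=None,
                                   separators=(",", ":"), sort_keys=False),
                        encoding="ascii")
        return path

    @classmethod
    def load(cls, path: Path | str) -> "GroundTruthManifest":
        doc = json.loads(Path(path).read_text(encoding="ascii"))
        m = cls(workbooks=list(doc["workbooks"]))
        for d in doc["entries"]:
            m.add(ManifestEntry(**d))
        return m


# ---------------------------------------------------------------------------
# roster generation

def generate_patient_list(n: int, country_code: str, clinic_code: str,
                          rng: Optional[random.Random] = None,
                          ) -> list[tuple[str, str]]:
    """n rows of synthetic full names paired with sequential identifiers.

    Identifiers run ``<country><clinic>001`` upward; names are unique after
    normalization. A 3-digit sequence caps enrollment at 999 per clinic.
    """
    for code, label in ((country_code, "country"), (clinic_code, "clinic")):
        if not (len(code) == 2 and code.isalpha() and code.isupper()):
            raise ValueError(f"{label} code must be 2 uppercase letters: {code!r}")
    if n > 999:
        raise ValueError(f"cannot enroll {n} patients: 3-digit sequence "
                         f"exhausted at 999")
    rng = rng or random.Random(f"{country_code}{clinic_code}")
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i in range(1, n + 1):
        while True:
            name = f"{rng.choice(FIRST_NAMES)} {rng.choice(LAST_NAMES)}"
            if normalize_header(name) not in seen:
                break
            name = (f"{rng.choice(FIRST_NAMES)} "
                    f"{rng.choice(string.ascii_uppercase)}. "
                    f"{rng.choice(LAST_NAMES)}")
            if normalize_header(name) not in seen:
                break
        seen.add(normalize_header(name))
        rows.append((name, f"{country_code}{clinic_code}{i:03d}"))
    return rows


# ---------------------------------------------------------------------------
# cell rendering with corruption injection

def _pick_class(rng: random.Random, rates: dict[str, float],
                applicable: list[str]) -> str:
    u = rng.random()
    acc = 0.0
    for cls in applicable:
        acc += rates.get(cls, 0.0)
        if u < acc:
            return cls
    return "none"


def _misspell(rng: random.Random, name: str) -> str:
    """A misspelling that survives normalization differences."""
    letters = [i for i, c in enumerate(name) if c.isalpha()]
    i = rng.choice(letters)
    mode = rng.randrange(3)
    if mode == 0:      # drop a letter
        return name[:i] + name[i + 1:]
    if mode == 1:      # double a letter
        return name[:i] + name[i] + name[i:]
    sub = rng.choice([c for c in string.ascii_lowercase
                      if c != name[i].lower()])
    return name[:i] + sub + name[i + 1:]


_DATE_CLASSES = ["date_format_variant", "excel_serial", "embedded_date",
                 "typo_unrecoverable", "blank"]
_NUM_CLASSES = ["out_of_range", "typo_unrecoverable", "blank"]
_HBA1C_CLASSES = ["hba1c_inequality", "out_of_range", "typo_unrecoverable", "blank"]
_BP_CLASSES = ["bp_combined", "typo_unrecoverable", "blank"]
_HEIGHT_CLASSES = ["height_cm", "out_of_range", "typo_unrecoverable", "blank"]
_CAT_CLASSES = ["category_freetext", "blank"]
_TEXT_CLASSES = ["blank"]


def _render_date(rng, rates, true: date) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _DATE_CLASSES)
    if cls == "none":
        return true.isoformat(), cls, true.isoformat()
    if cls == "date_format_variant":
        style = rng.randrange(3)
        if style == 0:
            return f"{true.day}-{true.strftime('%b')}-{true.year}", cls, true.isoformat()
        if style == 1:
            return f"{true.day}/{true.month}/{true.year}", cls, true.isoformat()
        first = true.replace(day=1)  # month precision: truth is day 1
        return f"{first.strftime('%b')} {first.year}", cls, first.isoformat()
    if cls == "excel_serial":
        return (true - EXCEL_EPOCH).days, cls, true.isoformat()
    if cls == "embedded_date":
        return (f"recorded {true.day}-{true.strftime('%b')}-{true.year} by nurse",
                cls, true.isoformat())
    if cls == "typo_unrecoverable":
        return rng.choice(_TYPO_TOKENS), cls, true.isoformat()
    return "", "blank", true.isoformat()


def _render_number(rng, rates, true: float, bounds) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _NUM_CLASSES)
    if cls == "none":
        return true, cls, true
    if cls == "out_of_range":
        bad = round(bounds.max * 2 + 5, 1)
        return bad, cls, true
    if cls == "typo_unrecoverable":
        return rng.choice(_TYPO_TOKENS), cls, true
    return "", "blank", true


def _render_hba1c(rng, rates, true: float) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _HBA1C_CLASSES)
    if cls == "none":
        return true, cls, true
    if cls == "hba1c_inequality":
        return f"{rng.choice('<>')}{true}", cls, true
    if cls == "out_of_range":
        return rng.choice([27.5, 30.0, 48.0]), cls, true
    if cls == "typo_unrecoverable":
        return rng.choice(["high", "low", "n/a"]), cls, true
    return "", "blank", true


def _render_bp(rng, rates, s: int, d: int) -> tuple[object, str, object]:
    true = [float(s), float(d)]
    cls = _pick_class(rng, rates, _BP_CLASSES)
    if cls == "none":
        return f"{s}/{d}", cls, true
    if cls == "bp_combined":
        return rng.choice([f"{s} / {d} mmHg", f"{s}/ {d} mmhg", f"{s} /{d}"]), cls, true
    if cls == "typo_unrecoverable":
        return rng.choice([f"{s}-{d}", "high", f"{s}"]), cls, true
    return "", "blank", true


def _render_height(rng, rates, true_m: float) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _HEIGHT_CLASSES)
    if cls == "none":
        return true_m, cls, true_m
    if cls == "height_cm":
        return int(round(true_m * 100)), cls, true_m
    if cls == "out_of_range":
        return rng.choice([0.1, 3.2]), cls, true_m
    if cls == "typo_unrecoverable":
        return rng.choice(["tall", "n/a"]), cls, true_m
    return "", "blank", true_m


def _render_category(rng, rates, true: str) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _CAT_CLASSES)
    if cls == "none":
        style = rng.randrange(3)
        rendered = (true if style == 0 else
                    true.upper() if style == 1 else true.lower())
        return rendered, cls, true
    if cls == "category_freetext":
        return rng.choice(_FREETEXT_CATEGORY), cls, true
    return "", "blank", true


def _render_text(rng, rates, true: str) -> tuple[object, str, object]:
    cls = _pick_class(rng, rates, _TEXT_CLASSES)
    if cls == "blank" or true == "":
        return "", "blank" if cls == "blank" else "none", true
    return true, "none", true


# ---------------------------------------------------------------------------
# program generation

def _months(year_range: tuple[int, int], n_months: Optional[int]) -> list[str]:
    y0, y1 = year_range
    all_months = [f"{y}-{m:02d}" for y in range(y0, y1 + 1)
                  for m in range(1, 13)]
    if n_months is None or n_months >= len(all_months):
        return all_months
    if n_months <= 0:
        raise ValueError("n_months must be positive")
    if n_months == 1:
        return [all_months[-1]]
    # evenly spaced subsample spanning the whole range
    idx = sorted({round(i * (len(all_months) - 1) / (n_months - 1))
                  for i in range(n_months)})
    return [all_months[i] for i in idx]


def _truth_for(rng: random.Random, var, period: str, clinic4: str,
               config: Config):
    """Draw a plausible true value for one variable in one reporting month."""
    year, month = int(period[:4]), int(period[5:7])
    if var.dtype == "date":
        if var.name in ("visit_date", "record_date", "hba1c_date", "status_date"):
            return date(year, month, rng.randint(1, 28))
        if var.name == "date_of_birth":
            return date(rng.randint(max(1999, year - 24), year - 1),
                        rng.randint(1, 12), rng.randint(1, 28))
        if var.name == "expiry_date":
            return date(year + rng.randint(1, 3), rng.randint(1, 12),
                        rng.randint(1, 28))
        if var.name == "next_visit_date":
            return date(year, month, rng.randint(1, 28)) + timedelta(days=30)
        return date(rng.randint(max(2015, year - 8), year),
                    rng.randint(1, 12), rng.randint(1, 28))
    if var.dtype == "hba1c":
        return round(rng.uniform(5.0, 14.0), 1)
    if var.dtype == "height":
        return round(rng.uniform(0.9, 1.9), 2)
    if var.dtype == "blood_pressure":
        return (rng.randint(90, 140), rng.randint(55, 95))
    if var.dtype == "number":
        lo, hi = var.bounds.min, var.bounds.max
        if var.name == "age":
            return float(rng.randint(1, 25))
        if var.name == "age_at_diagnosis":
            return float(rng.randint(1, 20))
        span = hi - lo
        return round(lo + rng.random() * min(span, span * 0.6 + 1), 1)
    if var.dtype == "category":
        return rng.choice(list(var.allowed_values))
    # text
    if var.name == "clinic_code":
        return clinic4
    return rng.choice([t for t in _TEXT_TOKENS if t])


def _render_cell(rng, rates, var, true):
    if var.dtype == "date":
        return _render_date(rng, rates, true)
    if var.dtype == "hba1c":
        return _render_hba1c(rng, rates, true)
    if var.dtype == "height":
        return _render_height(rng, rates, true)
    if var.dtype == "blood_pressure":
        return _render_bp(rng, rates, *true)
    if var.dtype == "number":
        return _render_number(rng, rates, true, var.bounds)
    if var.dtype == "category":
        return _render_category(rng, rates, true)
    return _render_text(rng, rates, true)


def _truth_json(var, true) -> object:
    if var.dtype == "date":
        return true.isoformat() if isinstance(true, date) else true
    if var.dtype == "blood_pressure":
        return [float(true[0]), float(true[1])]
    return true


_NAME_HEADERS = ["Patient Name", "Name", "Full Name"]


def _header_variant(rng: random.Random, config: Config, canonical: str) -> str:
    variants = config.synonyms.variants_of(canonical)
    raw = rng.choice(variants)
    style = rng.randrange(3)
    if style == 0:
        return raw
    if style == 1:
        return raw.upper()
    return " ".join(w.capitalize() for w in raw.split(" "))


def generate_program(config: GeneratorConfig, out_dir: Path | str,
                     schema: Optional[Config] = None,
                     ) -> tuple[list[Path], GroundTruthManifest]:
    """Generate one workbook per clinic plus the ground-truth manifest.

    Each workbook holds a "Patient List" roster sheet, one patient worksheet
    per reporting month (named ``YYYY-MM``) and one product worksheet per
    month (``Products YYYY-MM``). Column headers vary by clinic; sheets dated
    before 2024-01 omit the insulin-type columns. The manifest (saved as
    ``manifest.json``) records every generated data cell's true value,
    rendered value and corruption class.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = schema or load_default_config()
    rates = config.corruption_rates
    master = random.Random(config.seed)

    countries = COUNTRY_CODES[:config.n_countries]
    clinic_codes = ["".join(p) for p in itertools.islice(
        itertools.product(string.ascii_uppercase, repeat=2), config.n_clinics)]
    # round-robin country assignment guarantees every country gets a clinic
    clinics = [(countries[i % len(countries)], clinic_codes[i])
               for i in range(config.n_clinics)]

    base, extra = divmod(config.n_patients, config.n_clinics)
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_clinics)]
    if any(s > 999 for s in sizes):
        raise ValueError("more than 999 patients assigned to one clinic")
    if all(s == 0 for s in sizes):
        raise ValueError("zero patients")

    months = _months(config.year_range, config.n_months)
    patient_vars = {v.name: v for v in schema.entity_variables("patient")}
    product_vars = {v.name: v for v in schema.entity_variables("product")}
    optional_pool = sorted(set(patient_vars)
                           - set(CORE_PATIENT_VARS) - set(INSULIN_TYPE_VARS)
                           - {"patient_id", "clinic_code"})

    manifest = GroundTruthManifest()
    paths: list[Path] = []

    for (country, clinic), size in zip(clinics, sizes):
        clinic4 = f"{country}{clinic}"
        rng = random.Random(f"{config.seed}|{clinic4}")
        roster = generate_patient_list(size, country, clinic, rng=rng)

        extras = rng.sample(optional_pool, k=rng.randint(4, 8))
        clinic_vars = CORE_PATIENT_VARS + sorted(extras)
        headers = {name: _header_variant(rng, schema, name)
                   for name in clinic_vars + INSULIN_TYPE_VARS}
        name_header = rng.choice(_NAME_HEADERS)
        title_row = rng.random() < 0.5
        end_marker = rng.random() < 0.5

        wb = Workbook()
        ws = wb.active
        ws.title = "Patient List"
        ws.append([name_header, "Patient ID"])
        for name, ident in roster:
            ws.append([name, ident])

        wbname = f"{clinic4}.xlsx"

        for period in months:
            cols = list(clinic_vars)
            if period >= INSULIN_TYPES_FROM:
                cols += INSULIN_TYPE_VARS
            ws = wb.create_sheet(title=period)
            row_idx = 0
            if title_row:
                ws.append([f"{clinic4} monthly tracker {period}"])
                row_idx += 1
            ws.append([name_header] + [headers[c] for c in cols])
            row_idx += 1
            attendees = [p for p in roster if rng.random() < 0.8]
            for pname, ident in attendees:
                cells: list[object] = []
                # name cell: the pseudonymization target
                roster_norms = {normalize_header(n) for n, _ in roster}
                if rng.random() < rates.get("name_misspelling", 0.0):
                    mis = _misspell(rng, pname)
                    if normalize_header(mis) in roster_norms:
                        mis = pname + "x"
                    cells.append(mis)
                    manifest.add(ManifestEntry(wbname, period, row_idx,
                                               "patient_id", ident,
                                               str(cells[-1]),
                                               "typo_unrecoverable"))
                else:
                    cells.append(pname)
                    manifest.add(ManifestEntry(wbname, period, row_idx,
                                               "patient_id", ident, pname,
                                               "none"))
                for cname in cols:
                    var = patient_vars[cname]
                    true = _truth_for(rng, var, period, clinic4, schema)
                    rendered, cls, true_out = _render_cell(rng, rates, var, true)
                    cells.append(rendered)
                    manifest.add(ManifestEntry(
                        wbname, period, row_idx, cname,
                        _truth_json(var, true_out), str(rendered), cls))
                ws.append([c if c != "" else None for c in cells])
                row_idx += 1
            if end_marker:
                ws.append(["END"])

            # product sheet for the same month
            ws = wb.create_sheet(title=f"Products {period}")
            prow = 0
            ws.append([_header_variant(rng, schema, c) for c in PRODUCT_VARS])
            prow += 1
            n_products = rng.randint(4, 8)
            items = rng.sample(_PRODUCT_CATALOG, k=n_products)
            for pname_, pcat, punit in items:
                cells = []
                for cname in PRODUCT_VARS:
                    var = product_vars[cname]
                    if cname == "product_name":
                        true = pname_
                    elif cname == "product_category":
                        true = pcat
                    elif cname == "unit":
                        true = punit
                    elif cname == "batch_number":
                        true = f"B{rng.randint(10000, 99999)}"
                    elif cname == "record_date":
                        true = date(int(period[:4]), int(period[5:7]), 1)
                    else:
                        true = _truth_for(rng, var, period, clinic4, schema)
                    rendered, cls, true_out = _render_cell(rng, rates, var, true)
                    cells.append(rendered)
                    manifest.add(ManifestEntry(
                        wbname, f"Products {period}", prow, cname,
                        _truth_json(var, true_out), str(rendered), cls))
                ws.append([c if c != "" else None for c in cells])
                prow += 1

        path = out_dir / wbname
        save_workbook_deterministic(wb, path)
        paths.append(path)
        manifest.workbooks.append(wbname)

    manifest.save(out_dir / "manifest.json")
    return paths, manifest
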