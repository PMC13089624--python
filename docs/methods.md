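# Methods

This note documents the models, rules and design decisions behind
trackerforge: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical and
tie-breaking choices that make the pipeline deterministic and auditable.

## Problem setting

A multi-country clinical support program receives one spreadsheet workbook
per hospital per month. Each workbook holds a "Patient List" roster (names
paired with program identifiers) and data worksheets whose column names,
layout and available variables differ by site and by era of the template.
The toolkit turns these into two harmonized columnar tables (patient-month
rows and product rows) while (a) pseudonymizing before any other
processing, (b) never silently dropping or altering data — every
substitution or mapping failure is logged as a coded, cell-addressed event
— and (c) keeping every stage a pure function of its inputs, so reruns are
byte-identical and results are reproducible from seeds.

## Canonical schema and synonym mapping

Harmonization is driven entirely by a YAML configuration with four parts:
the canonical variables (name, entity, dtype, bounds/allowed values), the
synonym map (normalized raw header → canonical name), the sentinel policy
and the validation thresholds. Header matching is deliberately *exact after
normalization* (case-fold, non-breaking-space conversion, whitespace
collapse): fuzzy matching could silently mis-map a column, which is worse
than an honest `W_UNMAPPED_COLUMN` warning. The shipped configuration
declares 69 patient and 14 product variables with 202 header synonyms; it
is a representative schema for this class of program (the real programs'
variable lists are site-internal), and users supply their own YAML for a
concrete deployment. Configuration is validated exhaustively at load time,
including the structural invariants: bounds exactly for numeric-like
dtypes, non-empty allowed values exactly for categoricals, every synonym
targeting a declared variable, and the numeric sentinel falling outside
every declared bounds interval.

## Pseudonymization

Identifiers have the fixed shape country(2 letters) + clinic(2 letters) +
zero-padded 3-digit sequence, rendered without separators (`LAVT001`); the
fixed 7-character width makes the validation pattern exact, and sequence
000 is reserved. Name→identifier replacement is whole-cell and exact after
normalization — substring rewriting inside free text risks corrupting
clinical notes, and fuzzy matching risks substituting the wrong patient.
Cells in name-designated columns (headers "name" / "patient name" /
"full name") that match no roster entry are redacted to `[UNRESOLVED]`
rather than left in place: the design fails closed on privacy and routes
the case to manual review via `W_NAME_UNMATCHED`. These events deliberately
do not echo the unmatched name text (it is potentially identifying); the
sheet/row provenance locates the cell for follow-up. Structural `END`
marker cells are exempt from redaction. The output directory must differ
from the input directory; originals are never touched.

## Extraction

The header row is the first row with at least 3 cells normalizing to known
synonyms — tolerant of decorative title rows and partial template drift,
while rejecting prose. The data span is half-open, 0-based, from the row
after the header to the first fully empty row, the first `END` marker, or
the sheet end. Reporting periods parse from `YYYY-MM` in the sheet name;
unparseable names yield period "unknown", counted in the run summary.
Unmatched columns are retained on the raw record and logged once per
(sheet, header) — silent exclusion of unrecognized fields is exactly the
failure mode this design avoids. A sheet's entity (patient vs product) is
the one with more entity-exclusive mapped variables, ties going to patient.

## Cleaning

Failures never drop records. Unconvertible numbers become the sentinel
999999, unconvertible dates 9999-12-31 — values conspicuous enough that no
downstream aggregate can absorb them unnoticed — and every substitution
emits one warning event with (workbook, sheet, row, column) provenance.
Blank cells are missing values, not errors: no sentinel, no event. This
distinction (missingness vs corruption) keeps completeness statistics and
error statistics separate.

The date cascade tries, in fixed order: spreadsheet serial number (epoch
1899-12-30, accepted only inside the window 20000–60000 ≈ years 1954–2064,
so heights and ages can never be misread as dates); ISO `YYYY-MM-DD`;
day–monthname–year (`15-Mar-2022`); monthname–year (`Mar 2022`), completed
to day 1 with an explicit month-precision flag and an info event, since the
true day is unknown but the month is still analytically useful; all-numeric
`d/m/y`, read day-first per the program countries' convention; and finally
the first embedded substring matching any of the above inside a longer
string. Only when all steps fail does the date sentinel apply.

Clinical rules: a leading `<` or `>` on HbA1c is stripped and preserved as
a threshold-exceeded flag (the numeral is then range-checked against
0–25 %; stripping precedes the range check). Combined blood pressure must
match `number / number` with optional spacing and a trailing unit;
components are checked against systolic 50–250 / diastolic 30–150 mmHg, and
any other shape sentinels both components under one `W_BP_MALFORMED` event
for the source cell. Heights above 50 are interpreted as centimeters and
divided by 100 with a unit-conversion flag; the result must fall in
0.3–2.5 m (pediatric-to-adult band). All bounds are closed intervals: "age
0–100" includes both endpoints. Categorical values match allowed values
case-insensitively and take canonical casing; failures retain the raw text
(free-text entries often carry site-specific clinical information) with a
`W_CATEGORY` warning instead of a sentinel.

## Loading and staging

Tables are projected onto the canonical column order; the combined
blood-pressure field expands to systolic/diastolic columns; flags
materialize as boolean columns (`hba1c_threshold_exceeded`,
`height_unit_converted`, `<date>_month_precision`). Patient rows sort by
(identifier, visit date), product rows by (clinic, record date, product
name), with ties broken by (workbook, sheet, row) so the order is a total,
deterministic function of content; duplicate (patient, date) rows are both
kept. Three `source_*` provenance columns accompany every row. Parquet is
written with explicit logical types — date32 for dates, which represents
the 9999-12-31 sentinel exactly (nanosecond timestamps could not) — and
with pinned metadata, so identical tables produce identical files. The
staging directory is the pipeline's only output interface; a cloud uploader
could be layered on top without touching the stages.

## Audit

Events aggregate into a count matrix over (clinic, period, code);
malformed log lines count under a PARSE_ERROR bucket rather than being
dropped. Completeness per variable is (# rows with a usable value)/(# rows
of the entity table), where usable excludes both missing values and
sentinels. The denominator is deliberately *all* rows of the entity, not
just rows where the column was mapped: a variable that is structurally
absent in early template eras (insulin-type fields before 2024) thereby
surfaces as incompleteness, making temporal template drift visible in the
report instead of hiding it.

## Synthetic generator

The generator stands in for the private program data. Its defaults mirror
the emulated program's published scale — 7 countries, 42 clinics, 1400
patients, reporting years 2017–2025 — while tests and the acceptance script
use desk-scale slices (2 clinics, ~20 patients, 12 months sampled evenly
across the year range so both pre- and post-2024 template eras appear).
Each clinic gets a fixed header dialect (one synonym variant per variable,
randomized casing), optional decorative title row and `END` marker, a
roster of unique ASCII names, and per-month attendance of roughly 80 % of
its roster. Corruptions are injected i.i.d. per cell at configurable rates
(defaults: format-variant dates 0.30, centimeter heights 0.40, combined-BP
spacing variants 0.20, serial dates 0.10, blanks 0.08, HbA1c inequalities
0.08, free-text categoricals 0.05, typos 0.02, name misspellings 0.02,
out-of-range values 0.01 — chosen as a plausibly messy mix in which most
cells are clean but every rule is exercised). Every written cell is
recorded in a ground-truth manifest with its intended value and corruption
class; recoverable classes keep the truth reconstructible (the month-only
date variant coerces its truth to the first of the month, so recovery is
exact by construction), unrecoverable classes must surface as sentinels
plus exactly one warning, and blanks must surface as missing.

What the generator does **not** emulate: statistically realistic clinical
trajectories (HbA1c dynamics, growth curves), non-ASCII names and
locale-specific normalization, cross-cell consistency (BMI vs
height/weight), and real tracker marker conventions (the `END` marker and
`YYYY-MM` sheet names are self-consistent stand-ins). Passing tests
therefore demonstrate that the *structural* cleaning and accounting
guarantees hold under heavy format heterogeneity — not that clinical
content is realistic.

## Determinism

Every stage is reproducible to the byte. Workbooks are written with pinned
document properties and normalized zip archives (fixed member order and
timestamps); per-clinic random streams are seeded from (seed, clinic code)
so output is independent of iteration order; event logs have stable key
order; Parquet and JSON outputs are canonicalized. The test suite asserts
byte-identity for generate, anonymize, run and audit reruns.

## Known limitations

* Header matching is exact after normalization; a genuinely novel header
  spelling requires a synonym-file update (by design, but it is manual).
* The day-first rule for all-numeric dates is a convention, not an
  inference; month-first sources would need a config-level dialect switch.
* Entity detection assumes a sheet is predominantly one entity; mixed
  patient/product sheets are not supported.
* Completeness is a per-column aggregate over all staged rows; per-era
  breakdowns require filtering by period before auditing.
* The anonymizer's name-column designation relies on recognizable name
  headers; a name column under an unrecognized header would only be
  protected by whole-cell roster matching.
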