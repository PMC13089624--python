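# trackerforge

A tested, reusable toolkit for harmonizing heterogeneous clinical tracker
workbooks into database-ready columnar tables — built for the setting of a
multi-country diabetes support program whose hospitals exchange patient and
medical-product data monthly as Excel spreadsheets whose column names,
layouts and entry conventions vary by site and have drifted over the years.

It is aimed at data engineers and analysts running such programs: people who
need every monthly workbook pseudonymized before processing, every messy
cell either cleaned or conspicuously flagged (never silently dropped), and a
per-site, per-month audit trail of data quality.

## What it does

The pipeline is a three-stage **extract–clean–load** architecture with
pseudonymization strictly first, plus a synthetic-data generator and an
audit layer:

1. **Anonymize** — each workbook's "Patient List" roster sheet pairs names
   with structured program identifiers (`^[A-Z]{2}[A-Z]{2}[0-9]{3}$`:
   country + clinic + zero-padded sequence, e.g. `LAVT001`). Every name cell
   is replaced by its identifier; unmatched names are redacted to
   `[UNRESOLVED]` and logged `W_NAME_UNMATCHED` for manual review.
2. **Extract** — region detection (header row = first row with ≥3 known
   synonyms; data span ends at the first blank row or `END` marker) and
   configuration-driven column mapping: a YAML synonym file maps raw header
   variants onto a canonical schema (69 patient and 14 product variables in
   the shipped configuration). Unmatched columns are retained and logged,
   never silently excluded.
3. **Clean** — typed conversion with *sentinel substitution*: unparseable
   numbers become `999999`, unparseable dates become `9999-12-31`, each with
   a coded warning event carrying cell provenance. Dates go through a fixed
   cascade (spreadsheet serial number → ISO → `15-Mar-2022` → `Mar 2022`
   with a month-precision flag → day-first `d/m/y` → first embedded date
   substring). Clinical rules: HbA1c inequality prefixes (`<7.0`) are
   stripped with a threshold-exceeded flag; combined blood pressure
   (`120/80 mmHg`) splits into systolic/diastolic; heights above 50 are
   converted from centimeters to meters. Range validation enforces closed
   clinically plausible bounds (age 0–100 y, HbA1c 0–25 %); categorical
   fields pass allowed-value checks, with free text retained and flagged.
4. **Load** — records assemble into patient and product tables in canonical
   column order, sorted by (patient, date) and (clinic, date, product), and
   serialize to Apache Parquet in a local staging directory, byte-for-byte
   reproducibly.
5. **Audit** — the JSON-Lines event log aggregates into a count matrix by
   (clinic × reporting period × warning code) plus per-variable
   completeness, where sentinels never count as observed data.

A seeded **synthetic generator** produces realistically messy multi-clinic
programs (mixed date formats, unit confusion, typos, blanks, template drift:
insulin-type columns only from 2024 onward) together with a per-cell
ground-truth manifest, so every cleaning rule is testable against known
truth.

## Worked example

```sh
trackerforge generate --clinics 2 --patients 8 --months 4 --seed 3 --out raw/
# wrote 2 workbooks and manifest.json to raw/
# manifest entries: 1267

trackerforge anonymize --in raw/ --out-dir anon/ --log anon.jsonl
# anonymized 2 workbooks into anon/ (0 events)

trackerforge run --in anon/ --out staged/ --seed 3
# staged 29 patient and 53 product records; 56 events

trackerforge audit --events staged/events.jsonl --tables staged/ --out audit.json
# audit report written to audit.json (56 events)
```

The generator wrote two clinic workbooks (`LAAA.xlsx`, `VNAB.xlsx`) with 1267
manifest-tracked cells. Anonymization replaced every roster name (0 events
means no misspelled names needed redaction in this draw). The pipeline
staged 29 patient-month rows and 53 product rows and logged 56 validation
events — each a JSON line like

```json
{"code": "W_RANGE", "severity": "warning", "workbook": "LAAA.xlsx",
 "sheet": "2025-12", "row": 4, "column": "strips_provided", "raw": "4005",
 "substituted": "999999", "clinic": "LAAA", "period": "2025-12"}
```

telling an analyst exactly which cell of which sheet was implausible and
what was substituted. The audit report then shows, per clinic and month,
how many of each warning occurred and what fraction of each variable is
usable (e.g. `patient.insulin_type_basal` shows depressed completeness
because pre-2024 template eras simply lacked the column).

The same workflow is available as library calls (`generate_program`,
`build_lookup`/`anonymize_workbook`, `run_pipeline`, `build_audit`); see the
module docstrings.

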