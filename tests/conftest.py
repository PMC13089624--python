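"""Shared fixtures: one small synthetic program reused across the suite."""

from __future__ import annotations

from pathlib import Path

import pytest

from trackerforge.anonymize import anonymize_workbook, build_lookup
from trackerforge.clean import clean_record
from trackerforge.config import load_default_config
from trackerforge.extract import extract_records
from trackerforge.load import run_pipeline
from trackerforge.synthetic import GeneratorConfig, generate_program

#: desk-scale study conditions used throughout the suite
PROGRAM_KW = dict(n_countries=2, n_clinics=2, n_patients=20, n_months=12,
                  seed=7)


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def program(tmp_path_factory):
    """A generated two-clinic program with its ground-truth manifest."""
    raw_dir = tmp_path_factory.mktemp("raw")
    gc = GeneratorConfig(**PROGRAM_KW)
    paths, manifest = generate_program(gc, raw_dir)
    return {"dir": raw_dir, "paths": paths, "manifest": manifest,
            "generator_config": gc}


@pytest.fixture(scope="session")
def anonymized(program, tmp_path_factory):
    """The same program after pseudonymization."""
    out_dir = tmp_path_factory.mktemp("anon")
    events = []
    lookups = {}
    for path in program["paths"]:
        lookup = build_lookup(path)
        lookups[path.name] = lookup
        _, evs = anonymize_workbook(path, lookup, out_dir)
        events.extend(evs)
    return {"dir": out_dir, "events": events, "lookups": lookups}


@pytest.fixture(scope="session")
def cleaned(anonymized, config):
    """Extracted + cleaned records and the full event stream."""
    records, events = [], []
    for path in sorted(Path(anonymized["dir"]).glob("*.xlsx")):
        raws, evs = extract_records(path, config)
        events.extend(evs)
        for raw in raws:
            rec, more = clean_record(raw, config)
            records.append(rec)
            events.extend(more)
    return {"records": records, "events": events}


@pytest.fixture(scope="session")
def staged(anonymized, config, tmp_path_factory):
    """Full pipeline output: parquet tables, event log, summary."""
    out_dir = tmp_path_factory.mktemp("staged")
    summary = run_pipeline(anonymized["dir"], out_dir, config, seed=7)
    return {"dir": out_dir, "summary": summary}
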