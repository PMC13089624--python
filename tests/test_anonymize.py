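"""Pseudonymization: identifier validation, roster lookup, workbook rewrite."""

from __future__ import annotations

import itertools
import re

import pytest
from openpyxl import Workbook, load_workbook

from trackerforge.anonymize import (IdentifierLookup, LookupError_,
                                    PatientIdentifier, REDACTION_TOKEN,
                                    anonymize_workbook, build_lookup,
                                    validate_identifier)
from trackerforge.config import normalize_header

ID_RE = re.compile(r"^[A-Z]{2}[A-Z]{2}[0-9]{3}$")


class TestIdentifier:
    @pytest.mark.parametrize("candidate,ok", [
        ("VNHC007", True), ("LAVT001", True), ("VNHC07", False),
        ("vnhc007", False), ("VNHC0007", False), ("VNH0007", False),
        ("", False), ("VNHC000", False),
    ])
    def test_examples(self, candidate, ok):
        valid, event = validate_identifier(candidate)
        assert valid is ok
        if not ok:
            assert event.code == "W_ID_PATTERN" and event.raw == candidate

    def test_structural_parser_matches_regex_oracle_exhaustively(self):
        # every string of length <= 8 over a small mixed alphabet
        alphabet = "AV07"
        for n in range(9):
            for tup in itertools.product(alphabet, repeat=n):
                s = "".join(tup)
                expected = bool(ID_RE.match(s)) and s[4:] != "000"
                assert validate_identifier(s)[0] is expected, s

    def test_round_trip(self):
        ident = PatientIdentifier.parse("LAVT042")
        assert (ident.country, ident.clinic, ident.sequence) == ("LA", "VT", 42)
        assert ident.rendered == "LAVT042"


def _roster_workbook(tmp_path, rows, name="wb.xlsx", extra_sheets=()):
    wb = Workbook()
    ws = wb.active
    ws.title = "Patient List"
    ws.append(["Patient Name", "Patient ID"])
    for row in rows:
        ws.append(list(row))
    for title, sheet_rows in extra_sheets:
        ws = wb.create_sheet(title=title)
        for row in sheet_rows:
            ws.append(list(row))
    path = tmp_path / name
    wb.save(path)
    return path


class TestBuildLookup:
    def test_minimal_roster(self, tmp_path):
        path = _roster_workbook(tmp_path, [("Anna B", "LAVT001")])
        lookup = build_lookup(path)
        assert len(lookup) == 1 and lookup.get("anna  b") == "LAVT001"

    def test_conflicting_duplicate_names(self, tmp_path):
        path = _roster_workbook(tmp_path, [("Anna B", "LAVT001"),
                                           ("anna  b", "LAVT002")])
        with pytest.raises(LookupError_, match="duplicate"):
            build_lookup(path)

    def test_pattern_violation_logged(self, tmp_path):
        path = _roster_workbook(tmp_path, [("Anna B", "LAVT1")])
        lookup = build_lookup(path)
        assert [e.code for e in lookup.events] == ["W_ID_PATTERN"]
        assert lookup.events[0].raw == "LAVT1"

    def test_missing_roster_sheet(self, tmp_path):
        wb = Workbook()
        wb.active.title = "2022-01"
        path = tmp_path / "bad.xlsx"
        wb.save(path)
        with pytest.raises(LookupError_, match="Patient List"):
            build_lookup(path)


class TestAnonymizeWorkbook:
    def test_refuses_same_directory(self, tmp_path):
        path = _roster_workbook(tmp_path, [("Anna B", "LAVT001")])
        with pytest.raises(ValueError, match="differ"):
            anonymize_workbook(path, build_lookup(path), tmp_path)

    def test_misspelling_redacted_and_logged(self, tmp_path):
        path = _roster_workbook(
            tmp_path, [("Anna Sok", "LAVT001")],
            extra_sheets=[("2022-01", [("Name", "Visit Date"),
                                       ("Anna Sk", "2022-01-15")])])
        out, events = anonymize_workbook(path, build_lookup(path),
                                         tmp_path / "anon")
        assert [e.code for e in events] == ["W_NAME_UNMATCHED"]
        wb = load_workbook(out)
        assert wb["2022-01"].cell(row=2, column=1).value == REDACTION_TOKEN

    def test_completeness_no_roster_name_survives(self, program, anonymized):
        for path in program["paths"]:
            lookup = anonymized["lookups"][path.name]
            wb = load_workbook(anonymized["dir"] / path.name, read_only=True)
            for ws in wb.worksheets:
                for row in ws.iter_rows(values_only=True):
                    for cell in row:
                        if cell is None:
                            continue
                        assert normalize_header(str(cell)) not in lookup.mapping
            wb.close()

    def test_unmatched_events_equal_injected_misspellings(self, program,
                                                          anonymized):
        injected = sum(1 for e in program["manifest"].entries
                       if e.column == "patient_id"
                       and e.corruption_class == "typo_unrecoverable")
        unmatched = [e for e in anonymized["events"]
                     if e.code == "W_NAME_UNMATCHED"]
        assert len(unmatched) == injected

    def test_structure_conserved(self, program, anonymized):
        for path in program["paths"]:
            wb_in = load_workbook(path, read_only=True)
            wb_out = load_workbook(anonymized["dir"] / path.name,
                                   read_only=True)
            assert wb_in.sheetnames == wb_out.sheetnames
            for name in wb_in.sheetnames:
                rows_in = list(wb_in[name].iter_rows(values_only=True))
                rows_out = list(wb_out[name].iter_rows(values_only=True))
                assert len(rows_in) == len(rows_out), name
            wb_in.close()
            wb_out.close()

    def test_rewrite_is_deterministic(self, program, anonymized, tmp_path):
        path = program["paths"][0]
        lookup = anonymized["lookups"][path.name]
        out, _ = anonymize_workbook(path, lookup, tmp_path / "again")
        assert out.read_bytes() == (anonymized["dir"] / path.name).read_bytes()
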