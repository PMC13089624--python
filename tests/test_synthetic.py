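"""Synthetic program generator: determinism, structure, manifest coverage."""

from __future__ import annotations

import pytest
from openpyxl import load_workbook

from trackerforge.config import normalize_header
from trackerforge.synthetic import (DEFAULT_CORRUPTION_RATES, GeneratorConfig,
                                    GroundTruthManifest, generate_patient_list,
                                    generate_program)

SMALL = dict(n_countries=2, n_clinics=2, n_patients=10, n_months=6, seed=7)


class TestPatientList:
    def test_sequential_zero_padded_identifiers(self):
        rows = generate_patient_list(3, "LA", "VT")
        assert [ident for _, ident in rows] == ["LAVT001", "LAVT002", "LAVT003"]

    def test_names_unique_after_normalization(self):
        rows = generate_patient_list(500, "VN", "HC")
        norms = {normalize_header(name) for name, _ in rows}
        assert len(norms) == 500

    def test_empty_roster(self):
        assert generate_patient_list(0, "VN", "HC") == []

    def test_sequence_exhaustion(self):
        with pytest.raises(ValueError, match="exhausted"):
            generate_patient_list(1000, "VN", "HC")

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError, match="country"):
            generate_patient_list(1, "La", "VT")


class TestDeterminism:
    def test_identical_seed_gives_identical_bytes_and_manifest(self, tmp_path):
        gc = GeneratorConfig(**SMALL)
        paths_a, man_a = generate_program(gc, tmp_path / "a")
        paths_b, man_b = generate_program(gc, tmp_path / "b")
        assert [p.name for p in paths_a] == [p.name for p in paths_b]
        for pa, pb in zip(paths_a, paths_b):
            assert pa.read_bytes() == pb.read_bytes()
        assert man_a.to_dict() == man_b.to_dict()

    def test_different_seed_differs(self, tmp_path):
        _, man_a = generate_program(GeneratorConfig(**SMALL), tmp_path / "a")
        other = dict(SMALL, seed=8)
        _, man_b = generate_program(GeneratorConfig(**other), tmp_path / "b")
        assert man_a.to_dict() != man_b.to_dict()

    def test_manifest_round_trips_through_json(self, tmp_path):
        _, man = generate_program(GeneratorConfig(**SMALL), tmp_path / "a")
        loaded = GroundTruthManifest.load(tmp_path / "a" / "manifest.json")
        assert loaded.to_dict() == man.to_dict()


class TestCorruptionRates:
    def test_zero_rates_give_clean_cells_only(self, tmp_path):
        rates = {k: 0.0 for k in DEFAULT_CORRUPTION_RATES}
        gc = GeneratorConfig(**dict(SMALL, corruption_rates=rates))
        _, man = generate_program(gc, tmp_path)
        assert set(man.count_by_class()) == {"none"}

    def test_forced_inequality_prefixes_every_hba1c(self, tmp_path):
        rates = {k: 0.0 for k in DEFAULT_CORRUPTION_RATES}
        rates["hba1c_inequality"] = 1.0
        gc = GeneratorConfig(**dict(SMALL, corruption_rates=rates))
        _, man = generate_program(gc, tmp_path)
        hba1c = [e for e in man.entries if e.column == "hba1c"]
        assert hba1c and all(e.rendered_value[0] in "<>" for e in hba1c)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            GeneratorConfig(**dict(SMALL,
                                   corruption_rates={"blank": 1.5}))


class TestStructure:
    def test_manifest_covers_every_nonempty_data_cell(self, program):
        manifest = program["manifest"]
        nonblank = [e for e in manifest.entries if e.corruption_class != "blank"]
        rows_by_wb: dict[str, set] = {}
        for e in manifest.entries:
            rows_by_wb.setdefault(e.workbook, set()).add((e.sheet, e.row))
        counted = 0
        for path in program["paths"]:
            wb = load_workbook(path, read_only=True)
            for ws in wb.worksheets:
                rows = list(ws.iter_rows(values_only=True))
                for i, row in enumerate(rows):
                    if (ws.title, i) in rows_by_wb[path.name]:
                        counted += sum(1 for c in row if c is not None
                                       and str(c).strip() != "")
            wb.close()
        assert counted == len(nonblank)

    def test_insulin_type_columns_drift_at_2024(self, program, config):
        insulin = {"insulin_type_basal", "insulin_type_bolus",
                   "insulin_type_premixed", "insulin_type_other"}
        for path in program["paths"]:
            wb = load_workbook(path, read_only=True)
            for ws in wb.worksheets:
                if not ws.title[:4].isdigit():
                    continue  # roster / product sheets
                headers = set()
                for row in ws.iter_rows(values_only=True):
                    mapped = {config.synonyms.lookup(str(c))
                              for c in row if c is not None}
                    if len(mapped - {None}) >= 3:
                        headers = mapped
                        break
                if ws.title < "2024-01":
                    assert not (headers & insulin), ws.title
                else:
                    assert headers & insulin, ws.title
            wb.close()

    def test_every_country_has_a_clinic(self, tmp_path):
        gc = GeneratorConfig(n_countries=3, n_clinics=4, n_patients=8,
                             n_months=2, seed=1)
        paths, _ = generate_program(gc, tmp_path)
        prefixes = {p.name[:2] for p in paths}
        assert prefixes == {"LA", "VN", "KH"}

    def test_clinic_count_below_country_count_rejected(self):
        with pytest.raises(ValueError, match="n_clinics"):
            GeneratorConfig(n_countries=3, n_clinics=2, n_patients=10)
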