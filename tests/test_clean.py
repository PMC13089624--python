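"""Cleaning rules: conversions, the date cascade, clinical field cleaners."""

from __future__ import annotations

import random
from datetime import date, datetime, timedelta

import pytest

from trackerforge.clean import (EXCEL_EPOCH, SERIAL_WINDOW, check_category,
                                check_range, clean_hba1c, convert_numeric,
                                normalize_height, parse_date,
                                split_blood_pressure)
from trackerforge.config import Bounds, CanonicalVariable


@pytest.fixture(scope="module")
def policy(config):
    return config.sentinels


@pytest.fixture(scope="module")
def rules(config):
    return config.rules


def num_var(name="x", lo=0, hi=100):
    return CanonicalVariable(name=name, entity="patient", dtype="number",
                             bounds=Bounds(min=lo, max=hi))


class TestConvertNumeric:
    @pytest.mark.parametrize("raw,expected", [
        ("42", 42.0), (" 7.25 ", 7.25), (13, 13.0), ("1,234", 1234.0),
    ])
    def test_clean_parse(self, raw, expected, policy):
        cv, ev = convert_numeric(raw, num_var(hi=10000), policy)
        assert cv.value == expected and ev is None and not cv.is_sentinel

    def test_failure_becomes_sentinel_with_event(self, policy):
        cv, ev = convert_numeric("abc", num_var(), policy)
        assert cv.value == 999999 and cv.is_sentinel
        assert ev.code == "W_TYPE_NUM" and ev.severity == "warning"

    def test_blank_is_missing_not_error(self, policy):
        for blank in ("", "   ", None):
            cv, ev = convert_numeric(blank, num_var(), policy)
            assert cv.is_missing and not cv.is_sentinel and ev is None


class TestDateCascade:
    @pytest.mark.parametrize("raw,expected", [
        ("15-Mar-2022", date(2022, 3, 15)),
        ("2022-03-15", date(2022, 3, 15)),
        ("15/3/2022", date(2022, 3, 15)),
        ("3/4/2022", date(2022, 4, 3)),          # day-first convention
        ("1 January 2020", date(2020, 1, 1)),
        ("recorded 15-Mar-2022 by nurse", date(2022, 3, 15)),
    ])
    def test_full_precision_formats(self, raw, expected, policy):
        cv, ev = parse_date(raw, policy)
        assert cv.value == expected
        assert "month_precision" not in cv.flags

    def test_serial_number_against_calendar_oracle(self, policy):
        # independent oracle: count days from the spreadsheet epoch
        oracle = date.fromordinal(date(1899, 12, 30).toordinal() + 44635)
        cv, ev = parse_date(44635, policy)
        assert cv.value == oracle == date(2022, 3, 15)

    def test_month_precision_completed_to_day_one(self, policy):
        cv, ev = parse_date("Mar 2022", policy)
        assert cv.value == date(2022, 3, 1)
        assert "month_precision" in cv.flags
        assert ev.code == "I_DATE_MONTH_PRECISION" and ev.severity == "info"

    def test_unparseable_becomes_date_sentinel(self, policy):
        cv, ev = parse_date("not a date", policy)
        assert cv.value == date(9999, 12, 31) and cv.is_sentinel
        assert ev.code == "W_TYPE_DATE"

    def test_small_numbers_are_not_serial_dates(self, policy):
        # a height or age must never be misread as a date
        cv, ev = parse_date(170, policy)
        assert cv.is_sentinel and ev.code == "W_TYPE_DATE"

    def test_datetime_payload_passes_through(self, policy):
        cv, ev = parse_date(datetime(2021, 5, 4, 10, 30), policy)
        assert cv.value == date(2021, 5, 4) and ev is None

    def test_cascade_agrees_with_brute_force_oracle(self, policy):
        """Render random dates in every generator format and reparse."""
        rng = random.Random(12345)
        for _ in range(300):
            true = date(2015, 1, 1) + timedelta(days=rng.randrange(4000))
            renders = [
                true.isoformat(),
                f"{true.day}-{true.strftime('%b')}-{true.year}",
                f"{true.day}/{true.month}/{true.year}",
                (true - EXCEL_EPOCH).days,
                f"noted {true.day}-{true.strftime('%b')}-{true.year} late",
            ]
            for raw in renders:
                cv, _ = parse_date(raw, policy)
                assert cv.value == true, (raw, cv.value)
            # month-only render recovers the first of the month
            cv, _ = parse_date(f"{true.strftime('%b')} {true.year}", policy)
            assert cv.value == true.replace(day=1)

    def test_serial_window_bounds(self, policy):
        lo, hi = SERIAL_WINDOW
        assert parse_date(lo, policy)[0].value == EXCEL_EPOCH + timedelta(days=lo)
        assert parse_date(hi + 1, policy)[0].is_sentinel


class TestHbA1c:
    def test_inequality_stripped_with_flag(self, rules, policy):
        cv, events = clean_hba1c("<7.0", rules, policy)
        assert cv.value == 7.0
        assert "threshold_exceeded" in cv.flags
        assert [e.code for e in events] == ["I_HBA1C_THRESHOLD"]

    def test_spaced_inequality(self, rules, policy):
        cv, _ = clean_hba1c("> 9.5", rules, policy)
        assert cv.value == 9.5 and "threshold_exceeded" in cv.flags

    def test_plain_value(self, rules, policy):
        cv, events = clean_hba1c("8.2", rules, policy)
        assert cv.value == 8.2 and not cv.flags and not events

    def test_out_of_band_is_sentinel(self, rules, policy):
        cv, events = clean_hba1c("30", rules, policy)
        assert cv.value == 999999 and cv.is_sentinel
        assert [e.code for e in events] == ["W_RANGE"]

    def test_unparseable_is_sentinel(self, rules, policy):
        cv, events = clean_hba1c("high", rules, policy)
        assert cv.is_sentinel
        assert [e.code for e in events] == ["W_TYPE_NUM"]


class TestBloodPressure:
    @pytest.mark.parametrize("raw", ["120/80", "120 / 80 mmHg", "120/ 80 mmhg"])
    def test_combined_string_split(self, raw, rules, policy):
        s, d, events = split_blood_pressure(raw, rules, policy)
        assert (s.value, d.value) == (120.0, 80.0) and not events

    def test_malformed_separator(self, rules, policy):
        s, d, events = split_blood_pressure("120-80", rules, policy)
        assert s.is_sentinel and d.is_sentinel
        assert [e.code for e in events] == ["W_BP_MALFORMED"]

    def test_component_range_checked(self, rules, policy):
        s, d, events = split_blood_pressure("300/80", rules, policy)
        assert s.is_sentinel and d.value == 80.0
        assert [e.code for e in events] == ["W_RANGE"]

    def test_blank(self, rules, policy):
        s, d, events = split_blood_pressure("", rules, policy)
        assert s.is_missing and d.is_missing and not events


class TestHeight:
    @pytest.fixture
    def height_var(self):
        return CanonicalVariable(name="height", entity="patient",
                                 dtype="height", bounds=Bounds(min=0.3, max=2.5))

    def test_centimeters_converted(self, rules, policy, height_var):
        cv, events = normalize_height(170, rules, policy, height_var)
        assert cv.value == pytest.approx(1.70)
        assert "unit_converted" in cv.flags
        assert [e.code for e in events] == ["I_HEIGHT_CONVERTED"]

    def test_meters_untouched(self, rules, policy, height_var):
        cv, events = normalize_height(1.45, rules, policy, height_var)
        assert cv.value == 1.45 and not cv.flags and not events

    def test_threshold_is_strict(self, rules, policy, height_var):
        # exactly 50 is read as meters (the rule fires above 50) -> implausible
        cv, events = normalize_height(50, rules, policy, height_var)
        assert cv.is_sentinel
        assert [e.code for e in events] == ["W_RANGE"]

    def test_implausible_meters_rejected(self, rules, policy, height_var):
        cv, events = normalize_height(49, rules, policy, height_var)
        assert cv.is_sentinel and events[-1].code == "W_RANGE"


class TestRangeAndCategory:
    def test_closed_bounds(self, policy):
        age = num_var("age", 0, 100)
        assert check_range(34, age, policy)[0].value == 34.0
        assert check_range(100, age, policy)[1] is None  # boundary included
        assert check_range(0, age, policy)[1] is None
        cv, ev = check_range(150, age, policy)
        assert cv.value == 999999 and ev.code == "W_RANGE" and ev.raw == "150"

    def test_category_casefold_match(self):
        var = CanonicalVariable(name="insulin_regimen", entity="patient",
                                dtype="category",
                                allowed_values=("Basal-Bolus", "Premixed"))
        cv, ev = check_category("basal-bolus", var)
        assert cv.value == "Basal-Bolus" and ev is None

    def test_category_freetext_retained_with_warning(self):
        var = CanonicalVariable(name="insulin_regimen", entity="patient",
                                dtype="category", allowed_values=("Premixed",))
        cv, ev = check_category("unknown regimen text", var)
        assert cv.value == "unknown regimen text" and not cv.is_sentinel
        assert ev.code == "W_CATEGORY"

    def test_category_blank_is_missing(self):
        var = CanonicalVariable(name="sex", entity="patient",
                                dtype="category", allowed_values=("Male",))
        cv, ev = check_category("", var)
        assert cv.is_missing and ev is None

    def test_tightening_bounds_is_monotone_in_range_events(self, policy):
        values = [5, 20, 45, 60, 80, 99, 120]
        def count(lo, hi):
            var = num_var("x", lo, hi)
            return sum(1 for v in values
                       if check_range(v, var, policy)[1] is not None)
        wide = count(0, 130)
        for hi in (120, 100, 70, 40, 10):
            narrower = count(0, hi)
            assert narrower >= wide
            wide = narrower
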