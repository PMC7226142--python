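"""Raw-table IO, report assembly and demographic derivations."""

from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.faers_io import (
    AGE_CLASSES,
    FAERS_ASCII,
    SchemaError,
    age_to_class,
    age_years_from_code,
    assemble_reports,
    read_table_set,
    write_table_set,
)

_HEADERS = {
    "demo": "primaryid$caseid$caseversion$event_dt$age$age_cod$sex$occp_cod$reporter_country$fda_dt",
    "drug": "primaryid$caseid$drug_seq$role_cod$drugname",
    "reac": "primaryid$caseid$pt",
    "outc": "primaryid$caseid$outc_cod",
    "indi": "primaryid$caseid$indi_drug_seq$indi_pt",
    "ther": "primaryid$caseid$dsg_drug_seq$start_dt$end_dt",
}


def _write_fixture(tmp_path: Path, rows_by_table) -> dict:
    paths = {}
    for table, header in _HEADERS.items():
        lines = [header] + rows_by_table.get(table, [])
        path = tmp_path / f"{table}.txt"
        path.write_text("\n".join(lines) + "\n")
        paths[table] = path
    return paths


@pytest.fixture
def fixture_paths(tmp_path):
    return _write_fixture(
        tmp_path,
        {
            "demo": [
                "101$10$1$20180415$65$YR$M$MD$US$20180501",
                "201$20$1$201803$$$F$CN$FR$20180601",
                "301$30$1$$$$$$$20190101",
            ],
            "drug": ["101$10$1$PS$TASIGNA", "101$10$2$C$ASPIRIN"],
            "reac": ["101$10$Synthetic sign A", "101$10$Synthetic sign B", "101$10$Synthetic sign C", "$10$Orphan term"],
            "outc": ["101$10$HO"],
            "ther": ["101$10$1$20180101$"],
        },
    )


def test_read_counts_and_dropped_keys(fixture_paths):
    tables = read_table_set(fixture_paths)
    assert len(tables.demo) == 3
    # the REAC row with an empty key is dropped and accounted for
    assert len(tables.reac) == 3
    assert tables.load_report == {"dropped_missing_key_reac": 1}


def test_unknown_layout_names_offending_file(tmp_path, fixture_paths):
    bad = tmp_path / "demo_bad.txt"
    bad.write_text("wrongcol$caseid\n1$2\n")
    fixture_paths["demo"] = bad
    with pytest.raises(SchemaError, match="demo_bad"):
        read_table_set(fixture_paths)


def test_roundtrip_is_lossless(tmp_path, small_tables):
    tables, _ = small_tables
    first = write_table_set(tables, tmp_path / "a")
    reread = read_table_set(first)
    second = write_table_set(reread, tmp_path / "b")
    for name, path in first.items():
        assert path.read_bytes() == second[name].read_bytes()


def test_assemble_groups_lines_under_report(fixture_paths):
    reports = assemble_reports(read_table_set(fixture_paths))
    assert len(reports) == 3
    by_id = {r.report_id: r for r in reports}
    r = by_id["101"]
    assert len(r.drugs) == 2 and len(r.events) == 3
    assert r.serious and r.outcome == frozenset({"hospitalization"})
    assert r.age_years == 65 and r.age_class == "51-75"
    assert r.sex == "male" and r.reporter_type == "health professional"
    assert r.drugs[0].therapy_start.isoformat() == "2018-01-01"
    assert all(e.onset_date.isoformat() == "2018-04-15" for e in r.events)
    # partial event date and missing age propagate as such
    assert by_id["201"].age_class == "unknown"
    assert by_id["201"].events == []
    assert not by_id["301"].serious


def test_report_count_equals_distinct_demo_keys(small_tables):
    tables, _ = small_tables
    reports = assemble_reports(tables)
    assert len(reports) == tables.demo["primaryid"].nunique()


def test_conflicting_demo_rows_keep_first(tmp_path):
    paths = _write_fixture(
        tmp_path,
        {"demo": ["101$10$1$$65$YR$M$MD$US$20180501", "101$10$1$$30$YR$F$CN$FR$20180501"]},
    )
    reports = assemble_reports(read_table_set(paths))
    assert len(reports) == 1 and reports[0].age_years == 65


@pytest.mark.parametrize(
    "age, cod, expected",
    [("65", "YR", 65.0), ("6", "DEC", 60.0), ("18", "MON", 1.5), ("65", "", 65.0), ("65", "XX", None), ("", "YR", None)],
)
def test_age_unit_normalization(age, cod, expected):
    if expected is None:
        assert age_years_from_code(age, cod) is None
    else:
        assert age_years_from_code(age, cod) == pytest.approx(expected)


@pytest.mark.parametrize(
    "age, expected",
    [(0, "<=25"), (25, "<=25"), (26, "26-50"), (50, "26-50"), (51, "51-75"), (65, "51-75"), (75, "51-75"), (76, ">=76"), (120, ">=76"), (None, "unknown")],
)
def test_age_class_bins(age, expected):
    assert age_to_class(age) == expected


@settings(deadline=None)
@given(st.one_of(st.none(), st.floats(min_value=0, max_value=150, allow_nan=False)))
def test_age_class_total_and_deterministic(age):
    cls = age_to_class(age)
    assert cls in AGE_CLASSES
    assert age_to_class(age) == cls
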