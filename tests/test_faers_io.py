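"""Quarter parsing, case assembly and deduplication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvscreen import faers_io
from pvscreen.faers_io import (
    CaseReport,
    Dialect,
    DrugEntry,
    FaersFormatError,
    assemble_cases,
    deduplicate,
    parse_age,
    read_quarter,
)
from pvscreen.synthetic_data import default_config, generate, generate_reports, latest_cases
from pvscreen.vocabulary import normalize_drug


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def quarter(tmp_path):
    demo = _write(tmp_path / "demo.txt", [
        "primaryid$caseid$caseversion$sex$age$age_cod$occp_cod$occr_country",
        "p11$c1$1$F$34$YR$MD$US",
        "p21$c2$1$M$420$MON$CN$GB",
        "p31$c3$1$$$$$",
    ])
    drug = _write(tmp_path / "drug.txt", [
        "primaryid$caseid$role_cod$drugname",
        "p11$c1$PS$bupropion",
        "p21$c2$PS$sertraline",
        "p31$c3$C$unmapped-drug-x",
        "p99$c9$PS$orphan-drug",
    ])
    reac = _write(tmp_path / "reac.txt", [
        "primaryid$caseid$pt",
        "p11$c1$90010001",
        "p11$c1$90090001",
        "p31$c3$90090002",
    ])
    indi = _write(tmp_path / "indi.txt", [
        "primaryid$caseid$indi_pt",
        "p11$c1$90080001",
    ])
    return demo, drug, reac, indi


class TestReadQuarter:
    def test_row_counts_per_table(self, quarter):
        result = read_quarter(*quarter)
        assert len(result.table("DEMO")) == 3
        assert len(result.table("DRUG")) == 4
        assert len(result.table("REAC")) == 3
        assert len(result.table("INDI")) == 1
        assert result.rejects == []

    def test_malformed_row_routed_to_rejects(self, quarter, tmp_path):
        demo, drug, reac, indi = quarter
        bad = _write(tmp_path / "drug_bad.txt", [
            "primaryid$caseid$role_cod$drugname",
            "p11$c1$PS$bupropion",
            "p21$c2$PS",  # 3 fields under a 4-field header
        ])
        result = read_quarter(demo, bad, reac, indi)
        assert len(result.rejects) == 1
        assert result.rejects[0].table_name == "DRUG"
        assert result.rejects[0].n_fields == 3
        assert len(result.table("DRUG")) == 1  # parse continued

    def test_missing_file_is_fatal(self, quarter, tmp_path):
        demo, drug, reac, indi = quarter
        with pytest.raises(FaersFormatError, match="not found"):
            read_quarter(demo, tmp_path / "nope.txt", reac, indi)

    def test_header_without_key_column_is_fatal(self, quarter, tmp_path):
        demo, drug, reac, indi = quarter
        bad = _write(tmp_path / "reac_bad.txt", ["primaryid$pt", "p11$90010001"])
        with pytest.raises(FaersFormatError, match="caseid"):
            read_quarter(demo, drug, bad, indi)

    def test_tab_dialect(self, tmp_path, quarter):
        _, drug, reac, indi = quarter
        demo = _write(tmp_path / "demo_tab.txt", [
            "primaryid\tcaseid\tcaseversion\tsex",
            "p11\tc1\t1\tF",
        ])
        result = faers_io._read_table(demo, "DEMO", Dialect("\t"))
        assert len(result.records) == 1


class TestAssemble:
    def test_joins_drug_and_events(self, quarter, dictionary):
        records = read_quarter(*quarter).records
        result = assemble_cases(records, normalize_drug=lambda r: normalize_drug(r, dictionary))
        by_id = {c.primary_id: c for c in result.cases}
        c1 = by_id["p11"]
        assert c1.sex == "female" and c1.age_years == 34
        assert c1.reporter == "health_professional" and c1.region == "NorthAmerica"
        assert c1.drugs == (DrugEntry("bupropion", "PS", "N06AX12"),)
        assert c1.event_pts == {"90010001", "90090001"}
        assert c1.indication_pts == {"90080001"}
        c3 = by_id["p31"]
        assert c3.sex == "unknown" and c3.age_years is None
        assert c3.drugs[0].atc_code is None  # unmapped drug name

    def test_no_event_report_excluded_and_counted(self, quarter):
        records = read_quarter(*quarter).records
        result = assemble_cases(records)
        # p21 has a drug but no REAC row
        assert result.n_no_event == 1
        assert {c.primary_id for c in result.cases} == {"p11", "p31"}

    def test_orphan_rows_counted(self, quarter):
        records = read_quarter(*quarter).records
        result = assemble_cases(records)
        assert result.n_orphan_rows == 1  # DRUG row p99 has no DEMO row

    def test_age_in_months_converted(self, quarter):
        records = read_quarter(*quarter).records
        cases = assemble_cases(records).cases
        # p21 is excluded (no events) but the conversion path is exercised via parse_age
        assert parse_age("420", "MON") == pytest.approx(35.0)

    def test_no_demo_rows_fatal(self):
        with pytest.raises(FaersFormatError, match="DEMO"):
            assemble_cases([])


@pytest.mark.parametrize(
    ("value", "unit", "expected"),
    [
        ("34", "YR", 34.0),
        ("34", "", 34.0),
        ("6", "DEC", 60.0),
        ("24", "MON", 2.0),
        ("52", "WK", 1.0),
        ("365.25", "DY", 1.0),
        ("", "YR", None),
        ("abc", "YR", None),
        ("200", "YR", None),  # implausible → missing
        ("34", "XX", None),  # unknown unit
    ],
)
def test_parse_age(value, unit, expected):
    assert parse_age(value, unit) == expected


def _case(case_id, primary_id, seq):
    return CaseReport(
        case_id=case_id, primary_id=primary_id, receipt_sequence=seq,
        sex="unknown", age_years=None, reporter="unknown", region="unknown",
        drugs=(DrugEntry("x", "PS"),), event_pts=frozenset({"p"}),
    )


class TestDeduplicate:
    def test_latest_version_retained(self):
        cases = [_case("C1", "C11", 1), _case("C1", "C13", 3), _case("C1", "C12", 2)]
        out = deduplicate(cases)
        assert len(out) == 1 and out[0].primary_id == "C13"

    def test_tie_breaks_on_primary_id(self):
        cases = [_case("C1", "A", 1), _case("C1", "B", 1)]
        assert deduplicate(cases)[0].primary_id == "B"

    def test_distinct_cases_pass_through(self):
        cases = [_case("C2", "b", 1), _case("C1", "a", 1)]
        out = deduplicate(cases)
        assert [c.case_id for c in out] == ["C1", "C2"]  # sorted, nothing dropped

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(1, 4)), max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_idempotent(self, spec):
        cases = [
            _case(f"C{cid}", f"C{cid}{seq}", seq) for i, (cid, seq) in enumerate(spec)
        ]
        once = deduplicate(cases)
        assert deduplicate(once) == once
        assert len(once) == len({c.case_id for c in cases})

    def test_generator_duplicate_rate(self):
        config = default_config(n_cases=1000, seed=5, duplicate_rate=0.2)
        reports, truth = generate_reports(config)
        assert len(reports) > truth.n_distinct_cases
        out = deduplicate(reports)
        assert len(out) == truth.n_distinct_cases == 1000


class TestRoundTrip:
    def test_quarter_files_reproduce_generator_truth(self, tmp_path, small_config, dictionary):
        """generator → files → read → assemble → dedup matches the truth table."""
        paths, truth = generate(small_config, tmp_path / "q")
        parsed = read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["INDI"])
        assert len(parsed.records) == sum(truth.record_counts.values())
        assert parsed.rejects == []
        assembly = assemble_cases(
            parsed.records, normalize_drug=lambda r: normalize_drug(r, dictionary)
        )
        assert assembly.n_no_event == assembly.n_orphan_rows == 0
        cases = deduplicate(assembly.cases)
        assert len(cases) == truth.n_distinct_cases

        reference = {c.case_id: c for c in latest_cases(generate_reports(small_config)[0])}
        truth_by_id = truth.case_frame.set_index("case_id")
        for case in cases:
            ref = reference[case.case_id]
            row = truth_by_id.loc[case.case_id]
            assert case.event_pts == ref.event_pts
            assert case.indication_pts == ref.indication_pts
            assert case.drugs[0].atc_code == row["drug"]
            assert case.sex == row["sex"]
            assert case.reporter == row["reporter"]
            assert case.region == row["region"]
            assert case.receipt_sequence == (2 if row["duplicate"] else 1)

    def test_case_table_round_trip(self, tmp_path, small_config):
        reports, _ = generate_reports(small_config)
        cases = deduplicate(reports)
        path = tmp_path / "cases.tsv"
        faers_io.write_cases(cases, path)
        assert faers_io.read_cases(path) == cases
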