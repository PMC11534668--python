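"""Quarterly-file dialect: parsing, validation, round-trip identity."""

import pytest
from hypothesis import given, settings, strategies as st

from faerspv.faers_io import (
    PtSocDictionary,
    QuarterTables,
    default_dictionary,
    read_coded_reviews,
    read_pt_soc_dictionary,
    read_quarter,
    write_coded_reviews,
    write_quarter,
)
from faerspv.records import (
    CodedReview,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    TherRecord,
    DatePrecision,
)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def minimal_quarter(tmp_path, demo_lines):
    write_lines(
        tmp_path / "DEMO23Q1.txt",
        ["primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$"
         "reporter_country$occp_cod"] + demo_lines,
    )
    write_lines(tmp_path / "DRUG23Q1.txt",
                ["primaryid$drug_seq$role_cod$drugname$route$dose_form$dose_freq"])
    write_lines(tmp_path / "REAC23Q1.txt", ["primaryid$pt"])
    write_lines(tmp_path / "OUTC23Q1.txt", ["primaryid$outc_cod"])
    write_lines(tmp_path / "THER23Q1.txt",
                ["primaryid$dsg_drug_seq$start_dt$end_dt"])


class TestPartialDate:
    @pytest.mark.parametrize("text,precision,year", [
        ("20220301", DatePrecision.DAY, 2022),
        ("202203", DatePrecision.MONTH, 2022),
        ("2022", DatePrecision.YEAR, 2022),
    ])
    def test_precision_tagging(self, text, precision, year):
        date = PartialDate.parse(text)
        assert date.precision is precision
        assert date.year == year

    def test_empty_is_absent(self):
        assert PartialDate.parse("") is None

    @pytest.mark.parametrize("bad", ["20220231", "999", "20221301", "abc"])
    def test_malformed_dates_rejected(self, bad):
        with pytest.raises(ValueError):
            PartialDate.parse(bad)

    def test_only_day_precision_has_calendar_date(self):
        assert PartialDate.parse("20220301").to_date().day == 1
        assert PartialDate.parse("202203").to_date() is None


class TestReadQuarter:
    def test_well_formed_lines_parse(self, tmp_path):
        minimal_quarter(tmp_path, [
            "11$1$20220101$20220105$62$YR$F$US$MD",
            "21$2$20220102$$$$M$$",
            "31$3$$202203$6$DEC$$GB$CN",
        ])
        tables = read_quarter(tmp_path, "23Q1")
        assert len(tables.demo) == 3
        assert tables.demo[0].age == 62
        assert tables.demo[2].event_dt.precision is DatePrecision.MONTH
        assert tables.parse_report.total_skipped == 0

    def test_short_line_skipped_and_counted(self, tmp_path):
        minimal_quarter(tmp_path, [
            "11$1$20220101$$$$F$US$MD",
            "21$2$too$few",
        ])
        tables = read_quarter(tmp_path, "23Q1")
        assert len(tables.demo) == 1
        assert tables.parse_report.lines_skipped["DEMO"] == 1

    def test_invalid_field_skipped(self, tmp_path):
        minimal_quarter(tmp_path, ["11$1$20220101$$$$X$US$MD"])  # bad sex code
        tables = read_quarter(tmp_path, "23Q1")
        assert len(tables.demo) == 0
        assert tables.parse_report.lines_skipped["DEMO"] == 1

    def test_missing_table_file_is_hard_error(self, tmp_path):
        minimal_quarter(tmp_path, [])
        (tmp_path / "REAC23Q1.txt").unlink()
        with pytest.raises(FileNotFoundError, match="REAC23Q1"):
            read_quarter(tmp_path, "23Q1")

    def test_bad_header_is_hard_error(self, tmp_path):
        minimal_quarter(tmp_path, [])
        (tmp_path / "OUTC23Q1.txt").write_text("wrong$header\n")
        with pytest.raises(ValueError, match="header"):
            read_quarter(tmp_path, "23Q1")


ids = st.integers(1, 10**8).map(str)
dates = st.one_of(
    st.none(),
    st.integers(0, 2000).map(
        lambda n: PartialDate.parse(str(20180101 + (n % 28)))
    ),
    st.sampled_from([PartialDate.parse("202203"), PartialDate.parse("2021")]),
)
# parsing trims surrounding whitespace, so round-trip identity holds for
# trimmed free text
free_text = st.text(
    alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789 ()-", min_size=1, max_size=20
).map(str.strip).filter(bool)

demo_records = st.builds(
    DemoRecord,
    primaryid=ids, caseid=ids, fda_dt=dates, event_dt=dates,
    age=st.one_of(st.none(), st.integers(0, 99).map(float)),
    age_cod=st.sampled_from([None, "YR", "DEC", "MON"]),
    sex=st.sampled_from([None, "M", "F"]),
    reporter_country=st.sampled_from([None, "US", "GB", "JP"]),
    occp_cod=st.sampled_from([None, "MD", "CN", "HP"]),
)
drug_records = st.builds(
    DrugRecord,
    primaryid=ids, drug_seq=st.integers(1, 9),
    role_cod=st.sampled_from(["PS", "SS", "C", "I"]),
    drugname=free_text,
    route=st.one_of(st.none(), free_text),
    dose_form=st.one_of(st.none(), free_text),
    dose_freq=st.sampled_from([None, "QD", "QW"]),
)
reac_records = st.builds(ReacRecord, primaryid=ids, pt=free_text)
outc_records = st.builds(
    OutcRecord, primaryid=ids,
    outc_cod=st.sampled_from(["DE", "LT", "HO", "DS", "CA", "RI", "OT"]),
)
ther_records = st.builds(
    TherRecord, primaryid=ids, dsg_drug_seq=st.integers(1, 9),
    start_dt=dates, end_dt=st.none(),
)


class TestRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        demo=st.lists(demo_records, max_size=8),
        drug=st.lists(drug_records, max_size=8),
        reac=st.lists(reac_records, max_size=8),
        outc=st.lists(outc_records, max_size=8),
        ther=st.lists(ther_records, max_size=8),
    )
    def test_write_read_identity(self, tmp_path_factory, demo, drug, reac,
                                 outc, ther):
        tmp = tmp_path_factory.mktemp("rt")
        tables = QuarterTables(demo=demo, drug=drug, reac=reac,
                               outc=outc, ther=ther)
        write_quarter(tables, tmp, "RT")
        back = read_quarter(tmp, "RT")
        assert back.demo == demo
        assert back.drug == drug
        assert back.reac == reac
        assert back.outc == outc
        assert back.ther == ther
        assert back.parse_report.total_skipped == 0

    def test_empty_tables_give_header_only_files(self, tmp_path):
        paths = write_quarter(QuarterTables(), tmp_path, "E")
        assert len(paths) == 5
        for path in paths:
            assert len(path.read_text().splitlines()) == 1

    def test_simulated_extract_round_trips(self, tmp_path, small_sim):
        _, tables, _ = small_sim
        write_quarter(tables, tmp_path, "S")
        back = read_quarter(tmp_path, "S")
        assert back.counts() == tables.counts()
        assert back.demo == tables.demo
        assert back.drug == tables.drug


class TestPtSocDictionary:
    def test_lookup_is_case_and_whitespace_normalized(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("pt\tsoc\nNausea\tGastrointestinal disorders\n")
        d = read_pt_soc_dictionary(path)
        assert d["nausea"] == "Gastrointestinal disorders"
        assert d["  NAUSEA "] == "Gastrointestinal disorders"
        assert d.display("nausea") == "Nausea"
        with pytest.raises(KeyError):
            d["vomiting"]

    def test_header_only_file_gives_empty_mapping(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("pt\tsoc\n")
        assert len(read_pt_soc_dictionary(path)) == 0

    def test_conflicting_duplicate_names_the_pt(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("pt\tsoc\nNausea\tA\nnausea\tB\n")
        with pytest.raises(ValueError, match="[Nn]ausea"):
            read_pt_soc_dictionary(path)

    def test_consistent_duplicate_is_tolerated(self):
        d = PtSocDictionary([("Nausea", "GI"), ("NAUSEA", "GI")])
        assert len(d) == 1

    def test_packaged_dictionary_loads(self):
        d = default_dictionary()
        assert len(d) >= 70
        assert d["nausea"] == "Gastrointestinal disorders"
        assert d["dupuytren's contracture"] == (
            "Musculoskeletal and connective tissue disorders"
        )


class TestCodedReviews:
    def test_semicolon_pt_lists_split(self, tmp_path):
        path = tmp_path / "reviews.csv"
        path.write_text(
            "review_id,date,age,sex,pts\n"
            "R1,20230105,55,F,Nausea;Hiccups\n"
            "R2,20230106,41,M,\n"
        )
        reviews = read_coded_reviews(path)
        assert reviews[0].pts == ("Nausea", "Hiccups")
        assert reviews[1].pts == ()

    def test_missing_id_column_is_hard_error(self, tmp_path):
        path = tmp_path / "reviews.csv"
        path.write_text("id,pts\nR1,Nausea\n")
        with pytest.raises(ValueError, match="review_id"):
            read_coded_reviews(path)

    def test_round_trip_at_study_scale(self, tmp_path):
        reviews = [
            CodedReview(review_id=f"R{i}", age=float(30 + i % 40),
                        sex="F" if i % 4 else "M",
                        pts=("Nausea",) if i % 3 else ("Nausea", "Vomiting"))
            for i in range(422)
        ]
        path = write_coded_reviews(reviews, tmp_path / "r.csv")
        back = read_coded_reviews(path)
        assert len(back) == 422
        assert back == reviews
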