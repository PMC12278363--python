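"""Reader, deduplication, event flagging and drug-name normalization."""

import pandas as pd
import pytest

from pvsignal.errors import InputFormatError
from pvsignal.io import (EventDefinition, case_table, deduplicate,
                         exposure_matrix, flag_event_cases, iter_reports,
                         normalize_drug_names, parse_faers_dates,
                         read_quarter, _parse_age_years)


def _write_quarter(tmp_path, demo_rows, drug_rows=(), reac_rows=(),
                   ther_rows=()):
    headers = {
        "DEMO": "primaryid$caseid$caseversion$event_dt$sex$age$age_cod$wt$occp_cod",
        "DRUG": "primaryid$caseid$drug_seq$drugname$role_cod",
        "REAC": "primaryid$caseid$pt",
        "THER": "primaryid$caseid$dsg_drug_seq$start_dt",
    }
    rows = {"DEMO": demo_rows, "DRUG": drug_rows, "REAC": reac_rows,
            "THER": ther_rows}
    tmp_path.mkdir(parents=True, exist_ok=True)
    for name, header in headers.items():
        path = tmp_path / f"{name}24Q1.txt"
        path.write_text("\n".join([header, *rows[name]]) + "\n",
                        encoding="latin-1")
    return tmp_path


class TestReadQuarter:
    def test_roundtrip_counts(self, small_quarter):
        outdir, tables, config = small_quarter
        rs = read_quarter(outdir)
        assert rs.n_reports == len(tables.demo)
        assert rs.log["reports_read"] == len(tables.demo)

    def test_orphan_rows_dropped_and_counted(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["101$10$1$20200101$F$50$YR$60$MD"],
            drug_rows=["101$10$1$ASPIRIN$PS", "999$99$1$GHOST$PS"],
            reac_rows=["101$10$Nausea"],
        )
        rs = read_quarter(d)
        assert rs.log["orphan_drug"] == 1
        assert list(rs.drugs["drugname"]) == ["ASPIRIN"]

    def test_malformed_rows_dropped_and_counted(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["101$10$1$20200101$F$50$YR$60$MD", "101$10$1"],
            drug_rows=["101$10$1$ASPIRIN$PS"],
            reac_rows=["101$10$Nausea"],
        )
        rs = read_quarter(d)
        assert rs.log["malformed_demo"] == 1
        assert rs.n_reports == 1

    def test_missing_table_names_it(self, tmp_path):
        d = _write_quarter(tmp_path, demo_rows=["101$10$1$$F$$$$"])
        (d / "REAC24Q1.txt").unlink()
        with pytest.raises(InputFormatError, match="REAC"):
            read_quarter(d)

    def test_empty_demo_is_an_error(self, tmp_path):
        d = _write_quarter(tmp_path, demo_rows=[])
        with pytest.raises(InputFormatError, match="DEMO"):
            read_quarter(d)


class TestDeduplicate:
    def test_latest_version_survives(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["71$7$1$20200101$F$50$YR$60$MD",
                       "72$7$2$20200101$F$51$YR$60$MD"],
            drug_rows=["71$7$1$ASPIRIN$PS", "72$7$1$ASPIRIN$PS"],
            reac_rows=["71$7$Nausea", "72$7$Nausea"],
        )
        rs = deduplicate(read_quarter(d))
        assert list(rs.demo["primaryid"]) == ["72"]
        assert rs.demo["age_years"].iloc[0] == 51

    def test_idempotent(self, small_quarter):
        outdir, _, _ = small_quarter
        once = deduplicate(read_quarter(outdir))
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.demo, twice.demo)

    def test_no_shared_caseids_is_identity(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["11$1$1$$F$$$$", "21$2$1$$M$$$$"],
            drug_rows=["11$1$1$A$PS", "21$2$1$B$PS"],
            reac_rows=["11$1$X", "21$2$Y"],
        )
        rs = read_quarter(d)
        assert deduplicate(rs).n_reports == rs.n_reports

    def test_roundtrip_recovers_surviving_case_set(self, small_quarter):
        """generate -> write -> read -> dedup keeps exactly the generator's
        surviving versions, demographics included."""
        outdir, tables, _ = small_quarter
        rs = deduplicate(read_quarter(outdir))
        truth = tables.truth_cases
        assert set(rs.demo["caseid"]) == set(truth["caseid"].astype(str))
        surviving = tables.demo.drop_duplicates("caseid", keep="first") \
            .sort_values("caseid")
        # the generator's surviving version is caseversion max per case
        surviving = tables.demo.loc[
            tables.demo.groupby("caseid")["caseversion"].idxmax()]
        got = rs.demo.set_index("caseid")
        for row in surviving.itertuples(index=False):
            rec = got.loc[str(row.caseid)]
            assert rec["sex"] == row.sex
            assert str(rec["primaryid"]) == str(row.primaryid)


class TestEventFlagging:
    def test_case_insensitive_match(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["11$1$1$$F$$$$", "21$2$1$$F$$$$"],
            drug_rows=["11$1$1$A$PS", "21$2$1$A$PS"],
            reac_rows=["11$1$HYPOTHYROIDISM", "21$2$Nausea"],
        )
        rs = read_quarter(d)
        flags = flag_event_cases(rs, EventDefinition("hypo",
                                                     frozenset({"hypothyroidism"})))
        assert flags["1"] and not flags["2"]

    def test_flags_equal_generator_truth(self, small_quarter, event_def):
        outdir, tables, _ = small_quarter
        rs = deduplicate(read_quarter(outdir))
        flags = flag_event_cases(rs, event_def)
        truth = tables.truth_cases.set_index(
            tables.truth_cases["caseid"].astype(str))["event"].astype(bool)
        assert (flags.sort_index() == truth.sort_index()).all()

    def test_order_invariance(self, tmp_path):
        rows = ["11$1$Nausea", "11$1$Hypothyroidism"]
        d1 = _write_quarter(tmp_path / "a", ["11$1$1$$F$$$$"],
                            ["11$1$1$A$PS"], rows)
        d2 = _write_quarter(tmp_path / "b", ["11$1$1$$F$$$$"],
                            ["11$1$1$A$PS"], rows[::-1])
        ev = EventDefinition("hypo", frozenset({"Hypothyroidism"}))
        f1 = flag_event_cases(read_quarter(d1), ev)
        f2 = flag_event_cases(read_quarter(d2), ev)
        assert f1.equals(f2)

    def test_empty_term_list_rejected(self):
        with pytest.raises(InputFormatError):
            EventDefinition("empty", frozenset({"  "}))


class TestNormalization:
    def _rs(self, tmp_path, name):
        d = _write_quarter(tmp_path, ["11$1$1$$F$$$$"],
                           [f"11$1$1${name}$PS"], ["11$1$X"])
        return read_quarter(d)

    def test_synonym_mapping(self, tmp_path):
        rs = self._rs(tmp_path, "KEYTRUDA")
        out = normalize_drug_names(rs, {"keytruda": "pembrolizumab"})
        assert list(out.drugs["drugname"]) == ["pembrolizumab"]

    def test_unmapped_name_lowercased(self, tmp_path):
        rs = self._rs(tmp_path, "  ASPIRIN ")
        out = normalize_drug_names(rs, {"keytruda": "pembrolizumab"})
        assert list(out.drugs["drugname"]) == ["aspirin"]

    def test_idempotent(self, tmp_path):
        rs = self._rs(tmp_path, "KEYTRUDA")
        m = {"keytruda": "pembrolizumab"}
        once = normalize_drug_names(rs, m)
        twice = normalize_drug_names(once, m)
        pd.testing.assert_frame_equal(once.drugs, twice.drugs)


class TestParsing:
    @pytest.mark.parametrize("age, cod, years", [
        ("50", "YR", 50.0), ("50", "", 50.0), ("24", "MON", 2.0),
        ("6", "DEC", 60.0), ("730.5", "DY", 2.0), ("5", "DEC", 50.0),
    ])
    def test_age_units(self, age, cod, years):
        out = _parse_age_years(pd.Series([age]), pd.Series([cod]))
        assert out.iloc[0] == pytest.approx(years, rel=1e-3)

    def test_unparseable_age_missing(self):
        out = _parse_age_years(pd.Series(["abc", "-4", ""]),
                               pd.Series(["YR", "YR", "YR"]))
        assert out.isna().all()

    @pytest.mark.parametrize("raw, prec, ts", [
        ("20200212", "day", "2020-02-12"),
        ("202002", "month", "2020-02-01"),
        ("2020", "year", "2020-01-01"),
        ("", "missing", None),
        ("20201335", "missing", None),
    ])
    def test_date_precision(self, raw, prec, ts):
        dates, precs = parse_faers_dates(pd.Series([raw]))
        assert precs.iloc[0] == prec
        if ts is None:
            assert pd.isna(dates.iloc[0])
        else:
            assert dates.iloc[0] == pd.Timestamp(ts)


class TestCaseLevelViews:
    def test_exposure_matrix_matches_truth(self, small_quarter):
        outdir, tables, config = small_quarter
        rs = normalize_drug_names(deduplicate(read_quarter(outdir)))
        expo = exposure_matrix(rs, ["druga", "drugb"])
        truth = tables.truth_cases.set_index(
            tables.truth_cases["caseid"].astype(str))
        for drug in ("druga", "drugb"):
            got = expo[drug].sort_index()
            want = truth[f"exposed_drug{drug[-1].upper()}"].astype(bool) \
                .sort_index()
            assert (got == want).all(), drug

    def test_case_table_levels(self, small_quarter):
        outdir, _, _ = small_quarter
        ct = case_table(deduplicate(read_quarter(outdir)))
        assert set(ct["sex"].unique()) <= {"female", "male", "missing"}
        assert set(ct["occupation"].unique()) <= {
            "consumer", "lawyer", "physician", "other_health_professional",
            "pharmacist", "missing"}

    def test_iter_reports_materialises(self, tmp_path):
        d = _write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$F$50$YR$61.5$MD"],
            drug_rows=["11$1$1$ASPIRIN$PS"],
            reac_rows=["11$1$Nausea"],
            ther_rows=["11$1$1$20191201"],
        )
        (report,) = list(iter_reports(read_quarter(d)))
        assert report.sex == "female" and report.age_years == 50
        assert report.drugs[0].drug_name == "ASPIRIN"
        assert report.drugs[0].therapy_start_date == pd.Timestamp("2019-12-01")
        assert report.reactions == ("Nausea",)
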