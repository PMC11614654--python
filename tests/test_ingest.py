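"""Raw-file parsing, date precision, deduplication and target selection."""

import datetime

import numpy as np
import pytest
from hypothesis import given, strategies as st

from irbvigil._dates import parse_date
from irbvigil.ingest import (
    deduplicate_faers,
    jader_age_to_years,
    read_faers_quarter,
    read_jader,
    select_target_reports,
)

from conftest import make_corpus


def _write_faers(tmp_path, demo_rows, drug_rows, reac_rows, ther_rows=None):
    paths = {}
    tables = {
        "demo": ["PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$WT$WT_COD$OCCR_COUNTRY$OCCP_COD"] + demo_rows,
        "drug": ["PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME"] + drug_rows,
        "reac": ["PRIMARYID$PT"] + reac_rows,
    }
    if ther_rows is not None:
        tables["ther"] = ["PRIMARYID$DSG_DRUG_SEQ$START_DT$END_DT"] + ther_rows
    for key, lines in tables.items():
        p = tmp_path / f"{key}.txt"
        p.write_text("\n".join(lines) + "\n")
        paths[key] = p
    return paths


class TestDateParsing:
    @pytest.mark.parametrize("raw, date, precision", [
        ("20200417", datetime.date(2020, 4, 17), "day"),
        ("202004", datetime.date(2020, 4, 1), "month"),
        ("2020", datetime.date(2020, 1, 1), "year"),
        ("20190230", None, "missing"),   # invalid calendar day
        ("20191301", None, "missing"),   # invalid month
        ("", None, "missing"),
        ("n/a", None, "missing"),
    ])
    def test_precision_tracking(self, raw, date, precision):
        parsed = parse_date(raw)
        assert parsed.date == date
        assert parsed.precision == precision


class TestReadFaers:
    def test_minimal_fixture_row_counts(self, tmp_path):
        paths = _write_faers(
            tmp_path,
            ["1$C1$20200101$$F$50$YR$$$FR$MD",
             "2$C2$20200102$$M$$$$$US$CN",
             "3$C3$20200103$$$$$$$GB$"],
            ["1$1$PS$IRBESARTAN"],
            ["1$hyperkalaemia"],
        )
        corpus = read_faers_quarter(paths)
        assert corpus.n_reports == 3
        assert len(corpus.drugs) == 1
        assert len(corpus.reactions) == 1
        assert corpus.audit["skipped_rows"] == 0

    def test_invalid_receipt_date_retained_as_missing(self, tmp_path):
        paths = _write_faers(
            tmp_path,
            ["1$C1$20190230$$F$$$$$$"], ["1$1$PS$X"], ["1$pt"],
        )
        corpus = read_faers_quarter(paths)
        assert corpus.n_reports == 1
        row = corpus.reports.iloc[0]
        assert row["receipt_date"] is None
        assert row["receipt_precision"] == "missing"

    def test_year_only_therapy_start_marked_imprecise(self, tmp_path):
        paths = _write_faers(
            tmp_path,
            ["1$C1$20200101$$F$$$$$$"], ["1$1$PS$X"], ["1$pt"],
            ther_rows=["1$1$2019$"],
        )
        corpus = read_faers_quarter(paths)
        d = corpus.drugs.iloc[0]
        assert d["start_precision"] == "year"
        assert d["start_date"] == datetime.date(2019, 1, 1)

    def test_missing_required_table_is_hard_error(self, tmp_path):
        paths = _write_faers(tmp_path, ["1$C1$20200101$$F$$$$$$"], ["1$1$PS$X"], ["1$pt"])
        del paths["reac"]
        with pytest.raises(FileNotFoundError, match="REAC"):
            read_faers_quarter(paths)

    def test_event_date_copied_onto_reactions(self, tmp_path):
        paths = _write_faers(
            tmp_path,
            ["1$C1$20200101$20200417$F$$$$$$"], ["1$1$PS$X"], ["1$pt"],
        )
        corpus = read_faers_quarter(paths)
        r = corpus.reactions.iloc[0]
        assert r["event_date"] == datetime.date(2020, 4, 17)
        assert r["event_precision"] == "day"


class TestJader:
    @pytest.mark.parametrize("raw, expected", [
        ("60歳代", 65.0),
        ("20歳代", 25.0),
        ("45歳", 45.0),
        ("高齢者", np.nan),   # elderly: non-numeric category
        ("新生児", np.nan),
        ("不明", np.nan),
    ])
    def test_age_decade_midpoint(self, raw, expected):
        got = jader_age_to_years(raw)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_read_jader_roles_and_ages(self, tmp_path):
        (tmp_path / "demo.csv").write_text(
            "識別番号,性別,年齢,体重,転帰\nJ1,女性,60歳代,60kg代,回復\nJ2,男性,高齢者,,死亡\n",
            encoding="cp932")
        (tmp_path / "drug.csv").write_text(
            "識別番号,医薬品（一般名）,医薬品の関与,投与開始日\n"
            "J1,イルベサルタン,被疑薬,20200101\nJ1,アムロジピン,併用薬,\n",
            encoding="cp932")
        (tmp_path / "reac.csv").write_text(
            "識別番号,有害事象,有害事象発現日\nJ1,高カリウム血症,20200301\n", encoding="cp932")
        corpus = read_jader({"demo": tmp_path / "demo.csv", "drug": tmp_path / "drug.csv",
                             "reac": tmp_path / "reac.csv"})
        assert corpus.n_reports == 2
        r1 = corpus.reports.set_index("report_id").loc["J1"]
        assert r1["sex"] == "female" and r1["age_value"] == 65.0 and r1["age_raw"] == "60歳代"
        assert np.isnan(corpus.reports.set_index("report_id").loc["J2", "age_value"])
        assert list(corpus.drugs["role"]) == ["PS", "C"]


def _dedup_corpus(rows):
    return make_corpus(
        reports=[{"report_id": rid, "case_id": cid,
                  "receipt_date": d, "receipt_precision": "day" if d else "missing"}
                 for rid, cid, d in rows],
        drugs=[{"report_id": rid, "drug_name": "X"} for rid, _, _ in rows],
        reactions=[{"report_id": rid, "pt": "pt"} for rid, _, _ in rows],
    )


class TestDeduplication:
    def test_latest_receipt_date_kept(self):
        corpus = _dedup_corpus([
            ("1", "C1", datetime.date(2020, 1, 1)),
            ("2", "C1", datetime.date(2021, 1, 1)),
        ])
        out = deduplicate_faers(corpus)
        assert list(out.reports["report_id"]) == ["2"]
        assert out.audit["dedup_removed"] == 1
        # child tables follow
        assert set(out.drugs["report_id"]) == {"2"}

    def test_single_report_identity(self):
        corpus = _dedup_corpus([("1", "C1", datetime.date(2020, 1, 1))])
        out = deduplicate_faers(corpus)
        assert out.n_reports == 1 and out.audit["dedup_removed"] == 0

    def test_tie_break_prefers_higher_numeric_id(self):
        rows = [
            ("100021", "C1", datetime.date(2021, 1, 1)),
            ("100022", "C1", datetime.date(2021, 1, 1)),
            ("9", "C1", datetime.date(2020, 1, 1)),
        ]
        import itertools
        for perm in itertools.permutations(rows):
            out = deduplicate_faers(_dedup_corpus(list(perm)))
            assert list(out.reports["report_id"]) == ["100022"], perm

    def test_idempotent(self):
        corpus = _dedup_corpus([
            ("1", "C1", datetime.date(2020, 1, 1)),
            ("2", "C1", datetime.date(2021, 1, 1)),
            ("3", "C2", None),
        ])
        once = deduplicate_faers(corpus)
        twice = deduplicate_faers(once)
        assert list(once.reports["report_id"]) == list(twice.reports["report_id"])

    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, order):
        rows = [
            ("10", "C1", datetime.date(2020, 1, 1)),
            ("11", "C1", datetime.date(2020, 6, 1)),
            ("12", "C2", None),
            ("13", "C2", datetime.date(2019, 1, 1)),
            ("14", "C3", datetime.date(2020, 1, 1)),
            ("15", "C3", datetime.date(2020, 1, 1)),
        ]
        out = deduplicate_faers(_dedup_corpus([rows[i] for i in order]))
        assert sorted(out.reports["report_id"]) == ["11", "13", "15"]


class TestTargetSelection:
    @pytest.fixture
    def corpus(self):
        return make_corpus(
            reports=[{"report_id": "R1"}, {"report_id": "R2"}],
            drugs=[
                {"report_id": "R1", "drug_name": "IRBESARTAN", "role": "PS"},
                {"report_id": "R1", "drug_name": "ASPIRIN", "role": "C", "drug_seq": 2},
                {"report_id": "R2", "drug_name": "ASPIRIN", "role": "PS"},
            ],
            reactions=[{"report_id": "R1", "pt": "p"}, {"report_id": "R2", "pt": "p"}],
        )

    def test_primary_suspect_name_match(self, corpus):
        out = select_target_reports(corpus, ["IRBESARTAN"])
        assert list(out.reports["report_id"]) == ["R1"]

    def test_any_role_filter(self, corpus):
        out = select_target_reports(corpus, ["ASPIRIN"], role_filter={"PS", "SS", "C", "I"})
        assert sorted(out.reports["report_id"]) == ["R1", "R2"]
        # with the default PS-only filter, R1's concomitant aspirin does not count
        ps_only = select_target_reports(corpus, ["ASPIRIN"])
        assert list(ps_only.reports["report_id"]) == ["R2"]

    def test_substring_matches_dose_suffix(self):
        corpus = make_corpus(
            reports=[{"report_id": "R1"}],
            drugs=[{"report_id": "R1", "drug_name": "APROVEL 300MG"}],
            reactions=[{"report_id": "R1", "pt": "p"}],
        )
        assert select_target_reports(corpus, ["APROVEL"]).n_reports == 1
        with pytest.warns(UserWarning):
            assert select_target_reports(corpus, ["APROVEL"], match="exact").n_reports == 0

    def test_selection_is_subset_with_matching_entry(self, injected_corpus):
        out = select_target_reports(injected_corpus, ["IRBESARTAN"])
        assert out.n_reports <= injected_corpus.n_reports
        # brute-force re-scan: every retained report has a matching PS entry
        by_report = out.drugs.groupby("report_id")
        for rid, grp in by_report:
            assert ((grp["role"] == "PS")
                    & grp["drug_name"].str.upper().str.contains("IRBESARTAN")).any()
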