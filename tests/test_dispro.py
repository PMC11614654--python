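"""2×2 construction, the four estimators, thresholds and multiplicity."""

import math

import numpy as np
import pytest
from scipy import stats

from irbvigil.cohort import MeddraMap
from irbvigil.dispro import (
    ContingencyTable,
    ScanConfig,
    bonferroni_adjust,
    build_contingency,
    compute_bcpnn,
    compute_prr,
    compute_ror,
    evaluate_thresholds,
    report_event_pairs,
    run_signal_scan,
)

from conftest import make_corpus


def _random_tables(rng, n, lo=1, hi=500):
    return [ContingencyTable(*(int(x) for x in rng.integers(lo, hi, size=4)))
            for _ in range(n)]


class TestContingency:
    def _four_report_corpus(self):
        return make_corpus(
            reports=[{"report_id": r} for r in "R1 R2 R3 R4".split()],
            drugs=[{"report_id": "R1", "drug_name": "drugX"},
                   {"report_id": "R2", "drug_name": "drugX"},
                   {"report_id": "R3", "drug_name": "drugY"},
                   {"report_id": "R4", "drug_name": "drugY"}],
            reactions=[{"report_id": "R1", "pt": "p"}, {"report_id": "R2", "pt": "q"},
                       {"report_id": "R3", "pt": "p"}, {"report_id": "R4", "pt": "q"}],
        )

    def test_exhaustive_enumeration(self):
        corpus = self._four_report_corpus()
        pairs = report_event_pairs(corpus, None, level="pt")
        t = build_contingency(pairs, {"R1", "R2"}, "p")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_repeated_pt_counts_once(self):
        corpus = make_corpus(
            reports=[{"report_id": "R1"}, {"report_id": "R2"}],
            drugs=[{"report_id": "R1", "drug_name": "X"},
                   {"report_id": "R2", "drug_name": "Y"}],
            reactions=[{"report_id": "R1", "pt": "p"}, {"report_id": "R1", "pt": "p"},
                       {"report_id": "R2", "pt": "q"}],
        )
        pairs = report_event_pairs(corpus, None, level="pt")
        t = build_contingency(pairs, {"R1"}, "p")
        assert t.a == 1

    def test_two_pts_one_soc_count_once(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("pt\tpt_code\tsoc\tsoc_code\npa\t1\tS\t100\npb\t2\tS\t100\n")
        meddra = MeddraMap.from_file(p)
        corpus = make_corpus(
            reports=[{"report_id": "R1"}, {"report_id": "R2"}],
            drugs=[{"report_id": "R1", "drug_name": "X"},
                   {"report_id": "R2", "drug_name": "Y"}],
            reactions=[{"report_id": "R1", "pt": "pa"}, {"report_id": "R1", "pt": "pb"},
                       {"report_id": "R2", "pt": "pa"}],
        )
        pairs = report_event_pairs(corpus, meddra, level="soc")
        t = build_contingency(pairs, {"R1"}, "S")
        assert t.a == 1

    def test_marginals_conserved_small_corpora(self, injected_corpus, meddra):
        sub = injected_corpus.subset(injected_corpus.reports["report_id"].head(50))
        pairs = report_event_pairs(sub, meddra, level="pt")
        targets = set(sub.reports["report_id"].head(20))
        for term in pairs["term"].unique()[:15]:
            t = build_contingency(pairs, targets, term)
            assert t.n == len(pairs)
            # brute-force recount
            a_bf = len(pairs[(pairs["term"] == term) & pairs["report_id"].isin(targets)])
            assert t.a == a_bf


class TestRor:
    def test_arithmetic(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(math.exp(math.log(11.0) - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(math.log(11.0) + 1.959963984540054 * se))
        assert not corrected

    def test_independence_gives_one(self):
        ror, *_ = compute_ror(ContingencyTable(5, 50, 50, 500))
        assert ror == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(3, 0, 5, 100))
        assert corrected and np.isfinite(ror)
        ror2, *_ , c2 = compute_ror(ContingencyTable(3, 0, 5, 100), zero_cell="none")
        assert np.isnan(ror2) and not c2

    def test_published_renal_row_is_positive(self):
        # ROR 3.33 (3.13-3.53), 1,124 reports: comfortably past a>=3 and lower bound>1
        flags = evaluate_thresholds(1124, 3.13, 3.19, 1716.22, 0.01, 3.00)
        assert flags["ror_pos"] and flags["all_four_pos"]


class TestPrr:
    def test_arithmetic(self):
        prr, chi2, p = compute_prr(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)
        assert 0 < p < 1

    def test_independence(self):
        prr, chi2, _ = compute_prr(ContingencyTable(5, 50, 50, 500))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=0.2)

    def test_chi2_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for t in _random_tables(rng, 300):
            _, chi2, p = compute_prr(t)
            ref = stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_ror_at_least_prr_when_prr_above_one(self):
        rng = np.random.default_rng(7)
        checked = 0
        for t in _random_tables(rng, 400):
            prr, *_ = compute_prr(t)
            ror, *_ = compute_ror(t)
            if np.isfinite(prr) and prr >= 1.0:
                assert ror >= prr - 1e-12
                checked += 1
        assert checked > 50


class TestBcpnn:
    def test_zero_a_is_finite_negative(self):
        ic, ic025 = compute_bcpnn(ContingencyTable(0, 1, 1, 1))
        assert np.isfinite(ic) and ic < 0 and ic025 < ic

    def test_independence_large_table_near_zero(self):
        ic, _ = compute_bcpnn(ContingencyTable(100, 900, 900, 8100))
        assert abs(ic) < 0.05

    def test_fixed_offset_width_exact(self):
        t = ContingencyTable(30, 300, 200, 5000)
        ic, ic025 = compute_bcpnn(t, method="fixed_offset", offset=1.67)
        assert ic - ic025 == pytest.approx(1.67)

    def test_closed_form_matches_dirichlet_sampling(self):
        # oracle: sample the Beta posteriors of p11, p1., p.1 and plug the
        # sampled means into the information-component ratio
        rng = np.random.default_rng(11)
        for t in _random_tables(rng, 100, lo=5, hi=400):
            a, b, c = t.a, t.b, t.c
            n = t.n
            a1 = b1 = 1.0
            al = be = 2.0
            g11 = 1.0
            gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
            m = 200_000
            p11 = rng.beta(a + g11, n - a + gamma - g11, size=m).mean()
            p1_ = rng.beta(a + b + a1, n - (a + b) + al - a1, size=m).mean()
            p_1 = rng.beta(a + c + b1, n - (a + c) + be - b1, size=m).mean()
            ic_mc = math.log2(p11 / (p1_ * p_1))
            ic, _ = compute_bcpnn(t)
            assert abs(ic - ic_mc) < 0.05

    def test_monotone_in_a(self):
        prev = None
        for a in (5, 10, 20, 40):
            t = ContingencyTable(a, 100, 100, 5000)
            ic, _ = compute_bcpnn(t)
            ror, *_ = compute_ror(t)
            prr, *_ = compute_prr(t)
            if prev is not None:
                assert ic > prev[0] and ror > prev[1] and prr > prev[2]
            prev = (ic, ror, prr)


class TestThresholds:
    def test_published_jader_metabolism_row_all_four(self):
        flags = evaluate_thresholds(94, 4.14, 4.45, 260.87, 0.48, 3.55)
        assert flags == {"ror_pos": True, "prr_pos": True, "bcpnn_pos": True,
                         "mgps_pos": True, "all_four_pos": True}

    def test_published_faers_metabolism_fails_bcpnn(self):
        flags = evaluate_thresholds(1229, 3.04, 3.08, 1760.26, -0.05, 2.9)
        assert flags["ror_pos"] and flags["prr_pos"] and flags["mgps_pos"]
        assert not flags["bcpnn_pos"] and not flags["all_four_pos"]

    def test_minimum_count_rule(self):
        flags = evaluate_thresholds(2, 50.0, 80.0, 500.0, 3.0, 10.0)
        assert not flags["ror_pos"] and not flags["prr_pos"]
        assert flags["bcpnn_pos"] and flags["mgps_pos"] and not flags["all_four_pos"]

    def test_nan_statistics_never_positive(self):
        flags = evaluate_thresholds(10, np.nan, np.nan, np.nan, np.nan, np.nan)
        assert not any(flags.values())


class TestBonferroni:
    def test_threshold_scale(self):
        assert 0.05 / 219 == pytest.approx(2.2831e-4, rel=1e-3)
        p = bonferroni_adjust([1e-6, 0.3], n_tests=219)
        assert p[0] == pytest.approx(219e-6)
        assert p[1] == 1.0  # capped

    def test_single_test_unchanged(self):
        assert bonferroni_adjust([0.03], n_tests=1)[0] == pytest.approx(0.03)


class TestScan:
    def test_injected_signal_recovered(self, injected_scan):
        row = injected_scan.set_index("term").loc["pt_005"]
        assert bool(row["all_four_pos"])
        assert row["a"] >= 20

    def test_sorted_by_count_and_volcano_columns(self, injected_scan):
        assert (injected_scan["a"].to_numpy()[:-1] >= injected_scan["a"].to_numpy()[1:]).all()
        assert {"log2_ror", "neglog10_p_adj"} <= set(injected_scan.columns)
        assert (injected_scan["p_adj"] >= injected_scan["p_raw"] - 1e-15).all()

    def test_interval_orderings(self, injected_scan):
        s = injected_scan.dropna(subset=["ror"])
        assert (s["ror_lo95"] <= s["ror"] + 1e-12).all()
        assert (s["ror"] <= s["ror_hi95"] + 1e-12).all()
        assert (s["ic025"] <= s["ic"]).all()
        assert (s["ebgm05"] < s["ebgm"] + 1e-9).all()
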