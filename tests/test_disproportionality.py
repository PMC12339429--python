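"""Disproportionality statistics against closed-form and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_record, make_report_set
from pvmr.disproportionality import (
    ContingencyTable,
    chi_square,
    classify_signal,
    contingency_table,
    ic,
    prr,
    ror,
    volcano_stats,
)
from pvmr.reports import ReportSet

cells = st.integers(min_value=1, max_value=50)


class TestContingency:
    def test_one_report_per_cell(self):
        rs = make_report_set([(True, True, 1), (True, False, 1),
                              (False, True, 1), (False, False, 1)])
        t = contingency_table(rs, "somatropin", 10061019)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_set_semantics_single_contribution(self):
        # drug and PT each listed "twice" collapse by set semantics
        r = make_record(
            drugs=("somatropin", "somatropin "),
            pts=((10061019, "brain neoplasm"), (10061019, "brain neoplasm")),
        )
        t = contingency_table(ReportSet([r, make_record(report_id="R2",
                                                        drugs=("ibuprofen",),
                                                        pts=((1, "x"),))]),
                              "somatropin", 10061019)
        assert t.a == 1 and t.n == 2

    def test_empty_set_is_domain_error(self):
        with pytest.raises(ValueError):
            contingency_table(ReportSet([]), "somatropin", 10061019)

    def test_matches_bruteforce_recount(self):
        from pvmr.simulate import SrsConfig, simulate_srs

        rs = simulate_srs(SrsConfig(n_reports=10_000, p_drug=0.05,
                                    p_event_background=0.01, rr=5, seed=11))
        t = contingency_table(rs, "somatropin", 10061019)
        a = b = c = d = 0
        for r in rs.records:
            hd = "somatropin" in r.drugs
            he = 10061019 in {code for code, _ in r.pts}
            if hd and he:
                a += 1
            elif hd:
                b += 1
            elif he:
                c += 1
            else:
                d += 1
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.n == len(rs)


class TestRor:
    def test_symmetric_table(self):
        s = ror(ContingencyTable(10, 10, 10, 10))
        assert s.point == pytest.approx(1.0)
        assert not s.flag

    def test_worked_example(self):
        s = ror(ContingencyTable(20, 80, 100, 9800))
        assert s.point == pytest.approx(24.5)
        assert s.interval_low == pytest.approx(14.45, abs=0.005)
        assert s.interval_high == pytest.approx(41.55, abs=0.005)
        assert s.flag

    def test_a_below_3_never_flags(self):
        s = ror(ContingencyTable(2, 10, 10, 1000))
        assert not s.flag

    def test_zero_cell_haldane(self):
        s = ror(ContingencyTable(3, 0, 0, 997))
        assert s.corrected and math.isfinite(s.point)


class TestPrr:
    def test_symmetric_table(self):
        s = prr(ContingencyTable(10, 10, 10, 10))
        assert s.point == pytest.approx(1.0)
        assert s.chi2 == pytest.approx(0.0)
        assert not s.flag

    def test_worked_example_with_chi2_oracle(self):
        t = ContingencyTable(20, 80, 100, 9800)
        s = prr(t)
        assert s.point == pytest.approx(19.8)
        # expected-counts oracle for the Pearson statistic
        n = t.n
        obs = np.array([[20, 80], [100, 9800]], float)
        rows, cols = obs.sum(1), obs.sum(0)
        exp = np.outer(rows, cols) / n
        assert s.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)
        assert s.flag == (s.chi2 >= 4)

    def test_zero_cells_corrected_point_finite(self):
        s = prr(ContingencyTable(3, 0, 0, 997))
        assert math.isfinite(s.point) and s.corrected
        assert s.flag == (s.point >= 2 and s.chi2 >= 4)

    def test_zero_margin_is_domain_error(self):
        with pytest.raises(ValueError):
            prr(ContingencyTable(0, 0, 5, 5))


class TestIc:
    def test_observed_equals_expected_is_flat(self):
        # a == expected with large a: IC ~ 0
        s = ic(ContingencyTable(100, 900, 900, 8100))
        assert s.point == pytest.approx(0.0, abs=0.01)
        assert not s.flag

    def test_worked_example(self):
        t = ContingencyTable(20, 80, 100, 9800)
        assert t.expected_a == pytest.approx(1.2)
        s = ic(t)
        assert s.point == pytest.approx(math.log(20.5 / 1.7) / math.log(2), rel=1e-12)
        assert s.point == pytest.approx(3.592, abs=5e-4)

    def test_ic025_symbolic_plugin(self):
        t = ContingencyTable(3, 97, 27, 9873)  # expected ~0.1 scale
        s = ic(t)
        expected = (t.a + t.b) * (t.a + t.c) / t.n
        point = math.log2(3.5 / (expected + 0.5))
        assert s.interval_low == pytest.approx(point - 3.3 / math.sqrt(3.5)
                                               - 2 / 3.5 ** 1.5, rel=1e-12)


class TestClassify:
    def test_two_of_three_rule(self):
        # strong-signal table: all three flags on
        res = classify_signal("somatropin", "brain neoplasm",
                              ContingencyTable(20, 80, 100, 9800))
        assert res.n_positive_methods == 3 and res.is_signal
        # null table: none on
        res = classify_signal("somatropin", "brain neoplasm",
                              ContingencyTable(10, 10, 10, 10))
        assert res.n_positive_methods == 0 and not res.is_signal

    def test_planted_rr_12_all_methods_flag(self):
        from pvmr.simulate import SrsConfig, simulate_srs

        rs = simulate_srs(SrsConfig(n_reports=50_000, p_drug=0.02,
                                    p_event_background=0.002, rr=12, seed=7))
        t = contingency_table(rs, "somatropin", 10061019)
        res = classify_signal("somatropin", "brain neoplasm", t)
        # oracle: evaluate each criterion directly from the counts
        r, p, i = res.stats
        assert r.flag == (t.a >= 3 and r.interval_low > 1)
        assert p.flag == (t.a >= 3 and p.point >= 2 and p.chi2 >= 4)
        assert i.flag == (i.interval_low > 0)
        assert res.n_positive_methods == 3 and res.is_signal


class TestInvariants:
    @given(cells, cells, cells, cells)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_sign_concordance(self, a, b, c, d):
        # all three statistics compare a against its expectation, so their
        # signs agree exactly (ad > bc <=> a > E[a], preserved by shrinkage)
        t = ContingencyTable(a, b, c, d)
        signs = {
            int(np.sign(round(math.log(ror(t).point), 9))),
            int(np.sign(round(math.log(prr(t).point), 9))),
            int(np.sign(round(ic(t).point, 9))),
        }
        assert len(signs) == 1

    @given(cells, cells, cells, cells)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_doubling_cells(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        t2 = t.doubled()
        assert ror(t2).point == pytest.approx(ror(t).point, rel=1e-12)
        assert prr(t2).point == pytest.approx(prr(t).point, rel=1e-12)
        w1 = math.log(ror(t).interval_high) - math.log(ror(t).interval_low)
        w2 = math.log(ror(t2).interval_high) - math.log(ror(t2).interval_low)
        assert w2 < w1

    def test_ror_equals_prr_iff_bd_shares_match(self):
        # constructed so b/(a+b) == d/(c+d): ROR == PRR exactly
        t = ContingencyTable(10, 10, 40, 40)
        assert ror(t).point == pytest.approx(prr(t).point, rel=1e-12)
        # generic table: they differ
        t = ContingencyTable(20, 80, 100, 9800)
        assert ror(t).point != pytest.approx(prr(t).point, rel=1e-3)

    @given(cells, cells, cells, cells)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_ic025_below_ic(self, a, b, c, d):
        s = ic(ContingencyTable(a, b, c, d))
        assert s.interval_low < s.point


class TestVolcano:
    def test_single_pt_bonferroni_is_identity(self):
        # every drug report lists only the target PT: m = 1
        rs = make_report_set([(True, True, 5), (False, True, 5), (False, False, 5)])
        df = volcano_stats(rs, "somatropin")
        assert len(df) == 1
        row = df.iloc[0]
        assert row.p_bonferroni == pytest.approx(row.p_fisher)

    def test_bonferroni_is_monotone_in_m(self):
        rs = make_report_set([(True, True, 5), (True, False, 5),
                              (False, True, 5), (False, False, 5)])
        df = volcano_stats(rs, "somatropin")
        assert len(df) == 2  # target PT + the decoy PT on drug/no-event reports
        for _, row in df.iterrows():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_fisher * len(df)))
            assert row.p_bonferroni >= row.p_fisher - 1e-15

    def test_no_association_gives_p_one(self):
        rs = make_report_set([(True, True, 10), (True, False, 10),
                              (False, True, 10), (False, False, 10)])
        df = volcano_stats(rs, "somatropin")
        target = df[df.pt_code == 10061019].iloc[0]
        assert target.p_fisher == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 5 distinct PTs co-reported with the drug, mixed association
        rng = np.random.default_rng(5)
        records = []
        i = 0
        for _ in range(400):
            has_drug = rng.random() < 0.3
            pts = []
            for j in range(5):
                rate = 0.25 if (j == 0 and has_drug) else 0.08
                if rng.random() < rate:
                    pts.append((100 + j, f"pt{j}"))
            if not pts:
                pts = [(999, "filler")]
            records.append(make_record(
                report_id=f"V{i}",
                drugs=("somatropin",) if has_drug else ("ibuprofen",),
                pts=tuple(pts)))
            i += 1
        rs = ReportSet(records)
        df = volcano_stats(rs, "somatropin")
        for _, row in df.iterrows():
            from pvmr.disproportionality import contingency_table as ct
            t = ct(rs, "somatropin", int(row.pt_code))
            # exhaustive hypergeometric-tail enumeration oracle
            M, K, n_draw = t.n, t.a + t.c, t.a + t.b
            pmf_obs = stats.hypergeom.pmf(t.a, M, K, n_draw)
            p_enum = sum(
                stats.hypergeom.pmf(x, M, K, n_draw)
                for x in range(max(0, K + n_draw - M), min(K, n_draw) + 1)
                if stats.hypergeom.pmf(x, M, K, n_draw) <= pmf_obs * (1 + 1e-9)
            )
            assert row.p_fisher == pytest.approx(p_enum, rel=1e-9, abs=1e-12)
            assert 0 <= row.p_fisher <= 1
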