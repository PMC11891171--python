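"""Disproportionality estimators: closed-form oracles, invariants, flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from faersig import (ContingencyTable, SignalCriteria, bcpnn_ic, build_tables,
                     compute_signals, flag_signals, ic_from_ebgm, mgps_ebgm,
                     prr_chi2, ror)
from faersig.signals import forest_plot_frame, ic_arrays, tables_to_records

cells = st.integers(min_value=1, max_value=5000)


class TestClosedForms:
    def test_independence_table_is_exactly_null(self):
        t = ContingencyTable(1, 9, 9, 81)
        assert ror(t)[0] == 1.0
        assert prr_chi2(t) == (1.0, 0.0)
        assert bcpnn_ic(t)[0] == 0.0
        assert mgps_ebgm(t)[0] == 1.0

    def test_hand_arithmetic_ror_ci(self):
        # SE = sqrt(1/20+1/10+1/10+1/20) = sqrt(0.3)
        r, lo, hi = ror(ContingencyTable(20, 10, 10, 20))
        assert r == 4.0
        assert lo == pytest.approx(4.0 * np.exp(-1.96 * np.sqrt(0.3)), rel=1e-12)
        assert lo == pytest.approx(1.367, abs=5e-4)
        assert hi == pytest.approx(11.70, abs=5e-3)

    def test_hand_arithmetic_prr_chi2_ebgm(self):
        t = ContingencyTable(20, 80, 10, 890)
        prr, chi2 = prr_chi2(t)
        assert prr == pytest.approx(18.0, rel=1e-12)
        assert chi2 == pytest.approx(17000**2 * 1000 / (100 * 900 * 30 * 970),
                                     rel=1e-12)
        assert chi2 == pytest.approx(110.35, abs=5e-3)
        assert mgps_ebgm(t)[0] == pytest.approx(20 * 1000 / (30 * 100), rel=1e-12)
        assert bcpnn_ic(t)[0] == pytest.approx(np.log2(6.667), abs=1e-4)

    def test_zero_cell_contract(self):
        t = ContingencyTable(0, 5, 5, 5)
        assert all(np.isnan(v) for v in ror(t))
        assert np.isnan(mgps_ebgm(t)[0])
        assert np.isnan(bcpnn_ic(t)[0])
        prr, chi2 = prr_chi2(ContingencyTable(5, 5, 0, 5))
        assert np.isnan(prr)

    def test_haldane_correction_defines_zero_cell_tables(self):
        t = ContingencyTable(0, 5, 5, 5)
        r, lo, hi = ror(t, zero_correction=0.5)
        assert r == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))
        assert lo < r < hi

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_chi2_matches_brute_force_pearson_on_random_tables(self):
        rng = np.random.default_rng(42)
        tables = rng.integers(1, 2000, size=(200, 4))
        _, chi2 = zip(*(prr_chi2(ContingencyTable(*map(int, row)))
                        for row in tables))
        expected = [chi2_contingency([[a, b], [c, d]], correction=False).statistic
                    for a, b, c, d in tables]
        np.testing.assert_allclose(chi2, expected, rtol=1e-9)


class TestInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic_is_log2_ebgm_and_bounds_are_ordered(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ebgm, ebgm05 = mgps_ebgm(t)
        ic, ic025 = bcpnn_ic(t)
        assert ic == pytest.approx(float(ic_from_ebgm(ebgm)), abs=1e-12)
        assert ebgm05 < ebgm
        assert ic025 < ic
        r, lo, hi = ror(t)
        assert lo < r < hi
        assert r > 0 and ebgm > 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.integers(2, 500), b=cells, c=st.integers(2, 500), d=cells)
    def test_point_estimates_strictly_increase_in_a_with_margins_fixed(
            self, a, b, c, d):
        lo_t = ContingencyTable(a - 1, b + 1, c + 1, d - 1) if d > 1 else None
        hi_t = ContingencyTable(a, b, c, d)
        if lo_t is None:
            return
        assert ror(hi_t)[0] > ror(lo_t)[0]
        assert prr_chi2(hi_t)[0] > prr_chi2(lo_t)[0]
        assert mgps_ebgm(hi_t)[0] > mgps_ebgm(lo_t)[0]
        assert bcpnn_ic(hi_t)[0] > bcpnn_ic(lo_t)[0]

    def test_ror_close_to_prr_for_rare_events(self, base_analysis):
        sig = base_analysis.signals_pt
        rare = sig[(sig["a"] >= 5) & (sig["a"] < 0.04 * (sig["a"] + sig["b"]))
                   & (sig["c"] < 0.04 * (sig["c"] + sig["d"]))]
        assert len(rare) >= 3
        rel = (rare["ror"] - rare["prr"]).abs() / rare["prr"]
        assert (rel < 0.05).all()

    def test_fixed_offset_ic_mode(self):
        ic, ic025 = ic_arrays(20, 80, 10, 890, variance="fixed", kappa=1.66)
        assert float(ic) - float(ic025) == pytest.approx(1.66)
        with pytest.raises(ValueError):
            ic_arrays(1, 1, 1, 1, variance="bogus")


class TestBuildTables:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "pt"])

    def test_exhaustive_two_report_universe(self):
        tgt = self._pairs([("1", "nausea")])
        cmp_ = self._pairs([("2", "headache")])
        out = build_tables(tgt, cmp_).set_index("event")
        assert out.loc["nausea", ["a", "b", "c", "d"]].tolist() == [1, 0, 0, 1]
        assert out.loc["headache", ["a", "b", "c", "d"]].tolist() == [0, 1, 1, 0]
        assert (out[["a", "b", "c", "d"]].sum(axis=1) == 2).all()

    def test_soc_level_counts_each_report_once(self, base_config):
        from faersig import make_dictionary
        dic = make_dictionary(base_config)
        tgt = self._pairs([("1", "nausea"), ("1", "vomiting"), ("2", "nausea")])
        cmp_ = self._pairs([("3", "headache")])
        out = build_tables(tgt, cmp_, dic, level="SOC").set_index("event")
        # report 1 contributes a single pair to the gastrointestinal SOC
        assert out.loc["gastrointestinal disorders", "a"] == 2

    def test_unresolvable_pt_counted(self, base_config):
        from faersig import make_dictionary
        dic = make_dictionary(base_config)
        tgt = self._pairs([("1", "nausea"), ("1", "not a pt")])
        out = build_tables(tgt, self._pairs([("2", "nausea")]), dic, level="SOC")
        assert out.attrs["unresolved_pairs"] == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_tables(self._pairs([]), self._pairs([("1", "x")]))

    def test_margins_reconcile_on_synthetic_data(self, base_analysis):
        tab = base_analysis.tables_pt
        assert (tab["a"] + tab["b"]).nunique() == 1  # fixed target margin
        assert (tab["c"] + tab["d"]).nunique() == 1
        recs = tables_to_records(tab)
        assert all(r.n_total == recs[0].n_total for r in recs)


class TestFlags:
    def _row(self, **kw):
        base = dict(event="e", event_code="", level="PT", a=5, b=5, c=5, d=5,
                    n=5, ror=3.0, ror_ci_low=1.2, ror_ci_high=5.0, prr=2.5,
                    chi2=10.0, ebgm=2.4, ebgm05=2.1, ic=1.2, ic025=0.3)
        base.update(kw)
        return pd.DataFrame([base])

    def test_all_criteria_met_gives_consensus(self):
        out = flag_signals(self._row())
        assert bool(out.loc[0, "consensus"])

    def test_single_failing_algorithm_breaks_consensus(self):
        out = flag_signals(self._row(ebgm05=1.5))
        assert not bool(out.loc[0, "mgps_pos"])
        assert not bool(out.loc[0, "consensus"])

    def test_case_count_floor_overrides_large_ror(self):
        out = flag_signals(self._row(n=2, ror=50.0, ror_ci_low=10.0))
        assert not bool(out.loc[0, "ror_pos"])

    def test_undefined_statistics_fail_their_flag(self):
        out = flag_signals(self._row(ic025=np.nan, ebgm05=np.nan))
        assert not out.loc[0, ["bcpnn_pos", "mgps_pos", "consensus"]].any()

    def test_criteria_thresholds_configurable(self):
        strict = SignalCriteria(ebgm05_gt=5.0)
        out = flag_signals(self._row(), strict)
        assert not bool(out.loc[0, "mgps_pos"])

    def test_compute_signals_round_trips_contingency_audit(self, base_analysis):
        """Signal rows are reproducible from the audit table alone."""
        redo = compute_signals(base_analysis.tables_pt)
        pd.testing.assert_frame_equal(redo, base_analysis.signals_pt)

    def test_forest_frame_mirrors_ror(self, base_analysis):
        f = forest_plot_frame(base_analysis.signals_pt)
        assert list(f.columns) == ["label", "estimate", "low", "high", "level", "n"]
        np.testing.assert_array_equal(f["estimate"], base_analysis.signals_pt["ror"])
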