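import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgcea import (
    StratifiedTables,
    TwoByTwoTable,
    analyze_claims,
    apply_or,
    chi_square_p,
    mantel_haenszel_or,
    odds_ratio,
    percent_reduction,
    proportion,
    relative_risk,
    sample_size_two_proportions,
    tables_from_claims,
)

# 90-day switch-cohort counts: 126/3235 SSIs with spECG, 122/2167 with rECG
T90 = TwoByTwoTable(126, 3235, 122, 2167, "90 days")
T30 = TwoByTwoTable(70, 3235, 85, 2167, "30 days")
TIDX = TwoByTwoTable(34, 3235, 39, 2167, "index")


class TestRates:
    @pytest.mark.parametrize("events,total,rate,printed_pct", [
        (122, 2167, 0.056299, 5.6),   # rECG 90-day
        (85, 2167, 0.039224, 3.9),    # rECG 30-day
        (39, 2167, 0.017997, 1.8),    # rECG index admission
        (126, 3235, 0.038949, 3.9),   # spECG 90-day
        (70, 3235, 0.021638, 2.2),    # spECG 30-day
        (0, 100, 0.0, 0.0),
    ])
    def test_proportion_and_percent_rounding(self, events, total, rate, printed_pct):
        p = proportion(events, total)
        assert p == pytest.approx(rate, abs=5e-6)
        assert round(p * 100, 1) == printed_pct

    def test_total_zero_rejected(self):
        with pytest.raises(ValueError):
            proportion(1, 0)

    def test_percent_reduction_90day(self):
        red = percent_reduction(proportion(122, 2167), proportion(126, 3235))
        assert red == pytest.approx(100 * (1 - 0.038949 / 0.056299), abs=0.05)
        assert percent_reduction(0.05, 0.05) == 0.0
        assert percent_reduction(0.05, 0.0) == 100.0
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.1)


class TestOddsAndRisk:
    def test_odds_ratio_matches_woolf_oracle(self):
        a, b, c, d = T90.cells
        or_oracle = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        est, (lo, hi) = odds_ratio(T90)
        assert est == pytest.approx(or_oracle, rel=1e-12)
        assert est == pytest.approx(0.679, abs=5e-4)
        assert lo == pytest.approx(or_oracle * math.exp(-1.96 * se), rel=1e-3)
        assert hi == pytest.approx(or_oracle * math.exp(1.96 * se), rel=1e-3)
        assert (round(lo, 3), round(hi, 3)) == (0.526, 0.877)

    def test_relative_risk_oracle(self):
        est, _ = relative_risk(T90)
        assert est == pytest.approx((126 / 3235) / (122 / 2167), rel=1e-12)
        assert est == pytest.approx(0.692, abs=5e-4)

    def test_balanced_table_gives_unity(self):
        t = TwoByTwoTable(10, 110, 20, 220)
        assert odds_ratio(t)[0] == pytest.approx(1.0)
        assert relative_risk(t)[0] == pytest.approx(1.0)

    def test_rare_events_or_close_to_rr(self):
        or_, _ = odds_ratio(T90)
        rr, _ = relative_risk(T90)
        assert abs(or_ - rr) / rr < 0.05

    @given(k=st.integers(min_value=2, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance_narrows_ci(self, k):
        scaled = TwoByTwoTable(126 * k, 3235 * k, 122 * k, 2167 * k)
        est0, ci0 = odds_ratio(T90)
        est, ci = odds_ratio(scaled)
        assert est == pytest.approx(est0, rel=1e-9)
        assert (ci[1] - ci[0]) < (ci0[1] - ci0[0])
        rr0, _ = relative_risk(T90)
        rr, _ = relative_risk(scaled)
        assert rr == pytest.approx(rr0, rel=1e-9)

    def test_zero_cell_triggers_continuity_warning(self):
        t = TwoByTwoTable(0, 50, 5, 50)
        with pytest.warns(UserWarning, match="continuity"):
            est, _ = odds_ratio(t)
        assert est > 0


class TestMantelHaenszel:
    def test_single_stratum_equals_crude(self):
        est, _ = mantel_haenszel_or(StratifiedTables([T90]))
        assert est == pytest.approx(odds_ratio(T90)[0], rel=1e-9)

    def test_null_strata_pool_to_unity(self):
        strata = [TwoByTwoTable(5, 55, 10, 110), TwoByTwoTable(30, 330, 20, 220)]
        est, _ = mantel_haenszel_or(StratifiedTables(strata))
        assert est == pytest.approx(1.0, rel=1e-9)

    def test_confounded_strata_recover_common_or(self):
        # two unbalanced strata built with the same within-stratum OR 0.74;
        # cells constructed from exact odds so the MH estimate is exact
        def cells(n1, n0, p0):
            odds0 = p0 / (1 - p0)
            p1 = 0.74 * odds0 / (1 + 0.74 * odds0)
            return TwoByTwoTable(p1 * n1, n1, p0 * n0, n0)

        s1 = cells(4000, 500, 0.02)   # mostly exposed, low risk
        s2 = cells(500, 4000, 0.20)   # mostly control, high risk
        est, _ = mantel_haenszel_or(StratifiedTables([s1, s2]))
        assert est == pytest.approx(0.74, abs=1e-9)
        crude = StratifiedTables([s1, s2]).crude()
        assert odds_ratio(crude)[0] != pytest.approx(0.74, abs=0.01)

    def test_all_degenerate_rejected(self):
        empty = TwoByTwoTable(0, 10, 0, 10)
        with pytest.raises(ValueError, match="degenerate"):
            mantel_haenszel_or(StratifiedTables([empty]))


class TestChiSquare:
    def test_switch_cohort_windows(self):
        assert chi_square_p(T90) == pytest.approx(0.0028, abs=5e-4)
        assert chi_square_p(T30) < 0.01
        assert chi_square_p(TIDX) < 0.05

    def test_identical_arms_p_one(self):
        t = TwoByTwoTable(10, 100, 10, 100)
        assert chi_square_p(t) == pytest.approx(1.0)

    def test_continuity_correction_is_switchable(self):
        assert chi_square_p(T90, correction=True) > chi_square_p(T90)


class TestApplyOr:
    def test_headline_or_on_claims_rate(self):
        assert apply_or(0.0549, 0.74) == pytest.approx(0.041215, abs=1e-5)

    def test_identity_and_zero(self):
        assert apply_or(0.3, 1.0) == pytest.approx(0.3)
        assert apply_or(0.0, 0.5) == 0.0
        with pytest.raises(ValueError):
            apply_or(1.0, 0.5)

    @given(p=st.floats(0.001, 0.6), om=st.floats(0.1, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_recovers_odds_ratio(self, p, om):
        q = apply_or(p, om)
        recovered = (q / (1 - q)) / (p / (1 - p))
        assert recovered == pytest.approx(om, rel=1e-9)

    def test_reduction_monotone_in_or(self):
        p = 0.0549
        reds = [percent_reduction(p, apply_or(p, om))
                for om in (0.5, 0.7, 0.9, 1.0)]
        assert all(a > b for a, b in zip(reds, reds[1:]))


class TestSampleSize:
    def test_detecting_15pct_reduction_from_5_5pct(self):
        n = sample_size_two_proportions(0.055, 0.15, alpha=0.05, power=0.80,
                                        sidedness="one")
        assert n == 17540

    def test_monotone_in_power_and_effect(self):
        n80 = sample_size_two_proportions(0.055, 0.15, power=0.80)
        n90 = sample_size_two_proportions(0.055, 0.15, power=0.90)
        assert n80 < n90
        n_double = sample_size_two_proportions(0.055, 0.30)
        assert n_double < n80 / 3.5  # doubling the difference ~quarters N


class TestClaimsTables:
    @pytest.fixture()
    def claims(self):
        rows = []
        for fac, dev, n, k in [("A", "rECG", 100, 6), ("A", "spECG", 120, 5),
                               ("B", "rECG", 80, 4), ("B", "spECG", 90, 3)]:
            for i in range(n):
                ssi = i < k
                rows.append({"facility_id": fac, "device": dev,
                             "ssi_index": int(ssi and i % 3 == 0),
                             "ssi_30d": int(ssi and i % 3 <= 1),
                             "ssi_90d": int(ssi)})
        return pd.DataFrame(rows)

    def test_crude_equals_sum_of_strata(self, claims):
        crude = tables_from_claims(claims, "90", "none")
        strat = tables_from_claims(claims, "90", "facility")
        pooled = strat.crude()
        assert pooled.cells == crude.cells

    def test_window_selects_column(self, claims):
        t90 = tables_from_claims(claims, "90")
        t30 = tables_from_claims(claims, "30")
        assert t30.control_events <= t90.control_events
        with pytest.raises(ValueError, match="window"):
            tables_from_claims(claims, "60")

    def test_analyze_claims_summary_structure(self, claims):
        out = analyze_claims(claims, "90", "facility")
        assert out["control"]["events"] == 10
        assert out["exposed"]["total"] == 210
        assert 0 < out["odds_ratio"]["estimate"]
        assert out["mantel_haenszel_or"]["n_strata"] == 2
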