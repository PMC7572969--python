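"""Statistical primitives against independent brute-force / closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pibquant.comparison_stats import (
    StatsInputError,
    agreement_regression,
    annual_percent_change,
    apply_mad_exclusion,
    bland_altman,
    bonferroni_adjust,
    build_comparison_report,
    fit_linear_quadratic_aic,
    hodges_lehmann,
    mad_outliers,
    mann_whitney_u,
    paired_t_test,
    standardize_followup,
    trt_variability,
)
from pibquant.tac_core import ParameterTable


# ---------------------------------------------------------------------------
# brute-force oracles


def mad_mask_bruteforce(values, k=3.0):
    med = sorted(values)[len(values) // 2] if len(values) % 2 else (
        sorted(values)[len(values) // 2 - 1] + sorted(values)[len(values) // 2]
    ) / 2
    devs = sorted(abs(x - med) for x in values)
    mad = devs[len(devs) // 2] if len(devs) % 2 else (
        devs[len(devs) // 2 - 1] + devs[len(devs) // 2]
    ) / 2
    if mad == 0:
        return np.array([x != med for x in values])
    return np.array([abs(x - med) > k * 1.4826 * mad for x in values])


def hl_bruteforce(a, b):
    diffs = sorted(x - y for x in a for y in b)
    n = len(diffs)
    return diffs[n // 2] if n % 2 else (diffs[n // 2 - 1] + diffs[n // 2]) / 2


def mw_exact_bruteforce(a, b):
    """Enumerate every group assignment of the pooled sample (no ties)."""
    pooled = list(a) + list(b)
    m = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), m):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    mn = m * (len(pooled) - m)
    lo = min(u_obs, mn - u_obs)
    p = (np.sum(us <= lo) + np.sum(us >= mn - lo)) / us.size
    return u_obs, min(1.0, p)


def ols_normal_equations(x, y, degree):
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


# ---------------------------------------------------------------------------


class TestTrtVariability:
    def test_identity(self):
        assert trt_variability(1.3, 1.3) == 0.0

    def test_hand_arithmetic(self):
        assert trt_variability(1.1, 0.9) == pytest.approx(20.0, abs=1e-12)

    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.01, 100))
    @settings(deadline=None)
    def test_symmetric_and_scale_invariant(self, t, r, c):
        assert trt_variability(t, r) == pytest.approx(trt_variability(r, t), rel=1e-12)
        assert trt_variability(c * t, c * r) == pytest.approx(
            trt_variability(t, r), rel=1e-9
        )

    def test_degenerate_pair_rejected(self):
        with pytest.raises(StatsInputError):
            trt_variability(1.0, -1.0)


class TestAnnualChange:
    def test_no_change(self):
        assert annual_percent_change(1.4, 1.4, 2.0) == 0.0

    def test_hand_arithmetic(self):
        assert annual_percent_change(1.0, 1.26, 2.6) == pytest.approx(10.0, abs=1e-12)

    @given(st.floats(0.5, 3), st.floats(0.5, 3), st.floats(0.5, 5), st.floats(0.1, 10))
    @settings(deadline=None)
    def test_scale_invariant_and_year_homogeneous(self, bl, fu, yr, c):
        base = annual_percent_change(bl, fu, yr)
        assert annual_percent_change(c * bl, c * fu, yr) == pytest.approx(base, abs=1e-9)
        assert annual_percent_change(bl, fu, 2 * yr) == pytest.approx(base / 2, abs=1e-9)

    def test_standardize_followup(self):
        assert standardize_followup(1.0, 1.2, 2.6) == pytest.approx(1.2)
        assert standardize_followup(1.0, 1.2, 1.3) == pytest.approx(1.4, abs=1e-12)


class TestMadOutliers:
    def test_hand_enumeration(self):
        mask = mad_outliers([1, 2, 3, 4, 100])
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_all_equal_nothing_flagged(self):
        assert not mad_outliers([2.0] * 6).any()

    def test_zero_mad_degenerate_rule(self):
        mask = mad_outliers([1.0, 1.0, 1.0, 1.0, 3.0])
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=25))
    @settings(deadline=None)
    def test_matches_bruteforce(self, values):
        np.testing.assert_array_equal(mad_outliers(values), mad_mask_bruteforce(values))


class TestAgreementRegression:
    def test_identity(self):
        g = np.array([1.0, 1.5, 2.0, 2.5])
        res = agreement_regression(g, g)
        assert (res.r, res.slope, res.intercept) == pytest.approx((1.0, 1.0, 0.0), abs=1e-12)

    def test_affine(self):
        g = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        res = agreement_regression(g, 0.5 * g + 0.1)
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        g = rng.uniform(1, 3, 30)
        m = 0.8 * g + rng.normal(0, 0.1, 30)
        res = agreement_regression(g, m)
        beta, _ = ols_normal_equations(g, m, 1)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        r_oracle = np.cov(g, m)[0, 1] / np.sqrt(np.var(g, ddof=1) * np.var(m, ddof=1))
        assert res.r == pytest.approx(r_oracle, abs=1e-10)


class TestBlandAltman:
    def test_identity(self):
        g = np.array([1.0, 2.0, 3.0])
        res = bland_altman(g, g)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0
        assert res.trend_slope == 0

    def test_constant_offset(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(g, g + 0.2)
        assert res.bias == pytest.approx(0.2, abs=1e-12)
        assert res.trend_slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_bias_trend(self):
        """method = 2*gold: d = gold, mean = 1.5*gold, so trend slope = 2/3."""
        g = np.linspace(1.0, 3.0, 8)
        res = bland_altman(g, 2.0 * g)
        assert res.trend_slope == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_limits_match_oracle(self, rng):
        g = rng.uniform(1, 3, 25)
        m = g + rng.normal(0.1, 0.2, 25)
        res = bland_altman(g, m)
        d = m - g
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert res.loa_low <= res.bias <= res.loa_high


class TestHodgesLehmann:
    def test_enumeration_example(self):
        assert hodges_lehmann([1, 2], [3, 4]) == pytest.approx(-2.0)

    def test_identical_groups(self):
        assert hodges_lehmann([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.floats(-5, 5),
    )
    @settings(deadline=None)
    def test_matches_bruteforce_and_shift_equivariance(self, a, b, c):
        hl = hodges_lehmann(a, b)
        assert hl == pytest.approx(hl_bruteforce(a, b), abs=1e-12)
        shifted = hodges_lehmann([x + c for x in a], b)
        assert shifted == pytest.approx(hl + c, abs=1e-9)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_u_complement_identity(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 5)
        u_ab, _ = mann_whitney_u(a, b)
        u_ba, _ = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=15)
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        pooled = rng.permutation(np.arange(1.0, m + n + 1))  # distinct -> no ties
        a, b = pooled[:m], pooled[m:]
        u, p = mann_whitney_u(a, b)
        u_oracle, p_oracle = mw_exact_bruteforce(a, b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_asymptotic_close_to_exact_at_n10(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        _, p_asym = mann_whitney_u(a, b)  # m + n > 12 -> asymptotic
        _, p_exact = mw_exact_bruteforce(a, b)
        assert p_asym == pytest.approx(p_exact, abs=0.02)

    def test_sign_concordance_with_hodges_lehmann(self, rng):
        """HL < 0 iff the first group's rank sum sits below its null expectation."""
        for _ in range(20):
            a = rng.normal(rng.uniform(-1, 1), 1.0, 8)
            b = rng.normal(0.0, 1.0, 9)
            hl = hodges_lehmann(a, b)
            if hl == 0:
                continue
            u, _ = mann_whitney_u(a, b)
            expected_u = len(a) * len(b) / 2
            assert (hl < 0) == (u < expected_u)


class TestPairedT:
    def test_symmetric_differences(self):
        t, p = paired_t_test([0, 0, 0, 0], [1, -1, 1, -1])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form(self, rng):
        bl = rng.normal(1.5, 0.2, 12)
        fu = bl + rng.normal(0.05, 0.1, 12)
        t, p = paired_t_test(bl, fu)
        d = fu - bl
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), d.size - 1)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_constant_shift_is_monotone_in_t(self, rng):
        bl = rng.normal(1.0, 0.1, 10)
        noise = rng.normal(0, 0.05, 10)
        t1, _ = paired_t_test(bl, bl + noise + 0.05)
        t2, _ = paired_t_test(bl, bl + noise + 0.50)
        assert t2 > t1


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 5, 0.05), (0.4, 5, 1.0), (0.3, 1, 0.3)])
    def test_examples(self, p, m, expected):
        assert bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.integers(1, 30))
    @settings(deadline=None)
    def test_never_decreases(self, ps, m):
        adj = bonferroni_adjust(ps, m)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


class TestModelSelection:
    def test_aic_matches_hand_computation(self):
        x = np.array([0.0, 0.4, 0.9, 1.5, 2.2, 3.0])
        y = np.array([0.2, 0.5, 1.4, 1.2, 2.6, 2.4])
        res = fit_linear_quadratic_aic(x, y)
        for degree, aic in ((1, res.aic_linear), (2, res.aic_quadratic)):
            _, rss = ols_normal_equations(x, y, degree)
            k = degree + 2
            assert aic == pytest.approx(6 * math.log(rss / 6) + 2 * k, abs=1e-9)
        assert res.delta_aic == pytest.approx(res.aic_linear - res.aic_quadratic, abs=1e-12)

    def test_quadratic_data_prefers_quadratic(self, rng):
        x = np.linspace(0, 2, 25)
        y = 1.0 + 0.5 * x - 2.0 * x**2 + rng.normal(0, 0.01, x.size)
        assert fit_linear_quadratic_aic(x, y).preferred == "quadratic"

    def test_linear_data_mostly_prefers_linear(self):
        """True-linear data: AIC picks linear at roughly its theoretical rate
        (the chi-square(1) > 2 overfit probability of ~16% is inherent to AIC)."""
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = np.linspace(0, 1, 20)
            y = 1.0 + 2.0 * x + r.normal(0, 0.01, x.size)
            if fit_linear_quadratic_aic(x, y).preferred == "linear":
                wins += 1
        assert wins >= 70

    def test_preferred_consistent_with_delta(self, rng):
        x = rng.uniform(0, 2, 15)
        y = rng.normal(0, 1, 15)
        res = fit_linear_quadratic_aic(x, y)
        assert (res.preferred == "quadratic") == (res.delta_aic > 0)


# ---------------------------------------------------------------------------
# report assembly


def _table_rows(subject, scan, role, values_by_key):
    rows = []
    for (region, method, ref), value in values_by_key.items():
        rows.append(
            {
                "subject_id": subject,
                "scan_id": scan,
                "region": region,
                "method": method,
                "reference_region": ref,
                "value": value,
                "excluded": False,
            }
        )
    return rows


class TestComparisonReport:
    def _trt_cohort(self, retest_offset=0.0):
        rows, meta = [], []
        rng = np.random.default_rng(9)
        for i in range(6):
            subj = f"s{i}"
            base = {}
            for method in ("DVR_RLOGAN", "SUVR_40_60"):
                for ref in ("GMCB", "WCB"):
                    base[("composite", method, ref)] = 1.0 + 0.2 * i + rng.uniform(0, 0.01)
                    base[("ctx_a", method, ref)] = 1.1 + 0.2 * i
            for role, off in (("test", 0.0), ("retest", retest_offset)):
                scan = f"{subj}_{role}"
                shifted = {k: v + off for k, v in base.items()}
                rows += _table_rows(subj, scan, role, shifted)
                meta.append(
                    {"subject_id": subj, "scan_id": scan, "scan_role": role,
                     "visual_status": "negative", "followup_years": None}
                )
        return ParameterTable.from_rows(rows), pd.DataFrame(meta)

    def test_zero_noise_trt_is_zero(self):
        table, meta = self._trt_cohort(retest_offset=0.0)
        report = build_comparison_report(table, meta)
        assert not report.trt.empty
        assert np.allclose(report.trt["mean_trt_pct"], 0.0, atol=1e-12)

    def test_method_identical_to_gold_agrees_perfectly(self):
        rows, meta = [], []
        rng = np.random.default_rng(4)
        for i in range(8):
            subj, scan = f"s{i}", f"s{i}_test"
            for region in ("ctx_a", "ctx_b", "ctx_c"):
                gold = float(rng.uniform(1.0, 2.5))
                rows += _table_rows(subj, scan, "test", {
                    (region, "DVR_PI", "GMCB"): gold,
                    (region, "DVR_RLOGAN", "GMCB"): gold,
                    (region, "DVR_SRTM", "GMCB"): 0.8 * gold,
                })
            meta.append({"subject_id": subj, "scan_id": scan, "scan_role": "test",
                         "visual_status": None, "followup_years": None})
        report = build_comparison_report(ParameterTable.from_rows(rows), pd.DataFrame(meta))
        ag = report.agreement.set_index("method")
        assert ag.loc["DVR_RLOGAN", "slope"] == pytest.approx(1.0, abs=1e-9)
        assert ag.loc["DVR_RLOGAN", "r"] == pytest.approx(1.0, abs=1e-9)
        assert ag.loc["DVR_SRTM", "slope"] == pytest.approx(0.8, abs=1e-9)
        ba = report.bland_altman.set_index("method")
        assert ba.loc["DVR_RLOGAN", "bias"] == pytest.approx(0.0, abs=1e-12)

    def test_mad_exclusion_flags_and_logs(self):
        rows = []
        values = [1.0, 1.05, 0.95, 1.02, 5.0]
        for i, v in enumerate(values):
            rows += _table_rows(f"s{i}", f"s{i}_test", "test",
                                {("ctx_a", "DVR_RLOGAN", "GMCB"): v})
        table, log = apply_mad_exclusion(ParameterTable.from_rows(rows))
        assert table.data["excluded"].sum() == 1
        assert log.iloc[0]["value"] == 5.0
        # report-level: excluded value does not poison downstream stats
        assert len(table.included()) == 4
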