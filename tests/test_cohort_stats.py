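"""Yield CIs, Fisher tests, burden + FDR, Welch t, age-cutoff sweep."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from germcsg.cohort_stats import (
    age_cutoff_sweep,
    burden_from_counts,
    combine_yield,
    diagnostic_yield,
    fisher_exact_2x2,
    percent,
    round_half_up,
    welch_age_test,
)
from germcsg.core_model import ValidationError


def ci_by_tail_inversion(x, n, conf=0.95):
    """Clopper-Pearson endpoints by root-finding on binomial tail probabilities."""
    alpha = 1 - conf
    lo = 0.0 if x == 0 else brentq(
        lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
    hi = 1.0 if x == n else brentq(
        lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
    return lo, hi


class TestDiagnosticYield:
    @pytest.mark.parametrize("x,n,pct,lo,hi", [
        (85, 1336, 6.4, 5.1, 7.8),
        (64, 1336, 4.8, 3.7, 6.1),
        (60, 1336, 4.5, 3.4, 5.7),
    ])
    def test_published_cis(self, x, n, pct, lo, hi):
        assert diagnostic_yield(x, n).as_percent == (pct, lo, hi)

    def test_zero_carriers_lower_bound_is_zero(self):
        est = diagnostic_yield(0, 100)
        assert est.ci_low == 0.0 and est.proportion == 0.0

    def test_carriers_exceeding_cohort_rejected(self):
        with pytest.raises(ValidationError):
            diagnostic_yield(10, 5)

    def test_random_counts_match_tail_inversion_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            n = int(rng.integers(5, 3000))
            x = int(rng.integers(0, n + 1))
            est = diagnostic_yield(x, n)
            lo, hi = ci_by_tail_inversion(x, n)
            assert est.ci_low == pytest.approx(lo, abs=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_ci_orders_around_proportion(self):
        est = diagnostic_yield(7, 50)
        assert 0 <= est.ci_low <= est.proportion <= est.ci_high <= 1


class TestCombineYield:
    def test_counts_sum(self):
        assert combine_yield(82, 1336, 3).as_percent == (6.4, 5.1, 7.8)

    def test_zero_is_zero(self):
        assert combine_yield(0, 100, 0).proportion == 0.0

    def test_dual_carrier_counted_once_with_ids(self):
        est = combine_yield(["a", "b", "c"], 100, ["c", "d"])
        assert est.numerator == 4

    def test_mixed_ids_and_counts_rejected(self):
        with pytest.raises(ValidationError):
            combine_yield(["a"], 100, 3)


class TestFisher:
    def test_sex_contrast_reproduces_published_p(self):
        _, p = fisher_exact_2x2(49, 805, 36, 446)
        assert round_half_up(p, 2) == 0.24

    def test_empty_margin_gives_p_one(self):
        odds, p = fisher_exact_2x2(0, 10, 0, 10)
        assert p == 1.0 and np.isnan(odds)

    def test_sample_odds_ratio(self):
        odds, _ = fisher_exact_2x2(10, 20, 5, 40)
        assert odds == pytest.approx((10 * 40) / (20 * 5))
        odds_inf, _ = fisher_exact_2x2(5, 0, 3, 10)
        assert odds_inf == float("inf")

    def test_small_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            n, r1, c1 = a + b + c + d, a + b, a + c
            p_obs = stats.hypergeom.pmf(a, n, r1, c1)
            total = sum(
                pk for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                if (pk := stats.hypergeom.pmf(k, n, r1, c1)) <= p_obs * (1 + 1e-7)
            )
            assert p == pytest.approx(total, rel=1e-7)


class TestBurden:
    def test_zero_carriers_everywhere_gives_p_and_q_one(self):
        res = burden_from_counts({"G1": (0, 0), "G2": (0, 0)}, 100, 200)
        assert all(r.p_value == 1.0 and r.q_value == 1.0 for r in res)

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(37)
        counts = {f"G{i}": (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                  for i in range(40)}
        res = burden_from_counts(counts, 500, 2000)
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_gene_order_does_not_change_q(self):
        counts = {"A": (10, 5), "B": (2, 30), "C": (0, 0), "D": (7, 7)}
        res1 = {r.gene_symbol: r.q_value for r in burden_from_counts(counts, 300, 900)}
        shuffled = {k: counts[k] for k in ["D", "B", "A", "C"]}
        res2 = {r.gene_symbol: r.q_value for r in burden_from_counts(shuffled, 300, 900)}
        assert res1 == res2

    def test_empty_controls_rejected(self):
        with pytest.raises(ValidationError):
            burden_from_counts({"G": (1, 0)}, 100, 0)


class TestWelch:
    def test_identical_groups_give_statistic_zero_p_one(self):
        g = [50.0, 60.0, 70.0]
        res = welch_age_test(g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_age_test([50.0], [60.0, 61.0])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            a = rng.normal(60, 12, size=int(rng.integers(5, 80)))
            b = rng.normal(62, 10, size=int(rng.integers(5, 80)))
            res = welch_age_test(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert res.statistic == pytest.approx(t)
            assert res.p_value == pytest.approx(p)

    def test_simulated_carrier_age_contrast_is_not_extreme(self):
        """A ~3-year mean shift at carrier n=85 yields small-to-moderate p values.

        The published per-participant ages are unavailable, so this is a wide
        consistency envelope on the simulated contrast, not a reproduction.
        """
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            carriers = np.clip(rng.normal(58.6, 12, 85), 13, 88)
            others = np.clip(rng.normal(61.5, 12, 1251), 13, 88)
            ps.append(welch_age_test(carriers, others).p_value)
        assert 0.001 < float(np.median(ps)) < 0.5


class TestAgeSweep:
    def test_published_sensitivity_fixture(self):
        carrier_ages = [30.0] * 14 + [60.0] * 46      # 14 of 60 under the cutoff
        cohort_ages = [30.0] * 18 + [60.0] * 1318
        (pt,) = age_cutoff_sweep(carrier_ages, cohort_ages, [46])
        assert pt.carriers_detected == 14
        assert percent(pt.sensitivity) == 23.3
        assert percent(pt.cohort_fraction_under_cutoff) == 1.3

    def test_cutoff_above_max_age_detects_all(self):
        (pt,) = age_cutoff_sweep([20.0, 80.0], [20.0, 80.0, 50.0], [200])
        assert pt.sensitivity == 1.0

    def test_sweep_monotone_in_cutoff(self):
        rng = np.random.default_rng(43)
        carriers = rng.uniform(13, 88, 50)
        cohort = rng.uniform(13, 88, 500)
        pts = age_cutoff_sweep(carriers, cohort, sorted(rng.uniform(10, 90, 15)))
        sens = [p.sensitivity for p in pts]
        assert all(a <= b for a, b in zip(sens, sens[1:]))


class TestRounding:
    def test_half_up_at_the_boundary(self):
        assert round_half_up(6.35, 1) == 6.4
        assert round_half_up(0.05, 1) == 0.1
        assert percent(0.063623) == 6.4
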