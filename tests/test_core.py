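"""Unit and property tests for the gene-level likelihood-ratio tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from proxecat import core
from proxecat.core import (
    DegenerateCountsError,
    EstimateError,
    GeneCounts,
    OverdispersionParam,
    RateEstimates,
    WeightScheme,
)

from conftest import (
    COHORT_GENES,
    EXAC_GENES,
    CASE_CONTROL,
    agrees_at_2sf,
    poisson_constrained_oracle,
)

quadruples = st.tuples(*[st.integers(min_value=0, max_value=60)] * 4).filter(
    lambda q: q[0] + q[2] > 0 and q[1] + q[3] > 0
)


class TestNullMles:
    @pytest.mark.parametrize(
        "quad, expected",
        [
            ((15, 0, 13, 18), (420 / 46, 270 / 46, 868 / 46, 558 / 46)),
            ((0, 8, 62, 16), (496 / 86, 192 / 86, 4836 / 86, 1872 / 86)),
            ((10, 5, 20, 10), (10, 5, 20, 10)),
        ],
    )
    def test_closed_form_values(self, quad, expected):
        est = core.null_mles(GeneCounts(*quad))
        got = (est.lam1f, est.lam1p, est.lam0f, est.lam0p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert est.constrained

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DegenerateCountsError):
            core.null_mles(GeneCounts(0, 0, 0, 0))

    @given(quadruples)
    @settings(max_examples=200, deadline=None)
    def test_constraint_and_conservation_identities(self, quad):
        counts = GeneCounts(*quad)
        est = core.null_mles(counts)
        scale = max(est.lam1f * est.lam0p, est.lam0f * est.lam1p, 1.0)
        assert est.ratio_residual() <= 1e-10 * scale
        assert sum(est.as_tuple()) == pytest.approx(counts.total, abs=1e-10)

    @given(quadruples)
    @settings(max_examples=60, deadline=None)
    def test_matches_numeric_constrained_maximization(self, quad):
        counts = GeneCounts(*quad)
        res = core.proxecat(counts)
        _, g_oracle = poisson_constrained_oracle(quad)
        assert res.statistic == pytest.approx(max(g_oracle, 0.0), abs=1e-6)


class TestLrt:
    @pytest.mark.parametrize("gene", list(COHORT_GENES))
    def test_reported_cohort_pvalues(self, gene):
        quad, printed = COHORT_GENES[gene]
        counts = GeneCounts(*quad)
        res = core.lrt_pvalue(counts, core.null_mles(counts))
        assert res.valid and res.df == 1
        assert agrees_at_2sf(res.p_value, printed)

    @pytest.mark.parametrize("gene", list(EXAC_GENES))
    def test_reported_exac_pvalues(self, gene):
        quad, printed = EXAC_GENES[gene]
        assert agrees_at_2sf(core.proxecat(GeneCounts(*quad)).p_value, printed)

    def test_exact_null_gives_zero_statistic(self):
        counts = GeneCounts(10, 5, 20, 10)
        res = core.lrt_pvalue(counts, core.null_mles(counts))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_rejects_unconstrained_estimates(self):
        counts = GeneCounts(15, 0, 13, 18)
        bad = RateEstimates(15, 0, 13, 18, constrained=False)
        with pytest.raises(EstimateError):
            core.lrt_pvalue(counts, bad)

    def test_rejects_constraint_violating_estimates(self):
        counts = GeneCounts(15, 0, 13, 18)
        bad = RateEstimates(10, 5, 20, 3, constrained=True)  # 30 != 100
        with pytest.raises(EstimateError):
            core.lrt_pvalue(counts, bad)

    def test_negative_estimates_rejected_at_construction(self):
        with pytest.raises(EstimateError):
            RateEstimates(-1, 2, 3, 4, constrained=True)

    @pytest.mark.parametrize(
        "quad",
        [(0, 0, 0, 0), (0, 5, 0, 7), (3, 0, 8, 0)],
        ids=["all-zero", "functional-margin-zero", "proxy-margin-zero"],
    )
    def test_degenerate_genes_flagged_not_raised(self, quad):
        res = core.proxecat(GeneCounts(*quad))
        assert not res.valid
        assert math.isnan(res.p_value)

    @given(quadruples)
    @settings(max_examples=100, deadline=None)
    def test_statistic_nonnegative_and_group_swap_invariant(self, quad):
        x1f, x1p, x0f, x0p = quad
        res = core.proxecat(GeneCounts(x1f, x1p, x0f, x0p))
        swapped = core.proxecat(GeneCounts(x0f, x0p, x1f, x1p))
        assert res.statistic >= 0
        assert res.p_value == pytest.approx(swapped.p_value, rel=1e-9)
        # G == 0 exactly when the observed ratios already satisfy the null
        if x1f * x0p == x0f * x1p:
            assert res.statistic == pytest.approx(0.0, abs=1e-9)
        else:
            assert res.statistic > 0


class TestWeights:
    def test_odd_and_even_medians(self):
        genes = [GeneCounts(r, 1, 5, 5) for r in (1, 2, 3)]
        assert core.weight_medians(genes).m1 == pytest.approx(2.0)
        genes = [GeneCounts(r, 1, 5, 5) for r in (1, 2, 3, 10)]
        assert core.weight_medians(genes).m1 == pytest.approx(2.5)

    def test_zero_proxy_genes_excluded_per_group(self):
        genes = [GeneCounts(4, 0, 6, 2), GeneCounts(3, 1, 9, 3)]
        w = core.weight_medians(genes)
        assert w.m1 == pytest.approx(3.0)  # only the second gene counts in cases
        assert w.m0 == pytest.approx(3.0)  # both eligible in controls

    def test_no_eligible_genes_raises(self):
        with pytest.raises(DegenerateCountsError):
            core.weight_medians([GeneCounts(4, 0, 6, 2), GeneCounts(3, 0, 9, 3)])

    def test_null_simulation_gives_unit_medians(self):
        rng = np.random.default_rng(42)
        x = rng.poisson(20.0, size=(4, 1000)).astype(float)
        genes = [GeneCounts(*x[:, i]) for i in range(1000)]
        w = core.weight_medians(genes)
        assert w.m1 == pytest.approx(1.0, abs=0.1)
        assert w.m0 == pytest.approx(1.0, abs=0.1)

    def test_apply_weights_reported_medians(self):
        # genome-wide medians from the real-data analysis force the arithmetic
        out = core.apply_weights(GeneCounts(15, 0, 13, 18), WeightScheme(3.00, 1.89))
        assert out.x1f == pytest.approx(5.0)
        assert out.x0f == pytest.approx(13 / 1.89)
        assert (out.x1p, out.x0p) == (0, 18)

    @pytest.mark.parametrize("quad", [(15, 0, 13, 18), (6, 2, 9, 3)])
    def test_identity_weights_leave_counts_and_pvalue_unchanged(self, quad):
        counts = GeneCounts(*quad)
        ident = WeightScheme(1.0, 1.0)
        assert core.apply_weights(counts, ident).as_tuple() == counts.as_tuple()
        assert core.proxecat_weighted(counts, ident).p_value == pytest.approx(
            core.proxecat(counts).p_value
        )

    def test_exact_division(self):
        out = core.apply_weights(GeneCounts(6, 2, 9, 3), WeightScheme(2, 3))
        assert out.as_tuple() == (3, 2, 3, 3)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightScheme(0.0, 1.0)

    def test_weighting_deflates_genomewide_lambda_under_coverage_confounding(self):
        # cases sequenced deeper: functional counts inflated x1.5 genome-wide
        rng = np.random.default_rng(7)
        n = 2000
        x1f = rng.poisson(30.0, n).astype(float)
        x1p, x0f, x0p = (rng.poisson(20.0, n).astype(float) for _ in range(3))
        lam_raw = core.lambda_gc(p_values=core.proxecat_pvalues(x1f, x1p, x0f, x0p))
        import pandas as pd

        w = core.weight_medians(pd.DataFrame({"x1f": x1f, "x1p": x1p, "x0f": x0f, "x0p": x0p}))
        lam_w = core.lambda_gc(p_values=core.proxecat_pvalues(x1f / w.m1, x1p, x0f / w.m0, x0p))
        assert abs(lam_w - 1.0) < abs(lam_raw - 1.0)
        assert lam_raw > 1.5  # the confounding genuinely inflates the raw test


class TestNegativeBinomial:
    def test_large_eta_recovers_poisson_mles(self):
        counts = GeneCounts(15, 0, 13, 18)
        nb = core.nb_null_mles(counts, 1e9)
        po = core.null_mles(counts)
        for a, b in zip(nb.as_tuple(), po.as_tuple()):
            assert a == pytest.approx(b, rel=1e-4, abs=1e-4)

    @pytest.mark.parametrize("eta", [0.5, 5.0, 1e4])
    def test_constraint_satisfying_counts_are_their_own_mles(self, eta):
        est = core.nb_null_mles(GeneCounts(10, 5, 20, 10), eta)
        assert est.as_tuple() == pytest.approx((10, 5, 20, 10), rel=1e-6)

    def test_matches_dense_grid_search(self):
        # brute-force oracle over (lam1p, lam0p, rho), iteratively refined
        eta = 5.0
        x = (15.0, 0.0, 13.0, 18.0)

        def ll(l1p, l0p, rho):
            out = 0.0
            for xi, lam in zip(x, (rho * l1p, l1p, rho * l0p, l0p)):
                out += stats.nbinom.logpmf(xi, eta, eta / (eta + max(lam, 1e-12)))
            return out

        lo = np.array([0.5, 2.0, 0.2])
        hi = np.array([20.0, 40.0, 10.0])
        best = None
        for _ in range(8):
            g1, g2, g3 = (np.linspace(a, b, 25) for a, b in zip(lo, hi))
            vals = np.array([[l1p, l0p, r, ll(l1p, l0p, r)]
                             for l1p in g1 for l0p in g2 for r in g3])
            best = vals[np.argmax(vals[:, 3])]
            span = (hi - lo) / 8
            lo = np.maximum(best[:3] - span, 1e-6)
            hi = best[:3] + span
        est = core.nb_null_mles(GeneCounts(*x), eta)
        assert est.lam1p == pytest.approx(best[0], abs=1e-3)
        assert est.lam0p == pytest.approx(best[1], abs=1e-3)
        assert est.lam1f / est.lam1p == pytest.approx(best[2], abs=1e-3)

    def test_pvalue_poisson_limit(self):
        counts = GeneCounts(15, 0, 13, 18)
        p_nb = core.proxecat_over(counts, 1e9).p_value
        p_po = core.proxecat(counts).p_value
        assert abs(p_nb - p_po) / p_po < 1e-3

    def test_degenerate_counts_flagged(self):
        assert not core.proxecat_over(GeneCounts(0, 5, 0, 7), 5.0).valid
        with pytest.raises(DegenerateCountsError):
            core.nb_null_mles(GeneCounts(0, 5, 0, 7), 5.0)

    def test_invalid_eta_rejected(self):
        with pytest.raises(ValueError):
            OverdispersionParam(0.0)


class TestComparators:
    @pytest.mark.parametrize("key", list(CASE_CONTROL))
    def test_reported_case_control_pvalues(self, key):
        (x1, x0, n1, n0), printed = CASE_CONTROL[key]
        res = core.case_control_lrt(x1, x0, n1, n0)
        assert agrees_at_2sf(res.p_value, printed)

    def test_proportional_rates_give_null(self):
        res = core.case_control_lrt(10, 40, 1000, 4000)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_total_flagged(self):
        assert not core.case_control_lrt(0, 0, 100, 100).valid

    def test_case_only_null_and_closed_form(self):
        assert core.case_only_lrt(20, 20, 0.001, 1000).p_value == pytest.approx(1.0)
        # x = 0, e = 10: G = 2*e = 20
        res = core.case_only_lrt(0, 10, 0.001, 1000)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(20, 1), rel=1e-9)

    def test_case_only_requires_positive_expectation(self):
        with pytest.raises(ValueError):
            core.case_only_lrt(3, 0.0, 0.001, 1000)


class TestUtilities:
    @pytest.mark.parametrize("alpha, expected", [(0.05, 0.045), (0.01, 0.009), (0.5, 0.45)])
    def test_alpha_adjustment(self, alpha, expected):
        assert core.adjust_alpha(alpha) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            core.adjust_alpha(alpha)

    def test_lambda_of_reference_median_is_one(self):
        stats_in = np.full(101, core.CHI2_1_MEDIAN)
        assert core.lambda_gc(statistics=stats_in) == pytest.approx(1.0)

    def test_lambda_of_null_chi_square_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.chisquare(1, size=100_000)
        assert core.lambda_gc(statistics=draws) == pytest.approx(1.0, abs=0.02)

    def test_lambda_matches_brute_force_median_ratio(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=5001)
        p[: len(p) // 2] *= 0.25  # half the p-values deflated
        expected = np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)
        assert core.lambda_gc(p_values=p) == pytest.approx(expected, rel=1e-12)

    def test_lambda_empty_input_rejected(self):
        with pytest.raises(ValueError):
            core.lambda_gc(p_values=[])
        with pytest.raises(ValueError):
            core.lambda_gc()
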