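import itertools

import numpy as np
import pytest
from scipy import stats as sps

from dtialps.cohort import CohortSpec, generate_cohort
from dtialps.stats import (
    DegenerateStatisticError,
    adjusted_regression,
    bh_fdr,
    change_rate,
    chi_square_2x2,
    mann_whitney,
    paired_t,
    run_full_analysis,
    shapiro_wilk_gate,
    spearman,
    two_sample_t,
    wilcoxon_signed_rank,
)


class TestChangeRate:
    def test_no_change_is_zero(self):
        assert change_rate(1.2, 1.2, 14) == 0.0

    def test_hand_evaluated_value(self):
        # ((1.14 - 1.0)/1.0)/14 * 100 = 1 % per day
        assert change_rate(1.0, 1.14, 14) == pytest.approx(1.0)

    def test_swap_identity(self):
        # rate(bl, fu, d) = -(fu/bl) * rate(fu, bl, d)
        bl, fu, d = 1.1, 1.3, 12
        assert change_rate(bl, fu, d) == pytest.approx(
            -(fu / bl) * change_rate(fu, bl, d)
        )

    @pytest.mark.parametrize("bl,days", [(0.0, 14), (-1.0, 14), (1.0, 0)])
    def test_invalid_inputs(self, bl, days):
        with pytest.raises(ValueError):
            change_rate(bl, 1.2, days)

    def test_vectorized(self):
        out = change_rate([1.0, 2.0], [1.14, 2.0], [14, 10])
        assert out == pytest.approx([1.0, 0.0])


class TestPairedT:
    def test_hand_formula_small_sample(self):
        before = np.array([1.0, 1.2, 1.4])
        after = np.array([0.9, 1.0, 1.3])
        d = before - after
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = paired_t(before, after)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.statistic == pytest.approx(4.0, rel=1e-12)
        assert res.df == 2
        assert res.p_raw == pytest.approx(
            2 * sps.t.sf(expected, df=2), rel=1e-12
        )

    def test_constant_shift_sign(self):
        rng = np.random.default_rng(0)
        after = rng.normal(size=10)
        assert paired_t(after + 0.5, after).statistic > 0
        assert paired_t(after - 0.5, after).statistic < 0

    def test_all_zero_differences_is_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestTwoSampleT:
    def test_pooled_hand_value(self):
        res = two_sample_t([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(-np.sqrt(1.5), rel=1e-12)
        assert res.df == 4

    def test_identical_samples_give_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_welch_flag(self):
        a = [0.0, 0.1, 0.2, 0.1]
        b = [1.0, 3.0, 5.0, 7.0]
        assert two_sample_t(a, b, pooled=False).df < 6

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestWilcoxon:
    def test_uniform_improvement_exact_tail(self):
        before = np.arange(6) + 1.0
        after = np.arange(6).astype(float)
        res = wilcoxon_signed_rank(before, after)
        assert res.p_raw == pytest.approx(2 / 2**6)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_sign_enumeration_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 10))
        before = rng.integers(0, 5, n).astype(float)
        after = rng.integers(0, 5, n).astype(float)
        d = before - after
        if np.all(d == 0):
            pytest.skip("degenerate draw")
        res = wilcoxon_signed_rank(before, after)
        dd = d[d != 0]
        ranks = sps.rankdata(np.abs(dd))
        ws = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(dd))
        ])
        p = min(1.0, 2 * min((ws <= res.statistic).mean(),
                             (ws >= res.statistic).mean()))
        assert res.p_raw == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(1)
        before = rng.normal(size=12)
        after = before + rng.normal(0.3, 1.0, 12)
        ours = wilcoxon_signed_rank(before, after)
        ref = sps.wilcoxon(before, after, method="exact")
        assert ours.p_raw == pytest.approx(ref.pvalue, rel=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(2)
        before = rng.normal(size=40)
        after = before - rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed_rank(before, after)
        assert 0 < res.p_raw < 0.05

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestMannWhitney:
    def test_identical_samples_u_is_half_product(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.estimate == pytest.approx(9 / 2)
        assert res.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_u_matches_pairwise_win_count(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.integers(0, 6, 4).astype(float)
        b = rng.integers(0, 6, 4).astype(float)
        res = mann_whitney(a, b)
        wins = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in a for y in b
        )
        assert res.estimate == pytest.approx(wins)

    def test_z_sign_orientation(self):
        res = mann_whitney([5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic > 0


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        res = chi_square_2x2(np.array([[10, 20], [5, 10]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula(self):
        table = np.array([[10, 0], [0, 10]])
        expected = ((10 - 5) ** 2 / 5) * 4  # sum (O-E)^2/E, all E = 5
        res = chi_square_2x2(table)
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(20.0)

    def test_sex_distribution_contrast(self):
        # 11/6 male/female vs 13/5
        res = chi_square_2x2(np.array([[11, 13], [6, 5]]))
        assert res.statistic == pytest.approx(0.23, abs=0.005)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestShapiroGate:
    def test_gaussian_samples_pass(self):
        normal = sum(
            shapiro_wilk_gate(np.random.default_rng(s).normal(size=200)) == "normal"
            for s in range(20)
        )
        assert normal >= 18

    def test_exponential_samples_fail(self):
        non_normal = sum(
            shapiro_wilk_gate(np.random.default_rng(s).exponential(size=50))
            == "non-normal"
            for s in range(20)
        )
        assert non_normal >= 18

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            shapiro_wilk_gate([2.0, 2.0, 2.0, 2.0])


class TestSpearman:
    def test_monotone_function_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        res = spearman(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)

    def test_rank_then_pearson_oracle_with_tie(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        rho = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        res = spearman(x, y)
        assert res.statistic == pytest.approx(rho, rel=1e-12)

    def test_zero_rank_variance_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAdjustedRegression:
    def test_group_free_outcome_gives_zero_beta(self):
        rng = np.random.default_rng(3)
        n = 40
        age = rng.uniform(50, 75, n)
        bmi = rng.uniform(20, 30, n)
        onset = rng.uniform(5, 40, n)
        sex = rng.integers(0, 2, n)
        group = np.repeat([1.0, 0.0], n // 2)
        outcome = 0.01 * age - 0.002 * bmi + 0.001 * onset  # no group effect
        res = adjusted_regression(outcome, group, age, sex, bmi, onset)
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_coverage_of_true_effect(self):
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            n = 200
            group = np.repeat([1.0, 0.0], n // 2)
            age = rng.uniform(50, 75, n)
            sex = rng.integers(0, 2, n)
            bmi = rng.uniform(20, 30, n)
            onset = rng.uniform(5, 40, n)
            y = 0.5 * group + rng.normal(0, 0.1, n)
            res = adjusted_regression(y, group, age, sex, bmi, onset)
            hits += res.ci_low <= 0.5 <= res.ci_high
        assert hits / n_rep >= 0.93

    def test_collinear_design_named(self):
        n = 30
        rng = np.random.default_rng(4)
        group = np.repeat([1.0, 0.0], n // 2)
        age = rng.uniform(50, 75, n)
        with pytest.raises(ValueError, match="collinear"):
            adjusted_regression(
                rng.normal(size=n), group, age, group, age, age
            )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_change_rate_family(self):
        out = bh_fdr([0.013, 0.079, 0.428])
        assert out[0] == pytest.approx(0.039, abs=0.001)
        assert out[2] == pytest.approx(0.428, abs=1e-9)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_family(self):
        assert bh_fdr([]).size == 0


class TestRunFullAnalysis:
    def test_report_structure_and_fdr_families(self, default_cohort):
        report = run_full_analysis(default_cohort)
        assert set(report.table3) == {"total", "stimulated", "non_stimulated"}
        assert report.fdr_families["table3_change_rate"] == 3
        for region in report.table3.values():
            assert region.p_fdr >= region.p_raw
        d = report.to_dict()
        assert d["meta"]["n_hf"] == 17
        import json

        json.dumps(d)  # fully serializable

    def test_missing_columns_reported(self, default_cohort):
        broken = default_cohort.drop(columns=["alps_total_bl", "wmft_fu"])
        with pytest.raises(ValueError, match="alps_total_bl"):
            run_full_analysis(broken)

    def test_hf_only_scope_changes_correlation_n(self, default_cohort):
        pooled = run_full_analysis(default_cohort, "pooled")
        hf_only = run_full_analysis(default_cohort, "hf-only")
        assert pooled.correlations["delta"]["total"]["wmft"].n == 35
        assert hf_only.correlations["delta"]["total"]["wmft"].n == 17

    def test_markdown_rendering(self, default_cohort):
        from dtialps.report import render_markdown

        text = render_markdown(run_full_analysis(default_cohort).to_dict())
        assert "Change-rate contrasts" in text
        assert "Non-stimulated hemisphere" in text
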