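"""Chi-square, Welch t, and the proportional-odds regression.

The ordinal fitter is cross-checked against two independent oracles: the
closed-form 2x2 cross-product odds ratio (two-level degeneracy) and
statsmodels' OrderedModel on a full multi-covariate cohort.
"""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from certscore.inference import (
    DesignSpec,
    ProportionalOddsModel,
    RankDeficientError,
    build_design_matrix,
    chi_square_test,
    fit_ordinal_logit,
    records_to_design_frame,
    refit_with_reference,
    simulate_ordinal_outcomes,
    t_test,
)
from certscore.rules import assess_batch
from certscore.scoring import score_batch
from certscore.simulate import SyntheticConfig, paper_calibrated_config, sample_cohort, split_cohort


@pytest.fixture(scope="module")
def cohort():
    """Default-size three-arm cohort with detected scores."""
    records, _ = split_cohort(sample_cohort(paper_calibrated_config(seed=3)))
    scores = score_batch(assess_batch(records))
    return records, scores


def _fit(y, X, names=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ProportionalOddsModel(y, X, names).fit()


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_two_by_two(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20.0 / 3.0)
        assert res.df == 1

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(1, 60, size=(rng.integers(2, 5), rng.integers(2, 5)))
            ours = chi_square_test(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])


class TestWelchT:
    def test_identical_groups(self):
        assert t_test([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_hand_computed_value(self):
        res = t_test([0, 0, 2, 2], [2, 2, 4, 4])
        assert res.statistic == pytest.approx(-2.449489742783178)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 2, 55)
        ours = t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)
        assert ours.df == pytest.approx(ref.df)

    def test_separated_planted_means_detectable(self):
        # two arms whose mean scores differ by >= 0.5 at n = 500 each
        rng = np.random.default_rng(2)
        a = rng.poisson(2.6, 500)
        b = rng.poisson(2.0, 500)
        assert t_test(a, b).pvalue < 0.01

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1, 2, 3])


class TestTwoLevelDegeneracy:
    def test_matches_cross_product_odds_ratio(self):
        y = np.array([1] * 30 + [0] * 70 + [1] * 15 + [0] * 85)
        x = np.array([1.0] * 100 + [0.0] * 100)[:, None]
        res = _fit(y, x, ["exposed"])
        assert res.odds_ratios[0] == pytest.approx((30 * 85) / (70 * 15), abs=1e-6)

    def test_matches_logistic_fit_coefficients(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 400).astype(float)[:, None]
        y = (rng.random(400) < 0.3 + 0.25 * x[:, 0]).astype(int)
        res = _fit(y, x)
        import statsmodels.api as sm

        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        assert res.params[0] == pytest.approx(ref.params[1], abs=1e-6)


class TestProportionalOddsFit:
    def test_matches_statsmodels_on_full_cohort(self, cohort):
        records, scores = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_ordinal_logit(records, scores)
        df = records_to_design_frame(records, scores)
        X, _, _ = build_design_matrix(df, DesignSpec())
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        ref = OrderedModel(df["score"], X, distr="logit").fit(
            method="bfgs", maxiter=500, disp=False
        )
        assert res.llf >= ref.llf - 1e-4  # our Newton matches or beats BFGS
        assert np.abs(ref.params[: X.shape[1]].to_numpy() - res.params).max() < 5e-3

    def test_loglikelihood_ascent(self, cohort):
        records, scores = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_ordinal_logit(records, scores)
        history = np.array(res.loglike_history)
        assert res.converged
        assert (np.diff(history) >= -1e-9).all()

    def test_cutpoints_strictly_increasing_and_pvalues_valid(self, cohort):
        records, scores = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_ordinal_logit(records, scores)
        assert (np.diff(res.cutpoints) > 0).all()
        assert ((res.pvalues >= 0) & (res.pvalues <= 1)).all()
        assert np.allclose(res.odds_ratios, np.exp(res.params))

    def test_null_covariate_unbiased_on_average(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (2000, 1)).astype(float)
        coefs = []
        for _ in range(20):
            y = simulate_ordinal_outcomes([-1.0, 0.0, 1.0], X, [0.0], rng)
            coefs.append(_fit(y, X).params[0])
        # mean coefficient within 4 standard errors of its replicate mean
        assert abs(np.mean(coefs)) < 4 * np.std(coefs) / np.sqrt(len(coefs)) + 1e-3

    def test_rank_deficiency_names_aliased_columns(self):
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        x = np.ones((8, 1))
        X = np.hstack([x, x])
        with pytest.raises(RankDeficientError, match="dup"):
            ProportionalOddsModel(y, X, ["a", "dup"])

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            ProportionalOddsModel(np.zeros(10), np.ones((10, 1)))

    def test_sparse_level_warning(self):
        y = np.array([0] * 50 + [1] * 50 + [2] * 2)
        with pytest.warns(UserWarning, match="fewer than 5"):
            ProportionalOddsModel(y, np.zeros((102, 0)))


class TestReferenceSwitching:
    def test_loglikelihood_invariant_and_contrast_identity(self, cohort):
        records, scores = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            base = fit_ordinal_logit(records, scores)
            alt = refit_with_reference(records, scores, covariate="arm", new_reference="online")
        assert abs(base.llf - alt.llf) < 1e-8
        i_on = base.exog_names.index("arm[online]")
        i_ot = base.exog_names.index("arm[online_training]")
        j = alt.exog_names.index("arm[online_training]")
        assert alt.odds_ratios[j] == pytest.approx(
            base.odds_ratios[i_ot] / base.odds_ratios[i_on], abs=1e-6
        )

    def test_reciprocal_reading_of_protective_odds_ratio(self):
        # an odds ratio r for a higher score means 1/r odds of a lower score
        assert round(1 / 0.151, 1) == 6.6

    def test_missing_reference_level_rejected(self, cohort):
        records, scores = cohort
        with pytest.raises(ValueError, match="not present"):
            fit_ordinal_logit(
                records, scores, DesignSpec().with_reference("sex", "unknown")
            )


class TestStatisticalCalibration:
    def test_arm_coefficient_bias_small_at_large_n(self):
        # bias of each arm coefficient < 0.05 on the log-odds scale
        true_beta = np.log([0.283, 0.151])
        cut = np.array([-1.5, -0.8, -0.1, 0.5, 1.1, 1.7, 2.3, 3.0, 3.7])
        n = 10_000
        X = np.zeros((n, 2))
        X[n // 7 : 4 * n // 7, 0] = 1
        X[4 * n // 7 :, 1] = 1
        rng = np.random.default_rng(5)
        est = np.zeros(2)
        reps = 100
        for _ in range(reps):
            y = simulate_ordinal_outcomes(cut, X, true_beta, rng)
            est += _fit(y, X).params
        bias = est / reps - true_beta
        assert np.abs(bias).max() < 0.05

    def test_wald_pvalues_uniform_under_null(self):
        # Kolmogorov-Smirnov check over seeded null replicates
        rng = np.random.default_rng(6)
        n, reps = 1000, 500
        pvals = []
        X = rng.integers(0, 2, (n, 1)).astype(float)
        for _ in range(reps):
            y = simulate_ordinal_outcomes([-1.0, 0.0, 1.0], X, [0.0], rng)
            pvals.append(_fit(y, X).pvalues[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
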