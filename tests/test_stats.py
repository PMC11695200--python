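"""GLM contrasts, BH-FDR, partial correlations and demographic tests."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import dynconn as dc


def brute_force_bh(pvals, q=0.05):
    """Literal step-up rule: largest i with p_(i) <= i q / m is the cutoff."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p)
    mask = np.zeros(m, dtype=bool)
    cutoff = -1
    for i in range(m):
        if p[order[i]] <= (i + 1) * q / m:
            cutoff = i
    if cutoff >= 0:
        mask[order[:cutoff + 1]] = True
    return mask


class TestGLM:
    def test_reduces_to_two_sample_t_without_covariates(self, rng):
        y = rng.normal(size=50)
        group = np.r_[np.ones(25), np.zeros(25)]
        res = dc.glm_group_test(y, group)
        ref = sps.ttest_ind(y[:25], y[25:], equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_outcome_degenerate(self):
        group = np.r_[np.ones(10), np.zeros(10)]
        res = dc.glm_group_test(np.full(20, 3.0), group)
        assert res.beta == 0.0 and res.p == 1.0

    def test_parameter_recovery_with_covariate(self, rng):
        n = 200
        group = rng.integers(0, 2, n).astype(float)
        age = rng.normal(60, 7, n)
        y = 0.5 * group + 0.1 * age + rng.normal(size=n)
        res = dc.glm_group_test(y, group, covariates=age)
        # analytic check: estimate within 3 standard errors of the truth
        x = np.column_stack([np.ones(n), group, age])
        se_beta = np.sqrt(np.linalg.inv(x.T @ x)[1, 1]
                          * ((y - x @ np.linalg.lstsq(x, y, rcond=None)[0])**2).sum()
                          / (n - 3))
        assert abs(res.beta - 0.5) < 3 * se_beta

    def test_matches_statsmodels(self, rng):
        n = 40
        group = rng.integers(0, 2, n).astype(float)
        covs = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        ours = dc.glm_group_test(y, group, covs)
        x = sm.add_constant(np.column_stack([group, covs]))
        ref = sm.OLS(y, x).fit()
        assert ours.t == pytest.approx(ref.tvalues[1], abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalues[1], abs=1e-10)
        assert ours.df == int(ref.df_resid)

    def test_collinear_design_named(self, rng):
        group = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError, match="collinear"):
            dc.glm_group_test(rng.normal(size=20), group,
                              covariates=np.column_stack([group, group * 2]))

    def test_agrees_with_partial_correlation_route(self, rng):
        n = 80
        group = rng.integers(0, 2, n).astype(float)
        covs = rng.normal(size=(n, 2))
        y = 0.3 * group + covs @ [0.2, -0.1] + rng.normal(size=n)
        glm = dc.glm_group_test(y, group, covs)
        pc = dc.partial_correlation(y, group, covs)
        t_from_r = pc.r * np.sqrt(pc.df / (1 - pc.r**2))
        assert glm.t == pytest.approx(t_from_r, abs=1e-8)
        assert glm.p == pytest.approx(pc.p, abs=1e-10)


class TestBHFDR:
    def test_step_up_example(self):
        q, mask = dc.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert mask.all()
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_and_empty(self):
        q, mask = dc.bh_fdr([1.0])
        assert q[0] == 1.0 and not mask[0]
        q, mask = dc.bh_fdr([])
        assert q.size == 0 and mask.size == 0

    def test_monotone_and_bounded(self, rng):
        p = rng.random(50)
        q, _ = dc.bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1)

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            q, mask = dc.bh_fdr(p, 0.05)
            np.testing.assert_array_equal(mask, brute_force_bh(p, 0.05))
            ref_mask, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, ref_q, atol=1e-12)
            np.testing.assert_array_equal(mask, ref_mask)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dc.bh_fdr([0.5, 1.5])


class TestPartialCorrelation:
    def test_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        res = dc.partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_covariate_equal_to_y_errors(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="constant residuals"):
            dc.partial_correlation(x, z, covariates=z)

    def test_known_partial_correlation_recovered(self, rng):
        # trivariate normal with partial corr(x, y | z) = 0.4 by construction
        n = 10**4
        z = rng.normal(size=n)
        shared = rng.normal(size=n)
        x = 0.8 * z + np.sqrt(0.4) * shared + rng.normal(size=n) * np.sqrt(0.6)
        y = -0.5 * z + np.sqrt(0.4) * shared + rng.normal(size=n) * np.sqrt(0.6)
        res = dc.partial_correlation(x, y, covariates=z)
        assert res.r == pytest.approx(0.4, abs=0.03)

    def test_matches_pingouin(self, rng):
        n = 50
        frame = pd.DataFrame(rng.normal(size=(n, 4)),
                             columns=["x", "y", "c1", "c2"])
        ours = dc.partial_correlation(frame.x, frame.y,
                                      frame[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestSummaryStatisticTests:
    def test_equal_means_give_zero(self):
        assert dc.welch_t(5, 1, 10, 5, 2, 12)[0] == 0.0
        assert dc.pooled_t(5, 1, 10, 5, 2, 12)[0] == 0.0

    def test_doubling_n_scales_welch_t(self):
        t1, *_ = dc.welch_t(10, 2, 20, 8, 2, 20)
        t2, *_ = dc.welch_t(10, 2, 40, 8, 2, 40)
        assert t2 == pytest.approx(t1 * np.sqrt(2))

    def test_pooled_equals_welch_for_balanced_equal_sds(self):
        a = dc.pooled_t(3, 1.5, 25, 2, 1.5, 25)
        b = dc.welch_t(3, 1.5, 25, 2, 1.5, 25)
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            dc.welch_t(1, 0.0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            dc.pooled_t(1, 1, 1, 2, 1, 10)

    def test_chi_square_proportional_table_is_zero(self):
        chi2, p = dc.chi_square_2x2([[10, 10], [20, 20]])
        assert chi2 == 0.0 and p == 1.0

    def test_chi_square_transpose_invariance_and_scipy(self, rng):
        table = rng.integers(5, 40, size=(2, 2))
        chi2, p = dc.chi_square_2x2(table)
        chi2_t, _ = dc.chi_square_2x2(table.T)
        assert chi2 == pytest.approx(chi2_t, abs=1e-12)
        ref = sps.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dc.chi_square_2x2([[0, 0], [5, 3]])


class TestSubgroupContrast:
    def test_null_split_controls_fdr(self, rng):
        n, m = 66, 30
        false_rates = []
        for _ in range(20):
            split = rng.normal(26, 2, n)  # independent of all features
            feats = pd.DataFrame(rng.normal(size=(n, m)))
            covs = rng.normal(size=(n, 3))
            table = dc.subgroup_contrast(feats, split, 26.0, covs)
            false_rates.append(table.sig.mean())
        assert np.mean(false_rates) <= 0.05

    def test_empty_subgroup_reports_split(self, rng):
        feats = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="threshold 100"):
            dc.subgroup_contrast(feats, np.arange(10.0), 100.0)

    def test_duplication_keeps_estimates_shrinks_p(self, rng):
        n = 30
        split = rng.normal(size=n)
        feats = pd.DataFrame(split[:, None] * 0.5 + rng.normal(size=(n, 2)))
        doubled = pd.concat([feats, feats], ignore_index=True)
        t1 = dc.subgroup_contrast(feats, split, 0.0)
        t2 = dc.subgroup_contrast(doubled, np.r_[split, split], 0.0)
        np.testing.assert_allclose(t2.beta, t1.beta, atol=1e-10)
        assert np.all(np.abs(t2.t) >= np.abs(t1.t))
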