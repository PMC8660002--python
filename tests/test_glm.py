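"""Edge-wise moderated regression, BH correction, elimination ladder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from painconn.denoise import edge_list
from painconn.errors import ConfigurationError, ModelError
from painconn.glm import (
    TERM_INTER,
    TERM_WPINT,
    TERM_X,
    bh_qvalues,
    build_design,
    cohens_f2,
    elimination_ladder,
    fit_edge_model,
    fit_ols,
    screen_covariates,
)


class TestBHQvalues:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.001, 0.02, 0.03, 0.04]), [0.004, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_its_own_q(self):
        assert bh_qvalues([0.37])[0] == pytest.approx(0.37)

    def test_ties_share_q(self):
        q = bh_qvalues([0.01, 0.01, 0.01])
        assert q[0] == q[1] == q[2] == pytest.approx(0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_qvalues([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_qvalues(p), q_sm, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_q_at_least_p_and_monotone(self, seed):
        p = np.random.default_rng(seed).uniform(size=40)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestFitEdgeModel:
    def test_noiseless_recovery(self, pain_subjects):
        z = 0.1 + 0.02 * pain_subjects["log_wpdur"].to_numpy()
        fit = fit_edge_model(z, pain_subjects, "log")
        assert fit[TERM_X] == pytest.approx(0.02, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_outcome_zero_slopes(self, pain_subjects):
        fit = fit_edge_model(np.full(len(pain_subjects), 0.3), pain_subjects, "log")
        assert abs(fit[TERM_X]) < 1e-10
        assert abs(fit[TERM_WPINT]) < 1e-10
        assert abs(fit[TERM_INTER]) < 1e-10

    def test_matches_statsmodels_ols(self, pain_subjects):
        """Closed-form fit agrees with the statsmodels reference on all stats."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal(len(pain_subjects))
        fit = fit_edge_model(z, pain_subjects, "linear")
        X, names, rows = build_design(pain_subjects, "linear")
        ref = sm.OLS(z[rows], X).fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-10)
        np.testing.assert_allclose(fit.cov_params, ref.cov_params(), atol=1e-10)
        assert fit.df_resid == ref.df_resid

    def test_permuted_outcome_p_uniform(self, pain_subjects):
        """Permutation refits give uniform p-values (KS not rejecting at 0.01)."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal(len(pain_subjects))
        ps = []
        for _ in range(500):
            fit = fit_edge_model(rng.permutation(z), pain_subjects, "log")
            ps.append(fit.p(TERM_X))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_regressor_errors(self, pain_subjects):
        subs = pain_subjects.copy()
        subs["wpdur"] = 10.0  # constant duration -> wpdur5 constant
        subs = subs.drop(columns=["wpdur5"]).assign(wpdur5=1.0)
        with pytest.raises(ModelError, match="collinear"):
            fit_edge_model(np.zeros(len(subs)), subs, "dichotomous")

    def test_too_few_subjects(self, pain_subjects):
        few = pain_subjects.head(8)
        with pytest.raises(ModelError, match="parameters"):
            fit_edge_model(np.zeros(8), few, "log")


class TestCohensF2:
    def test_formula_arithmetic(self, pain_subjects):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(len(pain_subjects))
        full = fit_edge_model(z, pain_subjects, "log")
        red = fit_edge_model(z, pain_subjects, "log", terms=(TERM_X, TERM_WPINT))
        f2 = cohens_f2(full, red)
        assert f2 == pytest.approx(
            (full.r_squared - red.r_squared) / (1 - full.r_squared)
        )
        assert f2 >= 0

    def test_identical_models_zero(self, pain_subjects):
        z = np.random.default_rng(3).standard_normal(len(pain_subjects))
        fit = fit_edge_model(z, pain_subjects, "log")
        assert cohens_f2(fit, fit) == 0.0

    def test_matches_rss_oracle(self, pain_subjects):
        """f² recomputed from residual sums of squares agrees."""
        rng = np.random.default_rng(4)
        z = rng.standard_normal(len(pain_subjects))
        full = fit_edge_model(z, pain_subjects, "log")
        red = fit_edge_model(z, pain_subjects, "log", terms=(TERM_X,))
        tss = np.sum((z - z.mean()) ** 2)
        r2f, r2r = 1 - full.rss / tss, 1 - red.rss / tss
        assert cohens_f2(full, red) == pytest.approx((r2f - r2r) / (1 - r2f))

    def test_perfect_fit_undefined(self, pain_subjects):
        z = 0.5 * pain_subjects["log_wpdur"].to_numpy()
        full = fit_edge_model(z, pain_subjects, "log")
        with pytest.raises(ModelError, match="f²|undefined|R"):
            cohens_f2(full, full)


class TestEliminationLadder:
    def _null_Z(self, n, n_edges, seed):
        return np.random.default_rng(seed).standard_normal((n, n_edges)) * 0.1

    def test_alpha_one_keeps_full_model_everywhere(self, pain_subjects):
        Z = self._null_Z(len(pain_subjects), 45, 5)
        ladder = elimination_ladder(Z, pain_subjects, "log", alpha_elim=1.0,
                                    edges=edge_list(10))
        assert all(r.step == 1 for r in ladder.edge_results.values())
        assert all(r.surviving_terms == (TERM_X, TERM_WPINT, TERM_INTER)
                   for r in ladder.edge_results.values())

    def test_planted_interaction_survives(self, pain_subjects):
        rng = np.random.default_rng(6)
        n = len(pain_subjects)
        Z = rng.standard_normal((n, 45)) * 0.05
        x = pain_subjects["log_wpdur"].to_numpy()
        w = pain_subjects["wpint"].to_numpy()
        Z[:, 7] += 0.15 * x * w  # strong planted interaction
        ladder = elimination_ladder(Z, pain_subjects, "log", edges=edge_list(10))
        step1 = ladder.edges_at_step(1)
        assert 7 in step1
        assert len(step1) <= 1 + int(0.05 * 45) + 1  # at most FDR-level extras

    def test_x_always_retained(self, pain_subjects):
        Z = self._null_Z(len(pain_subjects), 10, 7)
        ladder = elimination_ladder(Z, pain_subjects, "log",
                                    edges=edge_list(5))
        for r in ladder.edge_results.values():
            assert TERM_X in r.surviving_terms

    def test_terminal_step_qvalues_attached(self, pain_subjects):
        Z = self._null_Z(len(pain_subjects), 10, 8)
        ladder = elimination_ladder(Z, pain_subjects, "log", edges=edge_list(5))
        for r in ladder.edge_results.values():
            if r.step == 3:
                assert set(r.qvalues) == {TERM_X}
            elif r.step == 2:
                assert set(r.qvalues) == {TERM_X, TERM_WPINT}
            else:
                assert set(r.qvalues) == {TERM_INTER}

    def test_invalid_edges_skipped(self, pain_subjects):
        Z = self._null_Z(len(pain_subjects), 6, 9)
        Z[0, 2] = np.nan
        ladder = elimination_ladder(Z, pain_subjects, "log", edges=edge_list(4))
        assert 2 not in ladder.edge_results
        assert len(ladder.edge_results) == 5

    def test_long_table_schema(self, pain_subjects):
        Z = self._null_Z(len(pain_subjects), 6, 10)
        ladder = elimination_ladder(Z, pain_subjects, "log", edges=edge_list(4))
        expected = {"edge_index", "roi_i", "roi_j", "coding", "step",
                    "surviving_model", "term", "beta", "se", "t", "p", "q", "f2"}
        assert expected == set(ladder.table.columns)
        assert (ladder.table.groupby("edge_index")["step"].nunique() == 1).all()


class TestScreenCovariates:
    def test_self_correlation_is_one(self, cohort):
        out = screen_covariates(cohort, extra_measures=["wpint"])
        cell = out[(out.measure == "wpint") & (out.target == "wpint")]
        assert cell["r"].iloc[0] == pytest.approx(1.0)

    def test_pairwise_deletion_counts(self, cohort):
        c = cohort.copy()
        c.loc[c.index[:5], "moca"] = np.nan
        out = screen_covariates(c)
        n_pain = (c.group == "pain").sum()
        cell = out[(out.measure == "moca") & (out.target == "wpint")]
        assert cell["n"].iloc[0] == n_pain - 5

    def test_null_r_distribution(self):
        """|r| of independent columns follows the null Pearson distribution."""
        rng = np.random.default_rng(11)
        n = 40
        rs = []
        for _ in range(400):
            a, b = rng.standard_normal((2, n))
            rs.append(stats.pearsonr(a, b)[0])
        # null CDF of Pearson r: t transform
        t = np.array(rs) * np.sqrt((n - 2) / (1 - np.square(rs)))
        assert stats.kstest(t, stats.t(df=n - 2).cdf).pvalue > 0.01

    def test_bh_applied_across_whole_table(self, cohort):
        out = screen_covariates(cohort)
        ok = out.dropna(subset=["p"])
        np.testing.assert_allclose(
            ok["q"].to_numpy(), bh_qvalues(ok["p"].to_numpy()), atol=1e-12
        )
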