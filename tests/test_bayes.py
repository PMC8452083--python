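import math

import numpy as np
import pandas as pd
import pytest

from sevocea.bayes import (
    AnalysisRow,
    MCMCConfig,
    ModelData,
    PosteriorDraws,
    PriorSpec,
    SingularDesignError,
    build_design,
    gibbs_sample,
    rows_from_frame,
    rows_to_frame,
    summarize_posterior,
)
from sevocea.synthetic import SyntheticConfig, generate_analysis_rows


def make_row(pid="A", cost=1000.0, spid=20.0, **kw):
    defaults = dict(treatment=1, aht=0, ulcer_duration=10.0, ulcer_number=2,
                    ulcer_depth=0, ulcer_pain=7.0)
    defaults.update(kw)
    return AnalysisRow(patient_id=pid, annual_cost=cost, spid=spid, **defaults)


class TestBuildDesign:
    def test_unit_cost_gives_zero_log_response(self):
        md = build_design([make_row(cost=1.0)])
        assert md.Y[0, 0] == 0.0

    def test_ulcer_number_truncated_at_four(self):
        md = build_design([make_row(ulcer_number=7)])
        assert md.X[0, 3] == 4.0

    def test_shape_contract(self, synth_rows):
        rows, _ = synth_rows
        md = build_design(rows)
        assert md.X.shape == (64, 7) and md.Y.shape == (64, 2)

    def test_nonpositive_cost_identifies_patient(self):
        with pytest.raises(ValueError, match="ZZ"):
            AnalysisRow("ZZ", 1, 0, 1.0, 1, 0, 5.0, annual_cost=0.0, spid=1.0)


class TestGibbsSampler:
    def test_reproducible_bit_for_bit(self, synth_rows):
        rows, _ = synth_rows
        md = build_design(rows)
        cfg = MCMCConfig(burn_in=100, kept_iterations=500, seed=42)
        d1 = gibbs_sample(md, PriorSpec(), cfg)
        d2 = gibbs_sample(md, PriorSpec(), cfg)
        assert np.array_equal(d1.beta_cost, d2.beta_cost)
        assert np.array_equal(d1.sigma, d2.sigma)

    def test_different_seeds_differ(self, synth_rows):
        rows, _ = synth_rows
        md = build_design(rows)
        d1 = gibbs_sample(md, config=MCMCConfig(burn_in=50, kept_iterations=200, seed=1))
        d2 = gibbs_sample(md, config=MCMCConfig(burn_in=50, kept_iterations=200, seed=2))
        assert not np.array_equal(d1.beta_cost, d2.beta_cost)

    def test_singular_design_names_columns(self):
        rows = [make_row(pid=f"P{i}", aht=1, ulcer_depth=1) for i in range(12)]
        with pytest.raises(SingularDesignError):
            gibbs_sample(build_design(rows))

    def test_null_treatment_effect_recovered(self):
        cfg = SyntheticConfig(
            n_treated=400, n_control=400, seed=5,
            beta_cost=np.array([7.0, 0.2, 0.01, 0.1, 0.5, 0.0, 0.0]),
            beta_eff=np.array([-5.0, 1.0, 0.05, 0.3, 1.0, 3.0, 0.0]),
        )
        rows, _ = generate_analysis_rows(cfg)
        draws = gibbs_sample(build_design(rows),
                             config=MCMCConfig(burn_in=500, kept_iterations=4000, seed=6))
        # posterior means within ~3 posterior SDs of the true zero effect
        assert abs(draws.treatment_cost.mean()) < 3 * draws.treatment_cost.std()
        assert abs(draws.treatment_eff.mean()) < 3 * draws.treatment_eff.std()

    def test_known_precision_reduction_matches_conjugate_normal(self):
        # Fix the error precision and use an intercept-only design: each
        # response's posterior is the textbook normal-normal closed form.
        rng = np.random.default_rng(3)
        n = 40
        y = rng.normal(2.0, 1.0, size=(n, 2))
        md = ModelData(X=np.ones((n, 1)), Y=y, patient_ids=[str(i) for i in range(n)],
                       columns=("intercept",))
        v0 = 10.0  # prior variance
        omega = np.diag([4.0, 0.25])  # known precisions 1/0.25, 1/4
        prior = PriorSpec(coef_prior_variance=v0)
        draws = gibbs_sample(md, prior, MCMCConfig(burn_in=200, kept_iterations=40_000, seed=8),
                             fixed_precision=omega)
        for j, prec in enumerate([4.0, 0.25]):
            post_var = 1.0 / (n * prec + 1.0 / v0)
            post_mean = post_var * prec * y[:, j].sum()
            sample = np.column_stack([draws.beta_cost, draws.beta_eff])[:, j]
            assert math.isclose(sample.mean(), post_mean, abs_tol=4 * np.sqrt(post_var / 40_000) + 1e-3)
            assert math.isclose(sample.var(ddof=1), post_var, rel_tol=0.05)

    def test_conjugate_oracle_bivariate_intercept_only(self):
        # Oracle: with an (effectively) flat coefficient prior, integrating the
        # mean out gives Omega | Y ~ Wishart(df0 + n - 1, (S0 + S)^-1) with S
        # the centered scatter, and mean | Omega, Y ~ N(ybar, (n Omega)^-1).
        # Closed-form moments: E[Sigma] = (S0 + S)/(df0 + n - 1 - 3),
        # E[mean] = ybar, Var[mean] = E[Sigma]/n.
        rng = np.random.default_rng(21)
        n = 60
        true_sigma = np.array([[1.0, 0.6], [0.6, 2.0]])
        y = rng.multivariate_normal([1.0, -2.0], true_sigma, size=n)
        md = ModelData(X=np.ones((n, 1)), Y=y, patient_ids=[str(i) for i in range(n)],
                       columns=("intercept",))
        draws = gibbs_sample(md, PriorSpec(coef_prior_variance=1e8),
                             MCMCConfig(burn_in=1000, kept_iterations=60_000, seed=9))
        ybar = y.mean(axis=0)
        S = (y - ybar).T @ (y - ybar)
        df_marg = 2.0 + n - 1
        exp_sigma = (np.eye(2) + S) / (df_marg - 3)
        mean_draws = np.column_stack([draws.beta_cost[:, 0], draws.beta_eff[:, 0]])
        assert np.allclose(mean_draws.mean(axis=0), ybar, atol=0.03)
        assert np.allclose(mean_draws.var(axis=0, ddof=1), np.diag(exp_sigma) / n, rtol=0.08)
        assert np.allclose(draws.sigma.mean(axis=0), exp_sigma, rtol=0.08)

    def test_needs_more_rows_than_covariates(self):
        rows = [make_row(pid=f"P{i}") for i in range(5)]
        with pytest.raises(ValueError, match="more observations"):
            gibbs_sample(build_design(rows))

    def test_thinning_and_chains_change_draw_count(self, synth_rows):
        rows, _ = synth_rows
        md = build_design(rows)
        d = gibbs_sample(md, config=MCMCConfig(burn_in=50, kept_iterations=400,
                                               thinning=4, chains=2, seed=3))
        assert d.n_draws == 200

    def test_cost_scale_equivariance(self, synth_rows):
        # multiplying all costs by k shifts only the cost-equation intercept
        rows, _ = synth_rows
        k = 10.0
        scaled = [AnalysisRow(r.patient_id, r.treatment, r.aht, r.ulcer_duration,
                              r.ulcer_number, r.ulcer_depth, r.ulcer_pain,
                              r.annual_cost * k, r.spid) for r in rows]
        cfg = MCMCConfig(burn_in=200, kept_iterations=2000, seed=17)
        d1 = gibbs_sample(build_design(rows), config=cfg)
        d2 = gibbs_sample(build_design(scaled), config=cfg)
        assert np.allclose(d2.beta_cost[:, 0], d1.beta_cost[:, 0] + np.log(k), atol=1e-3)
        assert np.allclose(d2.beta_cost[:, 1:], d1.beta_cost[:, 1:], atol=1e-3)
        assert np.allclose(d2.beta_eff, d1.beta_eff, atol=1e-3)


class TestSummarizePosterior:
    def test_constant_draws_degenerate_summary(self):
        m = 10
        draws = PosteriorDraws(
            beta_cost=np.full((m, 7), 2.0),
            beta_eff=np.full((m, 7), -1.0),
            sigma=np.tile(np.eye(2), (m, 1, 1)),
        )
        table = summarize_posterior(draws)
        row = table.loc["cost_intercept"]
        assert row["mean"] == 2.0 and row["sd"] == 0.0
        assert row["lower"] == row["upper"] == 2.0

    def test_percentiles_match_sort_and_index_oracle(self):
        vals = np.arange(1.0, 101.0)
        draws = PosteriorDraws(
            beta_cost=np.tile(vals[:, None], (1, 7)),
            beta_eff=np.tile(vals[:, None], (1, 7)),
            sigma=np.tile(np.eye(2), (100, 1, 1)),
        )
        row = summarize_posterior(draws).loc["eff_treatment"]
        # linear-interpolation quantile of 1..100: 1 + q*99
        assert math.isclose(row["lower"], 1 + 0.025 * 99)
        assert math.isclose(row["upper"], 1 + 0.975 * 99)

    def test_standard_normal_credible_interval(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(1_000_000)
        draws = PosteriorDraws(
            beta_cost=np.tile(vals[:, None], (1, 7)),
            beta_eff=np.tile(vals[:, None], (1, 7)),
            sigma=np.tile(np.eye(2), (len(vals), 1, 1)),
        )
        row = summarize_posterior(draws).loc["cost_treatment"]
        assert math.isclose(row["lower"], -1.9600, abs_tol=0.01)
        assert math.isclose(row["upper"], 1.9600, abs_tol=0.01)

    def test_cost_ratio_row_is_mean_of_exponentials(self, fitted_draws):
        draws, _ = fitted_draws
        table = summarize_posterior(draws)
        assert math.isclose(table.loc["cost_ratio", "mean"],
                            np.exp(draws.treatment_cost).mean(), rel_tol=1e-12)
        # Jensen: mean of exponentials >= exponential of the mean
        assert table.loc["cost_ratio", "mean"] >= np.exp(draws.treatment_cost.mean())


class TestRowSerialization:
    def test_round_trip(self, synth_rows):
        rows, _ = synth_rows
        assert rows_from_frame(rows_to_frame(rows)) == rows

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="spid"):
            rows_from_frame(pd.DataFrame({"patient_id": ["A"]}))
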