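import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sevocea.bayes import PosteriorDraws
from sevocea.cea import (
    ce_plane,
    ceac,
    comparator_cost_reference,
    costs_ratio,
    default_lambda_grid,
    dominance_probabilities,
    icer,
    incremental_cost_draws,
    incremental_effectiveness,
    plot_ce_plane,
    plot_ceac,
    summarize_cea,
)


def crafted_draws(b17, b27, sigma11=1.0):
    b17 = np.asarray(b17, float)
    b27 = np.asarray(b27, float)
    m = len(b17)
    beta_cost = np.zeros((m, 7))
    beta_cost[:, 6] = b17
    beta_eff = np.zeros((m, 7))
    beta_eff[:, 6] = b27
    sigma = np.tile(np.diag([sigma11, 1.0]), (m, 1, 1))
    return PosteriorDraws(beta_cost=beta_cost, beta_eff=beta_eff, sigma=sigma)


class TestCostsRatio:
    def test_zero_draws_ratio_one(self):
        d = crafted_draws([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        out = costs_ratio(d)
        assert out["mean"] == 1.0 and out["sd"] == 0.0

    def test_three_term_arithmetic_oracle(self):
        d = crafted_draws([-0.5, 0.0, 0.5], [1.0, 1.0, 1.0])
        expected = (math.exp(-0.5) + 1.0 + math.exp(0.5)) / 3.0
        assert math.isclose(costs_ratio(d)["mean"], expected, rel_tol=1e-12)

    def test_summary_is_of_transformed_draws(self, fitted_draws):
        draws, _ = fitted_draws
        out = costs_ratio(draws)
        r = np.exp(draws.treatment_cost)
        assert math.isclose(out["mean"], r.mean(), rel_tol=1e-12)
        assert math.isclose(out["lower"], np.percentile(r, 2.5), rel_tol=1e-9)
        # Jensen, strict with varying draws
        assert out["mean"] > math.exp(draws.treatment_cost.mean())


class TestIncrementalEffectiveness:
    def test_constant_draws(self):
        out = incremental_effectiveness(crafted_draws([0.0] * 4, [1.0] * 4))
        assert out["mean"] == 1.0 and out["sd"] == 0.0

    def test_sampling_oracle_normal_5(self):
        rng = np.random.default_rng(0)
        b27 = rng.normal(5.0, 1.0, 40_000)
        out = incremental_effectiveness(crafted_draws(np.zeros_like(b27), b27))
        assert math.isclose(out["mean"], 5.0, abs_tol=0.02)
        assert math.isclose(out["sd"], 1.0, abs_tol=0.02)


class TestDominance:
    def test_all_dominant(self):
        p = dominance_probabilities(crafted_draws([-1, -2, -1], [1, 2, 3]))
        assert p == (1.0, 1.0, 1.0)

    def test_enumeration_of_crafted_signs(self):
        # signs (-,+), (-,-), (+,+), (-,+) -> (0.75, 0.75, 0.5)
        d = crafted_draws([-1, -1, 1, -1], [1, -1, 1, 1])
        assert dominance_probabilities(d) == (0.75, 0.75, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(-50, 50)), min_size=1, max_size=40))
    def test_joint_bounded_by_marginals(self, pairs):
        b17 = [a for a, _ in pairs]
        b27 = [b for _, b in pairs]
        p_cheap, p_eff, p_dom = dominance_probabilities(crafted_draws(b17, b27))
        assert p_dom <= min(p_cheap, p_eff) + 1e-12
        assert 0 <= p_dom <= 1


class TestICER:
    def test_ratio_one_gives_zero_icer(self):
        d = crafted_draws([0.0, 0.0], [25.0, 25.0])
        out = icer(d, baseline_cost_reference=10_000.0)
        assert out["mean"] == 0.0

    def test_arithmetic_oracle_single_draw(self):
        # baseline 10000, ratio 0.5, effect 25 -> -5000/25 = -200 per unit
        d = crafted_draws([math.log(0.5)] * 2, [25.0] * 2)
        out = icer(d, baseline_cost_reference=10_000.0)
        assert math.isclose(out["mean"], -200.0, rel_tol=1e-12)

    def test_dominant_flagging(self):
        d = crafted_draws([-1.0] * 100, [10.0] * 100)
        out = icer(d, 1000.0)
        assert out["dominant"] and "not informative" in out["note"]

    def test_zero_effect_draws_excluded_and_counted(self):
        d = crafted_draws([-0.5, -0.5, -0.5], [10.0, 0.0, 10.0])
        out = icer(d, 1000.0, dominance_threshold=1.1)
        assert out["excluded_zero_effect_draws"] == 1


class TestCEAC:
    def test_lambda_zero_equals_p_cheaper(self, fitted_draws):
        draws, md = fitted_draws
        xbar = md.X[md.X[:, -1] == 0].mean(axis=0)
        base = comparator_cost_reference(draws, xbar)
        curve = ceac(draws, [0.0], base)
        p_cheap, _, _ = dominance_probabilities(draws)
        assert curve["probability"].iloc[0] == p_cheap

    def test_huge_lambda_approaches_p_more_effective(self, fitted_draws):
        draws, md = fitted_draws
        xbar = md.X[md.X[:, -1] == 0].mean(axis=0)
        base = comparator_cost_reference(draws, xbar)
        curve = ceac(draws, [1e12], base)
        _, p_eff, _ = dominance_probabilities(draws)
        assert curve["probability"].iloc[0] == p_eff

    def test_enumeration_on_crafted_draws(self):
        # five draws, baseline 100: inc_cost = 100*(e^b17 - 1)
        b17 = [math.log(0.5), math.log(2.0), 0.0, math.log(0.9), math.log(1.1)]
        b27 = [10.0, 10.0, -5.0, 1.0, -1.0]
        d = crafted_draws(b17, b27)
        curve = ceac(d, [0.0, 100.0, 1e6], 100.0)
        # lambda=0: nb = -inc_cost -> positive for draws 1 and 4 -> 2/5
        assert curve["probability"].iloc[0] == 0.4
        # lambda=100: nb = 100*b27 - inc  -> (1050, 900, -500, 110, -110) -> 3/5
        assert curve["probability"].iloc[1] == 0.6
        # lambda huge: sign of b27 -> 3/5
        assert curve["probability"].iloc[2] == 0.6

    def test_negative_lambda_rejected(self):
        d = crafted_draws([0.0], [1.0])
        with pytest.raises(ValueError):
            ceac(d, [-1.0], 100.0)

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(4)
        d = crafted_draws(rng.normal(-0.5, 0.5, 500), np.abs(rng.normal(20, 5, 500)) + 0.1)
        curve = ceac(d, default_lambda_grid(500.0, 26), 5000.0)
        probs = curve["probability"].to_numpy()
        assert np.all(np.diff(probs) >= -1e-12)


class TestCEPlane:
    def test_single_neutral_draw_maps_to_0_1(self):
        frame = ce_plane(crafted_draws([0.0], [0.0]))
        assert frame.iloc[0]["incremental_effectiveness"] == 0.0
        assert frame.iloc[0]["costs_ratio"] == 1.0
        assert frame.attrs["cost_neutral_y"] == 1.0

    def test_cardinality_preserved(self, fitted_draws):
        draws, _ = fitted_draws
        assert len(ce_plane(draws)) == draws.n_draws

    def test_dominant_quadrant_count_cross_check(self):
        rng = np.random.default_rng(9)
        d = crafted_draws(rng.normal(0, 1, 400), rng.normal(0, 10, 400))
        frame = ce_plane(d)
        _, _, p_dom = dominance_probabilities(d)
        in_quadrant = ((frame["costs_ratio"] < 1) & (frame["incremental_effectiveness"] > 0)).sum()
        assert in_quadrant == round(p_dom * 400)


class TestSummarizeCEA:
    def test_full_summary_serializes(self, fitted_draws, tmp_path):
        draws, md = fitted_draws
        xbar = md.X[md.X[:, -1] == 0].mean(axis=0)
        summary = summarize_cea(draws, comparator_xbar=xbar)
        payload = json.loads(summary.to_json())
        assert set(payload) >= {"costs_ratio", "p_dominant", "ceac", "icer"}
        assert 0 <= payload["p_dominant"] <= 1
        assert math.isclose(
            payload["relative_incremental_cost_pct"],
            (payload["costs_ratio"]["mean"] - 1) * 100,
        )

    def test_convention_free_parts_without_baseline(self, fitted_draws):
        draws, _ = fitted_draws
        summary = summarize_cea(draws)
        assert summary.icer is None and summary.ceac is None
        assert summary.p_dominant <= min(summary.p_cheaper, summary.p_more_effective)

    def test_figures_render(self, fitted_draws, tmp_path):
        draws, md = fitted_draws
        xbar = md.X[md.X[:, -1] == 0].mean(axis=0)
        summary = summarize_cea(draws, comparator_xbar=xbar)
        plot_ce_plane(draws, tmp_path / "plane.png")
        plot_ceac(summary.ceac, tmp_path / "ceac.png")
        assert (tmp_path / "plane.png").stat().st_size > 0
        assert (tmp_path / "ceac.png").stat().st_size > 0


class TestIncrementalCost:
    def test_sign_matches_treatment_coefficient(self, fitted_draws):
        draws, md = fitted_draws
        xbar = md.X[md.X[:, -1] == 0].mean(axis=0)
        inc = incremental_cost_draws(draws, comparator_cost_reference(draws, xbar))
        assert np.array_equal(inc < 0, draws.treatment_cost < 0)

    def test_nonpositive_baseline_rejected(self, fitted_draws):
        draws, _ = fitted_draws
        with pytest.raises(ValueError):
            incremental_cost_draws(draws, 0.0)
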