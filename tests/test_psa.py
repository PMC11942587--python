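"""Probabilistic sensitivity analysis: sampling, propagation, CEAC, intervals."""

import numpy as np
import pandas as pd
import pytest

from treecea import (
    Distribution,
    ParameterSet,
    ParameterSpec,
    PsaCloud,
    ceac,
    prediction_interval,
    rollback,
    run_psa,
    sample_parameters,
)


def make_cloud(costs, effects, strategies=("A", "B")):
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    return PsaCloud(
        strategies=tuple(strategies),
        costs=costs,
        effects=effects,
        samples=pd.DataFrame(index=range(len(costs))),
        seed=0,
        iterations=len(costs),
    )


class TestSampleParameters:
    def test_all_none_gives_base_vectors(self):
        params = ParameterSet(
            [
                ParameterSpec("p", "probability", 0.3),
                ParameterSpec("c", "cost", 10.0),
            ]
        )
        df = sample_parameters(params, 5, seed=0)
        assert df.shape == (5, 2)
        assert (df["p"] == 0.3).all() and (df["c"] == 10.0).all()

    def test_beta_sample_mean_matches_closed_form(self):
        params = ParameterSet(
            [
                ParameterSpec(
                    "p", "probability", 0.5, Distribution("beta", (2.0, 2.0))
                )
            ]
        )
        n = 100_000
        draws = sample_parameters(params, n, seed=42)["p"]
        # beta(2,2): mean 1/2, var 1/20
        se = np.sqrt(1 / 20 / n)
        assert abs(draws.mean() - 0.5) < 3 * se
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_dirichlet_block_stays_on_simplex(self):
        specs = [
            ParameterSpec(
                f"p{i}", "probability", b, Distribution("dirichlet", (a,), group="g")
            )
            for i, (a, b) in enumerate([(2.0, 0.2), (3.0, 0.3), (5.0, 0.5)])
        ]
        params = ParameterSet(specs)
        df = sample_parameters(params, 500, seed=3)
        total = df.sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_dirichlet_rest_leaves_room_for_complement(self):
        specs = [
            ParameterSpec(
                "p1", "probability", 0.25, Distribution("dirichlet", (1.0,), group="g")
            ),
            ParameterSpec(
                "p2", "probability", 0.25, Distribution("dirichlet", (1.0,), group="g")
            ),
        ]
        params = ParameterSet(specs, dirichlet_rest={"g": 2.0})
        df = sample_parameters(params, 2_000, seed=9)
        assert (df.sum(axis=1) < 1.0).all()
        assert abs(df["p1"].mean() - 0.25) < 0.02

    def test_invalid_hyperparameters_named_before_sampling(self):
        params = ParameterSet(
            [ParameterSpec("p", "probability", 0.5, Distribution("beta", (-1.0, 2.0)))]
        )
        with pytest.raises(ValueError, match="beta"):
            sample_parameters(params, 10, seed=0)


class TestRunPsa:
    def test_degenerate_distributions_reproduce_base_case_bitwise(
        self, picc_model, degenerate_params
    ):
        base = rollback(picc_model.tree, degenerate_params.base_values())
        cloud = run_psa(picc_model.tree, degenerate_params, 100, seed=5)
        for j, o in enumerate(base):
            assert (cloud.costs[:, j] == o.expected_cost).all()
            assert (cloud.effects[:, j] == o.expected_effect).all()

    def test_seed_reproducibility_and_seed_sensitivity(self, picc_model):
        a = run_psa(picc_model.tree, picc_model.params, 200, seed=7)
        b = run_psa(picc_model.tree, picc_model.params, 200, seed=7)
        c = run_psa(picc_model.tree, picc_model.params, 200, seed=8)
        assert (a.costs == b.costs).all() and (a.effects == b.effects).all()
        assert not (a.costs == c.costs).all()

    def test_psa_means_near_base_case(self, picc_model, base_outcomes):
        """Distributions are mean-centred on base values, so PSA means
        converge on the base case (checked at 3 Monte Carlo SEs)."""
        n = 4_000
        cloud = run_psa(picc_model.tree, picc_model.params, n, seed=11)
        for j, o in enumerate(base_outcomes):
            se_cost = cloud.costs[:, j].std(ddof=1) / np.sqrt(n)
            se_eff = cloud.effects[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(cloud.costs[:, j].mean() - o.expected_cost) < 3 * se_cost
            assert abs(cloud.effects[:, j].mean() - o.expected_effect) < 3 * se_eff

    def test_sampled_probabilities_in_unit_interval(self, picc_model):
        cloud = run_psa(picc_model.tree, picc_model.params, 500, seed=2)
        probs = [s.name for s in picc_model.params if s.kind == "probability"]
        block = cloud.samples[probs].to_numpy()
        assert ((block >= 0) & (block <= 1)).all()
        costs = [s.name for s in picc_model.params if s.kind == "cost"]
        assert (cloud.samples[costs].to_numpy() >= 0).all()


class TestCeac:
    def test_dominant_in_every_draw_gives_probability_one(self):
        cloud = make_cloud(
            costs=[[10, 20], [15, 30], [12, 25]],
            effects=[[0.9, 0.5], [0.8, 0.4], [0.85, 0.45]],
        )
        curve = ceac(cloud, [0.0, 50.0, 1e6])
        assert (curve.probabilities["A"] == 1.0).all()
        assert (curve.probabilities["B"] == 0.0).all()

    def test_lambda_zero_reduces_to_lowest_cost(self):
        cloud = make_cloud(
            costs=[[10, 20], [30, 25], [12, 40], [50, 45]],
            effects=[[0.1, 0.9], [0.1, 0.9], [0.1, 0.9], [0.1, 0.9]],
        )
        curve = ceac(cloud, [0.0])
        assert curve.probabilities.loc[0.0, "A"] == 0.5
        assert curve.probabilities.loc[0.0, "B"] == 0.5

    def test_two_iteration_hand_cloud_splits_half(self):
        # iteration 1 favours A, iteration 2 favours B at lambda=113120
        cloud = make_cloud(
            costs=[[100.0, 200.0], [200.0, 100.0]],
            effects=[[0.5, 0.5], [0.5, 0.5]],
        )
        curve = ceac(cloud, [113_120.0])
        assert curve.probabilities.iloc[0].tolist() == [0.5, 0.5]

    def test_probabilities_sum_to_one_with_ties(self):
        cloud = make_cloud(
            costs=[[100.0, 100.0], [50.0, 60.0]],
            effects=[[0.5, 0.5], [0.5, 0.5]],
        )
        curve = ceac(cloud, [0.0, 113_120.0])
        assert np.allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_limits_low_cost_vs_high_effect(self):
        # A cheaper, B more effective in every draw
        cloud = make_cloud(
            costs=[[10.0, 100.0]] * 4, effects=[[0.2, 0.9]] * 4
        )
        low = ceac(cloud, [1e-9]).probabilities.iloc[0]
        high = ceac(cloud, [1e9]).probabilities.iloc[0]
        assert low["A"] == 1.0 and high["B"] == 1.0

    def test_empty_grid_rejected(self):
        cloud = make_cloud(costs=[[1.0, 2.0]], effects=[[0.1, 0.2]])
        with pytest.raises(ValueError):
            ceac(cloud, [])


class TestPredictionInterval:
    def test_constant_cloud_zero_width(self):
        cloud = make_cloud(costs=[[5.0, 1.0]] * 10, effects=[[0.3, 0.3]] * 10)
        assert prediction_interval(cloud, "cost", "A") == (5.0, 5.0)

    def test_uniform_quantiles_closed_form(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 1, size=100_000)
        cloud = make_cloud(
            costs=np.column_stack([u, u]), effects=np.zeros((u.size, 2))
        )
        lo, hi = prediction_interval(cloud, "cost", "A", level=0.95)
        assert abs(lo - 0.025) < 0.01 and abs(hi - 0.975) < 0.01

    def test_widening_level_never_narrows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        cloud = make_cloud(costs=np.column_stack([x, x]), effects=np.zeros((x.size, 2)))
        lo80, hi80 = prediction_interval(cloud, "cost", "A", level=0.80)
        lo95, hi95 = prediction_interval(cloud, "cost", "A", level=0.95)
        assert lo95 <= lo80 and hi95 >= hi80

    def test_invalid_level_rejected(self):
        cloud = make_cloud(costs=[[1.0, 2.0]], effects=[[0.1, 0.2]])
        with pytest.raises(ValueError):
            prediction_interval(cloud, "cost", "A", level=1.5)
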