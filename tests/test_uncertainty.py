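import numpy as np
import pandas as pd
import pytest

from strokecea import (
    ModelPipeline,
    Parameter,
    ParameterSet,
    compute_ceac,
    parameterize,
    run_dsa,
    run_psa,
    run_scenarios,
)
from strokecea.uncertainty import (
    DegenerateRangeError,
    TREE_ONLY_HORIZON,
    tornado_frame,
)


class TestParameterize:
    def test_gamma_method_of_moments(self):
        spec = parameterize(Parameter("cost_edsl_tablet", 70, 63, 77, "gamma"))
        shape, scale = spec.args
        assert shape == pytest.approx(384.16, abs=0.01)
        assert scale == pytest.approx(0.18222, abs=1e-4)

    def test_lognormal_sdlog(self):
        spec = parameterize(Parameter("hr_mrs3", 3.18, 3.17, 3.19, "lognormal"))
        meanlog, sdlog = spec.args
        assert meanlog == pytest.approx(np.log(3.18))
        assert sdlog == pytest.approx((np.log(3.19) - np.log(3.17)) / 3.92)
        assert sdlog == pytest.approx(0.0016044, abs=1e-6)

    def test_beta_moments_match_base(self):
        spec = parameterize(Parameter("utility_mrs0", 0.983, 0.981, 0.985, "beta"))
        a, b = spec.args
        assert a / (a + b) == pytest.approx(0.983)

    def test_uniform_passthrough(self):
        spec = parameterize(Parameter("discount_rate_cost", 0.05, 0.0, 0.08, "uniform"))
        assert spec.args == (0.0, 0.08)

    def test_degenerate_range_collapses_to_fixed(self):
        with pytest.raises(DegenerateRangeError, match="collapse to fixed"):
            parameterize(Parameter("x", 1.0, 1.0, 1.0, "gamma"))

    def test_beta_base_outside_unit_interval(self):
        with pytest.raises(ValueError):
            parameterize(Parameter("x", 1.2, 1.0, 1.4, "beta"))

    def test_gamma_nonpositive_base(self):
        with pytest.raises(ValueError):
            parameterize(Parameter("x", 0.0, 0.0, 1.0, "gamma"))

    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError):
            Parameter("x", 5.0, 6.0, 7.0, "gamma")

    def test_sampler_means_match_base(self, default_params):
        """10^5 draws from every sampler reproduce the base value within
        2% (uniform: the midpoint)."""
        rng = np.random.default_rng(99)
        for p in default_params.varied():
            draws = parameterize(p).sample(rng, 100_000)
            target = (p.lower + p.upper) / 2 if p.dist == "uniform" else p.base
            assert np.mean(draws) == pytest.approx(target, rel=0.02), p.name

    def test_sampler_percentiles_bracket_bounds(self, default_params):
        """Empirical 2.5/97.5 percentiles land near the stated range."""
        rng = np.random.default_rng(7)
        for p in default_params.varied():
            if p.dist == "uniform":
                continue
            draws = parameterize(p).sample(rng, 100_000)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            half = (p.upper - p.lower) / 2
            assert abs(lo - p.lower) < 0.3 * (p.upper - p.lower) + 1e-9, p.name
            assert abs(hi - p.upper) < 0.3 * (p.upper - p.lower) + 1e-9, p.name
            del half


class TestParameterSet:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ParameterSet([Parameter("a", 1.0), Parameter("a", 2.0)])

    def test_fixed_parameters_never_varied(self, default_params):
        assert all(not p.varied for p in default_params if p.dist == "fixed")
        assert "recurrence_y1" in default_params
        assert not default_params["recurrence_y1"].varied


class TestRunDSA:
    def test_tornado_completeness_and_ranking(self, model, default_params):
        entries = run_dsa(model, default_params)
        varied = {p.name for p in default_params.varied()}
        assert [e.parameter for e in entries].count("hr_mrs0") == 1
        assert {e.parameter for e in entries} == varied
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_zero_width_bounds_rank_last(self, model, default_params):
        params = ParameterSet(
            list(default_params) + [Parameter("null_param", 1.0, 1.0, 1.0, "gamma")]
        )
        entries = run_dsa(model, params)
        assert entries[-1].parameter == "null_param"
        assert entries[-1].spread == 0.0

    def test_tablet_price_propagates_linearly(self, model, default_params):
        """Varying the tablet price 63 -> 77 moves the incremental drug
        cost by exactly (77 - 63) x 28."""
        values = default_params.base_values()
        deltas = []
        for price in (63.0, 77.0):
            v = dict(values, cost_edsl_tablet=price)
            res = model(v)
            deltas.append(
                res.edsl.cost_components["drug"] - res.edcsi.cost_components["drug"]
            )
        assert deltas[1] - deltas[0] == pytest.approx(14 * 28)

    def test_dominance_holds_at_every_bound(self, model, default_params):
        """Across the whole one-way grid the sublingual arm stays more
        effective and less costly."""
        base = default_params.base_values()
        for p in default_params.varied():
            for bound in (p.lower, p.upper):
                res = model(dict(base, **{p.name: bound}))
                assert res.delta_qalys > 0, p.name
                assert res.delta_cost < 0, p.name

    def test_frame_export(self, model, default_params):
        frame = tornado_frame(run_dsa(model, default_params))
        assert set(frame.columns) >= {"parameter", "spread", "metric"}


class TestRunPSA:
    def test_all_fixed_degenerates_to_base(self, model, default_params):
        fixed = ParameterSet(
            [Parameter(p.name, p.base, dist="fixed") for p in default_params]
        )
        out = run_psa(model, fixed, n_iter=5, seed=1)
        assert out["delta_cost"].nunique() == 1
        assert out["delta_qalys"].nunique() == 1
        base = model(default_params.base_values())
        assert out["delta_cost"].iloc[0] == pytest.approx(base.delta_cost)

    def test_fixed_seed_bit_identical(self, model, default_params):
        a = run_psa(model, default_params, n_iter=20, seed=5)
        b = run_psa(model, default_params, n_iter=20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_draws(self, model, default_params):
        a = run_psa(model, default_params, n_iter=10, seed=5)
        b = run_psa(model, default_params, n_iter=10, seed=6)
        assert not a["delta_cost"].equals(b["delta_cost"])

    def test_draw_columns_recorded(self, model, default_params):
        out = run_psa(model, default_params, n_iter=3, seed=0)
        for p in default_params.varied():
            assert p.name in out.columns


class TestComputeCEAC:
    def test_all_dominant_iterations_give_probability_one(self):
        psa = pd.DataFrame({"delta_cost": [-10.0, -5.0], "delta_qalys": [0.1, 0.2]})
        curve = compute_ceac(psa, np.array([0.0, 1e4, 3e5]))
        assert np.all(curve.probability == 1.0)

    def test_single_iteration_threshold_step(self):
        psa = pd.DataFrame({"delta_cost": [100.0], "delta_qalys": [0.01]})
        curve = compute_ceac(psa, np.array([9_999.0, 10_001.0]))
        assert list(curve.probability) == [0.0, 1.0]

    def test_lambda_zero_is_cost_only(self):
        psa = pd.DataFrame(
            {"delta_cost": [-1.0, 2.0, -3.0, 4.0], "delta_qalys": [0.1] * 4}
        )
        curve = compute_ceac(psa, np.array([0.0]))
        assert curve.probability[0] == 0.5

    def test_monotone_when_all_gain_qalys(self):
        rng = np.random.default_rng(3)
        psa = pd.DataFrame(
            {
                "delta_cost": rng.normal(0, 500, 200),
                "delta_qalys": rng.uniform(0.01, 0.5, 200),
            }
        )
        curve = compute_ceac(psa)
        assert np.all(np.diff(curve.probability) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_ceac(pd.DataFrame({"delta_cost": [], "delta_qalys": []}))


@pytest.fixture(scope="module")
def grid(day90_pair, default_params, life_table):
    day90 = {"ATE": day90_pair, "ATT": day90_pair}
    return run_scenarios(
        day90, default_params, life_table,
        horizons=(TREE_ONLY_HORIZON, 5, 10, 40),
    )


class TestRunScenarios:
    def test_grid_shape(self, grid):
        assert len(grid) == 8  # 4 horizons x 2 estimands
        assert set(grid["estimand"]) == {"ATE", "ATT"}

    def test_qaly_gain_grows_with_horizon(self, grid):
        ate = grid[grid["estimand"] == "ATE"].sort_values("horizon_years")
        de = ate["delta_qalys"].to_numpy()
        assert np.all(np.diff(de) >= -1e-12)

    def test_ninety_day_scenario_is_tree_only(
        self, day90_pair, default_params, life_table
    ):
        """The 90-day cell must be invariant to discount rates and
        recurrence inputs (structurally undiscounted, no Markov phase)."""
        day90 = {"ATE": day90_pair}
        base = run_scenarios(
            day90, default_params, life_table,
            horizons=(TREE_ONLY_HORIZON,), estimands=("ATE",),
        )
        shifted = ParameterSet(
            [
                Parameter(
                    p.name,
                    0.0 if p.name.startswith("discount") else p.base,
                    dist="fixed",
                )
                for p in default_params
            ]
        )
        alt = run_scenarios(
            day90, shifted, life_table,
            horizons=(TREE_ONLY_HORIZON,), estimands=("ATE",),
        )
        assert base["delta_cost"].iloc[0] == pytest.approx(alt["delta_cost"].iloc[0])
        assert base["delta_qalys"].iloc[0] == pytest.approx(alt["delta_qalys"].iloc[0])

    def test_unknown_estimand_rejected(self, day90_pair, default_params, life_table):
        with pytest.raises(ValueError):
            run_scenarios(
                {"ATE": day90_pair}, default_params, life_table,
                estimands=("ITT",),
            )

    def test_fractional_long_horizon_rejected(
        self, day90_pair, default_params, life_table
    ):
        with pytest.raises(ValueError):
            run_scenarios(
                {"ATE": day90_pair}, default_params, life_table,
                horizons=(2.5,), estimands=("ATE",),
            )
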