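import numpy as np
import pandas as pd
import pytest

from topotreeline.modeling import (
    ConditionalInferenceTree,
    DeviationForest,
    ForestConfig,
    fit_ctree,
    fit_forest,
    split_features,
    summarize_terminal_nodes,
)
from topotreeline.synthetic import EffectSpec, generate_feature_table


def table_with(effect, n=600, seed=0):
    return generate_feature_table(n, effect, seed=seed)


@pytest.fixture(scope="module")
def curvature_table():
    # deviation = 300 on concave terrain, 0 on convex, plus noise
    effect = EffectSpec(
        intercept=300.0,
        threshold_terms=[("curvature", 0.0, -300.0)],
        noise_sd=40.0,
    )
    return table_with(effect, n=600, seed=5)


class TestSplitFeatures:
    def test_identifier_columns_are_excluded(self, curvature_table):
        t = curvature_table.copy()
        t["point_id"] = "p"
        t["easting"] = 0.0
        X, y = split_features(t)
        assert "easting" not in X.columns and "point_id" not in X.columns
        assert X.shape[1] == 17 and len(y) == len(t)

    def test_missing_values_rejected(self, curvature_table):
        t = curvature_table.copy()
        t.loc[3, "slope_percent"] = np.nan
        with pytest.raises(ValueError):
            split_features(t)


class TestDeviationForest:
    def test_strong_single_variable_signal_gives_high_oob_r2(self, curvature_table):
        forest = fit_forest(curvature_table, ForestConfig(n_trees=150, seed=1))
        assert forest.oob_r2_ >= 0.8

    def test_pure_noise_gives_near_zero_oob_r2(self):
        effect = EffectSpec(intercept=200.0, noise_sd=60.0)
        forest = fit_forest(table_with(effect, seed=2), ForestConfig(n_trees=150, seed=2))
        assert forest.oob_r2_ <= 0.05

    def test_same_seed_reproduces_oob_predictions(self, curvature_table):
        cfg = ForestConfig(n_trees=60, seed=9)
        a = fit_forest(curvature_table, cfg)
        b = fit_forest(curvature_table, cfg)
        np.testing.assert_array_equal(a.oob_prediction_, b.oob_prediction_)
        assert a.oob_r2_ == b.oob_r2_

    def test_noiseless_deterministic_response_recovered(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 800), "z": rng.uniform(0, 1, 800)})
        y = 100.0 * (X["x"] > 0.5)
        forest = DeviationForest(n_trees=150, random_state=3).fit(X, y)
        assert forest.oob_r2_ >= 0.9

    def test_too_few_rows_rejected(self, curvature_table):
        with pytest.raises(ValueError):
            fit_forest(curvature_table.head(20))


class TestPermutationImportance:
    def test_driving_variable_ranked_first(self, curvature_table):
        forest = fit_forest(curvature_table, ForestConfig(n_trees=150, seed=4))
        imp = forest.permutation_importance()
        assert imp.iloc[0]["variable"] == "curvature"
        assert sorted(imp["rank"]) == list(range(1, 18))

    def test_irrelevant_variables_near_zero(self, curvature_table):
        forest = fit_forest(curvature_table, ForestConfig(n_trees=150, seed=4))
        imp = forest.permutation_importance().set_index("variable")
        assert abs(imp.loc["erosion_index", "pct_inc_mse"]) < 5.0

    def test_permuted_response_nulls_all_importances(self, curvature_table):
        t = curvature_table.copy()
        rng = np.random.default_rng(6)
        t["elevation_deviation"] = rng.permutation(t["elevation_deviation"].to_numpy())
        forest = fit_forest(t, ForestConfig(n_trees=150, seed=6))
        imp = forest.permutation_importance()
        assert imp["pct_inc_mse"].abs().max() < 5.0


class TestPartialDependence:
    def test_constant_ensemble_gives_flat_curve(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 200), "z": rng.uniform(0, 1, 200)})
        y = np.full(200, 42.0)
        forest = DeviationForest(n_trees=40, random_state=7).fit(X, y)
        curve = forest.partial_dependence("x")
        assert np.allclose(curve["mean_prediction"], 42.0)

    def test_linear_response_recovers_slope(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"x": rng.uniform(0, 10, 1000), "z": rng.uniform(0, 10, 1000)}
        )
        y = 2.0 * X["x"] + rng.normal(0, 0.5, 1000)
        forest = DeviationForest(n_trees=100, random_state=8).fit(X, y)
        curve = forest.partial_dependence("x")
        interior = curve.iloc[3:-3]
        slope = np.polyfit(interior["grid_value"], interior["mean_prediction"], 1)[0]
        assert slope == pytest.approx(2.0, abs=0.3)

    def test_irrelevant_variable_curve_is_flat(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            {"x": rng.uniform(0, 10, 1000), "z": rng.uniform(0, 10, 1000)}
        )
        y = 2.0 * X["x"] + rng.normal(0, 0.5, 1000)
        # let every split see both variables so the informative one wins
        forest = DeviationForest(
            n_trees=100, candidate_vars_per_split=2, random_state=9
        ).fit(X, y)
        curve = forest.partial_dependence("z")
        spread = curve["mean_prediction"].max() - curve["mean_prediction"].min()
        assert spread < 0.1 * np.std(y)

    def test_unknown_variable_rejected(self, curvature_table):
        forest = fit_forest(curvature_table, ForestConfig(n_trees=30, seed=1))
        with pytest.raises(ValueError):
            forest.partial_dependence("not_a_variable")


class TestConditionalInferenceTree:
    def test_threshold_recovery_on_step_response(self):
        effect = EffectSpec(
            intercept=150.0,
            threshold_terms=[("annual_precipitation", 5664.0, 120.0)],
            noise_sd=20.0,
        )
        table = table_with(effect, n=1000, seed=11)
        tree = fit_ctree(table, n_permutations=999, seed=11)
        root = tree.tree_
        assert root.split_var == "annual_precipitation"
        assert 5564.0 <= root.threshold <= 5764.0
        assert root.p_adjusted < 0.05

    def test_nested_thresholds_recovered_in_order(self):
        effect = EffectSpec(
            intercept=100.0,
            threshold_terms=[
                ("annual_precipitation", 5000.0, 200.0),
                ("curvature", 0.0, -80.0),
            ],
            noise_sd=15.0,
        )
        table = table_with(effect, n=1200, seed=12)
        tree = fit_ctree(table, n_permutations=999, seed=12)
        root = tree.tree_
        assert root.split_var == "annual_precipitation"
        assert {root.left.split_var, root.right.split_var} == {"curvature"}

    def test_constant_response_yields_terminal_root(self):
        effect = EffectSpec(intercept=150.0, noise_sd=0.0)
        table = table_with(effect, n=200, seed=13)
        tree = fit_ctree(table, n_permutations=199, seed=13)
        assert tree.tree_.is_terminal

    def test_partition_property_and_member_medians(self):
        effect = EffectSpec(
            intercept=120.0, beta_curvature=-100.0, noise_sd=25.0
        )
        table = table_with(effect, n=800, seed=14)
        tree = fit_ctree(table, n_permutations=499, seed=14)
        X, y = split_features(table)
        node_ids = tree.apply(X)
        terms = tree.terminal_nodes()
        assert sum(t.n for t in terms) == len(table)
        for t in terms:
            members = node_ids == t.node_id
            assert members.sum() == t.n
            assert np.median(y[members]) == pytest.approx(t.median)

    def test_predict_returns_terminal_medians_and_is_deterministic(self):
        effect = EffectSpec(intercept=100.0, beta_slope=-0.8, noise_sd=20.0)
        table = table_with(effect, n=500, seed=15)
        a = fit_ctree(table, n_permutations=499, seed=15)
        b = fit_ctree(table, n_permutations=499, seed=15)
        X, _ = split_features(table)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        medians = {t.node_id: t.median for t in a.terminal_nodes()}
        assert set(np.unique(a.predict(X))) <= set(medians.values())

    def test_min_node_respected(self):
        effect = EffectSpec(intercept=100.0, beta_curvature=-150.0, noise_sd=10.0)
        table = table_with(effect, n=400, seed=16)
        tree = fit_ctree(table, n_permutations=499, min_node=40, seed=16)
        assert min(t.n for t in tree.terminal_nodes()) >= 40

    def test_json_and_text_renderings(self):
        import json

        effect = EffectSpec(
            intercept=150.0,
            threshold_terms=[("annual_precipitation", 5664.0, 120.0)],
            noise_sd=20.0,
        )
        table = table_with(effect, n=600, seed=17)
        tree = fit_ctree(table, n_permutations=499, seed=17)
        blob = json.loads(tree.to_json())
        assert blob["alpha"] == 0.05
        assert blob["tree"]["n"] == 600
        text = tree.render_text()
        assert "annual_precipitation" in text

    def test_sklearn_params_protocol(self):
        est = ConditionalInferenceTree(alpha=0.01, min_node=10)
        params = est.get_params()
        assert params["alpha"] == 0.01 and params["min_node"] == 10


class TestSummarizeTerminalNodes:
    def test_single_node_tree_row_is_global_median(self):
        effect = EffectSpec(intercept=200.0, noise_sd=50.0)
        table = table_with(effect, n=300, seed=18)
        tree = fit_ctree(table, n_permutations=499, seed=18)
        summary = summarize_terminal_nodes(tree)
        if len(summary) == 1:
            assert summary.iloc[0]["median_deviation"] == pytest.approx(
                table["elevation_deviation"].median()
            )
            assert summary.iloc[0]["rule"] == "(root)"
        assert summary["n"].sum() == 300

    def test_rules_reconstruct_node_membership(self):
        effect = EffectSpec(
            intercept=150.0,
            threshold_terms=[("annual_precipitation", 5664.0, 120.0)],
            noise_sd=20.0,
        )
        table = table_with(effect, n=600, seed=19)
        tree = fit_ctree(table, n_permutations=499, seed=19)
        summary = summarize_terminal_nodes(tree)
        X, _ = split_features(table)
        node_ids = tree.apply(X)
        for _, row in summary.iterrows():
            if row["rule"] == "(root)":
                continue
            members = table.eval(
                " and ".join(f"({r})" for r in row["rule"].split(" and "))
            )
            assert members.sum() == row["n"]
            assert set(np.nonzero(members.to_numpy())[0]) == set(
                np.nonzero(node_ids == row["node_id"])[0]
            )
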