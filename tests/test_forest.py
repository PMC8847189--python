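import numpy as np
import pytest

from methylage.cohort import filter_age_range
from methylage.errors import ConfigurationError
from methylage.forest import (
    CurvatureForestRegressor,
    cohort_features,
    curvature_select,
    fit_forest,
    grow_tree,
    predict_age,
)

from _oracles import bin_codes, chi2_independence_oracle, reference_tree_predictions


class TestCurvatureSelect:
    def test_staircase_dependence_beats_noise(self):
        """A predictor that drives the response wins over pure noise."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 1, 200)
            b = rng.uniform(0, 1, 200)
            y = np.floor(a * 4) * 10.0 + rng.normal(0, 0.01, 200)
            best, pvals = curvature_select(np.column_stack([a, b]), y)
            if best == 0 and pvals[0] < 1e-6 and pvals[1] > 0.01:
                wins += 1
        assert wins >= 95

    def test_single_candidate_always_returned(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (30, 1))
        y = rng.uniform(0, 1, 30)
        best, pvals = curvature_select(X, y)
        assert best == 0 and pvals.shape == (1,)

    def test_twelve_row_fixture_matches_enumerated_table_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0])
        y = np.array([5.0, 4.0, 6.0, 5.5, 4.5, 6.5, 9.0, 8.0, 10.0, 9.5, 8.5, 10.5])
        best, pvals = curvature_select(x[:, None], y, n_bins=2)
        stat, df, p_oracle = chi2_independence_oracle(
            bin_codes(x, 2), bin_codes(y, 2), 2
        )
        assert best == 0
        assert df == 1
        assert pvals[0] == pytest.approx(p_oracle, rel=1e-8)

    def test_all_constant_candidates_give_none(self):
        X = np.full((20, 3), 7.0)
        y = np.arange(20.0)
        best, pvals = curvature_select(X, y)
        assert best is None
        assert (pvals == 1.0).all()

    def test_invariant_under_strictly_monotone_predictor_transform(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (100, 3))
        y = 10 * X[:, 1] + rng.normal(0, 0.5, 100)
        best1, p1 = curvature_select(X, y)
        X2 = X.copy()
        X2[:, 1] = np.exp(5 * X2[:, 1])  # strictly increasing
        best2, p2 = curvature_select(X2, y)
        assert best1 == best2 == 1
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_candidate_subset_respected(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (50, 3))
        y = 10 * X[:, 0] + rng.normal(0, 0.1, 50)
        best, pvals = curvature_select(X, y, candidate_set=[1, 2])
        assert best in (1, 2)
        assert pvals.shape == (2,)


class TestGrowTree:
    def test_constant_response_is_single_leaf(self):
        X = np.random.default_rng(0).uniform(0, 1, (20, 2))
        tree = grow_tree(X, np.full(20, 33.0), min_leaf=1)
        assert tree.feature.size == 1 and tree.feature[0] == -1
        assert tree.value[0] == 33.0

    def test_perfect_step_gives_depth_one_tree(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9])
        y = np.where(x < 0.5, 20.0, 60.0)
        tree = grow_tree(x[:, None], y, min_leaf=1, n_bins=2)
        assert tree.depth == 1
        assert sorted(tree.value[tree.feature == -1].tolist()) == [20.0, 60.0]
        assert 0.4 < tree.threshold[0] < 0.6

    def test_thirty_row_fixture_matches_exhaustive_split_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (30, 3))
        y = 30 * X[:, 0] + 10 * (X[:, 2] > 0.5) + rng.normal(0, 1, 30)
        for min_leaf in (3, 5):
            tree = grow_tree(X, y, min_leaf=min_leaf, n_bins=4)
            expected = reference_tree_predictions(X, y, min_leaf=min_leaf, n_bins=4)
            np.testing.assert_allclose(tree.predict(X), expected, rtol=1e-10)

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (60, 2))
        y = 50 * X[:, 0] + rng.normal(0, 1, 60)
        tree = grow_tree(X, y, min_leaf=7)
        assert tree.n_node[tree.feature == -1].min() >= 7


class TestForest:
    def test_single_tree_with_giant_leaf_predicts_mean(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (40, 3))
        y = rng.uniform(10, 60, 40)
        model = CurvatureForestRegressor(
            n_estimators=1, min_samples_leaf=40, random_state=0
        ).fit(X, y)
        # a bootstrap of all 40 rows cannot split: every prediction is its mean
        preds = model.predict(X)
        assert np.ptp(preds) == 0.0
        assert model.y_min_ <= preds[0] <= model.y_max_

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (80, 4))
        y = 40 * X[:, 0] + rng.normal(0, 2, 80)
        p1 = CurvatureForestRegressor(n_estimators=20, random_state=3).fit(X, y).predict(X)
        p2 = CurvatureForestRegressor(n_estimators=20, random_state=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_bounded_by_training_age_range(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (100, 4))
        y = 55 * X[:, 1] + 10 + rng.normal(0, 2, 100)
        model = CurvatureForestRegressor(n_estimators=30, random_state=1).fit(X, y)
        X_new = rng.uniform(-2, 3, (50, 4))  # far outside the training box
        preds = model.predict(X_new)
        assert (preds >= y.min()).all() and (preds <= y.max()).all()

    def test_training_mae_beats_constant_baseline(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (120, 4))
        y = 50 * X[:, 0] + rng.normal(0, 3, 120)
        model = CurvatureForestRegressor(n_estimators=50, random_state=2).fit(X, y)
        mae = np.mean(np.abs(model.predict(X) - y))
        baseline = np.mean(np.abs(y - y.mean()))
        assert mae <= baseline

    def test_two_tree_manual_trace(self):
        """Forest prediction equals the hand-traced mean of two depth-1 trees."""
        doc = {
            "schema": "methylage.curvature_forest/1",
            "params": CurvatureForestRegressor(n_estimators=2).get_params(),
            "n_features_in": 1,
            "feature_names": None,
            "y_range": [10.0, 70.0],
            "trees": [
                {"feature": [0, -1, -1], "threshold": [0.5, None, None],
                 "left": [1, -1, -1], "right": [2, -1, -1],
                 "value": [40.0, 20.0, 60.0], "n_node": [10, 5, 5]},
                {"feature": [0, -1, -1], "threshold": [0.25, None, None],
                 "left": [1, -1, -1], "right": [2, -1, -1],
                 "value": [40.0, 10.0, 70.0], "n_node": [10, 5, 5]},
            ],
        }
        import json

        model = CurvatureForestRegressor.from_json(json.dumps(doc))
        # x=0.3: tree1 -> 20 (0.3<=0.5), tree2 -> 70 (0.3>0.25) => 45
        # x=0.9: tree1 -> 60, tree2 -> 70 => 65
        np.testing.assert_allclose(model.predict([[0.3], [0.9]]), [45.0, 65.0])

    def test_json_round_trip_is_bit_stable(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (60, 3))
        y = 30 * X[:, 2] + rng.normal(0, 2, 60)
        model = CurvatureForestRegressor(n_estimators=10, random_state=4).fit(X, y)
        clone = CurvatureForestRegressor.from_json(model.to_json())
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))

    def test_oob_error_decreases_with_more_trees(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (150, 4))
        y = 40 * X[:, 0] + 15 * X[:, 1] + rng.normal(0, 3, 150)
        model = CurvatureForestRegressor(
            n_estimators=120, random_state=5, compute_oob=True
        ).fit(X, y)
        curve = model.oob_error_curve([5, 30, 120])
        assert curve[-1] <= curve[0]
        assert model.oob_mae_ == pytest.approx(curve[-1])

    def test_config_errors(self):
        with pytest.raises(ConfigurationError):
            CurvatureForestRegressor(n_estimators=0).fit([[1.0]], [1.0])

    def test_sklearn_params_round_trip(self):
        model = CurvatureForestRegressor(n_estimators=7, n_bins=3)
        params = model.get_params()
        assert params["n_estimators"] == 7
        clone = CurvatureForestRegressor(**params)
        assert clone.get_params() == params


@pytest.fixture(scope="module")
def screened(null_scenario):
    from methylage.cohort import select_cpgs_by_correlation

    cohort = filter_age_range(null_scenario.simulate(seed=8), 10, 65)
    panel, _ = select_cpgs_by_correlation(cohort.population_cohort("german"), 0.75)
    return cohort.with_panel(panel)


class TestCohortInterface:
    def test_fit_forest_and_predict_age(self, screened):
        de = screened.population_cohort("german")
        model = fit_forest(de, n_estimators=30, seed=0)
        assert list(model.feature_names_in_) == screened.panel.columns + ["sex"]
        japanese = screened.population_cohort("japanese")
        preds = predict_age(model, japanese)
        assert preds.shape == (japanese.n,)
        assert (preds >= model.y_min_).all() and (preds <= model.y_max_).all()

    def test_unexpected_panel_size_warns(self, screened, caplog):
        de = screened.population_cohort("german")
        small = screened.panel.subset(screened.panel.columns[:5])
        with caplog.at_level("WARNING"):
            fit_forest(de.with_panel(small), n_estimators=2, seed=0)
        assert "20" in caplog.text

    def test_missing_feature_is_named(self, screened):
        de = screened.population_cohort("german")
        model = fit_forest(de, n_estimators=2, seed=0)
        broken = screened.population_cohort("japanese").data.drop(columns=["PDE4C_CpG1"])
        with pytest.raises(ValueError, match="PDE4C_CpG1"):
            predict_age(model, broken)

    def test_sex_column_required(self, screened):
        de = screened.population_cohort("german")
        model = fit_forest(de, n_estimators=2, seed=0)
        broken = screened.population_cohort("japanese").data.drop(columns=["sex"])
        with pytest.raises(ValueError, match="sex"):
            predict_age(model, broken)
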