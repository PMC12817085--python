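import numpy as np
import pandas as pd
import pytest

import stopext as se
from stopext.model import ModelError, cross_val_auroc


def separable_data(n=120, seed=0):
    """Two planted informative features among noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)])
    X["f0"] += 3.0 * y
    X["f1"] -= 3.0 * y
    return X, y


class TestGridSearch:
    def test_default_grid_has_120_combinations(self):
        assert len(se.ModelConfig().grid) == 120

    def test_empty_grid_rejected(self):
        with pytest.raises(ModelError):
            se.ModelConfig(mtry_grid=())

    def test_separable_data_reaches_high_cv_auroc(self):
        X, y = separable_data()
        config = se.ModelConfig(mtry_grid=(2,), ntree_grid=(20, 50),
                                max_node_grid=(5, 10), seed=3)
        params, table = se.grid_search_cv(X, y, config)
        assert len(table) == 4
        assert table["cv_auroc"].max() >= 0.99

    def test_same_seed_gives_identical_selection(self):
        X, y = separable_data()
        config = se.ModelConfig(mtry_grid=(2, 4), ntree_grid=(20,),
                                max_node_grid=(5,), seed=5)
        p1, t1 = se.grid_search_cv(X, y, config)
        p2, t2 = se.grid_search_cv(X, y, config)
        assert p1 == p2
        pd.testing.assert_frame_equal(t1, t2)

    def test_ties_broken_toward_smaller_forest(self):
        X, y = separable_data()  # everything reaches AUROC 1.0 -> ties
        config = se.ModelConfig(mtry_grid=(2,), ntree_grid=(50, 20),
                                max_node_grid=(10, 5), seed=1)
        params, table = se.grid_search_cv(X, y, config)
        tied = table[table["cv_auroc"] == table["cv_auroc"].max()]
        assert params["ntree"] == tied["ntree"].min()

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ModelError, match="both classes"):
            cross_val_auroc(X, np.zeros(len(X)), 2, 20, 5)


@pytest.fixture(scope="module")
def small_model():
    X, y = separable_data(seed=2)
    return se.train(X, y, {"mtry": 2, "ntree": 50, "max_node": 10}, seed=2), X, y


class TestTrainPredict:
    def test_scores_in_unit_interval(self, small_model, session_rng):
        m, X, _ = small_model
        Xnew = pd.DataFrame(session_rng.normal(size=(1000, 8)), columns=X.columns)
        s = se.predict(m, Xnew)
        assert np.all((s >= 0) & (s <= 1))

    def test_identical_rows_get_identical_scores(self, small_model):
        m, X, _ = small_model
        twice = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        s = se.predict(m, twice)
        assert s[0] == s[1]

    def test_all_missing_row_scores_at_the_median_point(self, small_model):
        m, X, _ = small_model
        missing = pd.DataFrame([[np.nan] * X.shape[1]], columns=X.columns)
        medians = pd.DataFrame([m.medians[list(X.columns)]], columns=X.columns)
        assert se.predict(m, missing)[0] == se.predict(m, medians)[0]

    def test_prediction_is_the_mean_of_tree_outputs(self, small_model, session_rng):
        m, X, _ = small_model
        rows = pd.DataFrame(session_rng.normal(size=(10, 8)), columns=X.columns)
        ensemble = se.predict(m, rows)
        per_tree = np.mean(
            [t.predict_proba(rows.to_numpy())[:, 1] for t in m.forest.estimators_],
            axis=0,
        )
        np.testing.assert_allclose(ensemble, per_tree, atol=1e-12)

    def test_max_node_caps_terminal_leaves(self, small_model):
        m, _, _ = small_model
        for tree in m.forest.estimators_:
            assert tree.get_n_leaves() <= m.hyperparams["max_node"]

    def test_registry_mismatch_rejected(self, small_model):
        m, X, _ = small_model
        bad = X.rename(columns={"f0": "g0"})
        with pytest.raises(ModelError, match="registry"):
            se.predict(m, bad)

    def test_planted_class_separation_on_training_scores(self, small_model):
        m, X, y = small_model
        s = se.predict(m, X)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_tiny_dataset_trains(self):
        X, y = separable_data(n=10, seed=4)
        m = se.train(X, y, {"mtry": 2, "ntree": 10, "max_node": 5}, seed=4)
        assert m.cv_auroc is not None


class TestImportance:
    def test_planted_features_rank_top(self, small_model=None):
        X, y = separable_data(n=300, seed=6)
        m = se.train(X, y, {"mtry": 2, "ntree": 100, "max_node": 10}, seed=6)
        table = se.importance(m)
        assert len(table) == X.shape[1]
        assert table["importance"].iloc[0] == 100.0
        top = set(table["feature"].head(3))
        assert {"f0", "f1"} <= top

    def test_pure_noise_labels_show_no_dominant_feature(self):
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(100, 8)),
                             columns=[f"f{i}" for i in range(8)])
            y = rng.integers(0, 2, size=100)
            if len(np.unique(y)) < 2:
                continue
            m = se.train(X, y, {"mtry": 2, "ntree": 50, "max_node": 10}, seed=seed)
            imp = se.importance(m)["importance"]
            ratios.append(imp.max() / imp.median())
        assert np.median(ratios) < 3.0

    def test_importance_covers_all_37_features(self, trained_model):
        table = se.importance(trained_model)
        assert len(table) == 37
        assert set(table["feature"]) == set(se.FEATURE_NAMES)


class TestEvaluate:
    def test_perfect_separation(self):
        assert se.evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])["auroc"] == 1.0

    def test_reversed_scores_complement(self, session_rng):
        y = session_rng.integers(0, 2, size=200)
        s = session_rng.random(200)
        a = se.evaluate(s, y)["auroc"]
        assert se.evaluate(-s, y)["auroc"] == pytest.approx(1 - a)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(42)
        y = np.repeat([0, 1], 2000)
        s = rng.random(4000)
        assert se.evaluate(s, y)["auroc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            se.evaluate([0.1, 0.9], [1, 1])


class TestSerialization:
    def test_round_trip(self, tmp_path):
        X, y = separable_data(seed=8)
        m = se.train(X, y, {"mtry": 2, "ntree": 20, "max_node": 5}, seed=8)
        path = tmp_path / "model.joblib"
        se.save_model(m, path)
        back = se.load_model(path)
        np.testing.assert_array_equal(se.predict(back, X), se.predict(m, X))

    def test_refuses_registry_mismatch(self, tmp_path):
        X, y = separable_data(seed=9)
        m = se.train(X, y, {"mtry": 2, "ntree": 20, "max_node": 5}, seed=9)
        path = tmp_path / "model.joblib"
        se.save_model(m, path)
        with pytest.raises(ModelError, match="registry"):
            se.load_model(path, expected_features=("other",))
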