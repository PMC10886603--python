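"""Random survival forest: structure, determinism, degenerate cases, importance."""

import numpy as np
import pandas as pd
import pytest

from nbsig import RandomSurvivalForest, permutation_importance
from nbsig.simulate import CohortTruth, simulate_cohort


@pytest.fixture(scope="module")
def small_fit(planted_cohort_module):
    X, y = planted_cohort_module
    forest = RandomSurvivalForest(
        n_estimators=40, max_depth=3, min_node_size=10, max_features=3, random_state=1,
        oob_score=True,
    ).fit(X, y)
    return forest, X, y


@pytest.fixture(scope="module")
def planted_cohort_module():
    genes = [f"g{i}" for i in range(8)]
    truth = CohortTruth(signature_genes=tuple(genes[:4]), beta=0.9, covariate_betas={})
    expr, clin = simulate_cohort(250, genes, truth, seed=9)
    X = expr.values.T
    y = (clin["efs_time_years"].to_numpy(), clin["efs_event"].to_numpy())
    return X, y


class TestStructure:
    def test_tree_count_and_grid(self, small_fit):
        forest, X, y = small_fit
        assert len(forest.trees_) == 40
        assert (np.diff(forest.event_times_) > 0).all()

    def test_depth_and_node_size_respected(self, small_fit):
        forest, _, _ = small_fit
        for tree in forest.trees_:
            for node in tree.nodes:
                assert node.depth <= 3
                if node.is_leaf:
                    # every leaf reached via a split holds >= min_node_size
                    assert node.n_samples >= 10 or node.node_id == 0
                else:
                    assert node.n_events >= 1

    def test_terminal_hazard_is_nondecreasing(self, small_fit):
        forest, _, _ = small_fit
        for tree in forest.trees_:
            for node in tree.nodes:
                if node.is_leaf:
                    assert (np.diff(node.chf) >= -1e-12).all()

    def test_too_small_mtry_or_data_rejected(self, planted_cohort_module):
        X, y = planted_cohort_module
        with pytest.raises(ValueError, match="max_features"):
            RandomSurvivalForest(max_features=100).fit(X, y)
        with pytest.raises(ValueError, match="min_node_size"):
            RandomSurvivalForest(max_features=2, min_node_size=1000).fit(X, y)

    def test_all_censored_rejected(self, planted_cohort_module):
        X, _ = planted_cohort_module
        y = (np.linspace(1, 5, len(X)), np.zeros(len(X), int))
        with pytest.raises(ValueError, match="censored"):
            RandomSurvivalForest(max_features=2).fit(X, y)


class TestDegenerate:
    def test_depth_zero_gives_constant_mortality(self, planted_cohort_module):
        X, y = planted_cohort_module
        forest = RandomSurvivalForest(
            n_estimators=10, max_depth=0, min_node_size=10, max_features=2, random_state=0
        ).fit(X, y)
        scores = forest.predict(X)
        assert np.allclose(scores, scores[0])
        # closed form: every tree is one root; mortality = sum of root CHF
        mean_chf = np.mean([t.nodes[0].chf for t in forest.trees_], axis=0)
        assert scores[0] == pytest.approx(mean_chf.sum(), rel=1e-12)

    def test_perfect_binary_separation_orders_groups(self):
        n = 40
        x = np.repeat([1.0, 0.0], n // 2)
        time = np.r_[np.linspace(0.2, 1.0, n // 2), np.linspace(8, 10, n // 2)]
        event = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = pd.DataFrame({"risk": x})
        forest = RandomSurvivalForest(
            n_estimators=30, max_depth=2, min_node_size=5, max_features=1, random_state=2
        ).fit(X, (time, event))
        scores = forest.predict(X)
        assert scores[: n // 2].min() > scores[n // 2 :].max()


class TestDeterminism:
    def test_refit_identical(self, planted_cohort_module):
        X, y = planted_cohort_module
        kw = dict(n_estimators=15, max_depth=2, min_node_size=10, max_features=3, random_state=7)
        s1 = RandomSurvivalForest(**kw).fit(X, y).predict(X)
        s2 = RandomSurvivalForest(**kw).fit(X, y).predict(X)
        np.testing.assert_array_equal(s1, s2)

    def test_same_sample_scored_twice_identical(self, small_fit):
        forest, X, _ = small_fit
        one = forest.predict(X.iloc[[3]])
        again = forest.predict(X.iloc[[3]])
        assert one[0] == again[0]

    def test_feature_order_invariance(self, planted_cohort_module):
        X, y = planted_cohort_module
        kw = dict(n_estimators=15, max_depth=2, min_node_size=10, max_features=3, random_state=7)
        s1 = RandomSurvivalForest(**kw).fit(X, y).predict(X)
        shuffled = X[list(X.columns[::-1])]
        s2 = RandomSurvivalForest(**kw).fit(shuffled, y).predict(shuffled)
        np.testing.assert_array_equal(s1, s2)

    def test_missing_feature_at_predict_rejected(self, small_fit):
        forest, X, _ = small_fit
        with pytest.raises(ValueError, match="missing features"):
            forest.predict(X.drop(columns=[X.columns[0]]))

    def test_json_round_trip(self, small_fit):
        forest, X, _ = small_fit
        clone = RandomSurvivalForest.from_json(forest.to_json())
        np.testing.assert_allclose(clone.predict(X), forest.predict(X))


class TestEnsembleBehaviour:
    def test_oob_concordance_beats_mean_single_tree(self, small_fit):
        from sksurv.metrics import concordance_index_censored

        forest, X, y = small_fit
        time, event = y
        arr = X[forest.feature_names_].to_numpy(float)
        tree_scores = []
        for tree in forest.trees_:
            oob = np.flatnonzero(tree.inbag_counts == 0)
            if (event[oob] == 1).sum() < 2:
                continue
            c = concordance_index_censored(
                event[oob].astype(bool), time[oob], tree.mortality_for(arr[oob])
            )[0]
            tree_scores.append(c)
        assert forest.oob_score_ >= np.mean(tree_scores)

    def test_monotone_transform_keeps_median_split(self, small_fit):
        from nbsig import median_split

        forest, X, _ = small_fit
        scores = forest.predict(X)
        med = np.median(scores)
        labels = median_split(scores, med)
        labels2 = median_split(np.exp(scores), np.exp(med))
        assert (labels == labels2).all()


class TestPermutationImportance:
    def test_identity_permutation_is_exactly_zero(self, small_fit):
        forest, X, y = small_fit
        imp = permutation_importance(forest, X, y, seed=0, shuffle_fn=lambda v, rng: v)
        assert (imp == 0).all()

    def test_informative_feature_ranks_first(self):
        # one signal feature among three noise features
        rng = np.random.default_rng(4)
        n = 200
        signal = rng.standard_normal(n)
        X = pd.DataFrame(
            {
                "signal": signal,
                **{f"noise{i}": rng.standard_normal(n) for i in range(3)},
            }
        )
        time = rng.exponential(1 / np.exp(1.2 * signal))
        event = (rng.random(n) < 0.85).astype(int)
        forest = RandomSurvivalForest(
            n_estimators=50, max_depth=3, min_node_size=10, max_features=2, random_state=5
        ).fit(X, (time, event))
        imp = permutation_importance(forest, X, (time, event), seed=1)
        assert imp.idxmax() == "signal"
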