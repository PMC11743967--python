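"""Cluster-weighted exercise recommendation: statistics, weighting, scores,
ranking, and an end-to-end brute-force oracle on a toy cohort."""

import numpy as np
import pytest

from phenorec import (
    ConfigError,
    ExerciseRecommender,
    RecommenderConfig,
    SoftL1KMeans,
    UtilityRecord,
    cluster_weights,
    exercise_score,
    fit_utility_stats,
    rank_exercises,
)


@pytest.fixture()
def two_cluster_model():
    """1-D model with centroids pinned at 0.0 and 1.0."""
    X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
    return SoftL1KMeans(n_clusters=2, n_init=5, random_state=0).fit(X)


class TestUtilityStats:
    def test_constant_ratings(self):
        records = [UtilityRecord(f"P{i}", 1, 2) for i in range(4)]
        labels = {"P0": 0, "P1": 0, "P2": 1, "P3": 1}
        stats = fit_utility_stats(records, labels, n_exercises=2, n_clusters=2)
        assert stats.overall_mean[0] == 2.0
        assert stats.overall_sd[0] == 0.0
        assert stats.cluster_means[0, 0] == 2.0 and stats.cluster_means[1, 0] == 2.0

    def test_hand_computed_split(self):
        records = [UtilityRecord("P0", 1, 0), UtilityRecord("P1", 1, 4)]
        labels = {"P0": 0, "P1": 1}
        stats = fit_utility_stats(records, labels, n_exercises=1, n_clusters=2)
        assert stats.overall_mean[0] == 2.0
        assert stats.overall_sd[0] == 2.0  # population SD
        assert stats.cluster_means[0, 0] == 0.0
        assert stats.cluster_means[1, 0] == 4.0

    def test_empty_records_flag_all_unrated(self):
        stats = fit_utility_stats([], {}, n_exercises=3, n_clusters=2)
        assert stats.unrated == [1, 2, 3]

    def test_unknown_participant_rejected(self):
        with pytest.raises(ConfigError, match="GHOST"):
            fit_utility_stats(
                [UtilityRecord("GHOST", 1, 3)], {"P0": 0}, n_exercises=1, n_clusters=1
            )

    def test_rating_outside_scale_rejected(self):
        with pytest.raises(ValueError, match="usefulness"):
            UtilityRecord("P0", 1, 7)


class TestClusterWeights:
    def test_negative_exponential_hand_case(self):
        # distances (0, ln 2) at lambda=1 -> raw (1, 0.5), normalized (2/3, 1/3)
        ln2 = np.log(2)
        X = np.array([[0.0], [0.0], [ln2], [ln2]])
        model = SoftL1KMeans(n_clusters=2, n_init=5, random_state=0).fit(X)
        at_zero = int(model.predict([[0.0]])[0])
        raw, norm = cluster_weights(
            [0.0], model, RecommenderConfig(smoothing_rate=1.0)
        )
        assert raw[at_zero] == pytest.approx(1.0)
        assert raw[1 - at_zero] == pytest.approx(0.5)
        assert norm[at_zero] == pytest.approx(2 / 3)
        assert norm[1 - at_zero] == pytest.approx(1 / 3)

    def test_zero_distance_gives_weight_one(self, two_cluster_model):
        c0 = two_cluster_model.cluster_centers_[0]
        raw, _ = cluster_weights(c0, two_cluster_model)
        assert raw[0] == pytest.approx(1.0)

    def test_equidistant_uniform(self, two_cluster_model):
        _, norm = cluster_weights([0.5], two_cluster_model)
        assert np.allclose(norm, 0.5)

    def test_large_lambda_indicator_limit(self, two_cluster_model):
        _, norm = cluster_weights(
            [0.1], two_cluster_model, RecommenderConfig(smoothing_rate=500.0)
        )
        near = two_cluster_model.predict([[0.1]])[0]
        assert norm[near] == pytest.approx(1.0, abs=1e-12)


class TestExerciseScore:
    def _stats(self, cluster_mean, overall_mean, sd, count=5):
        from phenorec.recommend import UtilityStats

        return UtilityStats(
            n_exercises=1, n_clusters=1,
            overall_mean=np.array([overall_mean]),
            overall_sd=np.array([sd]),
            cluster_means=np.array([[cluster_mean]]),
            cluster_counts=np.array([[count]]),
            unrated=[],
        )

    def test_hand_example(self):
        assert exercise_score(1, 0, self._stats(3.0, 2.0, 1.0)) == 1.0

    def test_zero_deviation(self):
        assert exercise_score(1, 0, self._stats(2.5, 2.5, 1.3)) == 0.0

    def test_zero_sd_convention(self):
        assert exercise_score(1, 0, self._stats(3.0, 2.0, 0.0)) == 0.0

    def test_sparse_cluster_falls_back(self):
        stats = self._stats(4.0, 2.0, 1.0, count=1)
        cfg = RecommenderConfig(min_cluster_ratings=3)
        assert exercise_score(1, 0, stats, cfg) == 0.0

    def test_unknown_exercise_rejected(self):
        with pytest.raises(ConfigError, match="catalogue"):
            exercise_score(9, 0, self._stats(1, 1, 1))


class TestRanking:
    def test_single_cluster_direct_ordering(self):
        from phenorec.recommend import UtilityStats

        X = np.zeros((3, 1))
        model = SoftL1KMeans(n_clusters=1, n_init=1, random_state=0).fit(X)
        stats = UtilityStats(
            n_exercises=3, n_clusters=1,
            overall_mean=np.array([2.0, 2.0, 2.0]),
            overall_sd=np.array([1.0, 1.0, 1.0]),
            cluster_means=np.array([[3.0, 1.5, 2.0]]),  # scores 1.0, -0.5, 0.0
            cluster_counts=np.array([[4, 4, 4]]),
            unrated=[],
        )
        ranking = rank_exercises([0.0], model, stats)
        assert ranking.as_frame()["exercise_id"].tolist() == [1, 3, 2]

    def test_all_ties_rank_in_catalogue_order(self, two_cluster_model):
        records = [
            UtilityRecord(f"P{i}", e, u)
            for e in (1, 2, 3)
            for i, u in enumerate((1, 3, 1, 3))
        ]
        labels = {"P0": 0, "P1": 0, "P2": 1, "P3": 1}
        stats = fit_utility_stats(records, labels, n_exercises=3, n_clusters=2)
        ranking = rank_exercises([0.5], two_cluster_model, stats)
        assert np.allclose(ranking.expected_utility, ranking.expected_utility[0])
        assert ranking.as_frame()["exercise_id"].tolist() == [1, 2, 3]

    def test_default_catalogue_covers_17(self, default_table, default_model, default_events):
        from phenorec.recommend import records_from_events

        labels = dict(zip(default_table.participant_ids, default_model.labels_))
        rec = ExerciseRecommender(default_model, n_exercises=17).fit(
            records_from_events(default_events), labels
        )
        ranking = rec.recommend(default_table.values[0])
        assert sorted(ranking.exercise_ids) == list(range(1, 18))
        assert sorted(ranking.ranks.tolist()) == list(range(1, 18))

    def test_utility_invariant_to_weight_rescaling(self, two_cluster_model):
        records = [
            UtilityRecord("P0", 1, 4), UtilityRecord("P1", 1, 0),
            UtilityRecord("P2", 2, 1), UtilityRecord("P3", 2, 3),
        ]
        labels = {"P0": 0, "P1": 1, "P2": 0, "P3": 1}
        stats = fit_utility_stats(records, labels, n_exercises=2, n_clusters=2)
        ranking = rank_exercises([0.3], two_cluster_model, stats)
        raw, _ = cluster_weights([0.3], two_cluster_model)
        scores = np.array(
            [
                [exercise_score(e, c, stats) for e in (1, 2)]
                for c in (0, 1)
            ]
        )
        for scale in (1.0, 7.3, 0.002):
            w = raw * scale
            u = (w @ scores) / w.sum()
            assert np.allclose(u, ranking.expected_utility, atol=1e-12)

    def test_hard_cluster_limit_matches_best_cluster_score(self, two_cluster_model):
        records = [
            UtilityRecord("P0", 1, 4), UtilityRecord("P1", 1, 0),
            UtilityRecord("P2", 2, 0), UtilityRecord("P3", 2, 4),
            UtilityRecord("P4", 3, 2), UtilityRecord("P5", 3, 3),
        ]
        labels = {"P0": 0, "P1": 1, "P2": 0, "P3": 1, "P4": 0, "P5": 1}
        stats = fit_utility_stats(records, labels, n_exercises=3, n_clusters=2)
        cstar = 0
        x = two_cluster_model.cluster_centers_[cstar]
        cfg = RecommenderConfig(smoothing_rate=1e6)
        ranking = rank_exercises(x, two_cluster_model, stats, cfg)
        brute = [exercise_score(e, cstar, stats) for e in (1, 2, 3)]
        assert ranking.top(1)[0] == int(np.argmax(brute)) + 1
        assert np.allclose(ranking.expected_utility, brute, atol=1e-9)


class TestEndToEndOracle:
    def test_toy_pipeline_matches_brute_force(self):
        """6 participants, 2 clusters, 3 exercises: the pipeline's expected
        utilities equal a from-scratch recomputation to 1e-12."""
        X = np.array([[0.0, 0.1], [0.05, 0.0], [0.1, 0.05],
                      [0.9, 1.0], [1.0, 0.95], [0.95, 0.9]])
        w = np.array([1.0, 2.0])
        model = SoftL1KMeans(n_clusters=2, feature_weights=w, n_init=10,
                             random_state=0).fit(X)
        pids = [f"P{i}" for i in range(6)]
        labels = dict(zip(pids, (int(c) for c in model.labels_)))
        ratings = [
            ("P0", 1, 4), ("P1", 1, 3), ("P3", 1, 1), ("P4", 1, 2),
            ("P0", 2, 2), ("P2", 2, 1), ("P5", 2, 4),
            ("P1", 3, 3), ("P4", 3, 3), ("P5", 3, 2),
        ]
        records = [UtilityRecord(p, e, u) for p, e, u in ratings]
        lam = 1.7
        cfg = RecommenderConfig(smoothing_rate=lam)
        rec = ExerciseRecommender(model, n_exercises=3, config=cfg).fit(records, labels)
        x = np.array([0.25, 0.4])
        ranking = rec.recommend(x)

        # brute force from the raw ratings
        d = [sum(w * np.abs(x - model.cluster_centers_[c])) for c in (0, 1)]
        omega = np.exp(-lam * np.array(d))
        util = np.zeros(3)
        for e in (1, 2, 3):
            vals = np.array([u for p, ee, u in ratings if ee == e], dtype=float)
            mu, sd = vals.mean(), vals.std()
            s = np.zeros(2)
            for c in (0, 1):
                cvals = [u for p, ee, u in ratings if ee == e and labels[p] == c]
                if cvals and sd > 0:
                    s[c] = (np.mean(cvals) - mu) / sd
            util[e - 1] = (omega * s).sum() / omega.sum()
        assert np.allclose(ranking.expected_utility, util, atol=1e-12)
        expected_order = sorted(range(1, 4), key=lambda e: (-util[e - 1], e))
        assert ranking.as_frame()["exercise_id"].tolist() == expected_order
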