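"""Cluster-weighted exercise recommendation.

An exercise's fit for a cluster is the normalized deviation of the cluster's
mean usefulness from the overall mean, S_c(e) = (u_bar_{c,e} - u_bar_e) /
sigma_e. A test participant's cluster weights come from a negative
exponential of their centroid distances, omega_c = exp(-lambda * d_c), and
the expected utility of an exercise is the omega-weighted average of its
cluster scores, renormalized by the sum of the weights. Exercises are ranked
by expected utility, ties broken by catalogue order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from phenorec.cluster import SoftL1KMeans
from phenorec.config import ConfigError, RecommenderConfig

logger = logging.getLogger(__name__)


@dataclass
class UtilityRecord:
    """One usefulness rating: participant, exercise, 0-4 score."""

    participant_id: str
    exercise_id: int
    usefulness: int

    def __post_init__(self):
        if self.usefulness not in (0, 1, 2, 3, 4):
            raise ValueError(f"usefulness {self.usefulness} outside 0..4")


@dataclass
class UtilityStats:
    """Overall and per-cluster usefulness statistics per exercise.

    ``overall_sd`` is the population SD. ``cluster_means``/``cluster_counts``
    are (k, n_exercises) arrays; exercises with no ratings at all are listed
    in ``unrated``.
    """

    n_exercises: int
    n_clusters: int
    overall_mean: np.ndarray  # (n_exercises,)
    overall_sd: np.ndarray  # (n_exercises,)
    cluster_means: np.ndarray  # (k, n_exercises)
    cluster_counts: np.ndarray  # (k, n_exercises)
    unrated: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_exercises": self.n_exercises,
            "n_clusters": self.n_clusters,
            "overall_mean": self.overall_mean.tolist(),
            "overall_sd": self.overall_sd.tolist(),
            "cluster_means": self.cluster_means.tolist(),
            "cluster_counts": self.cluster_counts.tolist(),
            "unrated": list(self.unrated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityStats":
        return cls(
            n_exercises=d["n_exercises"],
            n_clusters=d["n_clusters"],
            overall_mean=np.asarray(d["overall_mean"], dtype=float),
            overall_sd=np.asarray(d["overall_sd"], dtype=float),
            cluster_means=np.asarray(d["cluster_means"], dtype=float),
            cluster_counts=np.asarray(d["cluster_counts"], dtype=int),
            unrated=list(d["unrated"]),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "UtilityStats":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RecommendationRanking:
    """Expected utility and rank per catalogue exercise for one participant."""

    exercise_ids: list
    expected_utility: np.ndarray
    ranks: np.ndarray  # permutation of 1..n_exercises
    cluster_weights_raw: np.ndarray
    cluster_weights: np.ndarray  # normalized

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "exercise_id": self.exercise_ids,
                "expected_utility": self.expected_utility,
                "rank": self.ranks,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, n: int = 1) -> list[int]:
        return list(self.as_frame()["exercise_id"].head(n))


def fit_utility_stats(
    records: Sequence[UtilityRecord],
    labels: Mapping[str, int],
    n_exercises: int,
    n_clusters: int,
) -> UtilityStats:
    """Aggregate usefulness ratings overall and by the rater's hard cluster.

    ``labels`` maps participant id to hard cluster index (0-based). Overall
    SD is the population SD of each exercise's ratings.
    """
    for rec in records:
        if rec.participant_id not in labels:
            raise ConfigError(
                f"rating references participant {rec.participant_id!r} with no "
                "cluster assignment"
            )
        if not 1 <= rec.exercise_id <= n_exercises:
            raise ConfigError(
                f"rating references exercise {rec.exercise_id}, outside "
                f"1..{n_exercises}"
            )
    overall_mean = np.zeros(n_exercises)
    overall_sd = np.zeros(n_exercises)
    cluster_means = np.zeros((n_clusters, n_exercises))
    cluster_counts = np.zeros((n_clusters, n_exercises), dtype=int)
    by_exercise: dict[int, list] = {e: [] for e in range(1, n_exercises + 1)}
    for rec in records:
        by_exercise[rec.exercise_id].append(rec)
    unrated = []
    for e in range(1, n_exercises + 1):
        recs = by_exercise[e]
        if not recs:
            unrated.append(e)
            continue
        vals = np.array([r.usefulness for r in recs], dtype=float)
        overall_mean[e - 1] = vals.mean()
        overall_sd[e - 1] = vals.std()  # population SD
        for c in range(n_clusters):
            cvals = [r.usefulness for r in recs if labels[r.participant_id] == c]
            cluster_counts[c, e - 1] = len(cvals)
            cluster_means[c, e - 1] = float(np.mean(cvals)) if cvals else 0.0
    if unrated:
        logger.info("exercises with no ratings: %s", unrated)
    return UtilityStats(
        n_exercises=n_exercises,
        n_clusters=n_clusters,
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        cluster_means=cluster_means,
        cluster_counts=cluster_counts,
        unrated=unrated,
    )


def cluster_weights(
    x,
    model: SoftL1KMeans,
    config: Optional[RecommenderConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-exponential smoothing of centroid distances into cluster
    weights; returns (raw, normalized)."""
    config = config or RecommenderConfig()
    config.validate()
    d = model.transform(np.atleast_2d(np.asarray(x, dtype=float)))[0]
    raw = np.exp(-config.smoothing_rate * d)
    return raw, raw / raw.sum()


def exercise_score(
    exercise_id: int,
    cluster: int,
    stats: UtilityStats,
    config: Optional[RecommenderConfig] = None,
) -> float:
    """Normalized utility deviation S_c(e) = (u_bar_{c,e} - u_bar_e)/sigma_e.

    Returns 0 when the exercise is unrated overall, when its ratings have
    zero dispersion, or when the cluster contributed fewer than
    ``min_cluster_ratings`` ratings (fall back to the overall mean).
    """
    config = config or RecommenderConfig()
    config.validate()
    if not 1 <= exercise_id <= stats.n_exercises:
        raise ConfigError(
            f"exercise {exercise_id} outside catalogue 1..{stats.n_exercises}"
        )
    e = exercise_id - 1
    if exercise_id in stats.unrated:
        return 0.0
    sd = stats.overall_sd[e]
    if sd == 0.0:
        return 0.0
    if stats.cluster_counts[cluster, e] < config.min_cluster_ratings:
        return 0.0
    return float((stats.cluster_means[cluster, e] - stats.overall_mean[e]) / sd)


def rank_exercises(
    x,
    model: SoftL1KMeans,
    stats: UtilityStats,
    config: Optional[RecommenderConfig] = None,
) -> RecommendationRanking:
    """Expected utility U(e) = sum_c omega_c S_c(e) / sum_c omega_c, ranked
    descending; ties broken by ascending exercise id."""
    config = config or RecommenderConfig()
    config.validate()
    if stats.n_exercises < 1:
        raise ConfigError("empty exercise catalogue")
    raw, norm = cluster_weights(x, model, config)
    scores = np.array(
        [
            [exercise_score(e, c, stats, config) for e in range(1, stats.n_exercises + 1)]
            for c in range(stats.n_clusters)
        ]
    )  # (k, n_exercises)
    utility = norm @ scores
    order = sorted(range(stats.n_exercises), key=lambda j: (-utility[j], j))
    ranks = np.empty(stats.n_exercises, dtype=int)
    for rank, j in enumerate(order, start=1):
        ranks[j] = rank
    return RecommendationRanking(
        exercise_ids=list(range(1, stats.n_exercises + 1)),
        expected_utility=utility,
        ranks=ranks,
        cluster_weights_raw=raw,
        cluster_weights=norm,
    )


class ExerciseRecommender:
    """Estimator wrapping the full recommendation procedure.

    ``fit`` aggregates the cohort's usefulness ratings by hard cluster label;
    ``recommend``/``predict`` rank the catalogue for a test participant's
    feature vector. Follows the scikit-learn protocol.
    """

    def __init__(
        self,
        model: SoftL1KMeans,
        n_exercises: int = 17,
        config: Optional[RecommenderConfig] = None,
    ):
        self.model = model
        self.n_exercises = n_exercises
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {
            "model": self.model,
            "n_exercises": self.n_exercises,
            "config": self.config,
        }

    def set_params(self, **params) -> "ExerciseRecommender":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(
        self,
        records: Sequence[UtilityRecord],
        labels: Mapping[str, int],
    ) -> "ExerciseRecommender":
        self.stats_ = fit_utility_stats(
            records, labels, self.n_exercises, self.model.n_clusters
        )
        return self

    def recommend(self, x) -> RecommendationRanking:
        if not hasattr(self, "stats_"):
            raise RuntimeError("ExerciseRecommender is not fitted")
        return rank_exercises(x, self.model, self.stats_, self.config)

    def predict(self, X) -> np.ndarray:
        """Top-ranked exercise id for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.recommend(row).top(1)[0] for row in X])


def records_from_events(events) -> list[UtilityRecord]:
    """Extract usefulness ratings from exercise_feedback interaction events."""
    out = []
    for ev in events:
        if ev.event_kind == "exercise_feedback":
            if ev.exercise_id is None:
                raise ConfigError("exercise_feedback event without exercise_id")
            out.append(
                UtilityRecord(ev.participant_id, int(ev.exercise_id), int(ev.usefulness))
            )
    return out
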