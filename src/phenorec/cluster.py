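"""Soft distance-based clustering under a weighted Manhattan metric.

K-means in the L1 sense: Lloyd iterations with component-wise median centroid
updates (the median minimizes the within-cluster L1 objective, which mean
updates would not descend), best of several seeded restarts, silhouette-based
selection of the cluster count, inverse-distance soft memberships and
stability checks across expert weight sets.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

EPSILON = 1e-9


def weighted_manhattan(x, y, w=None) -> float:
    """Sum_j w_j * |x_j - y_j|; the participant dissimilarity metric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"weight vector shape {w.shape} does not match {x.shape}")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return float(np.sum(w * np.abs(x - y)))


def _pairwise_l1(X: np.ndarray, C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All weighted L1 distances between rows of X and rows of C."""
    return np.abs(X[:, None, :] - C[None, :, :]).dot(w)


def soft_membership(x, centroids, w=None, epsilon: float = EPSILON) -> np.ndarray:
    """Normalized inverse-distance membership probabilities.

    m_c = (1/(d_c + eps)) / sum_c' (1/(d_c' + eps)). If any distance is
    exactly zero, mass concentrates uniformly on the zero-distance clusters.
    """
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    C = np.asarray(centroids, dtype=float)
    if w is None:
        w = np.ones(C.shape[1])
    d = _pairwise_l1(x, C, np.asarray(w, dtype=float))
    m = np.empty_like(d)
    for i in range(d.shape[0]):
        zeros = d[i] == 0.0
        if zeros.any():
            m[i] = zeros / zeros.sum()
        else:
            inv = 1.0 / (d[i] + epsilon)
            m[i] = inv / inv.sum()
    return m[0] if single else m


class SoftL1KMeans(BaseEstimator):
    """K-means under the weighted Manhattan distance with soft memberships.

    Parameters
    ----------
    n_clusters : number of clusters k.
    feature_weights : expert weight per feature (non-negative); ones if None.
    n_init : seeded restarts; the fit with the lowest objective is kept.
    max_iter : Lloyd iteration cap per restart.
    centroid_update : "median" (descends the L1 objective) or "mean"
        (classical update, kept for comparison).
    random_state : seed for restarts.

    Attributes
    ----------
    cluster_centers_ : (k, p) centroids.
    labels_ : hard assignments of the training rows.
    memberships_ : (n, k) soft membership probabilities.
    inertia_ : total weighted within-cluster L1 distance.
    objective_history_ : objective after each Lloyd iteration of the best run.
    n_iter_ : iterations of the best restart.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        feature_weights: Optional[Sequence[float]] = None,
        n_init: int = 10,
        max_iter: int = 300,
        centroid_update: str = "median",
        random_state: Optional[int] = None,
        epsilon: float = EPSILON,
    ):
        self.n_clusters = n_clusters
        self.feature_weights = feature_weights
        self.n_init = n_init
        self.max_iter = max_iter
        self.centroid_update = centroid_update
        self.random_state = random_state
        self.epsilon = epsilon

    # -- fitting -----------------------------------------------------------

    def _weights(self, p: int) -> np.ndarray:
        if self.feature_weights is None:
            return np.ones(p)
        w = np.asarray(self.feature_weights, dtype=float)
        if w.shape != (p,):
            raise ValueError(f"feature_weights has shape {w.shape}, expected ({p},)")
        if (w < 0).any():
            raise ValueError("feature_weights must be non-negative")
        return w

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y=None) -> "SoftL1KMeans":
        X = self._validate_X(X)
        n, p = X.shape
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters={self.n_clusters} not in 1..{n}")
        if self.centroid_update not in ("median", "mean"):
            raise ValueError("centroid_update must be 'median' or 'mean'")
        w = self._weights(p)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            result = self._lloyd(X, w, rng)
            if best is None or result[2] < best[2]:
                best = result
        centers, labels, objective, history, iters = best
        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = objective
        self.objective_history_ = history
        self.n_iter_ = iters
        self.weights_used_ = w
        self.memberships_ = soft_membership(X, centers, w, self.epsilon)
        return self

    def _lloyd(self, X, w, rng):
        n, p = X.shape
        k = self.n_clusters
        idx = rng.choice(n, size=k, replace=False)
        centers = X[idx].copy()
        labels = None
        history = []
        for it in range(1, self.max_iter + 1):
            d = _pairwise_l1(X, centers, w)
            new_labels = d.argmin(axis=1)
            # repopulate empty clusters from the worst-fit points (distinct
            # donors, never emptying another cluster)
            taken: set = set()
            for c in range(k):
                if not (new_labels == c).any():
                    fit = d[np.arange(n), new_labels].copy()
                    for j in range(n):
                        if j in taken or (new_labels == new_labels[j]).sum() <= 1:
                            fit[j] = -np.inf
                    far = int(fit.argmax())
                    logger.info("reseeding empty cluster %d at point %d", c, far)
                    taken.add(far)
                    new_labels[far] = c
                    centers[c] = X[far]
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = X[labels == c]
                centers[c] = (
                    np.median(members, axis=0)
                    if self.centroid_update == "median"
                    else members.mean(axis=0)
                )
            history.append(float(_pairwise_l1(X, centers, w)[np.arange(n), labels].sum()))
        objective = float(_pairwise_l1(X, centers, w)[np.arange(n), labels].sum())
        return centers, labels, objective, history, it

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("SoftL1KMeans is not fitted")

    def transform(self, X) -> np.ndarray:
        """Weighted Manhattan distance of each row to each centroid."""
        self._check_fitted()
        X = self._validate_X(X)
        return _pairwise_l1(X, self.cluster_centers_, self.weights_used_)

    def predict(self, X) -> np.ndarray:
        return self.transform(X).argmin(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Soft membership probabilities (rows sum to 1)."""
        self._check_fitted()
        X = np.atleast_2d(self._validate_X(np.atleast_2d(X)))
        return soft_membership(X, self.cluster_centers_, self.weights_used_, self.epsilon)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_clusters": self.n_clusters,
            "centroids": self.cluster_centers_.tolist(),
            "feature_weights": self.weights_used_.tolist(),
            "labels": self.labels_.tolist(),
            "memberships": self.memberships_.tolist(),
            "inertia": self.inertia_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SoftL1KMeans":
        model = cls(n_clusters=d["n_clusters"], feature_weights=d["feature_weights"])
        model.cluster_centers_ = np.asarray(d["centroids"], dtype=float)
        model.weights_used_ = np.asarray(d["feature_weights"], dtype=float)
        model.labels_ = np.asarray(d["labels"], dtype=int)
        model.memberships_ = np.asarray(d["memberships"], dtype=float)
        model.inertia_ = float(d["inertia"])
        return model


# ---------------------------------------------------------------------------
# model selection and stability


def silhouette_samples_weighted(X, labels, w=None) -> np.ndarray:
    """Per-point silhouette coefficients under the weighted Manhattan metric.

    Points in singleton clusters get silhouette 0. Raises if all pairwise
    distances vanish (silhouette undefined).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    w = np.ones(X.shape[1]) if w is None else np.asarray(w, dtype=float)
    D = _pairwise_l1(X, X, w)
    if not D.any():
        raise ValueError("all points identical: silhouette undefined")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            logger.info("singleton cluster at point %d: silhouette set to 0", i)
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def select_k_silhouette(
    X,
    w=None,
    k_grid: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
    n_init: int = 10,
    seed: Optional[int] = None,
) -> tuple[int, dict[int, float]]:
    """Mean silhouette over a grid of k; returns (argmax k, full profile)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    profile: dict[int, float] = {}
    for k in k_grid:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside 2..{n - 1}")
        model = SoftL1KMeans(
            n_clusters=k, feature_weights=w, n_init=n_init, random_state=seed
        ).fit(X)
        profile[k] = float(np.mean(silhouette_samples_weighted(X, model.labels_, w)))
    best_k = max(profile, key=lambda k: (profile[k], -k))
    return best_k, profile


def cluster_stability(
    X,
    weight_sets: Sequence[Sequence[float]],
    k: int,
    seed: Optional[int] = None,
    n_init: int = 10,
) -> np.ndarray:
    """Pairwise adjusted Rand index between clusterings under different expert
    weight vectors; near-1 entries mean the partition is weight-robust."""
    if len(weight_sets) < 2:
        raise ValueError("need at least 2 weight sets")
    labelings = [
        SoftL1KMeans(
            n_clusters=k, feature_weights=ws, n_init=n_init, random_state=seed
        ).fit(X).labels_
        for ws in weight_sets
    ]
    m = len(labelings)
    ari = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ari[i, j] = ari[j, i] = adjusted_rand_score(labelings[i], labelings[j])
    return ari
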