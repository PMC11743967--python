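"""Shapley-value attributions for soft cluster membership.

The explained quantity is the soft membership probability of one cluster:
features absent from a coalition are replaced by the background column
medians of the training table, and a feature's Shapley value is its average
marginal effect on the membership probability over coalitions. One-hot
indicator blocks are grouped into a single player (their parent raw
feature), matching per-feature reporting. Exact enumeration covers up to 15
players; permutation sampling with Monte-Carlo standard errors covers the
rest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import factorial
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from phenorec.cluster import SoftL1KMeans, soft_membership
from phenorec.features import FeatureTable

logger = logging.getLogger(__name__)

EXACT_PLAYER_LIMIT = 15


@dataclass
class ShapExplanation:
    """Per-feature Shapley contributions to one participant's membership in
    one cluster. Efficiency: contributions sum to prediction - baseline."""

    participant_id: Optional[str]
    cluster: int
    feature_names: list
    contributions: np.ndarray
    baseline: float  # membership of the all-background point
    prediction: float  # membership of the participant's own point
    std_errors: Optional[np.ndarray] = None  # sampling mode only
    mode: str = "exact"

    def as_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=self.feature_names)


@dataclass
class ClusterFeatureSummary:
    """Ranked mean member contributions for one cluster, thresholded for
    display the way the study's summary table/figure is."""

    cluster: int
    features: list  # of (name, score, rank), score descending
    threshold: float
    n_members: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.features, columns=["feature", "score", "rank"]
        ).assign(cluster=self.cluster)


def _membership_batch(Z: np.ndarray, model: SoftL1KMeans, cluster: int) -> np.ndarray:
    return soft_membership(
        Z, model.cluster_centers_, model.weights_used_, model.epsilon
    )[:, cluster]


class ClusterShapExplainer:
    """Shapley attribution engine for a fitted :class:`SoftL1KMeans` model.

    Parameters
    ----------
    model : fitted soft clustering model.
    background : FeatureTable (or array) whose column medians define the
        "absent feature" reference point.
    groups : mapping raw-feature name -> column indices; every column must be
        covered exactly once. Defaults to the table's groups (or one player
        per column for a bare array).
    mode : "exact", "sampling" or "auto" (exact when players <= 15).
    n_samples : permutations in sampling mode.
    """

    def __init__(
        self,
        model: SoftL1KMeans,
        background: FeatureTable | np.ndarray,
        groups: Optional[dict] = None,
        mode: str = "auto",
        n_samples: int = 256,
        random_state: Optional[int] = None,
    ):
        self.model = model
        if isinstance(background, FeatureTable):
            self.background_values = background.values
            groups = groups if groups is not None else dict(background.groups)
            self.feature_names_all = background.column_names
        else:
            self.background_values = np.asarray(background, dtype=float)
            self.feature_names_all = [
                f"x{j}" for j in range(self.background_values.shape[1])
            ]
        p_cols = self.background_values.shape[1]
        if groups is None:
            groups = {self.feature_names_all[j]: [j] for j in range(p_cols)}
        covered = sorted(j for idx in groups.values() for j in idx)
        if covered != list(range(p_cols)):
            raise ValueError("groups must cover every column exactly once")
        self.groups = groups
        self.player_names = list(groups.keys())
        self.mode = mode
        self.n_samples = n_samples
        self.random_state = random_state
        self.background_point = np.median(self.background_values, axis=0)

    # -- core --------------------------------------------------------------

    def _resolve_mode(self) -> str:
        p = len(self.player_names)
        if self.mode == "auto":
            return "exact" if p <= EXACT_PLAYER_LIMIT else "sampling"
        if self.mode == "exact" and p > EXACT_PLAYER_LIMIT:
            raise ValueError(
                f"exact mode enumerates 2^{p} coalitions; group features or "
                f"use mode='sampling' (limit {EXACT_PLAYER_LIMIT} players)"
            )
        return self.mode

    def _coalition_points(self, x: np.ndarray, masks: np.ndarray) -> np.ndarray:
        """Rows: background point with in-coalition groups set to x."""
        Z = np.tile(self.background_point, (masks.shape[0], 1))
        for g, name in enumerate(self.player_names):
            idx = self.groups[name]
            rows = masks[:, g]
            Z[np.ix_(rows, idx)] = x[idx]
        return Z

    def explain(
        self,
        x,
        cluster: int,
        participant_id: Optional[str] = None,
        seed: Optional[int] = None,
    ) -> ShapExplanation:
        x = np.asarray(x, dtype=float).ravel()
        mode = self._resolve_mode()
        if mode == "exact":
            phi, base, pred = self._exact(x, cluster)
            se = None
        else:
            phi, base, pred, se = self._sampling(
                x, cluster, seed if seed is not None else self.random_state
            )
        return ShapExplanation(
            participant_id=participant_id,
            cluster=cluster,
            feature_names=list(self.player_names),
            contributions=phi,
            baseline=base,
            prediction=pred,
            std_errors=se,
            mode=mode,
        )

    def _exact(self, x, cluster):
        p = len(self.player_names)
        n_masks = 1 << p
        bits = ((np.arange(n_masks)[:, None] >> np.arange(p)) & 1).astype(bool)
        values = _membership_batch(self._coalition_points(x, bits), self.model, cluster)
        sizes = bits.sum(axis=1)
        # Shapley kernel weight for a coalition of size s (excluding player g)
        wgt = np.array(
            [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
        )
        phi = np.zeros(p)
        for g in range(p):
            without = ~bits[:, g]
            s_idx = np.flatnonzero(without)
            v_s = values[s_idx]
            v_sg = values[s_idx | (1 << g)]
            phi[g] = np.sum(wgt[sizes[s_idx]] * (v_sg - v_s))
        return phi, float(values[0]), float(values[-1])

    def _sampling(self, x, cluster, seed):
        p = len(self.player_names)
        rng = np.random.default_rng(seed)
        n = self.n_samples
        perms = np.array([rng.permutation(p) for _ in range(n)])
        # walk each permutation: p+1 cumulative coalitions
        masks = np.zeros((n * (p + 1), p), dtype=bool)
        for t in range(n):
            row = t * (p + 1)
            for step in range(p):
                masks[row + step + 1] = masks[row + step]
                masks[row + step + 1, perms[t, step]] = True
        values = _membership_batch(
            self._coalition_points(x, masks), self.model, cluster
        ).reshape(n, p + 1)
        marginals = np.zeros((n, p))
        deltas = np.diff(values, axis=1)  # (n, p): marginal of perms[t, step]
        for t in range(n):
            marginals[t, perms[t]] = deltas[t]
        phi = marginals.mean(axis=0)
        se = marginals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(p)
        base = float(values[0, 0])
        pred = float(values[0, -1])
        return phi, base, pred, se

    # -- cohort-level ------------------------------------------------------

    def explain_all(self, table: FeatureTable) -> list[ShapExplanation]:
        """Explain every participant's membership in their own hard cluster."""
        X = table.values
        clusters = self.model.predict(X)
        out = []
        seed_base = self.random_state if self.random_state is not None else 0
        for i, pid in enumerate(table.participant_ids):
            out.append(
                self.explain(
                    X[i],
                    int(clusters[i]),
                    participant_id=pid,
                    seed=seed_base + i,
                )
            )
        return out


def shapley_membership(
    x,
    cluster: int,
    model: SoftL1KMeans,
    background: FeatureTable | np.ndarray,
    groups: Optional[dict] = None,
    mode: str = "auto",
    n_samples: int = 256,
    seed: Optional[int] = None,
) -> ShapExplanation:
    """Functional wrapper over :class:`ClusterShapExplainer.explain`."""
    explainer = ClusterShapExplainer(
        model, background, groups=groups, mode=mode, n_samples=n_samples,
        random_state=seed,
    )
    return explainer.explain(x, cluster, seed=seed)


def summarize_cluster_contributions(
    explanations: Sequence[ShapExplanation],
    model: SoftL1KMeans,
    threshold: float = 0.04,
) -> list[ClusterFeatureSummary]:
    """Per cluster, mean signed contribution among that cluster's own members,
    ranked descending; features scoring below the display threshold are
    dropped. An empty cluster yields an empty summary with a warning."""
    summaries = []
    for c in range(model.n_clusters):
        members = [e for e in explanations if e.cluster == c]
        if not members:
            warnings.warn(f"cluster {c} has no members to summarize", stacklevel=2)
            summaries.append(ClusterFeatureSummary(c, [], threshold, 0))
            continue
        names = members[0].feature_names
        scores = np.mean([e.contributions for e in members], axis=0)
        order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
        kept = [
            (names[j], float(scores[j]), rank + 1)
            for rank, j in enumerate(order)
            if scores[j] >= threshold
        ]
        summaries.append(ClusterFeatureSummary(c, kept, threshold, len(members)))
    return summaries


def summaries_frame(summaries: Sequence[ClusterFeatureSummary]) -> pd.DataFrame:
    frames = [s.as_frame() for s in summaries if s.features]
    if not frames:
        return pd.DataFrame(columns=["feature", "score", "rank", "cluster"])
    return pd.concat(frames, ignore_index=True)[["cluster", "feature", "score", "rank"]]


def plot_cluster_contributions(
    summaries: Sequence[ClusterFeatureSummary], path: str
) -> None:
    """Stacked-bar chart of retained feature contributions per cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    all_feats = sorted({f for s in summaries for f, _, _ in s.features})
    cmap = plt.get_cmap("tab20")
    colors = {f: cmap(i % 20) for i, f in enumerate(all_feats)}
    for s in summaries:
        bottom = 0.0
        for name, score, _ in s.features:
            ax.bar(s.cluster + 1, score, bottom=bottom, color=colors[name])
            bottom += score
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[f]) for f in all_feats]
    ax.legend(handles, all_feats, fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
    ax.set_xlabel("cluster")
    ax.set_ylabel("mean Shapley contribution to membership")
    ax.set_xticks([s.cluster + 1 for s in summaries])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
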