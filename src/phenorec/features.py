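"""Mixed-type preprocessing into a weighted, [0,1]-scaled feature table.

Categoricals are one-hot encoded (exhaustive, exclusive indicators); numerics
are discretized at empirical quantiles (or fixed edges) into indicator
blocks; ordinals and event-derived aggregates stay numeric and are min-max
scaled. Indicator columns inherit the parent feature's expert weight divided
by the number of indicators, so a multi-category feature cannot dominate the
weighted Manhattan distance. Features given zero expert weight are dropped
(expert feature selection).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from phenorec.cohort import (
    BEHAVIORAL_ITEMS,
    N_SURVEY_ITEMS,
    InteractionEvent,
)
from phenorec.config import ConfigError

logger = logging.getLogger(__name__)

VALID_KINDS = ("categorical", "numeric", "ordinal", "text_derived", "interaction_aggregate")
VALID_AGGREGATIONS = ("mean", "count", "sum")

# The study's age bins: 16-19, 20-22, 23-25, 26-32, 33+ (upper bounds; last open).
AGE_BIN_UPPER = (19.0, 22.0, 25.0, 32.0)
AGE_BIN_LABELS = ("16-19", "20-22", "23-25", "26-32", "33+")


class EncodingError(ValueError):
    """A raw value cannot be encoded under the declared schema."""


@dataclass
class FeatureSpec:
    """Declaration of one raw feature and how it enters the feature table.

    ``weight`` is the expert-assigned importance used by the weighted
    Manhattan distance; zero removes the feature. For ``interaction_aggregate``
    and ``text_derived`` kinds, ``event_kind``/``event_field`` select the log
    events and field to aggregate and ``fill`` covers participants with no
    matching events.
    """

    name: str
    kind: str
    weight: float = 1.0
    categories: Optional[Sequence[str]] = None
    n_quantile_bins: int = 5
    bin_edges: Optional[Sequence[float]] = None  # fixed upper bounds, last bin open
    bin_labels: Optional[Sequence[str]] = None
    aggregation: Optional[str] = None
    event_kind: Optional[str] = None
    event_field: Optional[str] = None
    fill: float = 0.0

    def validate(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.weight < 0:
            raise ConfigError(f"feature {self.name!r} has negative weight")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 1:
                raise ConfigError(f"categorical {self.name!r} needs categories")
        if self.kind == "numeric" and self.bin_edges is None and self.n_quantile_bins < 2:
            raise ConfigError(f"numeric {self.name!r} needs n_quantile_bins >= 2")
        if self.kind == "interaction_aggregate":
            if self.aggregation not in VALID_AGGREGATIONS:
                raise ConfigError(
                    f"unknown aggregation {self.aggregation!r} for {self.name!r}"
                )
            if self.event_kind is None:
                raise ConfigError(f"aggregate {self.name!r} needs event_kind")
        if self.kind == "text_derived" and self.event_field is None:
            raise ConfigError(f"text_derived {self.name!r} needs event_field")


@dataclass
class FeatureTable:
    """Participants x features matrix in [0,1] with aligned expert weights.

    ``groups`` maps each raw feature name to its (contiguous) column indices,
    so indicator blocks can be treated as one unit downstream (e.g. as a
    single Shapley player).
    """

    data: pd.DataFrame  # index: participant ids, columns: encoded features
    weights: np.ndarray
    groups: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def column_names(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def check(self) -> None:
        vals = self.values
        if vals.size and (np.isnan(vals).any() or vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("feature table values must lie in [0,1] with no missing entries")
        if len(self.weights) != vals.shape[1]:
            raise ValueError("weights not aligned to columns")
        if (np.asarray(self.weights) < 0).any():
            raise ValueError("weights must be non-negative")

    def write(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        self.data.to_csv(csv_path, index=True, index_label="participant_id")
        sidecar = {
            "weights": {c: float(w) for c, w in zip(self.data.columns, self.weights)},
            "groups": {k: list(map(int, v)) for k, v in self.groups.items()},
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path, sidecar_path: str | Path) -> "FeatureTable":
        df = pd.read_csv(csv_path, index_col="participant_id")
        sidecar = json.loads(Path(sidecar_path).read_text())
        weights = np.array([sidecar["weights"][c] for c in df.columns], dtype=float)
        groups = {k: list(v) for k, v in sidecar["groups"].items()}
        table = cls(data=df, weights=weights, groups=groups)
        table.check()
        return table


# ---------------------------------------------------------------------------
# elementary encoders


def one_hot_encode(values: Sequence, categories: Sequence[str]) -> pd.DataFrame:
    """Exhaustive, exclusive indicator columns, one per category."""
    values = list(values)
    cat_set = set(categories)
    for v in values:
        if v not in cat_set:
            raise EncodingError(f"value {v!r} not among categories {list(categories)}")
    out = pd.DataFrame(
        {c: [1.0 if v == c else 0.0 for v in values] for c in categories}
    )
    return out


def quantile_discretize(
    values: Sequence[float],
    n_bins: int,
    edges: Optional[Sequence[float]] = None,
    labels: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bin a numeric column into indicator columns.

    Edges are inner cut points (upper bounds of all but the last bin), taken
    from the empirical quantiles unless fixed ``edges`` are given. Intervals
    are right-closed, so a value equal to a cut point falls in the lower bin.
    An all-identical column collapses to a single constant indicator with a
    warning.
    """
    col = np.asarray(values, dtype=float)
    if col.size == 0:
        raise EncodingError("cannot discretize an empty column")
    if edges is None:
        if n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        qs = np.arange(1, n_bins) / n_bins
        edges = np.unique(np.quantile(col, qs))
        if edges.size == 0 or col.min() == col.max():
            warnings.warn("constant column: single-bin discretization", stacklevel=2)
            edges = np.array([])
    else:
        edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, col, side="left")
    k = len(edges) + 1
    if labels is None:
        labels = _default_bin_labels(edges)
    out = pd.DataFrame({labels[b]: (idx == b).astype(float) for b in range(k)})
    return out, np.asarray(edges)


def _default_bin_labels(edges: np.ndarray) -> list[str]:
    if len(edges) == 0:
        return ["all"]
    labels = [f"<={edges[0]:g}"]
    labels += [f"({edges[i - 1]:g},{edges[i]:g}]" for i in range(1, len(edges))]
    labels.append(f">{edges[-1]:g}")
    return labels


def aggregate_interactions(
    events: Sequence[InteractionEvent],
    spec: FeatureSpec,
    participant_ids: Sequence[str],
) -> pd.Series:
    """Per-participant mean/count/sum of one event field; `spec.fill` where a
    participant has no matching events."""
    spec.validate()
    if spec.kind not in ("interaction_aggregate", "text_derived"):
        raise ConfigError(f"spec {spec.name!r} is not event-derived")
    aggregation = spec.aggregation or "mean"
    values: dict[str, list[float]] = {pid: [] for pid in participant_ids}
    for ev in events:
        if spec.event_kind is not None and ev.event_kind != spec.event_kind:
            continue
        v = getattr(ev, spec.event_field) if spec.event_field else 1.0
        if v is None:
            continue
        if ev.participant_id in values:
            values[ev.participant_id].append(float(v))
    out = {}
    for pid in participant_ids:
        vs = values[pid]
        if aggregation == "count":
            out[pid] = float(len(vs))
        elif not vs:
            out[pid] = float(spec.fill)
        elif aggregation == "mean":
            out[pid] = float(np.mean(vs))
        else:
            out[pid] = float(np.sum(vs))
    return pd.Series(out, name=spec.name)


def min_max_scale(values: Sequence[float]) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine map of a column onto [0,1]; a constant column maps to all zeros."""
    col = np.asarray(values, dtype=float)
    if col.size == 0:
        raise EncodingError("cannot scale an empty column")
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        return np.zeros_like(col), (lo, hi)
    return (col - lo) / (hi - lo), (lo, hi)


# ---------------------------------------------------------------------------
# default study schema


def default_feature_schema() -> list[FeatureSpec]:
    """The default encoding schema: 130 post-encoding columns.

    Five categoricals (17 indicators), age in the study's five bins, the ten
    named behavioral Likert items, baseline well-being, four interaction
    aggregates, two text-sentiment scores and 91 filler survey items.
    Expert weights concentrate on the behavioral items, occupation and age —
    the variables the domain experts consider diagnostic of a behavioral
    profile — and nearly zero-weight the filler survey items.
    """
    schema: list[FeatureSpec] = [
        FeatureSpec("gender", "categorical", weight=0.1,
                    categories=("female", "male", "no_answer")),
        FeatureSpec("country", "categorical", weight=0.1,
                    categories=("italy", "switzerland")),
        FeatureSpec("occupation", "categorical", weight=2.0,
                    categories=("student", "worker", "other")),
        FeatureSpec("education", "categorical", weight=0.1,
                    categories=("high_school", "bachelor", "master", "other")),
        FeatureSpec("ses", "categorical", weight=0.1,
                    categories=("low", "lower_middle", "middle", "moderately_good", "high")),
        FeatureSpec("age", "numeric", weight=2.0,
                    bin_edges=AGE_BIN_UPPER, bin_labels=AGE_BIN_LABELS),
    ]
    schema += [FeatureSpec(item, "ordinal", weight=1.0) for item in BEHAVIORAL_ITEMS]
    schema.append(FeatureSpec("baseline_wellbeing", "ordinal", weight=1.0))
    schema += [
        FeatureSpec("ema_mean", "interaction_aggregate", weight=0.1,
                    aggregation="mean", event_kind="ema_response",
                    event_field="ema_value", fill=5.0),
        FeatureSpec("ema_response_count", "interaction_aggregate", weight=0.1,
                    aggregation="count", event_kind="ema_response"),
        FeatureSpec("usefulness_mean", "interaction_aggregate", weight=0.1,
                    aggregation="mean", event_kind="exercise_feedback",
                    event_field="usefulness", fill=2.0),
        FeatureSpec("exercises_completed", "interaction_aggregate", weight=0.1,
                    aggregation="count", event_kind="exercise_feedback"),
        FeatureSpec("polarity_mean", "text_derived", weight=0.1,
                    aggregation="mean", event_kind="ema_response",
                    event_field="polarity", fill=0.5),
        FeatureSpec("emotion_mean", "text_derived", weight=0.1,
                    aggregation="mean", event_kind="ema_response",
                    event_field="emotion", fill=0.5),
    ]
    schema += [
        FeatureSpec(f"survey_item_{j:02d}", "ordinal", weight=0.02)
        for j in range(1, N_SURVEY_ITEMS + 1)
    ]
    for spec in schema:
        spec.validate()
    return schema


# ---------------------------------------------------------------------------
# builder


class FeatureTableBuilder:
    """Transformer from (baseline table, event log) to a :class:`FeatureTable`.

    ``fit`` learns quantile edges and min-max ranges from a training cohort;
    ``transform`` applies them, so test participants embed into the training
    feature space consistently. Follows the scikit-learn estimator protocol
    (trailing-underscore fitted attributes, fit returns self).
    """

    def __init__(self, schema: Optional[Sequence[FeatureSpec]] = None):
        self.schema = schema

    def get_params(self, deep: bool = True) -> dict:
        return {"schema": self.schema}

    def set_params(self, **params) -> "FeatureTableBuilder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _schema(self) -> list[FeatureSpec]:
        schema = list(self.schema) if self.schema is not None else default_feature_schema()
        for spec in schema:
            spec.validate()
        return [s for s in schema if s.weight > 0]

    def fit(
        self,
        baseline: pd.DataFrame,
        events: Sequence[InteractionEvent] = (),
    ) -> "FeatureTableBuilder":
        schema = self._schema()
        self._check_inputs(baseline, events, schema)
        pids = [str(p) for p in baseline["participant_id"]]
        self.edges_: dict[str, np.ndarray] = {}
        self.ranges_: dict[str, tuple[float, float]] = {}
        for spec in schema:
            raw = self._raw_column(spec, baseline, events, pids)
            if spec.kind == "numeric":
                _, edges = quantile_discretize(
                    raw, spec.n_quantile_bins, spec.bin_edges, spec.bin_labels
                )
                self.edges_[spec.name] = edges
            elif spec.kind != "categorical":
                col = np.asarray(raw, dtype=float)
                self.ranges_[spec.name] = (float(col.min()), float(col.max()))
        self.schema_ = schema
        return self

    def transform(
        self,
        baseline: pd.DataFrame,
        events: Sequence[InteractionEvent] = (),
    ) -> FeatureTable:
        if not hasattr(self, "schema_"):
            raise RuntimeError("FeatureTableBuilder is not fitted")
        schema = self.schema_
        self._check_inputs(baseline, events, schema)
        pids = [str(p) for p in baseline["participant_id"]]
        blocks: list[pd.DataFrame] = []
        weights: list[float] = []
        groups: dict[str, list[int]] = {}
        col_cursor = 0
        for spec in schema:
            raw = self._raw_column(spec, baseline, events, pids)
            if spec.kind == "categorical":
                block = one_hot_encode(raw, spec.categories)
                block.columns = [f"{spec.name}={c}" for c in spec.categories]
                w = [spec.weight / len(spec.categories)] * len(spec.categories)
            elif spec.kind == "numeric":
                edges = self.edges_[spec.name]
                labels = spec.bin_labels if spec.bin_edges is not None else None
                block, _ = quantile_discretize(raw, spec.n_quantile_bins, edges, labels)
                block.columns = [f"{spec.name}={c}" for c in block.columns]
                w = [spec.weight / block.shape[1]] * block.shape[1]
            else:
                lo, hi = self.ranges_[spec.name]
                col = np.asarray(raw, dtype=float)
                scaled = np.zeros_like(col) if hi == lo else np.clip(
                    (col - lo) / (hi - lo), 0.0, 1.0
                )
                block = pd.DataFrame({spec.name: scaled})
                w = [spec.weight]
            block.index = pids
            blocks.append(block)
            weights.extend(w)
            groups[spec.name] = list(range(col_cursor, col_cursor + block.shape[1]))
            col_cursor += block.shape[1]
        data = pd.concat(blocks, axis=1)
        data.index.name = "participant_id"
        table = FeatureTable(
            data=data, weights=np.asarray(weights, dtype=float), groups=groups
        )
        table.check()
        return table

    def fit_transform(
        self,
        baseline: pd.DataFrame,
        events: Sequence[InteractionEvent] = (),
    ) -> FeatureTable:
        return self.fit(baseline, events).transform(baseline, events)

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _check_inputs(baseline, events, schema) -> None:
        if "participant_id" not in baseline.columns:
            raise ConfigError("baseline table needs a participant_id column")
        known = {str(p) for p in baseline["participant_id"]}
        for ev in events:
            if ev.participant_id not in known:
                raise ConfigError(
                    f"event references unknown participant {ev.participant_id!r}"
                )
        needed = {
            s.name for s in schema
            if s.kind in ("categorical", "numeric", "ordinal")
        }
        missing = needed - set(baseline.columns)
        if missing:
            raise ConfigError(f"baseline table lacks columns: {sorted(missing)}")

    @staticmethod
    def _raw_column(spec, baseline, events, pids):
        if spec.kind in ("interaction_aggregate", "text_derived"):
            return aggregate_interactions(events, spec, pids).to_numpy()
        col = baseline[spec.name]
        if col.isna().any():
            # real-data mode: impute mode (categorical) / median (numeric)
            n_missing = int(col.isna().sum())
            filler = col.mode().iloc[0] if spec.kind == "categorical" else col.median()
            logger.info("imputed %d missing values in %s", n_missing, spec.name)
            col = col.fillna(filler)
        return col.to_numpy()


def build_feature_table(
    baseline: pd.DataFrame,
    events: Sequence[InteractionEvent] = (),
    schema: Optional[Sequence[FeatureSpec]] = None,
) -> FeatureTable:
    """Fit-and-transform convenience over :class:`FeatureTableBuilder`."""
    return FeatureTableBuilder(schema).fit_transform(baseline, events)
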