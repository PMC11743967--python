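"""End-to-end orchestration: generate -> preprocess -> cluster -> explain ->
recommend, with validation, a run manifest and report artifacts.

All stages share one seed from the pipeline config; outputs are plain CSV /
JSON-lines / JSON and are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from phenorec.config import PipelineConfig
from phenorec.cohort import (
    cohort_frame,
    default_decision_tree,
    generate_cohort,
    read_cohort,
    read_events,
    simulate_sessions,
    write_cohort,
)
from phenorec.cluster import SoftL1KMeans, select_k_silhouette
from phenorec.explain import (
    ClusterShapExplainer,
    plot_cluster_contributions,
    summaries_frame,
    summarize_cluster_contributions,
)
from phenorec.features import build_feature_table, default_feature_schema
from phenorec.recommend import (
    ExerciseRecommender,
    records_from_events,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _package_version() -> str:
    import phenorec

    return phenorec.__version__

# scale bounds checked by validate_inputs
_EVENT_RANGES = {
    "ema_value": (0, 10),
    "usefulness": (0, 4),
    "satisfaction": (0, 5),
    "polarity": (0, 1),
    "emotion": (0, 1),
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def run_pipeline(config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the manifest (stage outputs, chosen k, cluster sizes, seeds). Any
    stage failure raises with the stage name; files written before the
    failure are recorded in a partial manifest on disk.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _package_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {},
        "stages_completed": [],
    }

    def _fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- generate ----------------------------------------------------------
    try:
        cohort_cfg = config.cohort
        cohort_cfg.seed = config.seed
        cohort = generate_cohort(cohort_cfg)
        tree = default_decision_tree(cohort_cfg.n_exercises)
        events = simulate_sessions(cohort, tree, cohort_cfg, seed=config.seed + 1)
        write_cohort(cohort, events, out / "baseline.csv", out / "events.jsonl")
        manifest["outputs"]["baseline"] = "baseline.csv"
        manifest["outputs"]["events"] = "events.jsonl"
        manifest["stages_completed"].append("generate")
    except Exception as err:  # noqa: BLE001
        _fail("generate", err)

    # -- preprocess --------------------------------------------------------
    try:
        schema = default_feature_schema()
        table = build_feature_table(cohort_frame(cohort), events, schema)
        table.write(out / "features.csv", out / "features.json")
        manifest["outputs"]["features"] = "features.csv"
        manifest["stages_completed"].append("preprocess")
    except Exception as err:  # noqa: BLE001
        _fail("preprocess", err)

    # -- cluster -----------------------------------------------------------
    try:
        X = table.values
        if len(config.k_grid) > 1:
            k, profile = select_k_silhouette(
                X, table.weights, config.k_grid, config.n_init, config.seed
            )
        else:
            k = int(config.k_grid[0])
            profile = {}
        model = SoftL1KMeans(
            n_clusters=k,
            feature_weights=table.weights,
            n_init=config.n_init,
            random_state=config.seed,
        ).fit(X)
        (out / "model.json").write_text(
            json.dumps(model.to_dict(), indent=1, sort_keys=True)
        )
        (out / "silhouette.json").write_text(
            json.dumps(
                {"selected_k": k, "profile": {str(kk): v for kk, v in profile.items()}},
                indent=1,
                sort_keys=True,
            )
        )
        sizes = np.bincount(model.labels_, minlength=k).tolist()
        manifest["selected_k"] = k
        manifest["cluster_sizes"] = sizes
        manifest["outputs"]["model"] = "model.json"
        manifest["outputs"]["silhouette"] = "silhouette.json"
        manifest["stages_completed"].append("cluster")
    except Exception as err:  # noqa: BLE001
        _fail("cluster", err)

    # -- explain -----------------------------------------------------------
    try:
        explainer = ClusterShapExplainer(
            model,
            table,
            mode=config.explain_mode,
            n_samples=config.explain_n_samples,
            random_state=config.seed,
        )
        explanations = explainer.explain_all(table)
        summaries = summarize_cluster_contributions(
            explanations, model, config.shap_display_threshold
        )
        summaries_frame(summaries).to_csv(
            out / "cluster_summary.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest["outputs"]["cluster_summary"] = "cluster_summary.csv"
        if config.make_figure:
            plot_cluster_contributions(summaries, str(out / "cluster_contributions.png"))
            manifest["outputs"]["figure"] = "cluster_contributions.png"
        manifest["stages_completed"].append("explain")
    except Exception as err:  # noqa: BLE001
        _fail("explain", err)

    # -- recommend ---------------------------------------------------------
    try:
        records = records_from_events(events)
        labels = {
            pid: int(lab) for pid, lab in zip(table.participant_ids, model.labels_)
        }
        recommender = ExerciseRecommender(
            model, n_exercises=cohort_cfg.n_exercises, config=config.recommender
        ).fit(records, labels)
        recommender.stats_.write(out / "utility_stats.json")
        rows = []
        for i, pid in enumerate(table.participant_ids):
            ranking = recommender.recommend(X[i])
            df = ranking.as_frame()
            df.insert(0, "participant_id", pid)
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(
            out / "rankings.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest["outputs"]["utility_stats"] = "utility_stats.json"
        manifest["outputs"]["rankings"] = "rankings.csv"
        manifest["stages_completed"].append("recommend")
    except Exception as err:  # noqa: BLE001
        _fail("recommend", err)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def validate_inputs(baseline_path: str | Path, events_path: str | Path) -> list[dict]:
    """Schema/range/consistency checks on a baseline CSV and event log.

    Returns a list of violations, each with the offending row number and a
    message; empty for clean inputs.
    """
    violations: list[dict] = []
    try:
        cohort = read_cohort(baseline_path)
    except Exception as err:  # noqa: BLE001
        return [{"row": None, "source": "baseline", "message": f"unreadable: {err}"}]
    known = set()
    for i, rec in enumerate(cohort):
        row = i + 2  # 1-based, after the header
        known.add(rec.participant_id)
        if rec.latent_profile not in (1, 2, 3, 4):
            violations.append(
                {"row": row, "source": "baseline",
                 "message": f"latent_profile {rec.latent_profile} outside 1..4"}
            )
        if not 0 <= rec.baseline_wellbeing <= 5:
            violations.append(
                {"row": row, "source": "baseline",
                 "message": f"baseline_wellbeing {rec.baseline_wellbeing} outside 0..5"}
            )
        for item, v in {**rec.behavioral, **rec.survey_items}.items():
            if not 0 <= v <= 5:
                violations.append(
                    {"row": row, "source": "baseline",
                     "message": f"{item}={v} outside 0..5"}
                )
    try:
        events = read_events(events_path)
    except Exception as err:  # noqa: BLE001
        violations.append(
            {"row": None, "source": "events", "message": f"unreadable: {err}"}
        )
        return violations
    for i, ev in enumerate(events):
        row = i + 1
        if ev.participant_id not in known:
            violations.append(
                {"row": row, "source": "events",
                 "message": f"unknown participant {ev.participant_id!r}"}
            )
        for fieldname, (lo, hi) in _EVENT_RANGES.items():
            v = getattr(ev, fieldname)
            if v is not None and not lo <= v <= hi:
                violations.append(
                    {"row": row, "source": "events",
                     "message": f"{fieldname}={v} outside {lo}..{hi}"}
                )
        if ev.event_kind == "exercise_feedback" and ev.exercise_id is None:
            violations.append(
                {"row": row, "source": "events",
                 "message": "exercise_feedback without exercise_id"}
            )
    return violations
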