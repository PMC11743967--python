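"""Synthetic trial cohort: baseline table, decision-tree chatbot sessions and
exercise feedback with planted behavioral profiles.

The generator emulates a one-month chatbot EMA trial. Each participant
belongs to one of four latent behavioral profiles; the profile elevates (or
depresses) its signature Likert items by a fixed effect size. Cohort-level
summaries that a small trial pins down tightly — the gender/country split and
the baseline and end-of-program life-satisfaction means — are drawn by
largest-remainder quota from the target distribution and then permuted across
participants, so the configured means are met at any seed to within rounding
(0.5 / n). Everything else is i.i.d. given the profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from phenorec.config import CohortConfig, ConfigError

# Ordinal behavioral items (0-5 Likert) driving the planted profiles.
BEHAVIORAL_ITEMS = (
    "online_notifications",
    "texting",
    "social_media",
    "insomnia",
    "bad_mood",
    "attention_problems",
    "energetic_charge",
    "obsession",
    "pain",
    "neighborhood",
)

# Per-profile signature directions: +1 elevated, -1 depressed (by 2*noise_sd).
# Profile 3 is driven by occupation (worker) and age rather than Likert items.
PROFILE_SIGNATURES = {
    1: {"online_notifications": 1, "texting": 1, "insomnia": 1, "bad_mood": 1, "neighborhood": 1},
    2: {"online_notifications": 1, "social_media": 1, "attention_problems": 1, "energetic_charge": -1},
    3: {},
    4: {"obsession": 1, "pain": 1, "attention_problems": 1, "energetic_charge": -1},
}

# Categorical signatures of the occupation/age-driven profiles.
PROFILE_OCCUPATION_PROBS = {
    1: {"student": 0.72, "worker": 0.22, "other": 0.06},
    2: {"student": 0.72, "worker": 0.22, "other": 0.06},
    3: {"student": 0.10, "worker": 0.85, "other": 0.05},
    4: {"student": 0.90, "worker": 0.05, "other": 0.05},
}
PROFILE_AGE_MEAN = {1: 26.0, 2: 21.0, 3: 31.0, 4: 26.0}

EDUCATION_MIX = {"high_school": 0.483, "bachelor": 0.25, "master": 0.16, "other": 0.107}
SES_MIX = {
    "low": 0.08,
    "lower_middle": 0.18,
    "middle": 0.25,
    "moderately_good": 0.402,
    "high": 0.088,
}

N_SURVEY_ITEMS = 91  # profile-independent filler survey items, 0-5 Likert

_BASE_LEVEL = {item: 1.5 for item in BEHAVIORAL_ITEMS}
_BASE_LEVEL["energetic_charge"] = 3.5

# Base distribution of usefulness ratings on {0..4}; its mean is exactly 3.77.
_USEFULNESS_BASE = np.array([0.005, 0.010, 0.025, 0.130, 0.830])
_USEFULNESS_TILT = 0.4  # exponential tilt for liked/disliked exercises


@dataclass
class ParticipantRecord:
    """One row of the baseline table, plus the generator-only latent profile."""

    participant_id: str
    latent_profile: int
    gender: str
    country: str
    occupation: str
    education: str
    ses: str
    age: int
    behavioral: dict = field(default_factory=dict)  # item name -> 0-5 int
    survey_items: dict = field(default_factory=dict)  # survey_item_XX -> 0-5 int
    baseline_wellbeing: int = 3
    final_wellbeing: int = 4  # generator-only endpoint target

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "latent_profile": self.latent_profile,
            "gender": self.gender,
            "country": self.country,
            "occupation": self.occupation,
            "education": self.education,
            "ses": self.ses,
            "age": self.age,
            "baseline_wellbeing": self.baseline_wellbeing,
            "final_wellbeing": self.final_wellbeing,
        }
        row.update(self.behavioral)
        row.update(self.survey_items)
        return row

    @classmethod
    def from_row(cls, row: dict) -> "ParticipantRecord":
        behavioral = {k: int(row[k]) for k in BEHAVIORAL_ITEMS}
        survey = {
            k: int(v) for k, v in row.items() if k.startswith("survey_item_")
        }
        return cls(
            participant_id=str(row["participant_id"]),
            latent_profile=int(row["latent_profile"]),
            gender=str(row["gender"]),
            country=str(row["country"]),
            occupation=str(row["occupation"]),
            education=str(row["education"]),
            ses=str(row["ses"]),
            age=int(row["age"]),
            behavioral=behavioral,
            survey_items=survey,
            baseline_wellbeing=int(row["baseline_wellbeing"]),
            final_wellbeing=int(row["final_wellbeing"]),
        )


@dataclass
class InteractionEvent:
    """One chatbot interaction: EMA prompt/response, tree step or feedback."""

    participant_id: str
    timestamp: str  # ISO-8601
    event_kind: str  # ema_prompt | ema_response | tree_step | exercise_proposed
    #                | exercise_feedback | satisfaction_feedback
    ema_value: Optional[int] = None  # 0-10
    tree_node: Optional[str] = None
    exercise_id: Optional[int] = None  # 1..n_exercises
    usefulness: Optional[int] = None  # 0-4
    satisfaction: Optional[int] = None  # 0-5
    polarity: Optional[float] = None  # simulated NLP sentiment, [0,1]
    emotion: Optional[float] = None  # simulated NLP emotional intensity, [0,1]

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "InteractionEvent":
        return cls(**json.loads(line))


@dataclass
class DecisionTree:
    """Scripted chatbot dialogue: internal question nodes and exercise leaves.

    ``nodes`` maps a node id to ``{"question": str, "branches": {label: child}}``
    where a child is another node id or a leaf id; ``leaves`` maps leaf ids to
    exercise ids. The root's branches carry EMA bands ``"lo-hi"`` routing on
    the participant's 0-10 well-being answer.
    """

    root: str
    nodes: dict
    leaves: dict  # leaf id -> exercise id

    def validate(self, n_exercises: int) -> None:
        for leaf, ex in self.leaves.items():
            if not 1 <= ex <= n_exercises:
                raise ConfigError(
                    f"leaf {leaf!r} maps to exercise {ex}, outside 1..{n_exercises}"
                )
        seen: set = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ConfigError(f"cycle through node {node!r}")
            if node in self.leaves:
                continue
            if node not in self.nodes:
                raise ConfigError(f"dangling reference to unknown node {node!r}")
            seen.add(node)
            stack.extend(self.nodes[node]["branches"].values())
        unreachable = set(self.leaves) - self._reachable_leaves()
        if unreachable:
            raise ConfigError(f"unreachable leaves: {sorted(unreachable)}")

    def _reachable_leaves(self) -> set:
        out: set = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in self.leaves:
                out.add(node)
            else:
                stack.extend(self.nodes[node]["branches"].values())
        return out


def default_decision_tree(n_exercises: int = 17) -> DecisionTree:
    """Two-level dialogue: EMA band at the root, a follow-up question per band,
    18 leaves cycling through the exercise catalogue."""
    bands = {"0-3": "low_mood", "4-6": "mid_mood", "7-10": "high_mood"}
    questions = {
        "low_mood": "What is weighing on you most right now?",
        "mid_mood": "What would you like to work on today?",
        "high_mood": "What would help you keep this energy?",
    }
    nodes = {"root": {"question": "How are you feeling right now, from 0 to 10?",
                      "branches": dict(bands)}}
    leaves = {}
    leaf_idx = 0
    for child in bands.values():
        branches = {}
        for opt in range(6):
            leaf_id = f"leaf_{leaf_idx:02d}"
            branches[f"option_{opt}"] = leaf_id
            leaves[leaf_id] = (leaf_idx % n_exercises) + 1
            leaf_idx += 1
        nodes[child] = {"question": questions[child], "branches": branches}
    tree = DecisionTree(root="root", nodes=nodes, leaves=leaves)
    tree.validate(n_exercises)
    return tree


# ---------------------------------------------------------------------------
# quota sampling helpers


def _largest_remainder(props: Sequence[float], n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to props (largest remainder)."""
    props = np.asarray(props, dtype=float)
    quotas = props / props.sum() * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:short]] += 1
    return counts


def _quota_categories(mix: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Category labels realizing `mix` exactly (largest remainder), shuffled."""
    labels = list(mix.keys())
    counts = _largest_remainder(list(mix.values()), n)
    out = np.repeat(np.array(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def _calibrated_scores(
    mean: float, n: int, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer scores in [lo, hi] whose sample mean equals round(mean*n)/n.

    Shape is a discretized Gaussian around `mean`; unit moves between adjacent
    scores then pin the total to the target. The result is shuffled.
    """
    support = np.arange(lo, hi + 1)
    probs = np.exp(-0.5 * ((support - mean) / max(sd, 1e-9)) ** 2)
    counts = _largest_remainder(probs, n)
    target = int(round(mean * n))
    target = min(max(target, lo * n), hi * n)
    total = int(np.dot(support, counts))
    while total != target:
        if total < target:
            # move one unit of mass up: from the most populated s < hi
            movable = [i for i in range(len(support) - 1) if counts[i] > 0]
            i = max(movable, key=lambda j: counts[j])
            counts[i] -= 1
            counts[i + 1] += 1
            total += 1
        else:
            movable = [i for i in range(1, len(support)) if counts[i] > 0]
            i = max(movable, key=lambda j: counts[j])
            counts[i] -= 1
            counts[i - 1] += 1
            total -= 1
    scores = np.repeat(support, counts)
    rng.shuffle(scores)
    return scores


def _usefulness_probs(mean: float) -> np.ndarray:
    """Tilt the base usefulness distribution so its mean equals `mean`."""
    support = np.arange(5)

    def tilted(t: float) -> np.ndarray:
        p = _USEFULNESS_BASE * np.exp(t * (support - 2) / 2.0)
        return p / p.sum()

    def gap(t: float) -> float:
        return float(np.dot(support, tilted(t)) - mean)

    if abs(gap(0.0)) < 1e-12:
        return tilted(0.0)
    return tilted(brentq(gap, -20.0, 20.0, xtol=1e-12))


def _affinity(profile: int, exercise_id: int, n_exercises: int) -> float:
    """Deterministic profile-exercise usefulness tilt: each profile likes four
    consecutive catalogue exercises and dislikes four others."""
    liked = {((profile - 1) * 4 + j) % n_exercises + 1 for j in range(4)}
    disliked = {((profile - 1) * 4 + 8 + j) % n_exercises + 1 for j in range(4)}
    if exercise_id in liked:
        return _USEFULNESS_TILT
    if exercise_id in disliked:
        return -_USEFULNESS_TILT
    return 0.0


def _draw_usefulness(
    base: np.ndarray, tilt: float, rng: np.random.Generator
) -> int:
    support = np.arange(5)
    p = base * np.exp(tilt * (support - 2) / 2.0)
    p = p / p.sum()
    return int(rng.choice(5, p=p))


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate the baseline table with planted latent profiles.

    Profiles are assigned in id order (first ``profile_sizes[0]`` participants
    to profile 1 and so on); quota-calibrated attributes are shuffled across
    ids, so profile and demographics are independent except where the profile
    itself drives them (occupation, age).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    profiles = np.repeat(
        np.arange(1, len(config.profile_sizes) + 1), config.profile_sizes
    )
    genders = _quota_categories(config.gender_mix, n, rng)
    countries = _quota_categories(config.country_mix, n, rng)
    educations = _quota_categories(EDUCATION_MIX, n, rng)
    ses = _quota_categories(SES_MIX, n, rng)
    baseline = _calibrated_scores(
        config.wellbeing_baseline_mean, n, config.wellbeing_sd, 0, 5, rng
    )
    final = _calibrated_scores(
        config.wellbeing_final_mean, n, config.wellbeing_sd, 0, 5, rng
    )

    records = []
    for i in range(n):
        profile = int(profiles[i])
        occ_probs = PROFILE_OCCUPATION_PROBS[profile]
        occupation = str(rng.choice(list(occ_probs), p=list(occ_probs.values())))
        age = int(np.clip(round(rng.normal(PROFILE_AGE_MEAN[profile], 4.0)), 18, 35))

        signature = PROFILE_SIGNATURES[profile]
        behavioral = {}
        for item in BEHAVIORAL_ITEMS:
            level = _BASE_LEVEL[item] + signature.get(item, 0) * config.effect_size
            value = level + rng.normal(0.0, config.noise_sd)
            behavioral[item] = int(np.clip(round(value), 0, 5))
        survey = {
            f"survey_item_{j:02d}": int(
                np.clip(round(2.5 + rng.normal(0.0, config.noise_sd)), 0, 5)
            )
            for j in range(1, N_SURVEY_ITEMS + 1)
        }

        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:03d}",
                latent_profile=profile,
                gender=str(genders[i]),
                country=str(countries[i]),
                occupation=occupation,
                education=str(educations[i]),
                ses=str(ses[i]),
                age=age,
                behavioral=behavioral,
                survey_items=survey,
                baseline_wellbeing=int(baseline[i]),
                final_wellbeing=int(final[i]),
            )
        )
    return records


def _traverse(
    tree: DecisionTree, ema_value: int, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Walk root to leaf: the root routes on the EMA band, deeper questions are
    answered uniformly at random. Returns (node path, exercise id)."""
    path = [tree.root]
    node = tree.root
    while node not in tree.leaves:
        branches = tree.nodes[node]["branches"]
        labels = sorted(branches)
        if node == tree.root:
            chosen = labels[0]
            for label in labels:
                lo, hi = (int(p) for p in label.split("-"))
                if lo <= ema_value <= hi:
                    chosen = label
                    break
        else:
            chosen = labels[int(rng.integers(len(labels)))]
        node = branches[chosen]
        path.append(node)
    return path, tree.leaves[node]


def simulate_sessions(
    cohort: Sequence[ParticipantRecord],
    tree: DecisionTree,
    config: CohortConfig,
    seed: int,
) -> list[InteractionEvent]:
    """Simulate the chatbot interaction log for a generated cohort.

    Per participant: ``trial_days * prompts_per_day`` EMA prompts, each
    answered with probability ``response_rate``; an answered prompt walks the
    decision tree to an exercise and records a usefulness rating; weekly
    satisfaction check-ins interpolate linearly from the participant's
    baseline to their endpoint well-being (both emitted exactly at day 0 and
    the final day).
    """
    config.validate()
    if not cohort:
        raise ConfigError("cohort is empty")
    tree.validate(config.n_exercises)
    rng = np.random.default_rng(seed)
    base_probs = _usefulness_probs(config.usefulness_mean)
    t0 = datetime.fromisoformat(config.start_date)
    prompt_hours = np.linspace(9, 19, config.prompts_per_day).round().astype(int)

    events: list[InteractionEvent] = []
    for rec in cohort:
        pid = rec.participant_id
        b, f = rec.baseline_wellbeing, rec.final_wellbeing
        # latent EMA level follows the satisfaction trajectory on the 0-10 scale
        for day in range(1, config.trial_days + 1):
            frac = day / config.trial_days
            latent_sat = b + (f - b) * frac
            for p in range(config.prompts_per_day):
                ts = t0 + timedelta(days=day - 1, hours=int(prompt_hours[p]))
                events.append(InteractionEvent(pid, ts.isoformat(), "ema_prompt"))
                if rng.random() >= config.response_rate:
                    continue
                ema = int(np.clip(round(2 * latent_sat + rng.normal(0, 1.2)), 0, 10))
                ts_r = ts + timedelta(minutes=2)
                events.append(
                    InteractionEvent(
                        pid, ts_r.isoformat(), "ema_response", ema_value=ema,
                        polarity=float(round(np.clip(ema / 10 + rng.normal(0, 0.1), 0, 1), 4)),
                        emotion=float(round(np.clip(rng.beta(2, 2), 0, 1), 4)),
                    )
                )
                path, exercise = _traverse(tree, ema, rng)
                for step, node in enumerate(path):
                    events.append(
                        InteractionEvent(
                            pid,
                            (ts_r + timedelta(minutes=1 + step)).isoformat(),
                            "tree_step",
                            tree_node=node,
                        )
                    )
                ts_e = ts_r + timedelta(minutes=2 + len(path))
                events.append(
                    InteractionEvent(
                        pid, ts_e.isoformat(), "exercise_proposed", exercise_id=exercise
                    )
                )
                usefulness = _draw_usefulness(
                    base_probs,
                    _affinity(rec.latent_profile, exercise, config.n_exercises),
                    rng,
                )
                events.append(
                    InteractionEvent(
                        pid,
                        (ts_e + timedelta(minutes=10)).isoformat(),
                        "exercise_feedback",
                        exercise_id=exercise,
                        usefulness=usefulness,
                    )
                )
        # weekly satisfaction check-ins; endpoints are exact
        for day in list(range(0, config.trial_days, 7)) + [config.trial_days]:
            frac = day / config.trial_days
            if day == 0:
                sat = b
            elif day == config.trial_days:
                sat = f
            else:
                sat = int(np.clip(round(b + (f - b) * frac + rng.normal(0, 0.3)), 0, 5))
            ts = t0 + timedelta(days=day, hours=20)
            events.append(
                InteractionEvent(
                    pid, ts.isoformat(), "satisfaction_feedback", satisfaction=int(sat)
                )
            )
    return events


# ---------------------------------------------------------------------------
# I/O


def write_cohort(
    cohort: Sequence[ParticipantRecord],
    events: Sequence[InteractionEvent],
    baseline_path: str | Path,
    events_path: str | Path,
) -> None:
    """Write the baseline table as CSV and the event log as JSON-lines."""
    df = pd.DataFrame([rec.to_row() for rec in cohort])
    df.to_csv(baseline_path, index=False)
    with open(events_path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_cohort(baseline_path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(baseline_path)
    return [ParticipantRecord.from_row(row) for row in df.to_dict("records")]


def read_events(events_path: str | Path) -> list[InteractionEvent]:
    out = []
    with open(events_path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(InteractionEvent.from_json(line))
    return out


def cohort_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Baseline table as a DataFrame (one row per participant)."""
    return pd.DataFrame([rec.to_row() for rec in cohort])


def events_frame(events: Sequence[InteractionEvent]) -> pd.DataFrame:
    return pd.DataFrame([asdict(ev) for ev in events])
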