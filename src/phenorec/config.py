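"""Configuration dataclasses for the cohort generator, recommender and pipeline.

All configs are plain dataclasses with an explicit :meth:`validate` that raises
:class:`ConfigError`; YAML round-tripping lives in :mod:`phenorec.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial cohort.

    Defaults reproduce the reference study conditions: 81 young adults in
    four latent behavioral profiles of sizes 19/16/24/22, a one-month trial
    with two EMA prompts per day, a 17-exercise catalogue, life satisfaction
    on 0-5 moving from a baseline mean of 3.06 to 4.1 at the end of the
    program, and exercise-usefulness ratings on 0-4 with grand mean 3.77.

    ``noise_sd`` is the SD (in raw Likert points, 0-5 scale) of the ordinal
    behavioral items around their profile-specific level; ``effect_size`` is
    the fixed shift of a profile's signature items, independent of the noise
    so that shrinking ``noise_sd`` makes the profiles arbitrarily separable.
    """

    n_participants: int = 81
    profile_sizes: Sequence[int] = (19, 16, 24, 22)
    gender_mix: dict = field(
        default_factory=lambda: {"female": 0.621, "male": 0.356, "no_answer": 0.023}
    )
    country_mix: dict = field(
        default_factory=lambda: {"italy": 0.609, "switzerland": 0.391}
    )
    wellbeing_baseline_mean: float = 3.06
    wellbeing_final_mean: float = 4.1
    wellbeing_sd: float = 0.95
    usefulness_mean: float = 3.77
    trial_days: int = 30
    prompts_per_day: int = 2
    n_exercises: int = 17
    noise_sd: float = 0.6
    effect_size: float = 3.0  # raw Likert-point shift of signature items
    response_rate: float = 0.8
    start_date: str = "2024-01-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if sum(self.profile_sizes) != self.n_participants:
            raise ConfigError(
                f"profile_sizes {tuple(self.profile_sizes)} sum to "
                f"{sum(self.profile_sizes)}, expected n_participants="
                f"{self.n_participants}"
            )
        if any(s < 0 for s in self.profile_sizes):
            raise ConfigError("profile_sizes must be non-negative")
        for name, value, lo, hi in (
            ("wellbeing_baseline_mean", self.wellbeing_baseline_mean, 0, 5),
            ("wellbeing_final_mean", self.wellbeing_final_mean, 0, 5),
            ("usefulness_mean", self.usefulness_mean, 0, 4),
        ):
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside scale [{lo}, {hi}]")
        for name, mix in (("gender_mix", self.gender_mix), ("country_mix", self.country_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} proportions must sum to 1")
        if self.n_exercises < 1:
            raise ConfigError("n_exercises must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if not 0.0 <= self.response_rate <= 1.0:
            raise ConfigError("response_rate must lie in [0, 1]")
        if self.trial_days < 1 or self.prompts_per_day < 1:
            raise ConfigError("trial_days and prompts_per_day must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile_sizes"] = list(self.profile_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RecommenderConfig:
    """Knobs of the cluster-weighted exercise recommender.

    ``smoothing_rate`` is the rate lambda of the negative exponential map
    from centroid distance to cluster weight, omega_c = exp(-lambda * d_c).
    Clusters contributing fewer than ``min_cluster_ratings`` ratings to an
    exercise score 0 for it (fall back to the overall mean), as do exercises
    with zero usefulness dispersion.
    """

    smoothing_rate: float = 1.0
    min_cluster_ratings: int = 1
    top_n: Optional[int] = None

    def validate(self) -> None:
        if self.smoothing_rate <= 0:
            raise ConfigError("smoothing_rate must be positive")
        if self.min_cluster_ratings < 0:
            raise ConfigError("min_cluster_ratings must be non-negative")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; the seed propagates to every stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    recommender: RecommenderConfig = field(default_factory=RecommenderConfig)
    k_grid: Sequence[int] = (2, 3, 4, 5, 6, 7, 8)
    n_init: int = 10
    explain_mode: str = "sampling"
    explain_n_samples: int = 64
    shap_display_threshold: float = 0.04
    output_dir: str = "phenorec_output"
    seed: int = 0
    make_figure: bool = True

    def validate(self) -> None:
        self.cohort.validate()
        self.recommender.validate()
        if len(self.k_grid) == 0:
            raise ConfigError("k_grid must be non-empty")
        if any(k < 1 for k in self.k_grid):
            raise ConfigError("k_grid entries must be >= 1")
        if self.explain_mode not in ("exact", "sampling", "auto"):
            raise ConfigError("explain_mode must be exact, sampling or auto")
        if self.explain_n_samples < 1:
            raise ConfigError("explain_n_samples must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["k_grid"] = list(self.k_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "recommender" in d:
            d["recommender"] = RecommenderConfig(**d["recommender"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
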