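"""Study configuration: group parameters, reference MVTs, and run settings.

A :class:`StudyConfig` fully determines a simulated study together with a
master seed.  The packaged ``data/default_config.yaml`` holds the default
study conditions (two groups of 20 resistance-trained males, loads 20-80 %1RM
in 10% steps, three repetitions per load, reference minimum velocity
thresholds of 0.17/0.37/0.40 m/s for bench press / back squat /
bent-over-row, a 50% absolute-error outlier threshold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

EXERCISES = ("bench_press", "back_squat", "bent_over_row")
GROUPS = ("young", "middle_aged")

#: Reference minimum velocity thresholds (m/s): the mean concentric velocity
#: assumed at the 1RM load, one population value per exercise.
REFERENCE_MVT: dict[str, float] = {
    "bench_press": 0.17,
    "back_squat": 0.37,
    "bent_over_row": 0.40,
}

ANOVA_TRIGGERS = ("mauchly", "always", "never")
REGRESS_DIRECTIONS = ("velocity_on_load", "load_on_velocity")


@dataclass(frozen=True)
class GroupParams:
    """Distributional parameters for one group x exercise cell.

    ``v20`` is the mean concentric velocity at 20 %1RM; ``mvt_ind`` the
    athlete's individual velocity at 100 %1RM.  The implied load-velocity
    slope is ``(mvt_ind - v20) / (0.8 * true_1rm)`` (m/s per kg, negative).
    ``flatten_prob`` is the chance an athlete shows a compressed low-load
    velocity range (velocities at <=40 %1RM pulled toward the 40 %1RM value
    by ``flatten_strength``), the mechanism behind extreme low-load
    prediction errors.
    """

    group_label: str
    n_athletes: int
    true_1rm_mean: float
    true_1rm_sd: float
    v20_mean: float
    v20_sd: float
    mvt_ind_mean: float
    mvt_ind_sd: float
    rep_noise_sd: float = 0.04
    flatten_prob: float = 0.0
    flatten_strength: float = 0.8

    def __post_init__(self) -> None:
        for name in ("true_1rm_sd", "v20_sd", "mvt_ind_sd", "rep_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_athletes < 1:
            raise ConfigurationError("n_athletes must be >= 1")
        if not (self.v20_mean > self.mvt_ind_mean > 0):
            raise ConfigurationError("require v20_mean > mvt_ind_mean > 0")
        if self.true_1rm_mean <= 0:
            raise ConfigurationError("true_1rm_mean must be > 0")
        for name in ("flatten_prob", "flatten_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed (besides a seed) to simulate and analyse a study."""

    master_seed: int = 20210507
    exercises: tuple[str, ...] = EXERCISES
    groups: Mapping[str, Mapping[str, GroupParams]] = field(default_factory=dict)
    reference_mvt: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_MVT)
    )
    relative_loads: tuple[int, ...] = (20, 30, 40, 50, 60, 70, 80)
    n_reps: int = 3
    outlier_threshold_pct: float = 50.0
    anova_trigger: str = "mauchly"
    equation_name: str = "brzycki"
    regress_direction: str = "velocity_on_load"
    round_loads_to: float | None = None
    heteroscedastic_noise: bool = False
    es_denominator: str = "pooled"

    def __post_init__(self) -> None:
        if self.anova_trigger not in ANOVA_TRIGGERS:
            raise ConfigurationError(
                f"anova_trigger must be one of {ANOVA_TRIGGERS}"
            )
        if self.regress_direction not in REGRESS_DIRECTIONS:
            raise ConfigurationError(
                f"regress_direction must be one of {REGRESS_DIRECTIONS}"
            )
        if self.es_denominator not in ("pooled", "combined"):
            raise ConfigurationError("es_denominator must be pooled|combined")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if not self.relative_loads:
            raise ConfigurationError("relative_loads must be non-empty")
        if any(not (0 < l < 100) for l in self.relative_loads):
            raise ConfigurationError("relative loads must lie in (0, 100) %1RM")
        if self.outlier_threshold_pct <= 0:
            raise ConfigurationError("outlier_threshold_pct must be > 0")
        for ex in self.exercises:
            if ex not in self.reference_mvt:
                raise ConfigurationError(f"no reference MVT for exercise {ex!r}")
        for group, per_ex in self.groups.items():
            sizes = {p.n_athletes for p in per_ex.values()}
            if len(sizes) > 1:
                raise ConfigurationError(
                    f"group {group!r} has inconsistent n_athletes across exercises"
                )
            for ex in self.exercises:
                if ex not in per_ex:
                    raise ConfigurationError(
                        f"group {group!r} lacks parameters for exercise {ex!r}"
                    )

    def params(self, group: str, exercise: str) -> GroupParams:
        try:
            return self.groups[group][exercise]
        except KeyError as exc:
            raise ConfigurationError(
                f"no parameters for group {group!r}, exercise {exercise!r}"
            ) from exc

    def n_athletes(self, group: str) -> int:
        per_ex = self.groups[group]
        return next(iter(per_ex.values())).n_athletes

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exercises"] = list(self.exercises)
        d["relative_loads"] = list(self.relative_loads)
        d["reference_mvt"] = dict(self.reference_mvt)
        d["groups"] = {
            g: {ex: dataclasses.asdict(p) for ex, p in per_ex.items()}
            for g, per_ex in self.groups.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        groups: dict[str, dict[str, GroupParams]] = {}
        for g, per_ex in d.get("groups", {}).items():
            per_ex = dict(per_ex)
            # allow n_athletes at the group level in config files
            n_group = per_ex.pop("n_athletes", None)
            groups[g] = {}
            for ex, p in per_ex.items():
                p = dict(p)
                p.setdefault("group_label", g)
                if n_group is not None:
                    p.setdefault("n_athletes", n_group)
                groups[g][ex] = GroupParams(**p)
        d["groups"] = groups
        if "exercises" in d:
            d["exercises"] = tuple(d["exercises"])
        if "relative_loads" in d:
            d["relative_loads"] = tuple(int(v) for v in d["relative_loads"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def noiseless_variant(config: StudyConfig, n_per_group: int | None = None,
                      mvt_equal_reference: bool = True) -> StudyConfig:
    """A deterministic-velocity variant of ``config``.

    Zeroes repetition noise, individual-MVT spread, and flattening, so every
    athlete's load-velocity points are exactly collinear; with
    ``mvt_equal_reference`` each athlete's velocity at 1RM equals the
    exercise's reference MVT, making 1RM prediction exact.  Used for
    exact-recovery and closed-form bias checks.
    """
    groups: dict[str, dict[str, GroupParams]] = {}
    for g, per_ex in config.groups.items():
        groups[g] = {}
        for ex, p in per_ex.items():
            updates: dict = {"rep_noise_sd": 0.0, "flatten_prob": 0.0,
                             "mvt_ind_sd": 0.0}
            if n_per_group is not None:
                updates["n_athletes"] = n_per_group
            if mvt_equal_reference:
                updates["mvt_ind_mean"] = float(config.reference_mvt[ex])
            groups[g][ex] = dataclasses.replace(p, **updates)
    return dataclasses.replace(config, groups=groups)


def default_config() -> StudyConfig:
    """The packaged default study conditions."""
    with resources.files("lv1rm.data").joinpath("default_config.yaml").open() as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))
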