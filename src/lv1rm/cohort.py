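"""Synthetic cohort generator for load-velocity 1RM studies.

Each athlete x exercise cell is an :class:`AthleteTruth`: a true 1RM, a mean
concentric velocity at 20 %1RM (``v20``) and an individual minimum velocity
threshold (``mvt_ind``, the velocity at 100 %1RM).  Velocity is linear in
absolute load through the two anchor points ``(0.2 * 1RM, v20)`` and
``(1RM, mvt_ind)``.  A configurable fraction of athletes are "flattened":
their velocities at loads <= 40 %1RM are compressed toward the 40 %1RM
velocity, emulating lifters who do not reach maximal intent at light loads
and producing the extreme low-load prediction errors seen in practice.

Seeding contract: :func:`generate_cohort` derives one
``numpy.random.SeedSequence`` per (group index, athlete index, exercise
index) from the master seed, so any subset of the cohort is reproducible in
isolation.  Within a cell, the athlete's truth is drawn first and the
session noise second, from the same stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GroupParams, StudyConfig
from .errors import ConfigurationError, InputError

#: Floor applied to simulated repetition velocities (m/s).
MIN_VELOCITY = 0.01

SESSION_COLUMNS = [
    "athlete_id",
    "group",
    "exercise",
    "relative_load_pct",
    "absolute_load_kg",
    "rep",
    "mean_velocity_mps",
]

TRUTH_COLUMNS = [
    "athlete_id",
    "group",
    "exercise",
    "true_1rm_kg",
    "v20_mps",
    "mvt_ind_mps",
    "flattened",
    "flatten_strength",
]


@dataclass(frozen=True)
class AthleteTruth:
    """Ground truth for one athlete x exercise cell."""

    athlete_id: str
    group_label: str
    exercise: str
    true_1rm: float
    v20: float
    mvt_ind: float
    flattened: bool = False
    flatten_strength: float = 0.8

    def __post_init__(self) -> None:
        if self.true_1rm <= 0:
            raise InputError("true_1rm must be > 0")
        if not (self.v20 > self.mvt_ind > 0):
            raise InputError("require v20 > mvt_ind > 0")

    @property
    def slope(self) -> float:
        """Load-velocity slope in m/s per kg (always negative)."""
        return (self.mvt_ind - self.v20) / (0.8 * self.true_1rm)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lower: float) -> float:
    """One draw from Normal(mean, sd) truncated below at ``lower``."""
    if sd == 0.0:
        if mean <= lower:
            raise ConfigurationError(
                f"degenerate draw: mean {mean} at or below truncation {lower}"
            )
        return float(mean)
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def sample_athlete(params: GroupParams, exercise: str,
                   rng: np.random.Generator | int,
                   athlete_id: str = "A01") -> AthleteTruth:
    """Draw one athlete's ground truth from the group distributions.

    Draw order (part of the seeding contract): true 1RM, individual MVT,
    v20 (truncated below at the drawn MVT), then the flattening Bernoulli.
    """
    rng = np.random.default_rng(rng)
    true_1rm = _draw_truncated(rng, params.true_1rm_mean, params.true_1rm_sd, 0.0)
    mvt_ind = _draw_truncated(rng, params.mvt_ind_mean, params.mvt_ind_sd, 1e-6)
    v20 = _draw_truncated(rng, params.v20_mean, params.v20_sd, mvt_ind + 1e-6)
    flattened = bool(rng.uniform() < params.flatten_prob)
    return AthleteTruth(
        athlete_id=athlete_id,
        group_label=params.group_label,
        exercise=exercise,
        true_1rm=true_1rm,
        v20=v20,
        mvt_ind=mvt_ind,
        flattened=flattened,
        flatten_strength=params.flatten_strength,
    )


def true_velocity(truth: AthleteTruth, absolute_load):
    """Noise-free mean concentric velocity (m/s) at an absolute load (kg).

    Linear through the 20 %1RM and 100 %1RM anchors; for flattened athletes
    velocities at loads <= 40 %1RM are compressed toward the 40 %1RM
    velocity by ``flatten_strength``.
    """
    load = np.asarray(absolute_load, dtype=float)
    if np.any(load <= 0):
        raise InputError("absolute_load must be > 0")
    s = truth.slope
    v = truth.v20 + s * (load - 0.2 * truth.true_1rm)
    if truth.flattened:
        v40 = truth.v20 + s * (0.2 * truth.true_1rm)  # velocity at 40 %1RM
        low = load <= 0.4 * truth.true_1rm * (1 + 1e-12)
        v = np.where(low, v40 + (1.0 - truth.flatten_strength) * (v - v40), v)
    return float(v) if np.isscalar(absolute_load) else v


def simulate_session(truth: AthleteTruth, relative_loads, n_reps: int,
                     rng: np.random.Generator | int,
                     rep_noise_sd: float = 0.0, *,
                     round_loads_to: float | None = None,
                     heteroscedastic: bool = False) -> pd.DataFrame:
    """Simulate one testing session: ``n_reps`` repetitions per load.

    Per-repetition velocity is the truth velocity plus i.i.d. Gaussian noise
    (SD ``rep_noise_sd`` m/s, or ``rep_noise_sd * v_true`` when
    ``heteroscedastic``), floored at 0.01 m/s.
    """
    relative_loads = list(relative_loads)
    if not relative_loads:
        raise InputError("relative_loads must be non-empty")
    if any(not (0 < l < 100) for l in relative_loads):
        raise InputError("relative loads must lie in (0, 100) %1RM")
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)

    rows = []
    for rel in relative_loads:
        abs_load = rel / 100.0 * truth.true_1rm
        if round_loads_to:
            abs_load = round(abs_load / round_loads_to) * round_loads_to
        v_true = true_velocity(truth, abs_load)
        sd = rep_noise_sd * v_true if heteroscedastic else rep_noise_sd
        for rep in range(1, n_reps + 1):
            v = v_true if sd == 0 else v_true + rng.normal(0.0, sd)
            rows.append((truth.athlete_id, truth.group_label, truth.exercise,
                         rel, abs_load, rep, max(v, MIN_VELOCITY)))
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def generate_cohort(config: StudyConfig,
                    master_seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort.

    Returns ``(sessions, truth)``: the rep-level session table and the
    ground-truth table (the latter is meant for parameter-recovery checks
    and for deriving the actual-1RM table of a synthetic study).
    """
    seed = config.master_seed if master_seed is None else master_seed
    prefixes = {"young": "Y", "middle_aged": "M"}

    session_frames: list[pd.DataFrame] = []
    truth_rows: list[tuple] = []
    seen_ids: set[str] = set()
    for gi, (group, per_ex) in enumerate(config.groups.items()):
        n = config.n_athletes(group)
        prefix = prefixes.get(group, group[:1].upper())
        for ai in range(n):
            athlete_id = f"{prefix}{ai + 1:02d}"
            if athlete_id in seen_ids:
                raise ConfigurationError(
                    f"duplicate athlete id generated: {athlete_id!r}"
                )
            seen_ids.add(athlete_id)
            for xi, exercise in enumerate(config.exercises):
                params = per_ex[exercise]
                ss = np.random.SeedSequence(entropy=(seed, gi, ai, xi))
                rng = np.random.default_rng(ss)
                truth = sample_athlete(params, exercise, rng, athlete_id)
                session_frames.append(simulate_session(
                    truth, config.relative_loads, config.n_reps, rng,
                    params.rep_noise_sd,
                    round_loads_to=config.round_loads_to,
                    heteroscedastic=config.heteroscedastic_noise,
                ))
                truth_rows.append((athlete_id, group, exercise,
                                   truth.true_1rm, truth.v20, truth.mvt_ind,
                                   truth.flattened, truth.flatten_strength))

    sessions = pd.concat(session_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return sessions, truth


def truth_to_onerm(truth: pd.DataFrame) -> pd.DataFrame:
    """Actual-1RM table (athlete_id, exercise, actual_1rm_kg, source)."""
    out = truth[["athlete_id", "exercise", "true_1rm_kg"]].rename(
        columns={"true_1rm_kg": "actual_1rm_kg"}
    ).copy()
    out["source"] = "direct"
    return out


def write_session_csv(sessions: pd.DataFrame, path) -> None:
    sessions.to_csv(path, index=False)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
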