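"""Load-velocity modeling and velocity-based 1RM prediction.

The individual load-velocity relation is fitted by ordinary least squares of
mean concentric velocity on absolute load (kg), restricted to the loads of
one of four configurations:

* ``multiple_point`` — all seven loads, 20-80 %1RM;
* ``distant_two_point`` — 20 and 80 %1RM;
* ``low_load`` — 20 and 40 %1RM;
* ``high_load`` — 60 and 80 %1RM.

The 1RM is then the load at which the fitted line reaches the exercise's
reference minimum velocity threshold (MVT):
``predicted_1rm = (mvt - v0) / s`` for intercept ``v0`` and slope ``s``.
On noise-free linear data the prediction error has the closed form
``(mvt_ref - mvt_ind) / s``: misspecifying the MVT hurts more the flatter
the slope, which is why low-load configurations on flattened athletes
produce extreme errors.

Also provides a pluggable registry of repetitions-to-failure (NRM) to 1RM
conversion equations (Brzycki, Epley shipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import REFERENCE_MVT
from .errors import ConfigurationError, InputError, MethodNotApplicableError

#: Relative loads (%1RM) required by each prediction method.
METHOD_LOADS: dict[str, tuple[int, ...]] = {
    "multiple_point": (20, 30, 40, 50, 60, 70, 80),
    "distant_two_point": (20, 80),
    "low_load": (20, 40),
    "high_load": (60, 80),
}

METHODS = tuple(METHOD_LOADS)

#: Slope guard (m/s per kg): fits flatter than this are not extrapolated.
SLOPE_GUARD = -1e-6


@dataclass(frozen=True)
class LVProfile:
    """One athlete x exercise load-velocity profile after rep averaging."""

    athlete_id: str
    group_label: str
    exercise: str
    loads_pct: tuple[float, ...]
    loads_kg: tuple[float, ...]
    velocities: tuple[float, ...]
    actual_1rm: float | None = None

    def __post_init__(self) -> None:
        n = len(self.loads_pct)
        if not (n == len(self.loads_kg) == len(self.velocities)):
            raise InputError("loads_pct, loads_kg, velocities must align")
        if n < 2:
            raise InputError("a profile needs at least 2 distinct loads")
        if len(set(self.loads_pct)) != n:
            raise InputError("relative loads must be unique")
        if any(v <= 0 for v in self.velocities):
            raise InputError("velocities must be > 0")


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of velocity (m/s) on absolute load (kg)."""

    intercept: float  # v0, velocity at zero load
    slope: float      # m/s per kg
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PredictedOneRM:
    athlete_id: str
    exercise: str
    method: str
    predicted_1rm: float  # NaN when not valid
    valid: bool
    invalid_reason: str | None = None
    group_label: str | None = None


def average_repetitions(records: pd.DataFrame,
                        actual_1rm: float | None = None) -> LVProfile:
    """Collapse rep-level records for one athlete x exercise to a profile.

    Velocities are averaged arithmetically per distinct relative load and
    the loads returned sorted ascending.
    """
    if len(records) == 0:
        raise InputError("no repetition records supplied")
    for col in ("athlete_id", "exercise"):
        if records[col].nunique() != 1:
            raise InputError(f"records mix multiple values of {col}")
    grouped = (
        records.groupby("relative_load_pct", sort=True)
        .agg(absolute_load_kg=("absolute_load_kg", "mean"),
             mean_velocity_mps=("mean_velocity_mps", "mean"))
        .reset_index()
    )
    group = records["group"].iloc[0] if "group" in records else ""
    return LVProfile(
        athlete_id=str(records["athlete_id"].iloc[0]),
        group_label=str(group),
        exercise=str(records["exercise"].iloc[0]),
        loads_pct=tuple(float(v) for v in grouped["relative_load_pct"]),
        loads_kg=tuple(float(v) for v in grouped["absolute_load_kg"]),
        velocities=tuple(float(v) for v in grouped["mean_velocity_mps"]),
        actual_1rm=actual_1rm,
    )


def _method_subset(profile: LVProfile, method: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        required = METHOD_LOADS[method]
    except KeyError as exc:
        raise ConfigurationError(f"unknown prediction method {method!r}") from exc
    available = {int(round(l)): i for i, l in enumerate(profile.loads_pct)}
    missing = [l for l in required if l not in available]
    if missing:
        raise MethodNotApplicableError(method, missing)
    idx = [available[l] for l in required]
    x = np.asarray([profile.loads_kg[i] for i in idx], dtype=float)
    y = np.asarray([profile.velocities[i] for i in idx], dtype=float)
    return x, y


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b x; returns (a, b, r_squared)."""
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    # exactly-determined two-point fits are interpolating
    if len(x) == 2:
        r2 = 1.0
    return float(a), float(b), r2


def fit_linear_lv(profile: LVProfile, method: str = "multiple_point") -> LinearFit:
    """OLS of velocity on absolute load over the method's load subset.

    With exactly two points the fit passes through both exactly.  Raises
    :class:`MethodNotApplicableError` when a required load is absent.
    """
    x, y = _method_subset(profile, method)
    a, b, r2 = _ols(x, y)
    return LinearFit(intercept=a, slope=b, r_squared=r2, n_points=len(x))


def predict_1rm_at_mvt(fit: LinearFit, mvt: float, *,
                       athlete_id: str = "", exercise: str = "",
                       method: str = "", group_label: str | None = None
                       ) -> PredictedOneRM:
    """Invert the fitted line at the reference MVT.

    Invalid (with a reason, never an exception) when the slope is flat or
    positive, when the MVT is at or above the fitted zero-load velocity, or
    when the implied load is non-positive.
    """
    if mvt <= 0:
        raise InputError("mvt must be > 0")

    def invalid(reason: str) -> PredictedOneRM:
        return PredictedOneRM(athlete_id, exercise, method, float("nan"),
                              False, reason, group_label)

    if fit.slope >= SLOPE_GUARD:
        return invalid("non-negative slope")
    if mvt >= fit.intercept:
        return invalid("reference MVT at or above fitted zero-load velocity")
    load = (mvt - fit.intercept) / fit.slope
    if not math.isfinite(load) or load <= 0:
        return invalid("non-positive predicted load")
    return PredictedOneRM(athlete_id, exercise, method, float(load), True,
                          None, group_label)


def _predict_load_on_velocity(x: np.ndarray, y: np.ndarray, mvt: float, *,
                              athlete_id: str, exercise: str, method: str,
                              group_label: str | None) -> PredictedOneRM:
    # alternative regression direction: load (kg) on velocity, read at MVT
    a, b, _ = _ols(y, x)
    if b >= -1e-6:  # kg per m/s; must be steeply negative too
        return PredictedOneRM(athlete_id, exercise, method, float("nan"),
                              False, "non-negative slope", group_label)
    load = a + b * mvt
    if not math.isfinite(load) or load <= 0:
        return PredictedOneRM(athlete_id, exercise, method, float("nan"),
                              False, "non-positive predicted load", group_label)
    return PredictedOneRM(athlete_id, exercise, method, float(load), True,
                          None, group_label)


def predict_all_methods(profile: LVProfile,
                        reference_mvt: Mapping[str, float] | float | None = None,
                        *, direction: str = "velocity_on_load"
                        ) -> list[PredictedOneRM]:
    """Predict 1RM by every load configuration applicable to the profile.

    Methods whose loads are missing appear in the output as invalid
    predictions with the missing loads named, never silently dropped.
    """
    if reference_mvt is None:
        reference_mvt = REFERENCE_MVT
    mvt = (float(reference_mvt) if isinstance(reference_mvt, (int, float))
           else float(reference_mvt[profile.exercise]))
    out: list[PredictedOneRM] = []
    for method in METHODS:
        try:
            x, y = _method_subset(profile, method)
        except MethodNotApplicableError as exc:
            out.append(PredictedOneRM(
                profile.athlete_id, profile.exercise, method, float("nan"),
                False, f"missing loads {exc.missing_loads} %1RM",
                profile.group_label))
            continue
        if direction == "load_on_velocity":
            out.append(_predict_load_on_velocity(
                x, y, mvt, athlete_id=profile.athlete_id,
                exercise=profile.exercise, method=method,
                group_label=profile.group_label))
        else:
            fit = fit_linear_lv(profile, method)
            out.append(predict_1rm_at_mvt(
                fit, mvt, athlete_id=profile.athlete_id,
                exercise=profile.exercise, method=method,
                group_label=profile.group_label))
    return out


# -- NRM -> 1RM conversion equations -------------------------------------

EquationFn = Callable[[float, int], float]

_EQUATIONS: dict[str, EquationFn] = {}


def register_equation(name: str) -> Callable[[EquationFn], EquationFn]:
    """Register an NRM->1RM conversion equation under ``name``."""

    def deco(fn: EquationFn) -> EquationFn:
        _EQUATIONS[name] = fn
        return fn

    return deco


@register_equation("brzycki")
def _brzycki(load: float, reps: int) -> float:
    return load / (1.0278 - 0.0278 * reps)


@register_equation("epley")
def _epley(load: float, reps: int) -> float:
    return load * (1.0 + reps / 30.0)


def convert_nrm_to_1rm(load: float, reps: int,
                       equation_name: str = "brzycki") -> float:
    """Estimate 1RM from an N-repetition-maximum test.

    A single repetition is already a 1RM and returns the load unchanged.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    if load <= 0:
        raise InputError("load must be > 0")
    if equation_name not in _EQUATIONS:
        raise ConfigurationError(
            f"unknown NRM equation {equation_name!r}; "
            f"registered: {sorted(_EQUATIONS)}"
        )
    if reps == 1:
        return float(load)
    return float(_EQUATIONS[equation_name](load, reps))


def predictions_to_frame(predictions: list[PredictedOneRM],
                         actual_1rm: Mapping[tuple[str, str], float] | None = None
                         ) -> pd.DataFrame:
    """Tabulate predictions; optionally joins actual 1RMs keyed by
    (athlete_id, exercise)."""
    rows = []
    for p in predictions:
        actual = (actual_1rm.get((p.athlete_id, p.exercise))
                  if actual_1rm else None)
        rows.append((p.athlete_id, p.group_label, p.exercise, p.method,
                     p.predicted_1rm, actual, p.valid, p.invalid_reason))
    return pd.DataFrame(rows, columns=[
        "athlete_id", "group", "exercise", "method", "predicted_1rm_kg",
        "actual_1rm_kg", "valid", "invalid_reason"])
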