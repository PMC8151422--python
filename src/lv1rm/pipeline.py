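"""End-to-end study pipeline: simulate -> predict -> validate.

Consumes a rep-level session CSV (athlete_id, group, exercise,
relative_load_pct, absolute_load_kg, rep, mean_velocity_mps) plus an
actual-1RM CSV (athlete_id, exercise, actual_1rm_kg[, source]) and emits a
:class:`ReportBundle`: prediction, validity, ANOVA, and outlier CSVs with a
JSON run manifest.  Everything is deterministic given (dataset, config).
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (absolute_pct_error, bonferroni_pairwise,
                        exclude_outliers, mixed_anova_gg, paired_validity)
from .cohort import SESSION_COLUMNS, generate_cohort, truth_to_onerm
from .config import StudyConfig
from .errors import InputError, InsufficientDataError
from .prediction import METHODS, average_repetitions, predict_all_methods

logger = logging.getLogger(__name__)

ONERM_COLUMNS = ["athlete_id", "exercise", "actual_1rm_kg"]

VALIDITY_COLUMNS = [
    "exercise", "group", "method", "n", "raw_diff_mean_kg", "raw_diff_sd_kg",
    "p_value", "es", "es_label", "r_pearson", "r_pearson_label", "r_hetero",
    "hetero_flag", "mean_abs_pct_error", "error_label",
]


def read_session_csv(path) -> pd.DataFrame:
    """Read and validate a rep-level session CSV (UTF-8, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"session CSV missing column(s): {', '.join(missing)}")
    bad = df.index[pd.to_numeric(df["mean_velocity_mps"], errors="coerce").isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 0-base
        raise InputError(f"non-numeric mean_velocity_mps at CSV row(s) {rows}")
    key = ["athlete_id", "exercise", "relative_load_pct", "rep"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise InputError(f"duplicate (athlete, exercise, load, rep) at row(s) {rows}")
    return df[SESSION_COLUMNS].copy()


def read_onerm_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ONERM_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"actual-1RM CSV missing column(s): {', '.join(missing)}")
    if (df["actual_1rm_kg"] <= 0).any():
        raise InputError("actual_1rm_kg must be > 0")
    return df


def predict_cohort(sessions: pd.DataFrame, onerm: pd.DataFrame,
                   config: StudyConfig) -> pd.DataFrame:
    """Rep averaging, load-velocity fits, and 1RM prediction per athlete."""
    actual = {(r.athlete_id, r.exercise): float(r.actual_1rm_kg)
              for r in onerm.itertuples()}
    rows = []
    for (athlete, exercise), records in sessions.groupby(
            ["athlete_id", "exercise"], sort=True):
        profile = average_repetitions(records)
        for p in predict_all_methods(profile, config.reference_mvt,
                                     direction=config.regress_direction):
            a = actual.get((athlete, exercise))
            rows.append((p.athlete_id, p.group_label, p.exercise, p.method,
                         p.predicted_1rm, a, p.valid, p.invalid_reason))
    df = pd.DataFrame(rows, columns=[
        "athlete_id", "group", "exercise", "method", "predicted_1rm_kg",
        "actual_1rm_kg", "valid", "invalid_reason"])
    no_actual = df["actual_1rm_kg"].isna() & df["valid"]
    if no_actual.any():
        missing = sorted(df.loc[no_actual, "athlete_id"].unique())
        raise InputError(f"no actual 1RM for athlete(s): {missing}")
    ok = df["valid"]
    df["abs_pct_error"] = np.nan
    df.loc[ok, "abs_pct_error"] = absolute_pct_error(
        df.loc[ok, "predicted_1rm_kg"], df.loc[ok, "actual_1rm_kg"])
    return df


@dataclass
class StudyReport:
    """In-memory study results (frames mirror the emitted CSVs)."""

    predictions: pd.DataFrame
    validity: pd.DataFrame
    anova: pd.DataFrame
    outliers: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _validity_rows(kept: pd.DataFrame, exercise: str,
                   config: StudyConfig) -> list[list]:
    rows = []
    group_sets = [(g, kept[kept["group"] == g])
                  for g in sorted(kept["group"].unique())]
    group_sets.append(("whole", kept))
    for group_label, sub in group_sets:
        for method in METHODS:
            cell = sub[sub["method"] == method]
            if len(cell) < 2:
                logger.warning("validity cell %s/%s/%s skipped (n=%d < 2)",
                               exercise, group_label, method, len(cell))
                rows.append([exercise, group_label, method, len(cell),
                             np.nan, np.nan, np.nan, np.nan, "", np.nan,
                             "", np.nan, False, np.nan, ""])
                continue
            v = paired_validity(cell["actual_1rm_kg"], cell["predicted_1rm_kg"],
                                es_denominator=config.es_denominator)
            rows.append([exercise, group_label, method, v.n,
                         v.raw_diff_mean, v.raw_diff_sd, v.t_p_value,
                         v.es, v.es_label, v.r_pearson, v.r_pearson_label,
                         v.r_hetero, v.heteroscedastic,
                         v.mean_abs_pct_error, v.error_label])
    return rows


def run_study(sessions: pd.DataFrame, onerm: pd.DataFrame,
              config: StudyConfig) -> StudyReport:
    """Full analysis chain on a rep-level dataset.

    Per exercise: rep averaging -> four-method prediction -> two-stage
    outlier exclusion -> validity suite per group and pooled ("whole") ->
    mixed ANOVA with Greenhouse-Geisser handling plus Bonferroni pairwise
    comparisons on complete cases.
    """
    predictions = predict_cohort(sessions, onerm, config)
    logger.info("predictions: %d (%d valid)", len(predictions),
                int(predictions["valid"].sum()))

    validity_rows: list[list] = []
    anova_rows: list[list] = []
    outlier_frames: list[pd.DataFrame] = []
    counts: dict = {"predictions": len(predictions),
                    "valid_predictions": int(predictions["valid"].sum()),
                    "outliers_excluded": 0, "excluded_subjects": 0}

    for exercise in config.exercises:
        ex_pred = predictions[(predictions["exercise"] == exercise)
                              & predictions["valid"]]
        if len(ex_pred) == 0:
            logger.warning("no valid predictions for %s", exercise)
            continue
        kept, report = exclude_outliers(ex_pred,
                                        config.outlier_threshold_pct)
        counts["outliers_excluded"] += report.n_excluded
        counts["excluded_subjects"] += len(report.excluded_subjects)
        if report.n_excluded:
            frame = report.excluded_predictions[
                ["athlete_id", "group", "method", "abs_pct_error", "stage"]
            ].copy()
            frame.insert(0, "exercise", exercise)
            frame["threshold_pct"] = report.threshold
            outlier_frames.append(frame)
        logger.info("%s: %d predictions kept, %d excluded (%d subjects)",
                    exercise, len(kept), report.n_excluded,
                    len(report.excluded_subjects))

        validity_rows.extend(_validity_rows(kept, exercise, config))

        complete = kept.groupby("athlete_id")["method"].nunique()
        complete_ids = complete.index[complete == len(METHODS)]
        cc = kept[kept["athlete_id"].isin(complete_ids)]
        try:
            results = mixed_anova_gg(cc, trigger=config.anova_trigger)
        except InsufficientDataError as exc:
            logger.warning("ANOVA skipped for %s: %s", exercise, exc)
        else:
            for r in results:
                anova_rows.append([exercise, r.effect, "", r.F, r.df_num,
                                   r.df_den, r.epsilon_gg, r.mauchly_w,
                                   r.mauchly_p, r.gg_applied, r.p, np.nan])
            posthoc = bonferroni_pairwise(cc)
            for r in posthoc.itertuples():
                anova_rows.append([exercise, "method_pairwise",
                                   f"{r.level_a}|{r.level_b}", r.t, np.nan,
                                   np.nan, np.nan, np.nan, np.nan, False,
                                   r.p_raw, r.p_bonferroni])

    validity = pd.DataFrame(validity_rows, columns=VALIDITY_COLUMNS)
    anova = pd.DataFrame(anova_rows, columns=[
        "exercise", "effect", "pair", "statistic", "df_num", "df_den",
        "epsilon_gg", "mauchly_w", "mauchly_p", "gg_applied", "p",
        "p_bonferroni"])
    outliers = (pd.concat(outlier_frames, ignore_index=True)
                if outlier_frames else pd.DataFrame(columns=[
                    "exercise", "athlete_id", "group", "method",
                    "abs_pct_error", "stage", "threshold_pct"]))
    counts["validity_cells_group"] = int(
        (validity["group"] != "whole").sum())
    counts["validity_cells_whole"] = int((validity["group"] == "whole").sum())
    return StudyReport(predictions=predictions, validity=validity,
                       anova=anova, outliers=outliers, counts=counts)


@dataclass(frozen=True)
class ReportBundle:
    predictions_csv: Path
    validity_csv: Path
    anova_csv: Path
    outliers_csv: Path
    manifest_json: Path


def write_report(report: StudyReport, out_dir, config: StudyConfig,
                 seed: int | None = None) -> ReportBundle:
    """Write the four CSVs and a manifest sufficient to reproduce them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "predictions": out / "predictions.csv",
        "validity": out / "validity.csv",
        "anova": out / "anova.csv",
        "outliers": out / "outliers.csv",
    }
    report.predictions.to_csv(paths["predictions"], index=False)
    report.validity.to_csv(paths["validity"], index=False)
    report.anova.to_csv(paths["anova"], index=False)
    report.outliers.to_csv(paths["outliers"], index=False)

    checksums = {name: hashlib.sha256(p.read_bytes()).hexdigest()
                 for name, p in paths.items()}
    manifest = {
        "package": "lv1rm",
        "version": __version__,
        "seed": config.master_seed if seed is None else seed,
        "config_sha256": config.sha256(),
        "config": config.to_dict(),
        "counts": report.counts,
        "output_sha256": checksums,
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True),
                             encoding="utf-8")
    return ReportBundle(paths["predictions"], paths["validity"],
                        paths["anova"], paths["outliers"], manifest_path)


def replicate(config: StudyConfig, out_dir, seed: int | None = None
              ) -> tuple[StudyReport, ReportBundle]:
    """Simulate a cohort under ``config`` and run the full analysis."""
    sessions, truth = generate_cohort(config, master_seed=seed)
    onerm = truth_to_onerm(truth)
    report = run_study(sessions, onerm, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions.to_csv(out / "sessions.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    onerm.to_csv(out / "actual_1rm.csv", index=False)
    bundle = write_report(report, out, config, seed=seed)
    return report, bundle
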