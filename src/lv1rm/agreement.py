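"""Method-agreement statistics for actual vs. predicted 1RM.

Implements the validity-analysis suite used in velocity-based 1RM studies:

* absolute percentage errors with the low/moderate/high magnitude scale;
* two-stage >50%-error outlier exclusion (subject-level, then per
  prediction);
* paired agreement statistics: raw differences, paired t, Cohen's d with
  the paired "SD both" denominator sqrt((sd_a^2 + sd_p^2)/2), Pearson r,
  and heteroscedasticity of error (r between differences and pairwise
  means, flagged when r > 0.32);
* a two-way mixed (split-plot) ANOVA — group between, prediction method
  within — with Mauchly's sphericity test and the Greenhouse-Geisser
  epsilon applied to within-effect degrees of freedom;
* Bonferroni-adjusted pairwise paired t-tests;
* exact noncentral-t power analysis for a two-sample t-test.

Scale boundary conventions: the absolute-error bins are low [0, 5.0),
moderate [5.0, 10.0], high (10.0, inf); correlation and effect-size bins
are closed on their printed lower bound and classify by absolute value.
Zero-variance degenerate cases return correlations of 0 (never NaN) and a
paired-t p of 1 when all differences are zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigurationError, InputError, InsufficientDataError

logger = logging.getLogger(__name__)

HETEROSCEDASTICITY_THRESHOLD = 0.32


# -- elementary scales ----------------------------------------------------

def absolute_pct_error(predicted, actual):
    """100 * |predicted - actual| / actual (symmetric in sign of the error)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if np.any(actual <= 0):
        raise InputError("actual 1RM must be > 0")
    out = 100.0 * np.abs(predicted - actual) / actual
    return float(out) if out.ndim == 0 else out


def classify_magnitude(value: float, scale: str) -> str:
    """Qualitative label for an absolute error (%), correlation, or ES."""
    if not np.isfinite(value):
        raise InputError("value must be finite")
    if scale == "abs_error":
        if value < 0:
            raise InputError("absolute errors are non-negative")
        if value < 5.0:
            return "low"
        if value <= 10.0:
            return "moderate"
        return "high"
    if scale == "correlation":
        v = abs(value)
        if v > 1.0 + 1e-9:
            raise InputError("|r| cannot exceed 1")
        if v >= 1.0 - 1e-12:
            return "perfect"
        for lower, label in ((0.90, "nearly perfect"), (0.70, "very large"),
                             (0.50, "large"), (0.30, "moderate"),
                             (0.10, "small")):
            if v >= lower:
                return label
        return "trivial"
    if scale == "effect_size":
        v = abs(value)
        if v < 0.20:
            return "trivial"
        if v < 0.60:
            return "small"
        if v < 1.20:
            return "moderate"
        if v <= 2.00:
            return "large"
        return "very large"
    raise ConfigurationError(f"unknown magnitude scale {scale!r}")


# -- outlier exclusion ----------------------------------------------------

@dataclass
class OutlierReport:
    """Accounting of the two-stage >threshold%-error exclusion."""

    threshold: float
    excluded_predictions: pd.DataFrame  # athlete_id, method, abs_pct_error, stage
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_predictions)


def exclude_outliers(predictions: pd.DataFrame,
                     threshold: float = 50.0
                     ) -> tuple[pd.DataFrame, OutlierReport]:
    """Apply the two-stage outlier rule to one exercise's predictions.

    ``predictions`` needs columns athlete_id, method, abs_pct_error (and is
    assumed already restricted to valid predictions of a single exercise).
    Stage 1 removes athletes whose errors exceed the threshold for every
    method they have (systematic failure); stage 2 removes remaining
    individual predictions above the threshold.
    """
    df = predictions.copy()
    if len(df) == 0:
        return df, OutlierReport(threshold, df.assign(stage=[]))

    min_err = df.groupby("athlete_id")["abs_pct_error"].min()
    systematic = sorted(min_err.index[min_err > threshold])
    stage1 = df[df["athlete_id"].isin(systematic)].assign(stage="subject")
    remaining = df[~df["athlete_id"].isin(systematic)]

    mask = remaining["abs_pct_error"] > threshold
    stage2 = remaining[mask].assign(stage="prediction")
    kept = remaining[~mask]

    excluded = pd.concat([stage1, stage2], ignore_index=True)
    report = OutlierReport(threshold, excluded, excluded_subjects=systematic)
    return kept.reset_index(drop=True), report


# -- paired validity ------------------------------------------------------

@dataclass(frozen=True)
class ValidityResult:
    """Agreement statistics for one group x method x exercise cell."""

    n: int
    raw_diff_mean: float
    raw_diff_sd: float
    t_p_value: float
    es: float
    es_label: str
    r_pearson: float
    r_pearson_label: str
    r_hetero: float
    heteroscedastic: bool
    mean_abs_pct_error: float
    error_label: str
    degenerate: bool = False


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r, returning (0, degenerate=True) on zero variance."""
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0, True
    r = float(stats.pearsonr(x, y).statistic)
    return r, False


def paired_validity(actual, predicted, *,
                    es_denominator: str = "pooled",
                    hetero_threshold: float = HETEROSCEDASTICITY_THRESHOLD
                    ) -> ValidityResult:
    """Full paired-agreement panel for aligned actual/predicted 1RMs (kg)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise InputError("actual and predicted must be aligned 1-d arrays")
    n = len(actual)
    if n < 2:
        raise InsufficientDataError("paired validity needs n >= 2")
    if np.any(actual <= 0) or np.any(predicted <= 0):
        raise InputError("1RM values must be > 0")

    diff = predicted - actual
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))

    if np.allclose(diff, 0.0):
        p_value = 1.0
    elif sd_diff == 0.0:
        p_value = 0.0  # constant non-zero difference: infinite t
    else:
        p_value = float(stats.ttest_rel(predicted, actual).pvalue)

    if es_denominator == "pooled":
        sd_both = float(np.sqrt((actual.var(ddof=1) + predicted.var(ddof=1)) / 2))
    elif es_denominator == "combined":
        sd_both = float(np.concatenate([actual, predicted]).std(ddof=1))
    else:
        raise ConfigurationError("es_denominator must be pooled|combined")
    degenerate = False
    if sd_both == 0.0:
        es = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff) * np.inf)
        degenerate = True
    else:
        es = mean_diff / sd_both

    r_pearson, deg_r = _safe_pearson(actual, predicted)
    r_hetero, deg_h = _safe_pearson(diff, (actual + predicted) / 2.0)
    degenerate = degenerate or deg_r or deg_h

    mape = float(np.mean(absolute_pct_error(predicted, actual)))
    return ValidityResult(
        n=n,
        raw_diff_mean=mean_diff,
        raw_diff_sd=sd_diff,
        t_p_value=p_value,
        es=float(es),
        es_label=(classify_magnitude(es, "effect_size")
                  if np.isfinite(es) else "very large"),
        r_pearson=r_pearson,
        r_pearson_label=classify_magnitude(r_pearson, "correlation"),
        r_hetero=r_hetero,
        heteroscedastic=bool(r_hetero > hetero_threshold),
        mean_abs_pct_error=mape,
        error_label=classify_magnitude(mape, "abs_error"),
        degenerate=degenerate,
    )


# -- mixed ANOVA with Greenhouse-Geisser ----------------------------------

@dataclass(frozen=True)
class AnovaResult:
    effect: str  # method | group | method_x_group
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon_gg: float | None = None  # within effects only
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_applied: bool = False


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-level covariance."""
    k = cov.shape[0]
    c = linalg.helmert(k, full=False)  # orthonormal (k-1) x k contrasts
    t = c @ cov @ c.T
    return float(np.trace(t) ** 2 / ((k - 1) * np.trace(t @ t)))


def _mauchly(cov: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test; returns (W, p).

    ``n_error`` is the error df the covariance was pooled over (N - g).
    Returns (1, 1) when the test is undefined (k = 2 or too few subjects).
    """
    k = cov.shape[0]
    if k <= 2 or n_error < k:
        return 1.0, 1.0
    c = linalg.helmert(k, full=False)
    t = c @ cov @ c.T
    det = linalg.det(t)
    if det <= 0:
        return 0.0, 0.0
    w = det / (np.trace(t) / (k - 1)) ** (k - 1)
    d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * n_error)
    chi2 = -n_error * d * np.log(w)
    dof = k * (k - 1) / 2 - 1
    return float(w), float(stats.chi2.sf(chi2, dof))


def mixed_anova_gg(data: pd.DataFrame, *, dv: str = "abs_pct_error",
                   subject: str = "athlete_id", within: str = "method",
                   between: str = "group", trigger: str = "mauchly"
                   ) -> list[AnovaResult]:
    """Two-way mixed ANOVA (between x within) on a long-format table.

    Incomplete subjects (missing any within level) are dropped listwise
    with a logged count.  The within-subject error covariance is pooled
    across groups; epsilon is always reported, and within-effect dfs are
    multiplied by epsilon when ``trigger`` fires ("mauchly": Mauchly's test
    rejects at p < 0.05; "always"; "never").
    """
    if trigger not in ("mauchly", "always", "never"):
        raise ConfigurationError("trigger must be mauchly|always|never")

    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, aggfunc="mean")
    n_before = wide.shape[0]
    wide = wide.dropna()
    n_dropped = n_before - wide.shape[0]
    if n_dropped:
        logger.info("mixed ANOVA: dropped %d incomplete subject(s) listwise",
                    n_dropped)

    levels = list(wide.columns)
    k = len(levels)
    groups = wide.index.get_level_values(between)
    group_names = sorted(set(groups))
    g = len(group_names)
    n_total = wide.shape[0]
    if k < 2 or g < 2:
        raise InsufficientDataError("need >=2 within levels and >=2 groups")
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise InsufficientDataError("need >=2 complete subjects per group")

    values = wide.to_numpy()

    # Between part: one-way ANOVA on subject means, scaled by k.
    subj_means = values.mean(axis=1)
    grand = float(subj_means.mean())
    ss_group = 0.0
    ss_subj = 0.0
    for name in group_names:
        m = subj_means[groups == name]
        ss_group += k * len(m) * (m.mean() - grand) ** 2
        ss_subj += k * float(np.sum((m - m.mean()) ** 2))
    df_group, df_subj = g - 1, n_total - g
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    p_group = float(stats.f.sf(f_group, df_group, df_subj))

    # Within part: Type III on subject-centered data.
    centered = values - subj_means[:, None]
    long = pd.DataFrame({
        "y": centered.ravel(),
        "g": np.repeat(np.asarray(groups, dtype=object), k),
        "w": np.tile(np.asarray(levels, dtype=object), n_total),
    })
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("y ~ C(g, Sum) * C(w, Sum)", data=long).fit()
    table = anova_lm(model, typ=3)
    ss_within = float(table.loc["C(w, Sum)", "sum_sq"])
    ss_inter = float(table.loc["C(g, Sum):C(w, Sum)", "sum_sq"])
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_w, df_i = k - 1, (g - 1) * (k - 1)
    df_err = (n_total - g) * (k - 1)
    ms_err = ss_err / df_err
    f_within = (ss_within / df_w) / ms_err
    f_inter = (ss_inter / df_i) / ms_err

    # Pooled within-group covariance of the within levels.
    pooled = np.zeros((k, k))
    for name in group_names:
        block = values[groups == name]
        pooled += (len(block) - 1) * np.cov(block, rowvar=False, ddof=1)
    pooled /= (n_total - g)
    eps = 1.0 if k == 2 else _gg_epsilon(pooled)
    w_stat, p_mauchly = _mauchly(pooled, n_total - g)

    apply_gg = {"always": True, "never": False,
                "mauchly": p_mauchly < 0.05}[trigger]
    scale = eps if apply_gg else 1.0

    def within_result(effect: str, f: float, dfn: int) -> AnovaResult:
        dfn_c, dfd_c = dfn * scale, df_err * scale
        return AnovaResult(effect=effect, F=float(f), df_num=dfn_c,
                           df_den=dfd_c, p=float(stats.f.sf(f, dfn_c, dfd_c)),
                           epsilon_gg=eps, mauchly_w=w_stat,
                           mauchly_p=p_mauchly, gg_applied=apply_gg)

    return [
        within_result("method", f_within, df_w),
        AnovaResult(effect="group", F=float(f_group), df_num=float(df_group),
                    df_den=float(df_subj), p=p_group),
        within_result("method_x_group", f_inter, df_i),
    ]


def bonferroni_pairwise(data: pd.DataFrame, *, dv: str = "abs_pct_error",
                        subject: str = "athlete_id", within: str = "method",
                        m: int | None = None) -> pd.DataFrame:
    """Paired t-tests for every within-level pair, Bonferroni adjusted.

    Adjusted p = min(1, m * p_raw) with m defaulting to the number of
    pairs (6 for four methods).
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean")
    levels = sorted(wide.columns)
    if len(levels) < 2:
        raise InsufficientDataError("need >= 2 within levels")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs) if m is None else m
    rows = []
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        if len(sub) < 2:
            rows.append((a, b, len(sub), np.nan, np.nan, np.nan))
            continue
        diffs = sub[a] - sub[b]
        if np.allclose(diffs, 0.0):
            t_stat, p_raw = 0.0, 1.0
        else:
            res = stats.ttest_rel(sub[a], sub[b])
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
        rows.append((a, b, len(sub), t_stat, p_raw, min(1.0, m * p_raw)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "n", "t",
                                       "p_raw", "p_bonferroni"])


# -- power analysis -------------------------------------------------------

def _two_sample_power(d: float, n: int, alpha: float, tails: int) -> float:
    """Exact noncentral-t power of a two-sample t-test with n per group."""
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    alpha_eff = alpha / tails
    crit = stats.t.ppf(1 - alpha_eff, df)
    power = float(stats.nct.sf(crit, df, nc))
    if tails == 2:
        power += float(stats.nct.cdf(-crit, df, nc))
    return power


def power_sample_size(d: float, alpha: float = 0.05, power: float = 0.95,
                      tails: int = 1, max_n: int = 10 ** 6) -> int:
    """Smallest per-group n reaching the target power for effect size d.

    Uses the exact noncentral-t distribution (noncentrality d*sqrt(n/2),
    df 2n-2); one-tailed by default.
    """
    if d <= 0:
        raise InputError("d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InputError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise InputError("tails must be 1 or 2")

    lo, hi = 2, 2
    while _two_sample_power(d, hi, alpha, tails) < power:
        lo = hi
        hi *= 2
        if hi > max_n:
            raise InputError(f"power {power} unreachable within n <= {max_n}")
    while lo < hi:  # power is monotone increasing in n
        mid = (lo + hi) // 2
        if _two_sample_power(d, mid, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
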