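# Methods

## The procedure being modeled

A velocity-based 1RM study proceeds in two sessions: actual maximal
strength is measured first (directly, or via an N-repetition-maximum test
converted to 1RM), then athletes lift submaximal loads (20–80 %1RM in 10%
steps, three repetitions per load) while mean concentric velocity is
recorded. The average of the three repetitions per load defines the
individual load-velocity profile; a straight line fitted to a chosen load
subset is extrapolated to a reference minimum velocity threshold (MVT) to
predict the 1RM. `lv1rm` implements that prediction chain and the
agreement statistics used to judge it, plus a synthetic cohort generator so
the chain can be exercised and tested without access to lab data.

## Load-velocity model and prediction

Velocity is regressed on absolute load in kg (OLS), and the fitted line is
inverted at the MVT: `1RM_pred = (MVT − v0)/s`. Regressing in this
direction keeps raw prediction errors in kg and matches the reading "the
load associated with a velocity"; the alternative direction (load on
velocity, read off at the MVT) is available via
`regress_direction: load_on_velocity` and differs only under noise.
Two-point configurations go through the same OLS routine — with two points
the least-squares line is the interpolating line, so this is exact and
keeps a single code path.

A fit is refused extrapolation (prediction marked invalid, with a reason,
rather than raising) when the slope exceeds −1e-6 m·s⁻¹·kg⁻¹, when the MVT
is at or above the fitted zero-load velocity, or when the implied load is
non-positive. The 1e-6 guard blocks near-infinite extrapolations while
leaving genuinely extreme-but-finite predictions in the data, where the
>50%-error exclusion rule (below) handles them — that rule, not the guard,
is the scientific filter.

NRM→1RM conversion uses a pluggable equation registry (`brzycki` default:
`load/(1.0278 − 0.0278·reps)`; `epley`: `load·(1 + reps/30)`); one
repetition returns the load unchanged. The study configuration records
which equation was used.

## Synthetic cohort generator

Each athlete × exercise cell draws, from truncated normal distributions: a
true 1RM, an individual MVT (velocity at 100 %1RM), and a velocity at
20 %1RM (`v20`, truncated below at the drawn MVT so the profile always
slopes downward). True velocity is linear through the `(0.2·1RM, v20)` and
`(1RM, MVT_ind)` anchors. Repetition velocities add i.i.d. Gaussian noise
(SD 0.04 m/s by default, roughly the disagreement reported between
commercial linear position transducers), floored at 0.01 m/s; an optional
heteroscedastic mode scales the SD with the true velocity. Loads are exact
fractions of true 1RM by default, with optional rounding (e.g. 0.5 kg
plates) behind `round_loads_to`.

With probability `flatten_prob` an athlete is "flattened": velocities at
loads ≤40 %1RM are compressed toward the 40 %1RM velocity by
`flatten_strength` (0.8 default), emulating lifters who do not reach
maximal intent at light loads. This is what produces >50%-error outliers,
almost exclusively through the low-load {20,40} configuration, whose fitted
slope collapses.

Default group parameters (packaged in `data/default_config.yaml`): 20
athletes per group; young/middle-aged true-1RM means 100/95 kg (bench),
130/120 kg (squat), 92/88 kg (row); `v20` means 1.50/1.30, 1.60/1.40,
1.40/1.30 m/s respectively, so middle-aged profiles are flatter (smaller
`v20 − MVT_ind` span) as observed in that population; individual-MVT means
equal the reference MVTs with SD 0.04–0.05 m/s (individual deviation from
the reference is the main bias source); `flatten_prob` 0.05 young vs. 0.30
middle-aged, consistent with roughly one young and six middle-aged low-load
outliers per exercise in a 20+20 cohort. The bent-over-row parameters were
chosen so the cohort's mean velocity at 80 %1RM is ≈0.64 m/s and its mean
row 1RM ≈90 kg, matching published anchors for this exercise. Athletes'
1RMs are drawn independently across exercises (no within-athlete strength
correlation), and day-to-day 1RM variability, fatigue across sets, and bar
path are not modeled — so passing tests demonstrate the statistical
machinery and the MVT-misspecification/flat-slope mechanisms, not the full
error budget of real testing.

Seeding: one `numpy.random.SeedSequence(entropy=(master_seed, group_index,
athlete_index, exercise_index))` per cell; truth is drawn before session
noise from the same stream. Any subset of the cohort is therefore
reproducible in isolation, and identical seeds give byte-identical CSVs.

## Agreement statistics

* **Absolute percentage error** `100·|pred − actual|/actual`, labeled low
  [0, 5.0), moderate [5.0, 10.0], high (10.0, ∞). Correlation and
  effect-size scales are closed on their printed lower bounds (e.g. small
  r = [0.10, 0.30)); correlations classify by absolute value.
* **Outlier exclusion** is two-stage: athletes whose errors exceed the
  threshold (50% default) for *every* method are removed entirely; then
  remaining individual predictions above the threshold are removed. Both
  stages are recorded in the outlier report so every valid prediction is
  accounted analyzed-or-excluded.
* **Cohen's d** uses the paired-design denominator
  `sqrt((SD_actual² + SD_pred²)/2)` ("SD both"); the combined-sample SD is
  available via `es_denominator: combined`.
* **Heteroscedasticity** is the signed Pearson r between differences and
  pairwise means, flagged only when r > +0.32 (one-sided by definition).
* **Degenerate inputs**: any correlation with a zero-variance argument
  returns 0 with a degenerate flag (never NaN); a paired t on all-zero
  differences returns p = 1, and on constant non-zero differences p = 0.
* **Power analysis** uses the exact noncentral-t distribution
  (df = 2n − 2, noncentrality d·√(n/2)) with doubling + bisection over n.
  One-tailed is the default (`tails` is explicit); with d = 1.1, α = 0.05,
  power 0.95 it returns 19 per group.

## Mixed ANOVA

The 2 (group, between) × 4 (method, within) ANOVA on absolute percentage
errors is computed as a split-plot decomposition: the between part is a
one-way ANOVA on subject means (×k); the within part takes Type-III sums
of squares for method and interaction from an OLS on subject-centered data
(sum-coded), with the within error SS as that model's residual and error
df (N − g)(k − 1). Subjects missing any method after exclusion are dropped
listwise with a logged count. On balanced data the F statistics match
pingouin's `mixed_anova` to machine precision (cross-checked in the test
suite, along with a from-scratch sums-of-squares oracle).

Greenhouse-Geisser epsilon is computed from the within-group *pooled*
covariance of the method levels (orthonormal-contrast form) — the pooled
covariance, not the total one, is the right error matrix when groups may
differ in level — and is always reported. Within-effect numerator and
denominator dfs are multiplied by epsilon when the trigger fires; the
trigger is configurable (`mauchly` default: Mauchly's test at p < 0.05;
`always`; `never`) because published reports are often ambiguous about
which assumption check gated the correction. Mauchly's W uses the classic
first-order chi-square approximation (SPSS convention); pingouin's
higher-order approximation agrees on W exactly and on p to ~0.01. With two
within levels epsilon is exactly 1 and no test is run. Bonferroni-adjusted
pairwise p-values are `min(1, m·p_raw)` with m = C(4,2) = 6.

## Pipeline and bookkeeping

`run_study` processes each exercise independently: rep averaging →
four-method prediction → exclusion → validity cells for each group and the
pooled "whole" cohort (2 groups × 4 methods × 3 exercises = 24 group cells
+ 12 whole cells) → mixed ANOVA and pairwise comparisons on
complete-case athletes. Cells with n < 2 after exclusion are emitted with
their n and empty statistics, and skipped ANOVAs are logged. All outputs
are plain CSV (UTF-8, comma-separated, '.' decimal — stated because
velocity data often circulates with comma decimals) plus a JSON manifest
carrying the seed, the config (and its SHA-256), and output checksums;
(config, seed) determines every output byte.

Randomized load order within a session is treated as metadata only: it
does not change any computed quantity and is not simulated.

## Problem sizes used in checks

The packaged default study is 20 + 20 athletes × 3 exercises × 7 loads ×
3 reps (2,520 repetition rows), which runs the full pipeline in a few
seconds. Exact-recovery and bias checks use noiseless 20-per-group
cohorts (120 profiles, 480 predictions); the qualitative error-structure
simulation uses 200 athletes per group, large enough that the method
ordering (low-load worst; middle-aged squat error above young) is stable
across seeds.

## Known limitations

* The generator's parameter values for submaximal velocities are field-
  plausible defaults, not estimates fitted to a specific dataset.
* No Bland-Altman limits of agreement or coefficient-of-variation
  reliability statistics; no plotting.
* The between-group design assumes exactly two groups for the ANOVA's
  pooled-covariance epsilon; more groups work arithmetically but are
  untested territory scientifically.
* Individualized-MVT prediction (using each athlete's own 1RM velocity) is
  deliberately out of scope: the point of the reference-MVT design is to
  avoid a direct 1RM test.
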