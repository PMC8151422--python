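"""Run the full simulate -> predict -> validate study pipeline.

Simulates the default cohort, predicts 1RM by all four methods, applies the
>50%-error outlier rules, and prints the bench-press validity table plus
the mixed-ANOVA summary for that exercise.
"""

import tempfile

from lv1rm import default_config, replicate

config = default_config()
with tempfile.TemporaryDirectory() as out:
    report, bundle = replicate(config, out, seed=7)

print("bookkeeping:", report.counts)
print()
bench = report.validity[report.validity["exercise"] == "bench_press"]
cols = ["group", "method", "n", "raw_diff_mean_kg", "p_value", "es",
        "r_pearson", "r_hetero", "mean_abs_pct_error", "error_label"]
print(bench[cols].round(3).to_string(index=False))
print()
anova = report.anova[(report.anova["exercise"] == "bench_press")
                     & (report.anova["effect"] != "method_pairwise")]
print(anova[["effect", "statistic", "df_num", "df_den", "epsilon_gg",
             "gg_applied", "p"]].round(4).to_string(index=False))
# Rows with group "whole" pool both groups after exclusion; the ANOVA is a
# 2 (group) x 4 (method) mixed design on absolute percentage errors.
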