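"""Simulate a rep-level testing cohort and inspect its structure.

Generates the default study conditions (20 young + 20 middle-aged athletes,
3 exercises, 7 loads x 3 reps) and prints the dataset's shape and a sample.
"""

from lv1rm import default_config, generate_cohort

config = default_config()
sessions, truth = generate_cohort(config, master_seed=42)

print(f"athletes: {truth['athlete_id'].nunique()}  "
      f"profiles: {len(truth)}  repetition rows: {len(sessions)}")
print()
print(sessions.head(6).to_string(index=False))
print()
# The ground-truth table carries each athlete's true 1RM and individual
# MVT; downstream prediction sees only the session rows.
print(truth.groupby("group")[["true_1rm_kg", "mvt_ind_mps"]]
      .mean().round(3).to_string())
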