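# Default study conditions: two groups of 20 resistance-trained males,
# three exercises, loads 20-80 %1RM in 10% steps, 3 reps per load.
# Velocity anchors: bent-over-row parameters put the cohort mean velocity at
# 80 %1RM near 0.638 m/s and the cohort row 1RM near 90 kg.  Middle-aged
# cells use a smaller v20 - mvt_ind span (flatter load-velocity slope) and a
# higher probability of low-load slope flattening.
master_seed: 20210507
exercises: [bench_press, back_squat, bent_over_row]
reference_mvt:
  bench_press: 0.17
  back_squat: 0.37
  bent_over_row: 0.40
relative_loads: [20, 30, 40, 50, 60, 70, 80]
n_reps: 3
outlier_threshold_pct: 50.0
anova_trigger: mauchly
equation_name: brzycki
regress_direction: velocity_on_load
round_loads_to: null
heteroscedastic_noise: false
es_denominator: pooled
groups:
  young:
    n_athletes: 20
    bench_press:
      {true_1rm_mean: 100.0, true_1rm_sd: 15.0, v20_mean: 1.50, v20_sd: 0.08,
       mvt_ind_mean: 0.17, mvt_ind_sd: 0.04, rep_noise_sd: 0.04,
       flatten_prob: 0.05, flatten_strength: 0.8}
    back_squat:
      {true_1rm_mean: 130.0, true_1rm_sd: 20.0, v20_mean: 1.60, v20_sd: 0.08,
       mvt_ind_mean: 0.37, mvt_ind_sd: 0.05, rep_noise_sd: 0.04,
       flatten_prob: 0.05, flatten_strength: 0.8}
    bent_over_row:
      {true_1rm_mean: 92.0, true_1rm_sd: 15.0, v20_mean: 1.40, v20_sd: 0.08,
       mvt_ind_mean: 0.40, mvt_ind_sd: 0.05, rep_noise_sd: 0.04,
       flatten_prob: 0.05, flatten_strength: 0.8}
  middle_aged:
    n_athletes: 20
    bench_press:
      {true_1rm_mean: 95.0, true_1rm_sd: 15.0, v20_mean: 1.30, v20_sd: 0.08,
       mvt_ind_mean: 0.17, mvt_ind_sd: 0.04, rep_noise_sd: 0.04,
       flatten_prob: 0.30, flatten_strength: 0.8}
    back_squat:
      {true_1rm_mean: 120.0, true_1rm_sd: 20.0, v20_mean: 1.40, v20_sd: 0.08,
       mvt_ind_mean: 0.37, mvt_ind_sd: 0.05, rep_noise_sd: 0.04,
       flatten_prob: 0.30, flatten_strength: 0.8}
    bent_over_row:
      {true_1rm_mean: 88.0, true_1rm_sd: 14.0, v20_mean: 1.30, v20_sd: 0.08,
       mvt_ind_mean: 0.40, mvt_ind_sd: 0.05, rep_noise_sd: 0.04,
       flatten_prob: 0.30, flatten_strength: 0.8}
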