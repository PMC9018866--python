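# Small end-to-end pipeline configuration (completes in a few minutes).
seed: 1
out_dir: pipeline_out
n_subjects: 8
maze_shape: [5, 5]

true_params:
  alpha: 0.9
  beta: 0.85
  p_lh: 0.4
  p_hl: 0.5
  n_history: 2

game:
  n_games: 16
  n_sessions: 4
  rng_seed: 0

fit:
  n_max: 3
  n_starts: 4
  seed: 0

patterns:
  n_features: 300
  n_informative: 60
  amplitude: 2.0
  sigma_high_conf: 0.5
  sigma_low_conf: 1.0

decoding:
  periods: [0, 3, 6, 8]
  n_undersample_repeats: 10
  min_samples_per_label_training: 3

conditions: [conf_high, conf_low, state_conf_high, state_conf_low]
perm_n_sbj: 30
perm_n_group: 200
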