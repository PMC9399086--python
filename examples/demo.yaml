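# Small end-to-end demo: 5 synthetic participants, 30-trial choice set,
# baseline model only, tiny sampler budget (completes in well under a minute).
#   socialrisk run --config examples/demo.yaml
seed: 5
out_dir: out/demo
design:
  n_mixed: 18
  n_gain_only: 12
population:
  group_log_means: [0.0677, 0.5766, 2.8904]
  group_log_sds: [0.25, 0.35, 0.4]
  true_social_effects:
    d_rho_other: -0.11
    d_lam_other: 0.06
    d_mu_other: 0.45
  subject_effect_sd: 0.15
  n_friend: 2
  n_stranger: 3
  seed: 5
models: [M0]
mcmc:
  chains: 2
  warmup: 100
  draws: 60
  seed: 5
  scaled_down: true
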