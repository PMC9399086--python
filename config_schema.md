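# Run configuration schema

`socialrisk run --config cfg.yaml` (and `socialrisk.pipeline.load_run_config`)
accept a YAML/JSON mapping with the following keys.  Unknown keys are
rejected.  Every field is optional; defaults are shown.

```yaml
seed: 0                 # master seed; all stage seeds derive from it
out_dir: out            # output directory

design:                 # choice-set sizes and value grids
  n_mixed: 54           # mixed gambles per condition (>= 0)
  n_gain_only: 36       # gain-only gambles per condition (>= 0)
  mixed_gains: [2, 4, 5, 6, 8, 9, 10, 12]
  loss_factor_range: [-0.25, -2.0]    # loss = gain x factor, within [-2, -0.25]
  gain_only_range: [3.25, 30.0]       # risky gains, evenly spaced
  guaranteed_fractions: [0.35, 0.4, 0.45, 0.5, 0.55, 0.6]  # in (0, 1)
  n_blocks: 3           # mini-blocks per condition; must divide the total

population:             # synthetic-cohort truth (defaults: published point
                        # estimates for means/effects; spreads are free
                        # choices, stated here explicitly)
  group_log_means: [0.0677, 0.5766, 2.8904]   # log(rho), log(lambda), log(mu)
  group_log_sds: [0.25, 0.35, 0.4]            # >= 0
  true_social_effects:                        # additive log-scale shifts
    d_rho_other: -0.11
    d_rho_sharing: 0.016
    d_rho_identity: -0.05
    d_lam_other: 0.06
    d_lam_sharing: 0.0
    d_lam_identity: 0.02
    d_mu_other: 0.45
    d_mu_sharing: 0.0
    d_mu_identity: -0.18
  subject_effect_sd: 0.15   # spread of subject-level 'other' shifts (>= 0)
  traits:                   # covariates tied to a subject-level shift
    - {name: social_risk, mean: 25.0, sd: 7.0, target_corr: 0.30,
       linked_effect: d_lam_other}
    - {name: empathy, mean: 70.0, sd: 10.0, target_corr: -0.25,
       linked_effect: d_rho_other}
  n_friend: 28
  n_stranger: 29
  seed: 0

models: [M1]            # any of M0 / M1 / M2; each is fitted in turn
effects_mode: model1_fixed   # or model2_mixed (subject-level generation)

mcmc:
  chains: 4
  warmup: 1000
  draws: 2500           # retained per chain (4 x 2500 = 10,000 total)
  seed: 0
  target_accept: 0.9
  trajectory_length: 3.0
  max_leapfrog: 64
  scaled_down: false    # metadata flag for reduced budgets
```
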