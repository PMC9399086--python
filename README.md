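# socialrisk

Hierarchical Bayesian prospect-theory modelling of risky monetary choices
made **for oneself**, **for another person**, or **with shared outcomes**
(friend vs. stranger partners).

The package provides:

- **Task construction** (`socialrisk.task_design`): the 90-gamble choice set
  (mixed 50/50 gain-loss gambles vs. a guaranteed $0; gain-only gambles vs. a
  smaller guaranteed gain), three-condition sessions (self first, other/shared
  counterbalanced) with signed social-indicator coding
  (other: 0/+1; sharing: +1 other-only / −1 shared; identity: +1 stranger / −1 friend).
- **The choice model** (`socialrisk.prospect_model`): utilities
  `u = p⁺·gain^ρ − p⁻·λ·|loss|^ρ`, softmax choice probability with
  consistency `µ`, and per-trial parameter composition
  `θ_trial = exp(log θ + other·δ_other + sharing·δ_sharing + identity·δ_identity)`.
- **A synthetic cohort generator** (`socialrisk.synthetic_cohort`): agents
  drawn from the hierarchy the model assumes, Bernoulli choice simulation
  with ground truth retained, and trait covariates generated with a target
  correlation to subject-level social effects.
- **Hierarchical Bayesian inference** (`socialrisk.inference`): Models
  M0 (baseline hierarchy), M1 (nine fixed additive social terms), and
  M2 ('other' terms as mixed effects, sharing fixed, no identity), estimated
  by an adaptive Hamiltonian Monte Carlo sampler with analytic gradients,
  plus shortest-interval HDIs, WAIC (with paired model comparison), and
  split-R̂/ESS convergence checks.
- **Reports** (`socialrisk.reports`): implied per-condition parameter means
  (draw-wise composition with HDIs), parameter-recovery summaries, Pearson
  trait correlations (with BH adjustment), and friend-vs-stranger t-tests on
  subject-level effects.
- **A pipeline + CLI** (`socialrisk.pipeline`, `socialrisk.cli`):
  `generate`, `simulate`, `fit`, `report`, `recover`, and `run`, all
  reproducible from a single master seed.

## CLI examples

```bash
socialrisk generate --n-stranger 29 --n-friend 28 --seed 0 --out design.csv
socialrisk simulate --seed 1 --out-dir out/          # trials.csv + agents.csv
socialrisk fit --data out/trials.csv --model M1 --chains 4 --draws 2500 \
    --warmup 1000 --seed 0 --out out/posterior_M1
socialrisk run --seed 1 --out-dir out/run            # full pipeline
```

Run configurations are YAML files validated against the schema described in
`config_schema.md`; every pipeline run re-serializes its config (with a
SHA-256 hash) into the output directory.

## Notes

- Sampler defaults mirror a 4-chain / 10,000-total-retained-draw
  configuration; tests run reduced budgets flagged `scaled_down` in the fit
  metadata.
- Priors are not pinned by the source analysis and are declared in
  `socialrisk.inference.PriorConfig`; they are recorded in every fit summary.
- The optional external benchmark (fitting the study's deposited dataset)
  runs only if a validated trial table is placed at `data/osf_trials.csv`.
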