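# painnma

Bayesian random-effects network meta-analysis (NMA) of arm-level
randomized-trial networks, built for multi-drug pain-trial syntheses but
generic over any connected treatment network. The package covers the full
pipeline:

- **`trial_data`** — arm-level data model, CSV loading/validation,
  follow-up time-point selection, network composition summaries and the
  comparison graph. Ships a 20-trial / 12-node fixture (11 drugs +
  placebo) transcribed from a published trial table (enrollment counts and
  metadata; per-study outcome values are not publicly available).
- **`effect_sizes`** — Hedges' g standardized mean differences (small-sample
  corrected) for continuous outcomes, Woolf log odds ratios (with 0.5
  continuity correction) for dichotomous outcomes, with orientation
  normalization so negative SMD always means greater relief.
- **`pairwise_meta`** — DerSimonian–Laird random-effects pairwise pooling
  (also the closed-form oracle for validating the Bayesian engine) and
  comparison-adjusted funnel data with an Egger-style asymmetry test.
- **`nma_engine`** — the arm-based consistency model: normal likelihood on
  anchor-based SMD contrasts or binomial-logit likelihood on raw arm
  counts, shared heterogeneity SD, 0.5-correlated multi-arm random
  effects, a reproducible Metropolis-within-Gibbs sampler (3 chains,
  50k burn-in / 100k updates by default), split-chain R-hat and batch-means
  MC error diagnostics, DIC, and league tables.
- **`inconsistency`** — node splitting (separate parameter for the direct
  evidence on one comparison; IF = direct − indirect with a two-sided
  Bayesian p-value) and a global DIC comparison against the
  unrelated-mean-effects model.
- **`ranking`** — rank probabilities, SUCRA, mean ranks, cumulative ranking
  curves and the cross-outcome heat-map matrix with explicit NA cells.
- **`synthetic_data`** — trial-network simulator with known ground truth
  (star / triangle / star-plus-edges / complete geometries, heterogeneity,
  optional loop inconsistency) including a canned 12-treatment, 20-trial
  scenario shaped like the motivating network.
- **`cli_report`** — `painnma` CLI with `summarize`, `fit`, `rank`,
  `nodesplit` and `simulate` verbs, YAML configuration, atomic CSV/JSON
  outputs and a run manifest (seed, version, config hash).

## CLI

```sh
# composition counts of the bundled fixture
painnma summarize --outdir out/

# simulate a 20-trial network with known truth, then analyse it
painnma simulate --outdir sim/ --seed 1
painnma fit      --input sim/simulated_trials.csv --outcome pain4w \
                 --outdir out/ --seed 1 --profile test
painnma rank     --input sim/simulated_trials.csv --outcome pain4w \
                 --outdir out/ --seed 1 --profile test
painnma nodesplit --input sim/simulated_trials.csv --outcome pain4w \
                 --outdir out/ --seed 1 --profile test
```

`--profile paper` (default) uses the full 3-chain 50k/100k protocol;
`--profile test` is the reduced profile used by the test suite. A YAML
config (`--config`) can set inputs, outcomes, output directory and any
`ModelSpec` override under a `model:` block.

## Input format

UTF-8 CSV, one row per study arm: `study_id, treatment, n, outcome_id,
followup_weeks, kind, events, mean_change, sd, scale_name, direction`
(plus optional `country, risk_of_bias, role`). Rows with an empty
`outcome_id` declare randomized arm sizes only; rows with an outcome carry
that arm's measurement at the stated follow-up. Missing numeric cells are
empty, not zero. `painnma.trial_data.write_network` emits the same schema.
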