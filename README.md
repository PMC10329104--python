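# metacontrol

Simulation and model-fitting toolkit for a two-step "space treasure"
decision task with stake amplification, plus the cohort-level statistical
pipeline used to study stake-sensitive arbitration (metacontrol) between
model-based and model-free control in children.

The package provides:

- **`metacontrol.task`** — the task environment: deterministic
  spaceship-to-planet transitions (two pairs, one ship per planet each),
  per-planet drifting 0–9 treasure rewards (reflected Gaussian walks), and a
  random ~50/50 schedule of 1x/5x stake trials.
- **`metacontrol.agent`** — a generative dual-systems agent: model-free TD
  values with an eligibility trace, model-based planning values over the
  known transition map, and a softmax mixture whose model-based weight is
  selected per trial by the stake condition (`w_low` vs `w_high`;
  `w_high - w_low` is the metacontrol score), with choice- and
  response-key-stickiness.
- **`metacontrol.fitting`** — trial-by-trial likelihood of an observed
  session, per-subject maximum-likelihood estimation with seeded multistart
  L-BFGS-B over transformed parameters, and metacontrol extraction.
- **`metacontrol.metrics`** — corrected reward rate vs. chance, the
  missed-more-than-30% exclusion rule, and a stay-probability logistic
  regression whose different-pair previous-reward effect indexes model-based
  generalization.
- **`metacontrol.cohort`** — a synthetic cohort generator (self-calibrating
  Gaussian copula) reproducing the individual-difference structure the
  analyses assume: age–model-based-weight correlation, age-independent
  metacontrol, Flanker-cost and cortical-thickness-proxy correlations with
  metacontrol.
- **`metacontrol.stats`** — Pearson tests with Fisher-z CIs, one-sample and
  Welch t-tests with Cohen's d, Bonferroni thresholds, exact
  correlation-power / sample-size computation (with Fisher-z and Monte Carlo
  alternatives), and percentile-bootstrap mediation.
- **`metacontrol.pipeline` / `metacontrol.cli`** — an end-to-end, fully
  seeded pipeline and a `metacontrol` command-line tool.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
values, the N=53 power computation, chance-level and likelihood oracles,
the model-based/model-free generalization dissociation, parameter recovery,
and mediation identity/coverage). The recovery test simulates and fits 60
subjects and takes a few minutes.

## CLI

```sh
metacontrol simulate --seed 1 --out trials.csv --n-trials 200
metacontrol fit --trials trials.csv --seed 1 --out fit.json
metacontrol metrics --trials trials.csv --out summary.csv
metacontrol power --rho 0.39 --tails one --method exact   # -> N = 53
metacontrol correlate --table cohort.csv --x-cols metacontrol_hat \
    --y-cols age,flanker --m-tests 21 --out battery.csv
metacontrol mediate --table cohort.csv --x thickness_left --m flanker \
    --y metacontrol_hat --seed 1 --out mediation.json
metacontrol run-all --seed 1 --out results/
```

Exit codes: 0 success, 1 data error, 2 configuration error. `run-all`
accepts a flat YAML config (`task.n_trials: 200`, `cohort.n_subjects: 69`,
`n_restarts: 10`, ...) and writes a report bundle (cohort, per-subject trial
CSVs, fits, behavioral summaries, correlation battery with Bonferroni flags,
mediation JSON, run log) that is byte-identical across runs with the same
config and seed.

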