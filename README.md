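# hiddensingle

Toolkit for the *hidden single* Sudoku reasoning task: procedural puzzle
generation with controlled digit roles, balanced practice/transfer
designs, a four-strategy latent Markov model of strategy acquisition with
exact path-posterior inference, a mixed-model solver classifier,
transfer-effect regressions, and synthetic cohort simulation so the whole
pipeline runs with no external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `hiddensingle.grid` / `hiddensingle.puzzle` | 9x9 board geometry; generate, validate, solve, and explain hidden-single puzzles; classify any response digit into target / distractor / absent / in-house |
| `hiddensingle.design` | per-participant feature assignment, 25-trial practice designs, and the balanced 64-trial transfer design (Williams Latin square over the 8 house-type x house-index x cell-index change combinations) |
| `hiddensingle.strategy` | strategy classes (UG < ADC < PD < S), the fixed emission matrix, parameter containers, bundled reference parameter sets for solver and non-solver groups |
| `hiddensingle.aggregate` | group-level response model `a X^(t-1) W R`, its negative log-likelihood, and constrained multi-start MLE |
| `hiddensingle.paths` | exact posterior over the 3,276 weakly monotone strategy paths (T=25), marginal/cumulative strategy probabilities, transition trials, forward-backward cross-check |
| `hiddensingle.classifier` | preregistered solver classification: logistic mixed model on log2(trial) with random intercepts + slopes, 0.8 threshold on predicted trial-25 accuracy |
| `hiddensingle.teststats` | transfer-phase accuracy (logit) and response-time (log2 s) mixed models per feature and trial window; Cohen's kappa with CI |
| `hiddensingle.cohort` | synthetic cohorts: latent paths, practice responses and digits, test-phase correctness and RTs with configurable effects |
| `hiddensingle.glmm` | shared Laplace-approximation logistic mixed-model engine |
| `hiddensingle.io` / `hiddensingle.cli` | CSV/JSON dialects, run manifests, and the `hiddensingle` command-line tool |

## CLI

All stages are subcommands of one entry point; every run writes a JSON
manifest next to its outputs:

```bash
hiddensingle generate-puzzles --house-type row --house-index 3 --cell-index 5 \
    --digit-set 1,3,5,7 --n 25 --seed 1 --out puzzles.json
hiddensingle build-design --seed 1 --out design.csv
hiddensingle simulate-cohort --config cohort.yaml --out-dir sim/
hiddensingle classify-solvers --responses sim/practice_responses.csv --out labels.csv
hiddensingle fit-aggregate --responses sim/practice_responses.csv --out params.json
hiddensingle fit-paths --responses sim/practice_responses.csv --params params.json \
    --top-k 3 --out posterior.json
hiddensingle analyze-test --responses sim/test_records.csv --out effects.csv
```

`cohort.yaml` keys mirror `hiddensingle.cohort.CohortConfig`
(`n_solvers`, `n_non_solvers`, `seed`, `include_puzzles`,
`accuracy_shifts`, `rt_shifts`, ...); omit the file to use defaults.

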