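# pavarb

Arbitration between Pavlovian and instrumental control on a reward Go/No-Go
task, as a tested simulation/fitting/analysis pipeline.

Two Beta-Bernoulli reward predictors learn in parallel: a stimulus-only
(Pavlovian) predictor and a stimulus-action (instrumental) predictor. A
log-odds accumulator infers whether outcomes are controllable from the
predictors' one-step predictive accuracy; its sigmoid is the Pavlovian
weight `w` that mixes the two sets of action values before a softmax choice.
The **adaptive** model updates `w` trial-by-trial; the **fixed** model fits
`w` as a constant free parameter. The task manipulates controllability with
a Decoy stimulus rewarded 50% regardless of action (Low Control) or 80% for
Go (High Control), alongside Go-to-Win and No-Go-to-Win stimuli rewarded 75%
for the correct response.

The package provides:

- `pavarb.task` — task configurations (Experiment 1: 120 trials between
  subjects; Experiment 2: 240 trials in two within-subject blocks), seeded
  trial sequences, Bernoulli outcomes, and a documented trial CSV schema.
- `pavarb.models` — the learners, controllability log-odds, value
  integration, softmax choice, forward simulation of agents, and session
  log-likelihoods.
- `pavarb.fitting` — per-participant multistart maximum-likelihood fitting
  of both model variants (5 and 6 free parameters) with BIC/AIC evidence
  approximations.
- `pavarb.model_comparison` — random-effects Bayesian model selection:
  Dirichlet posterior over model frequencies, exceedance probability, Bayes
  omnibus risk, and protected exceedance probability (PXP).
- `pavarb.analysis` — participant exclusion rules, Go bias (accuracy on
  Go-to-Win minus No-Go-to-Win), weight-quantile and timecourse analyses,
  the bias-variance decomposition of choice behavior, and group statistics.
- `pavarb.cli` — a `pavarb` command wiring it all together.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (task constants,
directional replications on synthetic cohorts, PXP on a surrogate cohort,
oracle equivalences, parameter recovery); the full run takes ~2 minutes on
one CPU.

## CLI

```sh
pavarb simulate --experiment exp1 --condition lc --n-agents 50 --seed 1 --out out/
pavarb fit      --trials out/trials.csv --seed 1 --out out/
pavarb compare  --fits out/fits.csv --out out/
pavarb analyze  --trials out/trials.csv --weights out/weights.csv --out out/
pavarb reproduce --seed 1 --out out/     # end-to-end synthetic pipeline
```

All commands are deterministic given `--seed`; every stochastic stage draws
from its own named substream of the global seed.

## File schemas

- Trials CSV: `participant_id,experiment,condition,block,trial,stimulus,action,reward,optimal_action`
  with `stimulus ∈ {go_win,nogo_win,decoy_lc,decoy_hc}`, `action ∈ {go,nogo}`,
  `reward ∈ {0,1}`.
- Weights CSV: `participant_id,trial,w`.
- Fits CSV: `participant_id,variant,beta,theta0_u,eta0_u,theta0_c,eta0_c,w_fixed,loglik,evidence,converged`.
- BMS JSON: `{models, alpha, expected_freq, ep, bor, pxp}`.
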