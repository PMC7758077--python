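# ibslik

Unbiased log-likelihood estimation for simulator-based models via inverse
binomial sampling (IBS), with fixed-sampling comparators, two fully
specified case-study cognitive models, information-theoretic estimators,
and reproducible calibration / parameter-recovery / log-likelihood-loss
experiments.

The core idea: for each observed trial, draw responses from the model's
simulator until one matches the observation. If the hit count is `K`, then
`psi(1) - psi(K)` (digamma) is an *unbiased* estimate of the trial's log
probability, with exactly known, uniformly bounded variance
(`Li2(1-p) < pi^2/6`) and a calibrated per-estimate variance estimator
(`trigamma(1) - trigamma(K)`). Summing across trials gives an unbiased,
approximately Gaussian estimate of the dataset log-likelihood that can be
fed to noise-tolerant optimizers — unlike fixed sampling, which is
inevitably biased when `p * M` is small.

## Library quick start

```python
import numpy as np
from ibslik import IBSConfig, ibs_loglik, TrialData

def my_simulator(stimulus, params, rng):
    ...  # return one discrete response

data = TrialData(stimuli=..., responses=...)
res = ibs_loglik(data, my_simulator, params, IBSConfig(repeats=3, seed=0))
print(res.loglik, res.variance, res.total_samples)
```

Key modules:

- `ibslik.estimators` — closed-form point/variance estimators, fixed-
  sampling comparators, exact enumeration oracles, repeat combination.
- `ibslik.engine` — dataset-level estimation with repeats, early-stopping
  floor, per-trial sample caps, and a reproducible per-(repeat, trial)
  substream contract (sequential and batched modes are bit-identical);
  plus a vectorised fast path for batch simulators.
- `ibslik.models` — orientation discrimination (psychometric function,
  exact likelihood), change localization (von Mises ideal observer,
  quadrature likelihood), and a known-p Bernoulli reference model; registry
  names `"orientation"`, `"changeloc"`, `"bernoulli"`.
- `ibslik.infotheory` — unbiased entropy / cross-entropy / KL estimation,
  and approximate estimation for continuous responses (metric + tolerance
  ball volume).
- `ibslik.experiments` — calibration (z-score) study, noise-robust
  maximum-likelihood fitting, parameter-recovery grids, log-likelihood
  loss.

## Command line

```sh
# generate a synthetic dataset
ibslik simulate --model orientation --params eta=0.693,mu=0.1,gamma=0.1 \
    -n 600 --seed 1 --out trials.csv

# estimate its log-likelihood (JSON on stdout or --out)
ibslik estimate --trials trials.csv --model orientation \
    --params eta=0.693,mu=0.1,gamma=0.1 --arm ibs --repeats 3 --seed 2

# maximum-likelihood fit
ibslik fit --trials trials.csv --model orientation --arm ibs --repeats 5 --seed 3

# calibration study, recovery experiment, entropy estimate
ibslik calibrate --params eta=0.693,mu=0.1,gamma=0.1 --n-datasets 1000 --seed 4
ibslik recover --model orientation --settings 2 --datasets 2 \
    --arms ibs:1+fixed:10 --records records.csv --seed 5
ibslik entropy --model bernoulli --params p=0.5 --stimulus 0 --seed 6
```

Trial tables are plain CSV with stimulus columns `s1..sk` and response
columns `r1..rm`. All randomness flows from `--seed`; rerunning a seeded
command is byte-identical.

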