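"""Known-probability Bernoulli reference model.

The estimation problem reduces per trial to sampling a Bernoulli variable
with unknown hit probability, so a model whose hit probability is known
exactly is the canonical ground truth for bias, variance and distributional
checks.  The stimulus is ignored; responses are 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..engine import TrialData

__all__ = [
    "BernoulliParams",
    "bernoulli_exact_loglik",
    "bernoulli_generate_dataset",
    "bernoulli_simulate",
    "bernoulli_simulate_batch",
]


@dataclass(frozen=True)
class BernoulliParams:
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


def bernoulli_simulate(stimulus, params: BernoulliParams, rng: np.random.Generator) -> int:
    return int(rng.random() < params.p)


def bernoulli_simulate_batch(
    stimuli, params: BernoulliParams, rng: np.random.Generator
) -> np.ndarray:
    n = np.asarray(stimuli).reshape(len(np.atleast_1d(stimuli)), -1).shape[0]
    return (rng.random(n) < params.p).astype(np.int64)


def bernoulli_generate_dataset(
    params: BernoulliParams,
    n_trials: int = 100,
    rng: np.random.Generator | None = None,
) -> TrialData:
    if rng is None:
        rng = np.random.default_rng()
    stimuli = np.zeros(n_trials)
    responses = bernoulli_simulate_batch(stimuli, params, rng)
    return TrialData(stimuli=stimuli, responses=responses)


def bernoulli_exact_loglik(data: TrialData, params: BernoulliParams) -> float:
    r = np.asarray(data.responses)
    with np.errstate(divide="ignore"):
        ll = np.where(r == 1, np.log(params.p), np.log1p(-params.p))
    return float(ll.sum())
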