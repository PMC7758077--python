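"""Orientation discrimination: a psychometric-function observer.

On each trial the observer sees a patch tilted by ``s`` degrees relative to a
reference, makes a noisy measurement ``x ~ Normal(s, sigma)`` and responds
"rightwards" iff ``x > mu``; with probability ``gamma`` (the lapse rate) the
response is instead uniformly random.  The trial likelihood is the standard
psychometric function

    Pr(rightwards | s) = gamma / 2 + (1 - gamma) * Phi((s - mu) / sigma)

with ``Phi`` the standard normal CDF.  The noise scale is parametrised as
``eta = log(sigma)`` with sigma in degrees.  Responses are coded as integers:
0 = leftwards, 1 = rightwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from ..engine import TrialData

__all__ = [
    "LEFT",
    "RIGHT",
    "OrientationTaskConfig",
    "PsychometricParams",
    "orientation_exact_loglik",
    "orientation_generate_dataset",
    "orientation_likelihood",
    "orientation_response_prob",
    "orientation_simulate",
    "orientation_simulate_batch",
]

LEFT = 0
RIGHT = 1


@dataclass(frozen=True)
class PsychometricParams:
    """Psychometric observer parameters ``(eta, mu, gamma)``.

    ``eta = log(sigma)`` with sigma the measurement noise in degrees; ``mu``
    the response bias in degrees; ``gamma`` the lapse rate in ``(0, 1]``.
    """

    eta: float
    mu: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def sigma(self) -> float:
        return float(np.exp(self.eta))


@dataclass(frozen=True)
class OrientationTaskConfig:
    n_trials: int = 600
    stim_mean: float = 0.0
    stim_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.stim_sd <= 0:
            raise ValueError("stim_sd must be > 0")


def prob_rightwards(s, p: PsychometricParams):
    """Pr(rightwards | s) for stimulus orientation(s) ``s`` in degrees."""
    s = np.asarray(s, dtype=float)
    out = p.gamma / 2.0 + (1.0 - p.gamma) * special.ndtr((s - p.mu) / p.sigma)
    return float(out) if out.shape == () else out


def orientation_likelihood(s: float, r: int, p: PsychometricParams) -> float:
    """Exact probability of response ``r`` (0 = left, 1 = right) at stimulus ``s``."""
    pr = prob_rightwards(s, p)
    if r == RIGHT:
        return pr
    if r == LEFT:
        return 1.0 - pr
    raise ValueError(f"response must be {LEFT} or {RIGHT}, got {r!r}")


def orientation_response_prob(data: TrialData, p: PsychometricParams) -> np.ndarray:
    """Vector of exact per-trial likelihoods for observed responses."""
    s = np.asarray(data.stimuli, dtype=float).reshape(-1)
    r = np.asarray(data.responses)
    pr = prob_rightwards(s, p)
    return np.where(r == RIGHT, pr, 1.0 - pr)


def orientation_exact_loglik(data: TrialData, p: PsychometricParams) -> float:
    """Exact dataset log-likelihood, finite whenever ``gamma > 0``."""
    return float(np.log(orientation_response_prob(data, p)).sum())


def orientation_simulate(s, p: PsychometricParams, rng: np.random.Generator) -> int:
    """Draw one response for stimulus ``s`` (degrees)."""
    if rng.random() < p.gamma:
        return int(rng.integers(2))
    x = rng.normal(float(np.asarray(s).reshape(-1)[0]), p.sigma)
    return int(x > p.mu)


def orientation_simulate_batch(
    stimuli, p: PsychometricParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw one response per stimulus, vectorised."""
    s = np.asarray(stimuli, dtype=float).reshape(-1)
    x = rng.normal(s, p.sigma)
    resp = (x > p.mu).astype(np.int64)
    lapse = rng.random(s.size) < p.gamma
    n_lapse = int(lapse.sum())
    if n_lapse:
        resp[lapse] = rng.integers(0, 2, n_lapse)
    return resp


def orientation_generate_dataset(
    p: PsychometricParams,
    cfg: OrientationTaskConfig = OrientationTaskConfig(),
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Simulate a dataset: stimuli ~ Normal(stim_mean, stim_sd), responses
    from the observer model."""
    if rng is None:
        rng = np.random.default_rng()
    s = rng.normal(cfg.stim_mean, cfg.stim_sd, cfg.n_trials)
    r = orientation_simulate_batch(s, p, rng)
    return TrialData(stimuli=s, responses=r)
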