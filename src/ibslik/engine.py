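"""Dataset-level log-likelihood estimation against an arbitrary simulator.

The estimation loop draws simulator responses for each trial until one
matches the observed response ("inverse binomial sampling"), optionally with
multiple independent repeats, an early-stopping floor on the accumulating
estimate, and a per-trial cap on simulator draws.

Randomness contract
-------------------
A root seed spawns an independent substream per ``(repeat, trial)`` pair via
``numpy.random.SeedSequence(seed, spawn_key=(repeat, trial))``.  Because each
pair consumes only its own stream, the sequential and per-pair batched
execution modes produce bit-identical sample counts, and any run is exactly
reproducible from ``(seed, config)``.

A faster, vectorised path (:func:`ibs_loglik_batch`) is provided for
simulators exposing a batch interface; it uses one stream per repeat and is
distributionally — not bit-for-bit — equivalent to the sequential mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .estimators import ibs_point_estimate, ibs_variance_estimate

__all__ = [
    "IBSConfig",
    "IBSResult",
    "TrialData",
    "batched_ibs_pass",
    "canonical_response",
    "early_stop_check",
    "fixed_loglik",
    "fixed_loglik_batch",
    "ibs_loglik",
    "ibs_loglik_batch",
    "substream",
]


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for substream ``key`` under a root ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def derive_seed(seed: int, *key: int) -> int:
    """Derive a child integer seed from a root seed and a key tuple."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def canonical_response(r) -> Any:
    """Canonical hashable form of a response for exact-equality matching."""
    if isinstance(r, np.generic):
        r = r.item()
    if isinstance(r, (list, tuple, np.ndarray)):
        return tuple(canonical_response(x) for x in r)
    return r


@dataclass
class TrialData:
    """Paired stimuli and discrete responses for ``N`` trials."""

    stimuli: Any
    responses: Any

    def __post_init__(self) -> None:
        n_stim = len(self.stimuli)
        n_resp = len(self.responses)
        if n_stim != n_resp:
            raise ValueError(
                f"stimuli ({n_stim}) and responses ({n_resp}) differ in length"
            )
        if n_stim < 1:
            raise ValueError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class IBSConfig:
    """Estimation controls for :func:`ibs_loglik`."""

    repeats: int = 1
    early_stop_threshold: Optional[float] = None
    max_samples_per_trial: Optional[int] = None
    execution: str = "sequential"
    batch_size: Optional[int] = None  # (repeat, trial) pairs per batched pass
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_samples_per_trial is not None and self.max_samples_per_trial < 1:
            raise ValueError("max_samples_per_trial must be >= 1")
        if self.early_stop_threshold is not None and not self.early_stop_threshold < 0:
            raise ValueError("early_stop_threshold must be < 0")
        if self.execution not in ("sequential", "batched"):
            raise ValueError("execution must be 'sequential' or 'batched'")


@dataclass
class IBSResult:
    """Outcome of a dataset-level estimation run.

    ``loglik`` is the dataset total averaged over repeats (nats);
    ``variance`` the matching repeat-combined variance; ``sample_counts`` an
    ``R x N`` array of draws per (repeat, trial); entries with
    ``completed = False`` are lower bounds on the true count (capped trials or
    work abandoned at early stopping).
    """

    loglik: float
    variance: float
    sample_counts: np.ndarray
    completed: np.ndarray
    total_samples: int
    early_stopped: bool
    capped_trials: int

    @property
    def variance_reliable(self) -> bool:
        return not self.early_stopped and self.capped_trials == 0


def early_stop_check(
    partial_total: float, trial_partial: float, threshold: float
) -> bool:
    """True when the running estimate has fallen below the stopping floor.

    ``partial_total`` is the sum of completed-trial estimates for the current
    repeat and ``trial_partial`` the current trial's partial estimate
    ``-sum_{j<K_so_far} 1/j``.  Since per-trial estimates are non-positive,
    once this returns True it stays True for any continuation of the trial.
    """
    if not threshold < 0:
        raise ValueError("threshold must be < 0")
    return partial_total + trial_partial < threshold


def _call_sim(sim, stimulus, params, rng, history):
    if getattr(sim, "uses_history", False):
        return sim(stimulus, params, rng, history=history)
    return sim(stimulus, params, rng)


def _finish_result(
    K: np.ndarray,
    completed: np.ndarray,
    attempted: np.ndarray,
    total: int,
    early: bool,
    capped: int,
    threshold: Optional[float],
) -> IBSResult:
    repeats = K.shape[0]
    if early:
        loglik = float(threshold)
    else:
        loglik = float(ibs_point_estimate(np.where(K >= 1, K, 1)).sum() / repeats)
    mask = np.where(K >= 1, K, 1)
    variance = float(
        (ibs_variance_estimate(mask) * attempted).sum() / repeats**2
    )
    return IBSResult(
        loglik=loglik,
        variance=variance,
        sample_counts=K,
        completed=completed,
        total_samples=int(total),
        early_stopped=early,
        capped_trials=int(capped),
    )


def ibs_loglik(
    data: TrialData,
    sim: Callable,
    params,
    cfg: IBSConfig = IBSConfig(),
) -> IBSResult:
    """Estimate the dataset log-likelihood by inverse binomial sampling.

    For each repeat and trial, simulator responses are drawn from the trial's
    own substream until the first exact match with the observed response.
    With ``R`` repeats the result averages the per-repeat dataset estimates;
    its expectation is the true total log-likelihood whenever neither early
    stopping nor capping triggered.

    A trial that reaches ``max_samples_per_trial`` without a match is marked
    incomplete and its current count is used as a lower bound on ``K`` (the
    resulting estimate is an upper bound on the trial's contribution).  If a
    repeat's running estimate falls below ``early_stop_threshold`` the whole
    run aborts and returns the threshold itself, flagged, so optimizers see a
    constant floor rather than a truncation-biased partial sum.
    """
    if cfg.execution == "batched":
        return _ibs_loglik_batched_pairs(data, sim, params, cfg)

    N = data.n_trials
    R = cfg.repeats
    targets = [canonical_response(r) for r in data.responses]
    K = np.zeros((R, N), dtype=np.int64)
    completed = np.zeros((R, N), dtype=bool)
    attempted = np.zeros((R, N), dtype=bool)
    total = 0
    capped = 0
    early = False

    for r in range(R):
        running = 0.0
        for i in range(N):
            rng = substream(cfg.seed, r, i)
            history = _trial_history(data, i, sim)
            k = 0
            while True:
                resp = _call_sim(sim, data.stimuli[i], params, rng, history)
                total += 1
                k += 1
                if canonical_response(resp) == targets[i]:
                    completed[r, i] = True
                    break
                if (
                    cfg.max_samples_per_trial is not None
                    and k >= cfg.max_samples_per_trial
                ):
                    capped += 1
                    break
                if cfg.early_stop_threshold is not None and early_stop_check(
                    running, ibs_point_estimate(k), cfg.early_stop_threshold
                ):
                    early = True
                    break
            K[r, i] = k
            attempted[r, i] = True
            if early:
                break
            running += ibs_point_estimate(k)
        if early:
            break

    return _finish_result(
        K, completed, attempted, total, early, capped, cfg.early_stop_threshold
    )


def _trial_history(data: TrialData, i: int, sim) -> Optional[List[Tuple[Any, Any]]]:
    if not getattr(sim, "uses_history", False):
        return None
    # History conditions on the *observed* past, matching the likelihood
    # factorisation over the data's own response sequence.
    return [(data.stimuli[j], data.responses[j]) for j in range(i)]


def batched_ibs_pass(
    active: Sequence[Tuple[int, int]],
    sim: Callable,
    params,
    data: TrialData,
    rngs: Dict[Tuple[int, int], np.random.Generator],
    targets: Sequence[Any],
    K: np.ndarray,
    completed: np.ndarray,
) -> List[Tuple[int, int]]:
    """One round of simulator calls for all not-yet-matched (repeat, trial)
    pairs.  Each pair draws exactly one sample from its own substream, so the
    marginal (indeed joint) distribution of every ``K`` is identical to
    sequential mode.  Returns the still-active pairs.
    """
    still_active: List[Tuple[int, int]] = []
    for (r, i) in active:
        resp = _call_sim(sim, data.stimuli[i], params, rngs[(r, i)], None)
        K[r, i] += 1
        if canonical_response(resp) == targets[i]:
            completed[r, i] = True
        else:
            still_active.append((r, i))
    return still_active


def _ibs_loglik_batched_pairs(data, sim, params, cfg) -> IBSResult:
    if getattr(sim, "uses_history", False):
        raise ValueError("batched execution does not support history-conditional simulators")
    N = data.n_trials
    R = cfg.repeats
    targets = [canonical_response(r) for r in data.responses]
    K = np.zeros((R, N), dtype=np.int64)
    completed = np.zeros((R, N), dtype=bool)
    attempted = np.ones((R, N), dtype=bool)
    rngs = {(r, i): substream(cfg.seed, r, i) for r in range(R) for i in range(N)}
    active = [(r, i) for r in range(R) for i in range(N)]
    capped_pairs: set = set()
    early = False

    while active:
        if cfg.batch_size is not None and len(active) > cfg.batch_size:
            # chunked passes; per-pair substreams make the split immaterial
            still: List[Tuple[int, int]] = []
            for lo in range(0, len(active), cfg.batch_size):
                still.extend(
                    batched_ibs_pass(
                        active[lo : lo + cfg.batch_size],
                        sim, params, data, rngs, targets, K, completed,
                    )
                )
            active = still
        else:
            active = batched_ibs_pass(
                active, sim, params, data, rngs, targets, K, completed
            )
        if cfg.max_samples_per_trial is not None:
            still = []
            for pair in active:
                if K[pair] >= cfg.max_samples_per_trial:
                    capped_pairs.add(pair)
                else:
                    still.append(pair)
            active = still
        if cfg.early_stop_threshold is not None and active:
            # Evaluate the floor on each repeat's current (partial) estimate.
            ks = np.where(K >= 1, K, 1)
            per_repeat = ibs_point_estimate(ks).sum(axis=1)
            if np.any(per_repeat < cfg.early_stop_threshold):
                early = True
                break

    total = int(K.sum())
    return _finish_result(
        K, completed, attempted, total, early, len(capped_pairs),
        cfg.early_stop_threshold,
    )


def fixed_loglik(
    data: TrialData,
    sim: Callable,
    params,
    n_samples: int,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Fixed-sampling dataset estimate: exactly ``M`` draws per trial.

    Returns ``(sum_i log((m_i + 1)/(M + 1)), hits)`` where ``hits[i]`` counts
    matches on trial ``i``.  Total simulator calls are exactly ``N * M``.
    """
    M = int(n_samples)
    if M < 1:
        raise ValueError("n_samples must be >= 1")
    N = data.n_trials
    targets = [canonical_response(r) for r in data.responses]
    hits = np.zeros(N, dtype=np.int64)
    for i in range(N):
        rng = substream(seed, 0, i)
        history = _trial_history(data, i, sim)
        for _ in range(M):
            resp = _call_sim(sim, data.stimuli[i], params, rng, history)
            if canonical_response(resp) == targets[i]:
                hits[i] += 1
    loglik = float(np.log((hits + 1.0) / (M + 1.0)).sum())
    return loglik, hits


# ---------------------------------------------------------------------------
# Vectorised fast paths for simulators with a batch interface.
# ---------------------------------------------------------------------------

def ibs_loglik_batch(
    data: TrialData,
    sim_batch: Callable,
    params,
    cfg: IBSConfig = IBSConfig(),
) -> IBSResult:
    """Vectorised IBS for batch simulators ``sim_batch(stimuli, params, rng)``.

    Uses one stream per repeat and one simulator call per round over all
    still-unmatched trials; distributionally equivalent to :func:`ibs_loglik`
    but not bit-identical (different stream discipline).  Responses must be
    numeric arrays supporting vectorised equality.
    """
    N = data.n_trials
    R = cfg.repeats
    stimuli = np.asarray(data.stimuli)
    responses = np.asarray(data.responses)
    K = np.zeros((R, N), dtype=np.int64)
    completed = np.zeros((R, N), dtype=bool)
    attempted = np.ones((R, N), dtype=bool)
    total = 0
    capped = 0
    early = False

    for r in range(R):
        rng = substream(cfg.seed, r)
        active = np.arange(N)
        misses = np.zeros(N, dtype=np.int64)  # drawn-and-missed so far
        done_sum = 0.0
        block = 1  # draws per active trial per round; grows geometrically so
        # low-probability stragglers do not force thousands of tiny rounds
        while active.size:
            if stimuli.ndim == 1:
                stim_rep = np.repeat(stimuli[active], block)
            else:
                stim_rep = np.repeat(stimuli[active], block, axis=0)
            resp = np.asarray(sim_batch(stim_rep, params, rng)).reshape(
                active.size, block
            )
            hits = resp == responses[active][:, None]
            any_hit = hits.any(axis=1)
            first = hits.argmax(axis=1)
            won = active[any_hit]
            K[r, won] = misses[won] + first[any_hit] + 1
            completed[r, won] = True
            total += int((first[any_hit] + 1).sum())
            if any_hit.any():
                done_sum += float(ibs_point_estimate(K[r, won]).sum())
            lost = active[~any_hit]
            misses[lost] += block
            total += int(block * lost.size)
            active = lost
            if cfg.max_samples_per_trial is not None and active.size:
                over = misses[active] >= cfg.max_samples_per_trial
                if over.any():
                    hit_cap = active[over]
                    K[r, hit_cap] = cfg.max_samples_per_trial
                    capped += int(over.sum())
                    active = active[~over]
            if cfg.early_stop_threshold is not None and active.size:
                partial = float(ibs_point_estimate(misses[active] + 1).sum())
                if done_sum + partial < cfg.early_stop_threshold:
                    K[r, active] = np.maximum(misses[active], 1)
                    early = True
                    break
            block = min(block * 2, 1024)
        if early:
            break

    Kc = np.where(K >= 1, K, 1)
    if early:
        loglik = float(cfg.early_stop_threshold)
    else:
        loglik = float(ibs_point_estimate(Kc).sum() / R)
    variance = float(ibs_variance_estimate(Kc).sum() / R**2)
    return IBSResult(
        loglik=loglik,
        variance=variance,
        sample_counts=K,
        completed=completed,
        total_samples=int(total),
        early_stopped=early,
        capped_trials=capped,
    )


def fixed_loglik_batch(
    data: TrialData,
    sim_batch: Callable,
    params,
    n_samples: int,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Vectorised fixed-sampling estimate for batch simulators."""
    M = int(n_samples)
    if M < 1:
        raise ValueError("n_samples must be >= 1")
    stimuli = np.asarray(data.stimuli)
    responses = np.asarray(data.responses)
    rng = substream(seed, 0)
    hits = np.zeros(data.n_trials, dtype=np.int64)
    for _ in range(M):
        resp = np.asarray(sim_batch(stimuli, params, rng))
        hits += resp == responses
    loglik = float(np.log((hits + 1.0) / (M + 1.0)).sum())
    return loglik, hits
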