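"""Closed-form estimator mathematics for sampling-based log-likelihood estimation.

This module collects the pure mathematical building blocks used everywhere
else in the package:

* the inverse-binomial-sampling (IBS) point estimator ``psi(1) - psi(K)`` and
  its per-draw variance estimator ``psi_1(1) - psi_1(K)``;
* the exact variance of the IBS estimator, ``Li2(1 - p)`` (Spence's function);
* fixed-sampling comparators (the regularised ``log((m+1)/(M+1))`` estimator
  and the naive ``log(m/M)`` estimator, the latter kept only as a documented
  reference because of its infinite bias at ``m = 0``);
* exact enumeration oracles for the bias and variance of fixed sampling under
  a binomial hit count; and
* the algebra for combining and iteratively refining independent repeats.

All logarithmic quantities are expressed in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import special, stats

__all__ = [
    "PI2_OVER_6",
    "RepeatedEstimate",
    "combine_repeats",
    "fixed_bias_exact",
    "fixed_point_estimate",
    "fixed_variance_exact",
    "ibs_expected_samples",
    "ibs_point_estimate",
    "ibs_variance_estimate",
    "ibs_variance_true",
    "iterative_update",
    "naive_point_estimate",
]

#: Upper bound of the IBS estimator variance, ``sum_{j>=1} 1/j**2``.
PI2_OVER_6 = float(np.pi**2 / 6.0)


def _validate_count(k) -> np.ndarray:
    """Validate a (possibly vector) sample count: integer-valued and >= 1."""
    arr = np.asarray(k)
    if arr.size == 0:
        raise ValueError("sample count must be non-empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.issubdtype(arr.dtype, np.number) or not np.all(np.mod(arr, 1) == 0):
            raise ValueError(f"sample count must be integer-valued, got {k!r}")
        arr = arr.astype(np.int64)
    if np.any(arr < 1):
        raise ValueError("sample count must be >= 1")
    return arr


def _validate_prob(p, *, allow_one: bool = True) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    hi_ok = arr <= 1.0 if allow_one else arr < 1.0
    if np.any(arr <= 0.0) or not np.all(hi_ok):
        raise ValueError(f"probability out of range (0, 1]: {p!r}")
    return arr


def _validate_summary(hits, draws) -> Tuple[np.ndarray, np.ndarray]:
    m = np.asarray(hits)
    M = np.asarray(draws)
    if np.any(np.mod(m, 1) != 0) or np.any(np.mod(M, 1) != 0):
        raise ValueError("hit and draw counts must be integers")
    m = m.astype(np.int64)
    M = M.astype(np.int64)
    if np.any(M < 1):
        raise ValueError("number of draws M must be >= 1")
    if np.any(m < 0) or np.any(m > M):
        raise ValueError("hit count m must satisfy 0 <= m <= M")
    return m, M


def _maybe_scalar(out: np.ndarray, template) -> float | np.ndarray:
    if np.isscalar(template) or np.asarray(template).shape == ():
        return float(out)
    return out


def ibs_point_estimate(k):
    """IBS point estimate of ``log p`` after ``k`` draws up to the first hit.

    Equals ``-sum_{j=1}^{k-1} 1/j`` which is ``digamma(1) - digamma(k)``;
    exactly 0 for ``k = 1``.  Accepts scalars or arrays.
    """
    arr = _validate_count(k)
    out = special.digamma(1.0) - special.digamma(arr.astype(float))
    return _maybe_scalar(out, k)


def ibs_variance_estimate(k):
    """Per-estimate variance ``trigamma(1) - trigamma(k) = sum_{j<k} 1/j**2``.

    Zero at ``k = 1``, strictly increasing in ``k``, bounded by ``pi**2/6``.
    """
    arr = _validate_count(k)
    out = special.polygamma(1, 1.0) - special.polygamma(1, arr.astype(float))
    return _maybe_scalar(out, k)


def ibs_variance_true(p):
    """Exact variance of the IBS estimator at true hit probability ``p``.

    Equals the dilogarithm ``Li2(1 - p)``; decreasing in ``p``, tends to
    ``pi**2/6`` as ``p -> 0`` and equals 0 at ``p = 1``.
    """
    arr = _validate_prob(p)
    # scipy's spence(x) is Li2(1 - x) in the series convention used here.
    out = special.spence(arr)
    return _maybe_scalar(out, p)


def ibs_expected_samples(p):
    """Expected number of simulator draws per trial, ``1/p``."""
    arr = _validate_prob(p)
    return _maybe_scalar(1.0 / arr, p)


def fixed_point_estimate(hits, draws):
    """Regularised fixed-sampling estimate ``log((m + 1) / (M + 1))``.

    Finite for every admissible summary, including ``m = 0``.
    """
    m, M = _validate_summary(hits, draws)
    out = np.log((m + 1.0) / (M + 1.0))
    return _maybe_scalar(out, hits)


def naive_point_estimate(hits, draws):
    """Naive fixed-sampling estimate ``log(m / M)``.

    Returns ``-inf`` when ``m = 0`` (never silently clipped); kept as a
    documented reference only — it has infinite bias and dataset-level code
    must not use it.
    """
    m, M = _validate_summary(hits, draws)
    with np.errstate(divide="ignore"):
        out = np.log(m / M)
    return _maybe_scalar(out, hits)


def fixed_bias_exact(p: float, draws: int) -> float:
    """Exact bias of the regularised fixed-sampling estimator.

    Enumerates ``E[log((m+1)/(M+1))] - log p`` under ``m ~ Binomial(M, p)``
    with log-space binomial weights (stable for ``M`` up to at least 1e4).
    """
    p_arr = _validate_prob(p)
    if p_arr.shape != ():
        raise ValueError("fixed_bias_exact expects scalar p")
    M = int(draws)
    if M < 1:
        raise ValueError("number of draws M must be >= 1")
    m = np.arange(M + 1)
    w = np.exp(stats.binom.logpmf(m, M, float(p_arr)))
    est = np.log((m + 1.0) / (M + 1.0))
    return float(np.sum(w * est) - math.log(float(p_arr)))


def fixed_variance_exact(p: float, draws: int) -> float:
    """Exact variance of the regularised fixed-sampling estimator."""
    p_arr = _validate_prob(p)
    if p_arr.shape != ():
        raise ValueError("fixed_variance_exact expects scalar p")
    M = int(draws)
    if M < 1:
        raise ValueError("number of draws M must be >= 1")
    m = np.arange(M + 1)
    w = np.exp(stats.binom.logpmf(m, M, float(p_arr)))
    est = np.log((m + 1.0) / (M + 1.0))
    mean = np.sum(w * est)
    return float(np.sum(w * (est - mean) ** 2))


@dataclass(frozen=True)
class RepeatedEstimate:
    """Running average of independent repeats of an unbiased estimate.

    ``variance`` is the variance of the *average*, i.e. it shrinks as 1/R for
    identically distributed repeats.  Only ``(value, variance, repeats)`` need
    to be stored to refine the estimate further.
    """

    value: float
    variance: float
    repeats: int

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


def combine_repeats(estimates: Sequence[Tuple[float, float]]) -> RepeatedEstimate:
    """Average independent ``(value, variance)`` repeats.

    ``value`` is the mean of the values and ``variance`` the sum of the
    per-repeat variances divided by ``R**2``.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot combine an empty sequence of estimates")
    values = np.array([e[0] for e in estimates], dtype=float)
    variances = np.array([e[1] for e in estimates], dtype=float)
    if np.any(variances < 0):
        raise ValueError("variances must be >= 0")
    r = len(estimates)
    return RepeatedEstimate(
        value=float(values.mean()),
        variance=float(variances.sum() / r**2),
        repeats=r,
    )


def iterative_update(
    current: RepeatedEstimate, new: Tuple[float, float]
) -> RepeatedEstimate:
    """Fold one additional repeat into a running :class:`RepeatedEstimate`."""
    value, variance = float(new[0]), float(new[1])
    if variance < 0:
        raise ValueError("variance must be >= 0")
    r = current.repeats
    return RepeatedEstimate(
        value=(r * current.value + value) / (r + 1),
        variance=(r**2 * current.variance + variance) / (r + 1) ** 2,
        repeats=r + 1,
    )
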