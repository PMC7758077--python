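"""Maximum-likelihood fitting with noisy sampling-based objectives.

The estimators produce stochastic objectives, so fitting runs in two stages:

1. a global derivative-free search (differential evolution) over the model's
   bounds, evaluated with *common random numbers* — a seed held fixed for
   the whole stage, which makes the objective deterministic in the
   parameters and correlates the noise between nearby candidates;
2. a local trust-region polish that regresses a quadratic surrogate on ~100
   independently-seeded evaluations per stage and moves to the surrogate
   optimum, shrinking the region and (for the inverse-sampling arm) raising
   the repeat count each stage.  The regression averages the evaluation
   noise, the same mechanism that lets Gaussian-process optimizers cope with
   stochastic objectives.

After optimization the log-likelihood at the solution is re-estimated with a
larger repeat count and a fresh stream, because the optimizer's incumbent
value is biased upward by selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from ..engine import (
    IBSConfig,
    TrialData,
    derive_seed,
    fixed_loglik_batch,
    ibs_loglik_batch,
    substream,
)
from ..models.registry import ModelSpec

__all__ = ["Arm", "FitResult", "OptimizerConfig", "loglik_loss", "mle_fit"]


@dataclass(frozen=True)
class Arm:
    """One estimator configuration under comparison.

    kind: 'ibs' (with ``repeats``), 'fixed' (with ``n_samples``) or 'exact'.
    """

    kind: str
    repeats: int = 1
    n_samples: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("ibs", "fixed", "exact"):
            raise ValueError("arm kind must be 'ibs', 'fixed' or 'exact'")

    @property
    def label(self) -> str:
        if self.kind == "ibs":
            return f"ibs_R{self.repeats}"
        if self.kind == "fixed":
            return f"fixed_M{self.n_samples}"
        return "exact"


@dataclass(frozen=True)
class OptimizerConfig:
    de_maxiter: int = 20
    de_popsize: int = 8
    polish_points: int = 100  # evaluations per surrogate stage
    polish_radius_fracs: Sequence[float] = (0.2, 0.1, 0.05)
    polish_repeat_factors: Sequence[int] = (1, 2, 4)
    n_starts: int = 10  # multistart count for the exact-likelihood arm
    refit_repeat_factor: int = 10  # repeats multiplier for the final re-estimate
    early_stop_floor_factor: float = 3.0  # floor = factor * N * log(1/n_responses)


@dataclass
class FitResult:
    theta: Dict[str, float]
    loglik: float
    variance: float
    arm: str
    n_evals: int
    samples_used: int
    failed: bool = False
    message: str = ""

    def theta_vector(self, model: ModelSpec) -> np.ndarray:
        return np.array([self.theta[k] for k in model.param_names])


class _Counter:
    def __init__(self) -> None:
        self.evals = 0
        self.samples = 0


def _make_eval(
    data: TrialData,
    model: ModelSpec,
    arm: Arm,
    opt_cfg: OptimizerConfig,
) -> Tuple[Callable[[np.ndarray, int, int], float], _Counter]:
    """Negative log-likelihood evaluator ``f(vec, repeat_factor, seed)``.

    ``repeat_factor`` multiplies the inverse-sampling repeats (the fixed arm
    keeps its own ``M`` in every stage: its bias is part of the arm under
    study, only the noise may be averaged away).
    """
    counter = _Counter()
    floor = opt_cfg.early_stop_floor_factor * data.n_trials * np.log(
        1.0 / model.response_space_size
    )

    if arm.kind == "exact":
        if model.exact_loglik is None:
            raise ValueError(f"model '{model.name}' has no exact likelihood")

        def evaluate(vec, repeat_factor=1, seed=0):
            counter.evals += 1
            return -model.exact_loglik(data, model.params_from_vector(vec))

        return evaluate, counter

    if arm.kind == "ibs":

        def evaluate(vec, repeat_factor=1, seed=0):
            counter.evals += 1
            cfg = IBSConfig(
                repeats=arm.repeats * repeat_factor,
                seed=seed,
                early_stop_threshold=float(floor),
                max_samples_per_trial=100_000,
            )
            res = ibs_loglik_batch(
                data, model.simulate_batch, model.params_from_vector(vec), cfg
            )
            counter.samples += res.total_samples
            return -res.loglik

        return evaluate, counter

    def evaluate(vec, repeat_factor=1, seed=0):
        counter.evals += 1
        ll, _ = fixed_loglik_batch(
            data, model.simulate_batch, model.params_from_vector(vec),
            arm.n_samples, seed=seed,
        )
        counter.samples += data.n_trials * arm.n_samples
        return -ll

    return evaluate, counter


def _quad_design(X: np.ndarray) -> np.ndarray:
    n, d = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, i] for i in range(d))
    cols.extend(X[:, i] * X[:, j] for i in range(d) for j in range(i, d))
    return np.column_stack(cols)


def _surrogate_polish(
    evaluate: Callable[[np.ndarray, int, int], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    opt_cfg: OptimizerConfig,
    seed: int,
) -> np.ndarray:
    """Quadratic-surrogate trust-region descent on a noisy objective."""
    d = len(x0)
    span = bounds[:, 1] - bounds[:, 0]
    x = np.clip(x0, bounds[:, 0], bounds[:, 1])
    rng = substream(seed, 77)
    for stage, (rad_frac, factor) in enumerate(
        zip(opt_cfg.polish_radius_fracs, opt_cfg.polish_repeat_factors)
    ):
        radius = rad_frac * span
        lo = np.maximum(bounds[:, 0], x - radius)
        hi = np.minimum(bounds[:, 1], x + radius)
        pts = lo + rng.random((opt_cfg.polish_points, d)) * (hi - lo)
        y = np.array(
            [
                evaluate(p, factor, derive_seed(seed, 78, stage, j))
                for j, p in enumerate(pts)
            ]
        )
        Z = (pts - x) / radius
        coef, *_ = np.linalg.lstsq(_quad_design(Z), y, rcond=None)

        def qfun(z: np.ndarray) -> float:
            return float((_quad_design(z[None, :]) @ coef)[0])

        zb = [
            (
                max(-1.0, (lo[i] - x[i]) / radius[i]),
                min(1.0, (hi[i] - x[i]) / radius[i]),
            )
            for i in range(d)
        ]
        res = optimize.minimize(qfun, np.zeros(d), method="L-BFGS-B", bounds=zb)
        x = x + res.x * radius
    return x


def _fit_exact_multistart(
    data: TrialData,
    model: ModelSpec,
    opt_cfg: OptimizerConfig,
    seed: int,
) -> Tuple[np.ndarray, float, int]:
    """Best of ``n_starts`` bounded local optimizations of the exact loglik."""
    evaluate, counter = _make_eval(data, model, Arm("exact"), opt_cfg)
    objective = lambda v: evaluate(v)  # noqa: E731
    bounds = model.bounds_array()
    rng = substream(seed, 17)
    best_x, best_f = None, np.inf
    for _ in range(opt_cfg.n_starts):
        x0 = bounds[:, 0] + rng.random(bounds.shape[0]) * (bounds[:, 1] - bounds[:, 0])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_x, best_f = np.asarray(res.x), float(res.fun)
    return best_x, best_f, counter.evals


def mle_fit(
    data: TrialData,
    model: ModelSpec,
    arm: Arm,
    opt_cfg: Optional[OptimizerConfig] = None,
    seed: int = 0,
) -> FitResult:
    """Maximize an arm's log-likelihood estimator over the model's bounds.

    For noisy arms the returned ``loglik`` is an unbiased re-estimate at the
    solution using ``refit_repeat_factor`` times the fitting repeats and a
    fresh random stream (the fixed arm re-estimates with its own, biased by
    construction, estimator).  Optimizer failures are flagged on the result,
    not raised.
    """
    opt_cfg = opt_cfg or OptimizerConfig()
    try:
        bounds = model.bounds_array()
        if arm.kind == "exact":
            x, f, evals = _fit_exact_multistart(data, model, opt_cfg, seed)
            theta = dict(zip(model.param_names, map(float, x)))
            return FitResult(
                theta=theta, loglik=-f, variance=0.0, arm=arm.label,
                n_evals=evals, samples_used=0,
            )

        evaluate, counter = _make_eval(data, model, arm, opt_cfg)
        crn_seed = derive_seed(seed, 23)
        de = optimize.differential_evolution(
            lambda v: evaluate(v, 1, crn_seed),
            bounds=bounds,
            seed=derive_seed(seed, 29) % (2**32),  # scipy wants a 32-bit seed
            maxiter=opt_cfg.de_maxiter,
            popsize=opt_cfg.de_popsize,
            init="sobol",
            polish=False,
            tol=1e-8,
        )
        x = _surrogate_polish(evaluate, de.x, bounds, opt_cfg, seed)
        theta = dict(zip(model.param_names, map(float, x)))
        params = model.params_from_vector(x)

        if arm.kind == "ibs":
            refit_cfg = IBSConfig(
                repeats=arm.repeats * opt_cfg.refit_repeat_factor,
                seed=derive_seed(seed, 31),
                max_samples_per_trial=100_000,
            )
            res = ibs_loglik_batch(data, model.simulate_batch, params, refit_cfg)
            counter.samples += res.total_samples
            loglik, variance = res.loglik, res.variance
        else:
            loglik, _ = fixed_loglik_batch(
                data, model.simulate_batch, params, arm.n_samples,
                seed=derive_seed(seed, 31),
            )
            counter.samples += data.n_trials * arm.n_samples
            variance = float("nan")

        return FitResult(
            theta=theta, loglik=float(loglik), variance=float(variance),
            arm=arm.label, n_evals=counter.evals, samples_used=counter.samples,
        )
    except Exception as exc:  # noqa: BLE001 - flagged record, not an exception
        return FitResult(
            theta={k: float("nan") for k in model.param_names},
            loglik=float("nan"), variance=float("nan"), arm=arm.label,
            n_evals=0, samples_used=0, failed=True, message=str(exc),
        )


def loglik_loss(
    data: TrialData,
    model: ModelSpec,
    theta_hat: Dict[str, float],
    *,
    n_starts: int = 10,
    seed: int = 0,
) -> float:
    """Exact log-likelihood gap between the multistart reference optimum and
    a candidate solution, clipped at zero (the candidate occasionally beats
    the stochastic reference)."""
    if model.exact_loglik is None:
        raise ValueError(f"model '{model.name}' has no exact likelihood")
    opt_cfg = OptimizerConfig(n_starts=max(10, n_starts))
    _, f_star, _ = _fit_exact_multistart(data, model, opt_cfg, seed)
    l_star = -f_star
    l_hat = model.exact_loglik(data, model.params_from_dict(theta_hat))
    return max(0.0, float(l_star - l_hat))
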