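"""Change localization: an ideal-observer model on circular stimuli.

A trial shows two displays of ``n_patches`` oriented patches; exactly one
patch (the change patch ``c``) rotates between displays by an angle drawn
from a von Mises distribution.  The observer measures every orientation with
von Mises noise of concentration ``kappa`` and reports the patch whose two
measurements differ most in absolute circular distance; with probability
``gamma`` it guesses uniformly.

Noise is parametrised as ``eta = log(sigma)`` with sigma in degrees and
``kappa = (180 / (pi * sigma))**2`` defined on radians, so printed sigma
values match the degree scale.

The trial likelihood reduces to a one-dimensional integral over the change
patch's measured difference ``d``:

    p0 = Pr(correct | no lapse)
       = Integral f_kappa(d - Delta) * G_kappa(|d|)**(n-1) dd

where ``f_kappa`` is the density of the difference of two independent
von Mises(kappa) measurements and ``G_kappa`` the CDF of the absolute
difference for an unchanged patch.  The response probability is then
``(1-gamma) * p0 + gamma/n`` for the change patch and
``(1-gamma) * (1-p0)/(n-1) + gamma/n`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, special

from ..engine import TrialData

__all__ = [
    "ChangeLocParams",
    "ChangeLocTaskConfig",
    "changeloc_exact_loglik",
    "changeloc_generate_dataset",
    "changeloc_likelihood",
    "changeloc_p_correct",
    "changeloc_p_correct_quad",
    "changeloc_simulate",
    "changeloc_simulate_batch",
    "kappa_from_sigma_deg",
    "recover_change_info",
    "sigma_deg_from_kappa",
    "vm_difference_density",
]

_CDF_GRID_SIZE = 2049  # knots of the precomputed null |difference| CDF


def kappa_from_sigma_deg(sigma_deg: float) -> float:
    """Von Mises concentration (on radians) for a noise sigma in degrees."""
    if sigma_deg <= 0:
        raise ValueError("sigma must be > 0")
    return float((180.0 / (np.pi * sigma_deg)) ** 2)


def sigma_deg_from_kappa(kappa: float) -> float:
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float(180.0 / (np.pi * np.sqrt(kappa)))


@dataclass(frozen=True)
class ChangeLocParams:
    """Observer parameters ``(eta, gamma)`` with ``eta = log(sigma_deg)``."""

    eta: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def sigma_deg(self) -> float:
        return float(np.exp(self.eta))

    @property
    def kappa(self) -> float:
        return kappa_from_sigma_deg(self.sigma_deg)


@dataclass(frozen=True)
class ChangeLocTaskConfig:
    n_trials: int = 400
    n_patches: int = 6
    kappa_s: float = 1.0  # concentration of the change-magnitude distribution

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_patches < 2:
            raise ValueError("n_patches must be >= 2")
        if self.kappa_s <= 0:
            raise ValueError("kappa_s must be > 0")


def _wrap_pi(x):
    """Wrap angles (radians) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), 2.0 * np.pi)


def _wrap_180(x):
    """Wrap angles (degrees) to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(x, dtype=float), 360.0)


def vm_difference_density(delta, kappa: float):
    """Density of ``X - Y`` for independent ``X, Y ~ vonMises(0, kappa)``.

    ``f(d) = I0(2 kappa cos(d/2)) / (2 pi I0(kappa)^2)``, evaluated with
    exponentially scaled Bessel functions so it is overflow-safe for any
    ``kappa >= 0``.  ``delta`` in radians; integrates to 1 over (-pi, pi].
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    d = _wrap_pi(delta)
    a = 2.0 * kappa * np.cos(d / 2.0)  # >= 0 since |d/2| <= pi/2
    out = (
        special.ive(0, a)
        / (2.0 * np.pi * special.ive(0, kappa) ** 2)
        * np.exp(a - 2.0 * kappa)
    )
    return float(out) if np.asarray(out).shape == () else out


@lru_cache(maxsize=64)
def _null_absdiff_cdf(kappa: float):
    """CDF grid of the absolute measured difference for an unchanged patch."""
    t = np.linspace(0.0, np.pi, _CDF_GRID_SIZE)
    f = vm_difference_density(t, kappa)
    G = 2.0 * integrate.cumulative_trapezoid(f, t, initial=0.0)
    G /= G[-1]  # enforce exact normalisation of the CDF
    return t, G


@lru_cache(maxsize=64)
def _quadrature_nodes(kappa: float):
    """Quadrature nodes/weights for the difference-density integral.

    The integrand is peaked at the origin with scale ~ sqrt(2/kappa); for
    large kappa a composite rule concentrates nodes in the peak.
    """
    scale = np.sqrt(2.0 / max(kappa, 1e-12))
    if scale * 6.0 >= np.pi:
        x, w = np.polynomial.legendre.leggauss(200)
        nodes = x * np.pi
        weights = w * np.pi
    else:
        c = min(10.0 * scale, np.pi / 2.0)
        xc, wc = np.polynomial.legendre.leggauss(160)
        xo, wo = np.polynomial.legendre.leggauss(64)
        mid_n = xc * c
        mid_w = wc * c
        hi_n = (np.pi + c) / 2.0 + xo * (np.pi - c) / 2.0
        hi_w = wo * (np.pi - c) / 2.0
        nodes = np.concatenate([-hi_n[::-1], mid_n, hi_n])
        weights = np.concatenate([hi_w[::-1], mid_w, hi_w])
    return nodes, weights


def changeloc_p_correct(
    delta_deg, p: ChangeLocParams, n_patches: int = 6
) -> np.ndarray | float:
    """Pr(correct | no lapse) as a function of the change magnitude.

    Vectorised over ``delta_deg`` (degrees); quadrature is shared across all
    values because the integrand peak does not move with Delta after the
    substitution ``u = d - Delta``.
    """
    kappa = p.kappa
    deltas = np.deg2rad(np.atleast_1d(np.asarray(delta_deg, dtype=float)))
    nodes, weights = _quadrature_nodes(kappa)
    f = vm_difference_density(nodes, kappa)
    t, G = _null_absdiff_cdf(kappa)
    x = np.abs(_wrap_pi(nodes[None, :] + deltas[:, None]))
    Gx = np.interp(x, t, G)
    p0 = (Gx ** (n_patches - 1)) @ (weights * f)
    p0 = np.clip(p0, 0.0, 1.0)
    if np.asarray(delta_deg).shape == ():
        return float(p0[0])
    return p0


def changeloc_p_correct_quad(
    delta_deg: float, p: ChangeLocParams, n_patches: int = 6, epsabs: float = 1e-8
) -> float:
    """Adaptive-quadrature reference for :func:`changeloc_p_correct`."""
    kappa = p.kappa
    delta = float(np.deg2rad(delta_deg))
    t, G = _null_absdiff_cdf(kappa)

    def integrand(u):
        x = abs(float(_wrap_pi(u + delta)))
        return vm_difference_density(u, kappa) * np.interp(x, t, G) ** (n_patches - 1)

    # |wrap(u + delta)| has kinks where u + delta crosses 0 or +-pi.
    kinks = sorted(
        k for k in (-delta, float(_wrap_pi(np.pi - delta)), 0.0)
        if -np.pi < k < np.pi
    )
    val, err = integrate.quad(
        integrand, -np.pi, np.pi, points=kinks, limit=300, epsabs=epsabs
    )
    if not np.isfinite(val) or err > max(1e-5, 100 * epsabs):
        raise ArithmeticError(
            f"quadrature did not converge (value={val}, err={err})"
        )
    return float(np.clip(val, 0.0, 1.0))


def changeloc_likelihood(
    delta_deg: float,
    response_is_change_patch: bool,
    p: ChangeLocParams,
    n_patches: int = 6,
):
    """Exact probability of a response given the change magnitude (degrees).

    Lapses are mixed in at the response stage; the probabilities over the
    ``n_patches`` possible responses sum to 1.
    """
    p0 = changeloc_p_correct(delta_deg, p, n_patches)
    if response_is_change_patch:
        return (1.0 - p.gamma) * p0 + p.gamma / n_patches
    return (1.0 - p.gamma) * (1.0 - p0) / (n_patches - 1) + p.gamma / n_patches


def changeloc_simulate(
    stimulus, p: ChangeLocParams, rng: np.random.Generator
) -> int:
    """Draw one response in ``{1..n}`` for a stimulus of ``2n`` orientations
    (degrees; first display then second display)."""
    stim = np.asarray(stimulus, dtype=float).reshape(-1)
    n = stim.size // 2
    if p.gamma > 0 and rng.random() < p.gamma:
        return int(rng.integers(1, n + 1))
    m = rng.vonmises(np.deg2rad(stim), p.kappa)
    d = _wrap_pi(m[n:] - m[:n])
    return int(np.argmax(np.abs(d))) + 1


def changeloc_simulate_batch(
    stimuli, p: ChangeLocParams, rng: np.random.Generator
) -> np.ndarray:
    stim = np.asarray(stimuli, dtype=float)
    if stim.ndim == 1:
        stim = stim[None, :]
    n = stim.shape[1] // 2
    m = rng.vonmises(np.deg2rad(stim), p.kappa)
    d = _wrap_pi(m[:, n:] - m[:, :n])
    resp = np.argmax(np.abs(d), axis=1).astype(np.int64) + 1
    lapse = rng.random(stim.shape[0]) < p.gamma
    n_lapse = int(lapse.sum())
    if n_lapse:
        resp[lapse] = rng.integers(1, n + 1, n_lapse)
    return resp


def changeloc_generate_dataset(
    p: ChangeLocParams,
    cfg: ChangeLocTaskConfig = ChangeLocTaskConfig(),
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Simulate a dataset.

    First-display orientations are uniform on [0, 360); one patch per trial
    rotates by an angle drawn (in radians) from vonMises(0, kappa_s) and
    stored in degrees.  The stimulus record concatenates both displays.
    """
    if rng is None:
        rng = np.random.default_rng()
    N, n = cfg.n_trials, cfg.n_patches
    first = rng.uniform(0.0, 360.0, size=(N, n))
    change_patch = rng.integers(0, n, size=N)
    delta_deg = np.rad2deg(rng.vonmises(0.0, cfg.kappa_s, size=N))
    second = first.copy()
    second[np.arange(N), change_patch] = np.mod(
        second[np.arange(N), change_patch] + delta_deg, 360.0
    )
    stimuli = np.hstack([first, second])
    responses = changeloc_simulate_batch(stimuli, p, rng)
    return TrialData(stimuli=stimuli, responses=responses)


def recover_change_info(data: TrialData):
    """Recover (change patch index, signed change in degrees) per trial."""
    stim = np.asarray(data.stimuli, dtype=float)
    n = stim.shape[1] // 2
    diff = _wrap_180(stim[:, n:] - stim[:, :n])
    change_patch = np.argmax(np.abs(diff), axis=1)
    delta = diff[np.arange(stim.shape[0]), change_patch]
    return change_patch, delta


def changeloc_exact_loglik(data: TrialData, p: ChangeLocParams) -> float:
    """Dataset log-likelihood via the quadrature expression."""
    stim = np.asarray(data.stimuli, dtype=float)
    n = stim.shape[1] // 2
    change_patch, delta = recover_change_info(data)
    p0 = changeloc_p_correct(delta, p, n_patches=n)
    resp = np.asarray(data.responses, dtype=np.int64)
    correct = (resp - 1) == change_patch
    probs = np.where(
        correct,
        (1.0 - p.gamma) * p0 + p.gamma / n,
        (1.0 - p.gamma) * (1.0 - p0) / (n - 1) + p.gamma / n,
    )
    return float(np.log(probs).sum())
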