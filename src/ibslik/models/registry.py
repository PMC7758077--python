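"""Plug-in registry of named models for the engine, CLI and experiments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Dict, Optional, Tuple

import numpy as np

from ..engine import TrialData
from . import bernoulli as _bern
from . import changeloc as _cl
from . import orientation as _ori

__all__ = ["MODELS", "ModelSpec", "get_model", "register_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Everything the rest of the package needs to know about a model."""

    name: str
    param_names: Tuple[str, ...]
    bounds: Dict[str, Tuple[float, float]]
    make_params: Callable[..., Any]
    simulate: Callable  # (stimulus, params, rng) -> response
    simulate_batch: Callable  # (stimuli, params, rng) -> responses
    generate_dataset: Callable  # (params, rng, n_trials=None) -> TrialData
    response_space_size: int
    exact_loglik: Optional[Callable] = None  # (data, params) -> float
    response_prob: Optional[Callable] = None  # (data, params) -> per-trial p_i

    def params_from_dict(self, values: Dict[str, float]):
        missing = set(self.param_names) - set(values)
        extra = set(values) - set(self.param_names)
        if missing or extra:
            raise ValueError(
                f"model '{self.name}' expects parameters {self.param_names}; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        return self.make_params(**{k: float(values[k]) for k in self.param_names})

    def params_from_vector(self, vec):
        vec = np.asarray(vec, dtype=float).reshape(-1)
        if vec.size != len(self.param_names):
            raise ValueError(
                f"expected {len(self.param_names)} parameters, got {vec.size}"
            )
        return self.make_params(**dict(zip(self.param_names, vec)))

    def bounds_array(self) -> np.ndarray:
        return np.array([self.bounds[k] for k in self.param_names], dtype=float)


def _orientation_generate(params, rng, n_trials: Optional[int] = None, **kw) -> TrialData:
    cfg_kw = dict(kw)
    if n_trials is not None:
        cfg_kw["n_trials"] = int(n_trials)
    cfg = _ori.OrientationTaskConfig(**cfg_kw)
    return _ori.orientation_generate_dataset(params, cfg, rng)


def _changeloc_generate(params, rng, n_trials: Optional[int] = None, **kw) -> TrialData:
    cfg_kw = dict(kw)
    if n_trials is not None:
        cfg_kw["n_trials"] = int(n_trials)
    cfg = _cl.ChangeLocTaskConfig(**cfg_kw)
    return _cl.changeloc_generate_dataset(params, cfg, rng)


MODELS: Dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec) -> None:
    MODELS[spec.name] = spec


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model '{name}'; registered models: {sorted(MODELS)}"
        ) from None


register_model(
    ModelSpec(
        name="orientation",
        param_names=("eta", "mu", "gamma"),
        # Default (overridable) fitting bounds.
        bounds={
            "eta": (float(np.log(0.1)), float(np.log(10.0))),
            "mu": (-2.0, 2.0),
            "gamma": (0.005, 0.5),
        },
        make_params=_ori.PsychometricParams,
        simulate=_ori.orientation_simulate,
        simulate_batch=_ori.orientation_simulate_batch,
        generate_dataset=_orientation_generate,
        response_space_size=2,
        exact_loglik=_ori.orientation_exact_loglik,
        response_prob=_ori.orientation_response_prob,
    )
)

def _bernoulli_generate(params, rng, n_trials: Optional[int] = None, **kw) -> TrialData:
    return _bern.bernoulli_generate_dataset(params, n_trials or 100, rng)


register_model(
    ModelSpec(
        name="bernoulli",
        param_names=("p",),
        bounds={"p": (0.001, 1.0)},
        make_params=_bern.BernoulliParams,
        simulate=_bern.bernoulli_simulate,
        simulate_batch=_bern.bernoulli_simulate_batch,
        generate_dataset=_bernoulli_generate,
        response_space_size=2,
        exact_loglik=_bern.bernoulli_exact_loglik,
    )
)

register_model(
    ModelSpec(
        name="changeloc",
        param_names=("eta", "gamma"),
        bounds={
            "eta": (float(np.log(1.0)), float(np.log(60.0))),
            "gamma": (0.005, 0.5),
        },
        make_params=_cl.ChangeLocParams,
        simulate=_cl.changeloc_simulate,
        simulate_batch=_cl.changeloc_simulate_batch,
        generate_dataset=_changeloc_generate,
        response_space_size=6,
        exact_loglik=_cl.changeloc_exact_loglik,
    )
)
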