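"""Shared fixtures: tiny reference simulators and datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ibslik.engine import TrialData, substream
from ibslik.models.bernoulli import BernoulliParams
from ibslik.models.orientation import (
    OrientationTaskConfig,
    PsychometricParams,
    orientation_generate_dataset,
)


def always_match_sim(stimulus, params, rng):
    """Simulator that reproduces every response (all p_i = 1)."""
    return 1


def never_match_sim(stimulus, params, rng):
    """Simulator whose output never equals the data (p_i = 0)."""
    return -1


def bernoulli_sim(stimulus, params: BernoulliParams, rng):
    return int(rng.random() < params.p)


@pytest.fixture
def ones_data():
    """Ten trials whose response is always 1."""
    return TrialData(stimuli=np.zeros(10), responses=np.ones(10, dtype=np.int64))


@pytest.fixture
def psychometric_params():
    return PsychometricParams(eta=float(np.log(2.0)), mu=0.1, gamma=0.1)


@pytest.fixture
def orientation_data(psychometric_params):
    rng = substream(1234, 0)
    return orientation_generate_dataset(
        psychometric_params, OrientationTaskConfig(n_trials=120), rng
    )
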