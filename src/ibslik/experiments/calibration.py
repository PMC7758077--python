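"""Calibration study: are the estimator and its variance report trustworthy?

For many synthetic datasets of the orientation task, run the estimator at the
true generating parameters and z-score (a) the total number of simulator
draws against its exact mean/variance, (b) the log-likelihood estimate
against the exact variance, and (c) the same estimate against the *estimated*
variance.  If the estimator is well behaved all three z samples look standard
normal, and the fraction inside ``|z| <= beta`` matches
``Phi(beta) - Phi(-beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from ..engine import IBSConfig, ibs_loglik_batch, substream
from ..estimators import ibs_variance_true
from ..models.orientation import (
    OrientationTaskConfig,
    PsychometricParams,
    orientation_generate_dataset,
    orientation_response_prob,
    orientation_simulate_batch,
)

__all__ = ["CalibrationRecord", "calibration_experiment", "zscore_dataset"]


@dataclass(frozen=True)
class CalibrationRecord:
    """z-scores for one synthetic dataset."""

    z_total_samples: float
    z_loglik_exact: float
    z_loglik_estimated: float


def zscore_dataset(p_i: np.ndarray, res, repeats: int) -> Optional[CalibrationRecord]:
    """z-scores for one dataset given exact per-trial likelihoods.

    Returns None for degenerate datasets with zero exact variance (e.g. a
    deterministic simulator with all ``p_i = 1``), which must be excluded
    with a diagnostic rather than divided by zero.
    """
    mean_k = float(np.sum(1.0 / p_i))
    var_k = float(np.sum((1.0 - p_i) / p_i**2))
    mean_l = float(np.log(p_i).sum())
    var_l = float(ibs_variance_true(p_i).sum())
    if var_k == 0.0 or var_l == 0.0 or res.variance == 0.0:
        return None
    z_k = (res.total_samples - repeats * mean_k) / np.sqrt(repeats * var_k)
    z_l_exact = (res.loglik - mean_l) / np.sqrt(var_l / repeats)
    z_l_est = (res.loglik - mean_l) / np.sqrt(res.variance)
    return CalibrationRecord(
        z_total_samples=float(z_k),
        z_loglik_exact=float(z_l_exact),
        z_loglik_estimated=float(z_l_est),
    )


def calibration_experiment(
    params: PsychometricParams,
    n_datasets: int,
    *,
    task_cfg: Optional[OrientationTaskConfig] = None,
    repeats: int = 1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Run the calibration study and summarise the z-score samples.

    Returns a dataframe with one :class:`CalibrationRecord` per dataset and a
    summary dict with mean/sd/skew for each z variable plus empirical versus
    nominal coverage of the ``|z| <= beta`` intervals for beta in {1, 2}.
    Degenerate datasets with zero exact variance are excluded and counted.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    cfg = task_cfg or OrientationTaskConfig()
    rows = []
    n_excluded = 0

    for d in range(n_datasets):
        rng = substream(seed, 0, d)
        data = orientation_generate_dataset(params, cfg, rng)
        p_i = orientation_response_prob(data, params)
        run_cfg = IBSConfig(repeats=repeats, seed=int(substream(seed, 1, d).integers(2**63)))
        res = ibs_loglik_batch(data, orientation_simulate_batch, params, run_cfg)
        record = zscore_dataset(p_i, res, repeats)
        if record is None:
            n_excluded += 1
            continue
        rows.append(record)

    records = pd.DataFrame(rows)
    summary: dict = {"n_datasets": n_datasets, "n_excluded": n_excluded}
    for col in records.columns:
        z = records[col].to_numpy()
        summary[col] = {
            "mean": float(z.mean()),
            "sd": float(z.std(ddof=1)),
            "skew": float(stats.skew(z)),
        }
        for beta in (1.0, 2.0):
            summary[col][f"coverage_{int(beta)}"] = float(np.mean(np.abs(z) <= beta))
            summary[col][f"coverage_{int(beta)}_nominal"] = float(
                special.ndtr(beta) - special.ndtr(-beta)
            )
    return records, summary
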