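"""Tests of the dataset-level estimation engine and its randomness contract."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ibslik.engine import (
    IBSConfig,
    TrialData,
    early_stop_check,
    fixed_loglik,
    fixed_loglik_batch,
    ibs_loglik,
    ibs_loglik_batch,
    substream,
)
from ibslik.estimators import ibs_point_estimate, ibs_variance_true
from ibslik.models.bernoulli import BernoulliParams, bernoulli_simulate_batch
from ibslik.models.orientation import (
    orientation_exact_loglik,
    orientation_response_prob,
    orientation_simulate,
    orientation_simulate_batch,
)

from conftest import always_match_sim, bernoulli_sim, never_match_sim


class TestTrialData:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            TrialData(stimuli=np.zeros(3), responses=np.zeros(2))

    def test_empty(self):
        with pytest.raises(ValueError):
            TrialData(stimuli=[], responses=[])


class TestConfigValidation:
    def test_bad_repeats(self):
        with pytest.raises(ValueError):
            IBSConfig(repeats=0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            IBSConfig(early_stop_threshold=1.0)

    def test_bad_execution(self):
        with pytest.raises(ValueError):
            IBSConfig(execution="parallel")


class TestDeterministicSimulator:
    def test_all_hits_first_draw(self, ones_data):
        res = ibs_loglik(ones_data, always_match_sim, None, IBSConfig(repeats=3, seed=5))
        assert res.loglik == 0.0
        assert res.variance == 0.0
        assert np.all(res.sample_counts == 1)
        assert res.total_samples == 3 * ones_data.n_trials
        assert not res.early_stopped
        assert res.capped_trials == 0

    def test_unreachable_response_capped(self, ones_data):
        cfg = IBSConfig(max_samples_per_trial=50, seed=2)
        res = ibs_loglik(ones_data, never_match_sim, None, cfg)
        assert res.capped_trials == ones_data.n_trials
        assert not res.completed.any()
        assert np.all(res.sample_counts == 50)
        assert not res.variance_reliable

    def test_fixed_deterministic(self, ones_data):
        ll, hits = fixed_loglik(ones_data, always_match_sim, None, 7, seed=0)
        assert ll == 0.0
        assert np.all(hits == 7)

    def test_fixed_never_match(self):
        data = TrialData(stimuli=np.zeros(10), responses=np.ones(10, dtype=int))
        ll, hits = fixed_loglik(data, never_match_sim, None, 9, seed=0)
        assert ll == pytest.approx(10 * math.log(0.1), abs=1e-12)
        assert np.all(hits == 0)

    def test_fixed_call_count_exact(self):
        calls = {"n": 0}

        def counting_sim(s, params, rng):
            calls["n"] += 1
            return 1

        data = TrialData(stimuli=np.zeros(6), responses=np.ones(6, dtype=int))
        fixed_loglik(data, counting_sim, None, 4, seed=0)
        assert calls["n"] == 6 * 4


class TestEarlyStop:
    def test_check_examples(self):
        assert early_stop_check(-10.0, -2.0, -11.0)
        assert not early_stop_check(0.0, 0.0, -1.0)

    @given(
        st.floats(-100, 0),
        st.floats(-50, 0),
        st.floats(-200, -1e-6),
        st.floats(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_trial_partial(self, total, partial, thresh, extra):
        # per-trial estimates only decrease, so a triggered stop stays triggered
        if early_stop_check(total, partial, thresh):
            assert early_stop_check(total, partial - extra, thresh)

    def test_engine_returns_floor(self, ones_data):
        cfg = IBSConfig(early_stop_threshold=-5.0, seed=3)
        res = ibs_loglik(ones_data, never_match_sim, None, cfg)
        assert res.early_stopped
        assert res.loglik == -5.0
        assert not res.variance_reliable

    def test_batch_engine_returns_floor(self, ones_data):
        cfg = IBSConfig(early_stop_threshold=-5.0, seed=3)

        def never_batch(stimuli, params, rng):
            return np.full(np.asarray(stimuli).shape[0], -1, dtype=np.int64)

        res = ibs_loglik_batch(ones_data, never_batch, None, cfg)
        assert res.early_stopped
        assert res.loglik == -5.0


class TestGeometricLaw:
    def test_chi_square_sequential(self):
        p = 0.3
        n = 6000
        data = TrialData(stimuli=np.zeros(n), responses=np.ones(n, dtype=int))
        res = ibs_loglik(data, bernoulli_sim, BernoulliParams(p), IBSConfig(seed=11))
        _assert_geometric(res.sample_counts.ravel(), p)

    def test_chi_square_batched_pairs(self):
        p = 0.35
        n = 4000
        data = TrialData(stimuli=np.zeros(n), responses=np.ones(n, dtype=int))
        cfg = IBSConfig(seed=12, execution="batched")
        res = ibs_loglik(data, bernoulli_sim, BernoulliParams(p), cfg)
        _assert_geometric(res.sample_counts.ravel(), p)

    def test_chi_square_vectorised(self):
        p = 0.25
        n = 8000
        data = TrialData(stimuli=np.zeros(n), responses=np.ones(n, dtype=int))
        res = ibs_loglik_batch(
            data, bernoulli_simulate_batch, BernoulliParams(p), IBSConfig(seed=13)
        )
        _assert_geometric(res.sample_counts.ravel(), p)


def _assert_geometric(counts: np.ndarray, p: float, alpha: float = 0.01) -> None:
    kmax = int(np.quantile(counts, 0.99))
    observed = np.array(
        [np.sum(counts == k) for k in range(1, kmax)] + [np.sum(counts >= kmax)]
    )
    probs = np.array(
        [p * (1 - p) ** (k - 1) for k in range(1, kmax)] + [(1 - p) ** (kmax - 1)]
    )
    expected = probs * counts.size
    keep = expected >= 5
    chi2 = float(np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep]))
    pval = 1.0 - stats.chi2.cdf(chi2, df=int(keep.sum()) - 1)
    assert pval > alpha


class TestUnbiasedness:
    def test_single_trial_monte_carlo(self):
        """Mean estimate at p = 0.5 equals log 0.5 within sampling error."""
        p = 0.5
        n_runs = 100_000
        data = TrialData(stimuli=np.zeros(1), responses=np.ones(1, dtype=int))
        vals = np.empty(n_runs)
        for s in range(n_runs):
            vals[s] = ibs_loglik(
                data, bernoulli_sim, BernoulliParams(p), IBSConfig(seed=s)
            ).loglik
        se = math.sqrt(ibs_variance_true(p) / n_runs)
        assert abs(vals.mean() - math.log(p)) < 3.5 * se

    def test_dataset_monte_carlo_orientation(self, psychometric_params):
        """Dataset-level mean matches the exact total log-likelihood."""
        from ibslik.models.orientation import (
            OrientationTaskConfig,
            orientation_generate_dataset,
        )

        data = orientation_generate_dataset(
            psychometric_params, OrientationTaskConfig(n_trials=100), substream(7, 0)
        )
        exact = orientation_exact_loglik(data, psychometric_params)
        p_i = orientation_response_prob(data, psychometric_params)
        n_runs = 1000
        vals = np.array(
            [
                ibs_loglik_batch(
                    data,
                    orientation_simulate_batch,
                    psychometric_params,
                    IBSConfig(seed=s),
                ).loglik
                for s in range(n_runs)
            ]
        )
        se = math.sqrt(float(ibs_variance_true(p_i).sum()) / n_runs)
        assert abs(vals.mean() - exact) < 4 * se

    def test_fixed_sampling_bias_matches_enumeration(self):
        """Fixed sampling with M = 1 at p = 0.5 shows its known positive bias."""
        from ibslik.estimators import fixed_bias_exact

        p, M, n_runs = 0.5, 1, 200_000
        rng = np.random.default_rng(8)
        m = rng.binomial(M, p, size=n_runs)
        est = np.log((m + 1.0) / (M + 1.0))
        se = est.std(ddof=1) / math.sqrt(n_runs)
        bias = est.mean() - math.log(p)
        assert abs(bias - fixed_bias_exact(p, M)) < 3 * se
        assert bias > 0.3


class TestReproducibility:
    def test_sequential_bit_identical(self, orientation_data, psychometric_params):
        cfg = IBSConfig(repeats=2, seed=42)
        a = ibs_loglik(orientation_data, orientation_simulate, psychometric_params, cfg)
        b = ibs_loglik(orientation_data, orientation_simulate, psychometric_params, cfg)
        assert a.loglik == b.loglik
        assert np.array_equal(a.sample_counts, b.sample_counts)

    def test_sequential_vs_batched_bit_identical(
        self, orientation_data, psychometric_params
    ):
        seq = ibs_loglik(
            orientation_data,
            orientation_simulate,
            psychometric_params,
            IBSConfig(repeats=2, seed=42),
        )
        bat = ibs_loglik(
            orientation_data,
            orientation_simulate,
            psychometric_params,
            IBSConfig(repeats=2, seed=42, execution="batched"),
        )
        assert np.array_equal(seq.sample_counts, bat.sample_counts)
        assert seq.loglik == bat.loglik
        assert seq.variance == bat.variance

    def test_batched_chunking_immaterial(self, orientation_data, psychometric_params):
        full = ibs_loglik(
            orientation_data, orientation_simulate, psychometric_params,
            IBSConfig(repeats=2, seed=42, execution="batched"),
        )
        chunked = ibs_loglik(
            orientation_data, orientation_simulate, psychometric_params,
            IBSConfig(repeats=2, seed=42, execution="batched", batch_size=13),
        )
        assert np.array_equal(full.sample_counts, chunked.sample_counts)

    def test_batch_path_deterministic(self, orientation_data, psychometric_params):
        cfg = IBSConfig(repeats=3, seed=9)
        a = ibs_loglik_batch(
            orientation_data, orientation_simulate_batch, psychometric_params, cfg
        )
        b = ibs_loglik_batch(
            orientation_data, orientation_simulate_batch, psychometric_params, cfg
        )
        assert a.loglik == b.loglik
        assert np.array_equal(a.sample_counts, b.sample_counts)

    def test_result_invariants(self, orientation_data, psychometric_params):
        cfg = IBSConfig(repeats=2, seed=4)
        res = ibs_loglik(
            orientation_data, orientation_simulate, psychometric_params, cfg
        )
        K = res.sample_counts
        assert res.completed.all()
        assert res.loglik == pytest.approx(
            float(ibs_point_estimate(K).sum()) / 2, abs=1e-10
        )
        assert res.total_samples == int(K.sum())
        assert res.variance >= 0


class TestExpectedCost:
    def test_self_generated_orientation_mean_k(self, psychometric_params):
        """Data from the model itself costs E[K] = number of reachable
        responses per trial (2 for a binary task)."""
        from ibslik.models.orientation import (
            OrientationTaskConfig,
            orientation_generate_dataset,
        )

        data = orientation_generate_dataset(
            psychometric_params, OrientationTaskConfig(n_trials=400), substream(21, 0)
        )
        res = ibs_loglik_batch(
            data,
            orientation_simulate_batch,
            psychometric_params,
            IBSConfig(repeats=10, seed=3),
        )
        counts = res.sample_counts.ravel().astype(float)
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - 2.0) < 4 * se


class TestHistory:
    def test_observed_history_passed(self):
        class RepeatLastSim:
            uses_history = True

            def __call__(self, stimulus, params, rng, history=None):
                return history[-1][1] if history else 0

        responses = np.array([0, 0, 0, 0], dtype=int)
        data = TrialData(stimuli=np.zeros(4), responses=responses)
        res = ibs_loglik(data, RepeatLastSim(), None, IBSConfig(seed=0))
        assert res.loglik == 0.0
        assert np.all(res.sample_counts == 1)
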