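"""Three-Gaussian model, SSE objective and two-stage PSO fitting."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsedecomp import (
    FitConfig,
    GaussianTriplet,
    fit_episode_batch,
    fit_pulse,
    gaussian,
    model_curve,
    objective,
)
from pulsedecomp.errors import FitError, ParameterError

from conftest import random_physiological_triplet


class TestGaussian:
    def test_peak_value_at_center(self):
        assert gaussian(260.0, h=0.6, w=90.0, c=260.0) == 0.6

    def test_half_width_point(self):
        val = gaussian(150.0 + 60.0, h=0.8, w=60.0, c=150.0)
        assert val == pytest.approx(0.8 * math.exp(-0.5), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.floats(min_value=-500, max_value=1500))
    def test_symmetry_about_center(self, n):
        c = 300.0
        assert gaussian(n, 0.7, 80.0, c) == pytest.approx(gaussian(2 * c - n, 0.7, 80.0, c), rel=1e-12)

    @pytest.mark.parametrize("h,w", [(0.0, 60.0), (0.5, 0.0), (-1.0, 60.0), (0.5, -3.0)])
    def test_invalid_parameters_rejected(self, h, w):
        with pytest.raises(ParameterError):
            gaussian(10.0, h, w, 100.0)


class TestModelCurve:
    def test_separated_peaks_reach_heights(self):
        params = GaussianTriplet(h=(0.8, 0.6, 0.3), w=(15.0, 15.0, 15.0), c=(150.0, 500.0, 850.0))
        curve = model_curve(params)
        for h, c in zip(params.h, params.c):
            assert curve[int(c) - 1] == pytest.approx(h, abs=1e-6)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ParameterError):
            GaussianTriplet(h=(0.8, 0.6, 0.3), w=(60.0, 90.0, 120.0), c=(260.0, 150.0, 450.0))

    def test_positions_bounded(self):
        with pytest.raises(ParameterError):
            GaussianTriplet(h=(0.8, 0.6, 0.3), w=(60.0, 90.0, 120.0), c=(150.0, 260.0, 1000.0))


class TestObjective:
    def test_perfect_fit_is_zero(self, example_triplet):
        assert objective(example_triplet, model_curve(example_triplet)) == 0.0

    def test_zero_signal_gives_curve_energy(self, example_triplet):
        curve = model_curve(example_triplet)
        assert objective(example_triplet, np.zeros(1000)) == pytest.approx(float(curve @ curve), rel=1e-12)

    def test_matches_brute_force_summation(self, example_triplet):
        """Independent scalar-loop oracle for the sum of squared errors."""
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 1, size=1000)
        expected = 0.0
        for n in range(1, 1001):
            f = sum(
                hk * math.exp(-((n - ck) ** 2) / (2 * wk * wk))
                for hk, wk, ck in zip(example_triplet.h, example_triplet.w, example_triplet.c)
            )
            expected += (s[n - 1] - f) ** 2
        assert objective(example_triplet, s) == pytest.approx(expected, abs=1e-12)


class TestFitPulse:
    def test_recovers_noiseless_ground_truth(self, example_triplet):
        s = model_curve(example_triplet)
        res = fit_pulse(s, FitConfig(seed=1))
        assert res.rmse < 0.01
        assert np.max(np.abs(np.array(res.params.c) - np.array(example_triplet.c))) <= 5
        assert np.max(np.abs(np.array(res.params.h) - np.array(example_triplet.h))) <= 0.02
        assert res.objective_value == objective(res.params, s)

    def test_seed_stability(self, example_triplet):
        s = model_curve(example_triplet) + np.random.default_rng(9).normal(0, 0.005, 1000)
        r1 = fit_pulse(s, FitConfig(seed=11, polish=True))
        r2 = fit_pulse(s, FitConfig(seed=22, polish=True))
        assert abs(r1.objective_value - r2.objective_value) <= 0.1 * max(
            r1.objective_value, r2.objective_value
        )
        assert np.max(np.abs(np.array(r1.params.c) - np.array(r2.params.c))) <= 3

    def test_determinism_given_seed(self, example_triplet, fast_fit_config):
        s = model_curve(example_triplet) + np.random.default_rng(2).normal(0, 0.01, 1000)
        a = fit_pulse(s, fast_fit_config)
        b = fit_pulse(s, fast_fit_config)
        assert a.params == b.params
        assert a.objective_value == b.objective_value

    def test_beats_coarse_grid_search(self, example_triplet):
        """PSO with full freedom must match a 2-parameter exhaustive grid."""
        s = model_curve(example_triplet)
        h, w, c = example_triplet.h, example_triplet.w, example_triplet.c
        best = np.inf
        for c1 in range(100, 201, 2):
            for c2 in range(210, 311, 2):
                params = GaussianTriplet(h=h, w=w, c=(float(c1), float(c2), c[2]))
                best = min(best, objective(params, s))
        res = fit_pulse(s, FitConfig(seed=3))
        assert res.objective_value <= best + 1e-9

    def test_constraints_hold_and_history_monotone(self):
        rng = np.random.default_rng(0)
        for i in range(3):
            t = random_physiological_triplet(rng)
            s = model_curve(t) + rng.normal(0, 0.01, 1000)
            res = fit_pulse(s, FitConfig(seed=50 + i, max_restarts=2))
            c1, c2, c3 = res.params.c
            assert 1 < c1 < c2 < c3 < 1000
            assert all(x > 0 for x in res.params.h + res.params.w)
            assert np.all(np.diff(res.history) <= 0)

    def test_wrong_length_rejected(self, fast_fit_config):
        with pytest.raises(ParameterError):
            fit_pulse(np.zeros(500), fast_fit_config)


class TestBatch:
    def _episodes(self, triplet, n, noise, seed=0):
        rng = np.random.default_rng(seed)
        base = model_curve(triplet)
        return [base + rng.normal(0, noise, 1000) for _ in range(n)]

    def test_singleton_batch_equals_fit_pulse(self, example_triplet, fast_fit_config):
        eps = self._episodes(example_triplet, 1, 0.005)
        batch = fit_episode_batch(eps, fast_fit_config)
        child = fit_pulse(
            eps[0],
            dataclasses.replace(
                fast_fit_config,
                seed=int(np.random.SeedSequence([fast_fit_config.seed, 0]).generate_state(1)[0] % 2**31),
            ),
        )
        assert batch[0].params == child.params

    def test_consecutive_beats_fit_stably(self, example_triplet):
        """Near-identical episodes give near-identical reflected-wave timing."""
        cfg = FitConfig(swarm_size=24, stage1_iters=60, stage2_iters=20, seed=4)
        eps = self._episodes(example_triplet, 10, 0.005, seed=3)
        fits = fit_episode_batch(eps, cfg)
        c2 = [f.params.c[1] for f in fits if f is not None]
        assert len(c2) == 10
        assert np.std(c2) < 10

    def test_content_seeding_is_order_invariant(self, example_triplet, fast_fit_config):
        cfg = dataclasses.replace(fast_fit_config, seed_mode="content")
        eps = self._episodes(example_triplet, 4, 0.01, seed=8)
        fits = fit_episode_batch(eps, cfg)
        shuffled = fit_episode_batch([eps[2], eps[0], eps[3], eps[1]], cfg)
        key = lambda f: tuple(np.round(f.params.as_vector(), 9))
        assert sorted(map(key, fits)) == sorted(map(key, shuffled))

    def test_empty_batch_rejected(self, fast_fit_config):
        with pytest.raises(FitError):
            fit_episode_batch([], fast_fit_config)
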