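"""Threshold fitting, loop control, final scoring and full-run determinism."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import halfnorm, norm

from atacdoublets import iterate
from atacdoublets.iterate import (DetectorConfig, IterationState,
                                  call_doublets, detect_doublets, finalize,
                                  fit_threshold, run_iteration,
                                  should_continue)
from atacdoublets.matrix_io import filter_peaks


class TestFitThreshold:
    def test_recovers_density_crossing_of_known_distributions(self):
        rng = np.random.default_rng(0)
        s_raw = np.abs(rng.normal(0, 0.1, 5000))
        s_sim = rng.normal(1.0, 0.1, 5000)
        fit = fit_threshold(s_raw, s_sim)
        true_root = brentq(
            lambda x: halfnorm.pdf(x, scale=0.1) - norm.pdf(x, 1.0, 0.1),
            1e-9, 1.0 - 1e-9)
        assert abs(fit.crossing - true_root) < 0.02
        assert fit.s_th == fit.crossing + 2 * fit.sigma_sim

    def test_constant_simulated_scores(self):
        rng = np.random.default_rng(1)
        s_raw = np.abs(rng.normal(0, 0.1, 100))
        s_sim = np.full(50, 5.0)
        fit = fit_threshold(s_raw, s_sim)
        assert fit.sigma_sim == 0.0
        assert fit.s_th == fit.crossing == 5.0

    def test_no_crossing_falls_back_to_detecting_nothing(self):
        # simulated scores centered inside the raw bulk with huge spread:
        # the Gaussian density never reaches the half-normal below its mean
        rng = np.random.default_rng(2)
        s_raw = np.abs(rng.normal(0, 0.1, 2000))
        s_sim = rng.normal(0.05, 2.0, 2000)
        fit = fit_threshold(s_raw, s_sim)
        assert fit.fallback
        assert fit.s_th > s_raw.max()

    def test_requires_minimum_sample_sizes(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_threshold(np.ones(5), np.ones(50))

    def test_half_normal_scale_is_root_mean_square(self):
        s_raw = np.array([3.0, 4.0] * 10)
        fit = fit_threshold(s_raw, np.random.default_rng(3).normal(50, 1, 20))
        assert fit.sigma_raw == pytest.approx(np.sqrt(12.5))


class TestFinalize:
    def test_affine_oracle(self):
        history = [np.array([0.0, 0.0]), np.array([2.0, 4.0])]
        assert np.allclose(finalize(history), [0.0, 1.0])

    def test_single_iteration(self):
        assert np.allclose(finalize([np.array([1.0, 3.0, 2.0])]),
                           [0.0, 1.0, 0.5])

    def test_output_spans_zero_to_one(self, rng):
        out = finalize(rng.random((4, 30)))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_all_equal_means_give_half(self):
        with pytest.warns(UserWarning, match="equal"):
            out = finalize([np.ones(5), np.ones(5)])
        assert (out == 0.5).all()

    def test_mask_excludes_post_detection_entries(self):
        history = np.array([[1.0, 1.0], [9.0, 1.0]])
        mask = np.array([[1.0, 1.0], [0.0, 1.0]])
        # droplet 0 averages only its first iteration score
        out = finalize(history, mask)
        assert np.allclose(out, [0.5, 0.5])


class TestCallDoublets:
    def test_exact_count_at_rate(self, rng):
        flags = call_doublets(rng.random(100), 0.2)
        assert flags.sum() == 20

    def test_flags_match_rank_oracle(self, rng):
        scores = rng.random(57)
        flags = call_doublets(scores, 0.3)
        top = np.argsort(-scores)[:17]
        assert set(np.flatnonzero(flags)) == set(top)

    def test_ties_broken_by_lower_index(self):
        scores = np.array([0.5, 0.9, 0.5, 0.5])
        flags = call_doublets(scores, 0.5)
        assert flags.tolist() == [True, True, False, False]


class TestShouldContinue:
    def _state(self, n_detected, n_new, p=1.0, t=1, n_raw=100, rate=0.2,
               seed=0):
        st = IterationState(n_raw=n_raw, expected_rate=rate,
                            rng=np.random.default_rng(seed))
        st.detected = list(range(n_detected))
        st.n_new_last = n_new
        st.p = p
        st.t = t
        return st

    def test_stops_at_expected_rate(self):
        st = self._state(n_detected=20, n_new=5)
        assert should_continue(st, DetectorConfig()) is False

    def test_continues_while_detecting(self):
        st = self._state(n_detected=5, n_new=5)
        assert should_continue(st, DetectorConfig()) is True

    def test_p_zero_and_no_detections_stops(self):
        st = self._state(n_detected=0, n_new=0, p=0.0)
        assert should_continue(st, DetectorConfig()) is False

    def test_hard_iteration_cap(self):
        st = self._state(n_detected=0, n_new=5, t=10)
        assert should_continue(st, DetectorConfig(max_iterations=10)) is False

    def test_annealing_probability_decays_compoundingly(self):
        st = self._state(n_detected=0, n_new=0, t=2)
        p0 = st.p
        should_continue(st, DetectorConfig())
        assert st.p == pytest.approx(p0 * math.exp(-2 / 3))
        should_continue(st, DetectorConfig())
        assert st.p == pytest.approx(p0 * math.exp(-2 / 3) * math.exp(-2 / 3))

    def test_annealing_decisions_reproducible(self):
        outcomes = []
        for _ in range(2):
            st = self._state(n_detected=0, n_new=0, p=0.5, seed=11)
            outcomes.append([should_continue(st, DetectorConfig())
                             for _ in range(5)])
        assert outcomes[0] == outcomes[1]


@pytest.fixture(scope="module")
def small_run(small_planted):
    config = DetectorConfig(max_iterations=2)
    res = detect_doublets(small_planted.counts, expected_rate=0.2, seed=1,
                          config=config)
    return small_planted, res


class TestFullRun:
    def test_deterministic_given_seed(self, small_planted, small_run):
        _, first = small_run
        again = detect_doublets(small_planted.counts, expected_rate=0.2,
                                seed=1, config=DetectorConfig(max_iterations=2))
        assert np.array_equal(first.final_scores, again.final_scores)
        assert np.array_equal(first.called_doublet, again.called_doublet)
        assert first.n_iterations == again.n_iterations

    def test_final_scores_span_unit_interval(self, small_run):
        _, res = small_run
        assert res.final_scores.min() == 0.0
        assert res.final_scores.max() == 1.0

    def test_calling_rate_count(self, small_run):
        ds, res = small_run
        assert res.called_doublet.sum() == math.floor(0.2 * ds.n_droplets)

    def test_detected_droplets_leave_the_active_pool(self, small_planted):
        X = filter_peaks(small_planted.counts)
        state = IterationState(n_raw=X.n_droplets, expected_rate=0.5,
                               rng=np.random.default_rng(4))
        config = DetectorConfig()
        run_iteration(state, X, config)
        first_detected = set(state.detected)
        assert set(state.active).isdisjoint(first_detected)
        run_iteration(state, X, config)
        assert first_detected <= set(state.detected)
        assert set(state.active).isdisjoint(state.detected)

    def test_reference_vector_partitions(self, small_planted):
        X = filter_peaks(small_planted.counts)
        state = IterationState(n_raw=X.n_droplets, expected_rate=0.5,
                               rng=np.random.default_rng(4))
        run_iteration(state, X, DetectorConfig())
        det = np.asarray(state.detected, dtype=int)
        undetected = np.setdiff1d(np.arange(state.n_raw), det)
        assert (state.L_raw[undetected] == 0).all()
        if len(det):
            assert (state.L_raw[det] >= 0.1).all()
            assert (state.L_raw[det] <= 0.9).all()

    def test_planted_doublets_score_higher_at_iteration_one(self, small_run):
        ds, res = small_run
        s1 = res.score_history[0]
        truth = ds.is_doublet[res.used_indices]
        assert s1[truth].mean() > s1[~truth].mean()
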