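"""Post-hoc statistics: weighting, activations, summaries, metrics, spectra."""

import itertools
import warnings

import numpy as np
import pytest

from modemix import posthoc


class TestWeightedAlphas:
    def test_equal_traces_leave_mixing_unchanged(self, rng):
        alpha = rng.dirichlet(np.ones(3), size=50)
        covs = np.stack([np.eye(4)] * 3)
        np.testing.assert_allclose(posthoc.weighted_alphas(alpha, covs), alpha)

    def test_closed_form_two_modes(self):
        alpha = np.array([[0.5, 0.5]])
        covs = np.stack([np.eye(2) * 0.5, np.eye(2) * 1.5])  # traces 1, 3
        np.testing.assert_allclose(
            posthoc.weighted_alphas(alpha, covs), [[0.25, 0.75]]
        )

    def test_simplex_preserved(self, rng):
        alpha = rng.dirichlet(np.ones(4), size=100)
        covs = np.stack([(j + 1.0) * np.eye(3) for j in range(4)])
        w = posthoc.weighted_alphas(alpha, covs)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestActivationDetection:
    def test_bimodal_series_recovers_generating_labels(self, rng):
        labels = rng.integers(0, 2, size=2000).astype(bool)
        series = np.where(labels, 0.6, 0.1) + 0.01 * rng.standard_normal(2000)
        course = posthoc.detect_activations(series, sampling_frequency=100.0)
        assert (course.active[:, 0] == labels).mean() > 0.99

    def test_constant_series_never_active_with_warning(self):
        with pytest.warns(UserWarning, match="never active"):
            course = posthoc.detect_activations(np.full(500, 0.3))
        assert not course.active.any()

    def test_output_binary_and_same_length(self, rng):
        series = rng.dirichlet(np.ones(3), size=400)
        course = posthoc.detect_activations(series)
        assert course.active.shape == (400, 3)
        assert course.active.dtype == bool


class TestSummaryStatistics:
    def test_hand_counted_example(self):
        course = posthoc.ActivationCourse(
            np.array([1, 1, 1, 0, 0, 0, 1, 1, 1], dtype=bool)[:, None], 250.0
        )
        s = posthoc.summary_statistics(course)
        np.testing.assert_allclose(s.lifetimes[0], [0.012, 0.012])
        np.testing.assert_allclose(s.intervals[0], [0.012])
        assert s.fractional_occupancy[0] == pytest.approx(6 / 9)

    def test_always_active_mode(self):
        course = posthoc.ActivationCourse(np.ones((100, 1), dtype=bool), 10.0)
        s = posthoc.summary_statistics(course)
        np.testing.assert_allclose(s.lifetimes[0], [10.0])
        assert s.intervals[0].size == 0
        assert s.fractional_occupancy[0] == 1.0

    def test_time_is_conserved(self, rng):
        active = rng.random((1000, 3)) > 0.6
        s = posthoc.summary_statistics(posthoc.ActivationCourse(active, 1.0))
        for j in range(3):
            total_active = s.lifetimes[j].sum()
            assert total_active == pytest.approx(active[:, j].sum())

    def test_hsmm_mean_lifetime_matches_gamma_mean(self):
        from modemix import simulate

        course = simulate.sample_hsmm(
            simulate.HSMMConfig(n_states=3, n_samples=200_000, seed=0)
        )
        # lifetimes of state 0 as a binary course at fs = 1
        s = posthoc.summary_statistics(
            posthoc.ActivationCourse((course == 0)[:, None], 1.0)
        )
        assert s.lifetimes[0].mean() == pytest.approx(50.0, rel=0.05)


class TestModeMatching:
    def test_identical_series_identity_permutation(self, rng):
        a = rng.standard_normal((300, 4))
        np.testing.assert_array_equal(posthoc.match_modes(a, a), np.arange(4))

    def test_recovers_a_known_shuffle(self, rng):
        a = rng.standard_normal((300, 4))
        shuffle = np.array([2, 0, 3, 1])
        b = a[:, shuffle]
        perm = posthoc.match_modes(a, b)
        np.testing.assert_allclose(b[:, perm], a)

    def test_hungarian_matches_exhaustive_search(self, rng):
        a = rng.standard_normal((200, 4))
        b = rng.standard_normal((200, 4)) + 0.3 * a
        perm = posthoc.match_modes(a, b)

        def total(p):
            return sum(
                np.corrcoef(a[:, i], b[:, p[i]])[0, 1] for i in range(4)
            )

        best = max(itertools.permutations(range(4)), key=total)
        assert total(perm) == pytest.approx(total(best))

    def test_unequal_mode_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            posthoc.match_modes(
                rng.standard_normal((10, 3)), rng.standard_normal((10, 4))
            )


class TestDice:
    def test_identical_courses(self, rng):
        course = rng.integers(0, 3, size=500)
        assert posthoc.dice_coefficient(course, course) == 1.0

    def test_invariant_to_relabelling(self, rng):
        course = rng.integers(0, 3, size=500)
        relabelled = (course + 1) % 3
        assert posthoc.dice_coefficient(relabelled, course) == 1.0

    def test_ten_percent_corruption_gives_point_nine(self, rng):
        course = np.repeat(np.arange(3), 100)
        corrupted = course.copy()
        idx = rng.choice(300, 30, replace=False)
        corrupted[idx] = (corrupted[idx] + 1) % 3
        assert posthoc.dice_coefficient(corrupted, course) == pytest.approx(0.9)

    def test_soft_mixture_is_binarised_by_argmax(self):
        truth = np.array([0, 1, 0, 1])
        alpha = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4], [0.4, 0.6]])
        assert posthoc.dice_coefficient(alpha, truth) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            posthoc.dice_coefficient(np.zeros(5), np.zeros(6))


class TestRiemannianDistance:
    def test_zero_on_identical_matrices(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T + np.eye(4)
        assert posthoc.riemannian_distance(S, S) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_scaled_identity(self):
        # d(I, e^2 I) in 4 dims: each log-eigenvalue is 2 -> sqrt(4 * 4) = 4
        d = posthoc.riemannian_distance(np.eye(4), np.exp(2.0) * np.eye(4))
        assert d == pytest.approx(4.0, abs=1e-10)

    def test_symmetry_and_congruence_invariance(self, rng):
        A_ = rng.standard_normal((3, 3))
        B_ = rng.standard_normal((3, 3))
        A = A_ @ A_.T + np.eye(3)
        B = B_ @ B_.T + np.eye(3)
        d = posthoc.riemannian_distance(A, B)
        assert d == pytest.approx(posthoc.riemannian_distance(B, A), abs=1e-8)
        M = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        d2 = posthoc.riemannian_distance(M @ A @ M.T, M @ B @ M.T)
        assert d2 == pytest.approx(d, abs=1e-8)

    def test_non_symmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError):
            posthoc.riemannian_distance(bad, np.eye(2))


class TestTimevaryingCovError:
    def test_perfect_reconstruction_has_zero_distance(self, rng):
        from modemix.simulate import random_covariances

        covs = random_covariances(3, 4, seed=0)
        alpha = rng.dirichlet(np.ones(3), size=50)
        truth = np.einsum("tj,jmn->tmn", alpha, covs)
        d, mean = posthoc.timevarying_cov_error(alpha, covs, truth)
        assert mean == pytest.approx(0.0, abs=1e-6)

    def test_paired_test_on_identical_inputs_is_zero(self, rng):
        d = rng.random(100)
        t, p = posthoc.compare_cov_errors(d, d)
        assert t == 0.0 and p == 1.0


class TestMixingPSD:
    def test_white_noise_spectrum_is_flat(self, rng):
        series = rng.standard_normal((200_000, 1))
        f, psd = posthoc.mixing_psd(series, sampling_frequency=100.0)
        keep = f > 0
        slope = np.polyfit(np.log(f[keep]), np.log(psd[0][keep]), 1)[0]
        assert abs(slope) < 0.05
        assert np.all(psd >= 0)

    def test_sinusoid_peaks_at_its_frequency(self):
        fs, f0 = 100.0, 7.0
        t = np.arange(50_000) / fs
        series = np.sin(2 * np.pi * f0 * t)[:, None]
        f, psd = posthoc.mixing_psd(series, fs)
        assert f[np.argmax(psd[0])] == pytest.approx(f0, abs=0.1)

    def test_binary_course_uses_windowed_occupancy(self, rng):
        course = (rng.random((30_000, 1)) > 0.5).astype(float)
        f, psd = posthoc.mixing_psd(course, sampling_frequency=250.0)
        assert np.all(np.isfinite(psd))


class TestRegressionSpectra:
    @staticmethod
    def _two_regime_data(rng, fs=100.0, seg=200, n_segs=60):
        """Alternating segments of white noise with variance 1 and 9."""
        sds = np.tile([1.0, 3.0], n_segs // 2)
        data = np.concatenate(
            [sd * rng.standard_normal(seg) for sd in sds]
        )[None]
        alpha = np.zeros((seg * n_segs, 2))
        for k, sd in enumerate(sds):
            alpha[k * seg : (k + 1) * seg, int(sd > 1)] = 1.0
        return data, alpha

    def test_recovers_two_known_regime_spectra(self, rng):
        fs = 100.0
        data, alpha = self._two_regime_data(rng, fs=fs)
        dec = posthoc.regression_spectra(
            data, alpha, fs, window_seconds=2.0
        )
        # white noise with std s: flat PSD at s^2 * 2 / fs (one-sided Welch)
        for j, var in enumerate([1.0, 9.0]):
            recovered = dec.mean_psd + dec.mode_psd[j]
            expected = 2.0 * var / fs
            inner = (dec.frequencies > 5) & (dec.frequencies < 45)
            assert np.median(recovered[inner]) == pytest.approx(expected, rel=0.2)

    def test_residuals_orthogonal_to_design(self, rng):
        data, alpha = self._two_regime_data(rng)
        dec = posthoc.regression_spectra(data, alpha, 100.0)
        n_frames = dec.residuals.shape[0]
        design = np.column_stack([np.ones(n_frames), np.zeros((n_frames, 0))])
        # rebuild the design used internally: intercept + frame-averaged alpha
        step = 100  # nperseg=200, overlap 0.5
        frames = np.array(
            [alpha[k * step : k * step + 200].mean(axis=0) for k in range(n_frames)]
        )
        design = np.column_stack([np.ones(n_frames), frames])
        np.testing.assert_allclose(
            design.T @ dec.residuals, 0.0, atol=1e-8
        )

    def test_true_mixing_beats_shuffled_mixing(self, rng):
        data, alpha = self._two_regime_data(rng)
        dec_true = posthoc.regression_spectra(data, alpha, 100.0)
        shuffled = alpha[rng.permutation(len(alpha))]
        dec_shuf = posthoc.regression_spectra(data, shuffled, 100.0)
        assert (
            dec_true.mean_reconstruction_error
            < dec_shuf.mean_reconstruction_error
        )

    def test_constant_mixing_warns_rank_deficient(self, rng):
        data = rng.standard_normal((1, 4000))[None][0]
        alpha = np.full((4000, 2), 0.5)
        with pytest.warns(UserWarning, match="rank"):
            posthoc.regression_spectra(data, alpha, 100.0)


class TestEvokedResponse:
    def test_constant_series_yields_null_response(self):
        series = np.full(5000, 2.5)
        events = np.array([10.0, 20.0, 30.0])
        evoked, times, sig, t = posthoc.epoch_evoked(
            series, events, (-0.2, 0.5), sampling_frequency=100.0,
            n_permutations=100, seed=0,
        )
        np.testing.assert_allclose(evoked, 0.0)
        assert not sig.any()

    def test_injected_boxcar_is_detected(self, rng):
        fs = 100.0
        series = 0.1 * rng.standard_normal(60_000)
        events = np.arange(20, 580, 10, dtype=float)
        for ev in events:
            c = int(ev * fs)
            series[c + 10 : c + 30] += 1.0  # 100-300 ms after each event
        evoked, times, sig, _ = posthoc.epoch_evoked(
            series, events, (-0.2, 0.5), fs, n_permutations=200, seed=0
        )
        box = (times >= 0.1) & (times < 0.3)
        assert sig[box, 0].mean() > 0.9
        assert sig[times < 0.0, 0].mean() < 0.2

    def test_edge_events_dropped_with_warning(self, rng):
        series = rng.standard_normal(1000)
        with pytest.warns(UserWarning, match="dropped"):
            posthoc.epoch_evoked(
                series, np.array([0.01, 5.0]), (-0.2, 0.5), 100.0,
                n_permutations=50,
            )
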