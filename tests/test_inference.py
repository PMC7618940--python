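"""Variational inference: posterior network, sampling, KL, free energy, training."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from modemix import inference
from modemix.inference import (
    InferenceRNN,
    LossReport,
    TrainingConfig,
    free_energy,
    gaussian_kl,
    infer_posterior,
    kl_annealing_factor,
    reparam_sample,
)
from modemix.model import ModeModel, ModeModelConfig


@pytest.fixture
def tiny_setup(rng):
    n_channels, n_modes = 4, 2
    model = ModeModel(
        ModeModelConfig(
            n_modes=n_modes,
            n_channels=n_channels,
            model_rnn_units=8,
            covariance_init="identity_jitter",
            seed=0,
        )
    )
    infnet = InferenceRNN(n_channels, n_modes, n_units=8, seed=1)
    x = rng.standard_normal((2, 15, n_channels))
    return model, infnet, x


class TestPosteriorNetwork:
    def test_posterior_std_positive_and_deterministic(self, tiny_setup):
        _, infnet, x = tiny_setup
        m1, s1 = infer_posterior(x, infnet)
        m2, s2 = infer_posterior(x, infnet)
        assert np.all(s1 > 0)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(s1, s2)

    def test_posterior_uses_future_context(self, tiny_setup):
        """Bidirectional contract: later inputs influence earlier posteriors."""
        _, infnet, x = tiny_setup
        m1, _ = infer_posterior(x, infnet)
        x2 = x.copy()
        x2[:, 10:] += 5.0
        m2, _ = infer_posterior(x2, infnet)
        assert not np.allclose(m1[:, :10], m2[:, :10])


class TestReparameterization:
    def test_zero_std_returns_the_mean(self):
        m = np.array([1.0, -2.0])
        out = reparam_sample(m, np.zeros(2), seed=0)
        np.testing.assert_array_equal(out, m)

    def test_closed_form_sample(self):
        out = reparam_sample(np.array([2.0]), np.array([3.0]), eps=np.array([1.0]))
        assert out[0] == 5.0

    def test_sample_moments(self):
        m, s = np.array([0.7]), np.array([1.9])
        draws = np.array(
            [reparam_sample(m, s, eps=e) for e in
             np.random.default_rng(0).standard_normal((100_000, 1))]
        )
        assert draws.mean() == pytest.approx(0.7, abs=3 * 1.9 / np.sqrt(1e5))
        assert draws.std() == pytest.approx(1.9, rel=0.02)


class TestGaussianKL:
    def test_zero_when_equal(self, rng):
        m = rng.standard_normal(5)
        s = np.abs(rng.standard_normal(5)) + 0.1
        assert gaussian_kl(m, s, m, s) == pytest.approx(0.0, abs=1e-12)

    def test_mean_shift_closed_form(self):
        assert gaussian_kl([0.0], [1.0], [1.0], [1.0]) == pytest.approx(0.5)

    def test_variance_ratio_closed_form(self):
        # N(0, 4) vs N(0, 1): 0.5 * (4 - 1 - ln 4)
        expected = 0.5 * (4 - 1 - np.log(4.0))
        assert gaussian_kl([0.0], [2.0], [0.0], [1.0]) == pytest.approx(expected)

    def test_matches_monte_carlo_estimate(self, rng):
        m, s = rng.standard_normal(3), np.abs(rng.standard_normal(3)) + 0.3
        mu, sig = rng.standard_normal(3), np.abs(rng.standard_normal(3)) + 0.3
        closed = gaussian_kl(m, s, mu, sig)
        n = 1_000_000
        draws = m + s * rng.standard_normal((n, 3))
        logq = -0.5 * (((draws - m) / s) ** 2 + np.log(2 * np.pi * s**2))
        logp = -0.5 * (((draws - mu) / sig) ** 2 + np.log(2 * np.pi * sig**2))
        diff = (logq - logp).sum(axis=1)
        se = diff.std() / np.sqrt(n)
        assert closed == pytest.approx(diff.mean(), abs=3 * se)

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kl([0.0], [0.0], [0.0], [1.0])


class TestKLAnnealing:
    def test_schedule_endpoints(self):
        assert kl_annealing_factor(0, 10.0, 100) <= 0.01
        assert kl_annealing_factor(100, 10.0, 100) == 1.0
        assert kl_annealing_factor(250, 10.0, 100) == 1.0

    def test_monotone_non_decreasing(self):
        vals = [kl_annealing_factor(e, 10.0, 100) for e in range(120)]
        assert np.all(np.diff(vals) >= 0)


class TestFreeEnergy:
    def test_zero_annealing_makes_loss_equal_negative_ll(self, tiny_setup):
        model, infnet, x = tiny_setup
        _, report = free_energy(x, model, infnet, annealing=0.0,
                                rng=np.random.default_rng(0))
        assert report.free_energy == pytest.approx(-report.log_likelihood)

    def test_report_identity_on_components(self, tiny_setup):
        model, infnet, x = tiny_setup
        _, report = free_energy(x, model, infnet, annealing=0.37,
                                rng=np.random.default_rng(0))
        assert report.free_energy == pytest.approx(
            -report.log_likelihood + 0.37 * report.kl
        )
        with pytest.raises(ValueError):
            LossReport(free_energy=1.0, log_likelihood=1.0, kl=1.0, annealing=1.0)

    def test_single_mode_ll_matches_dense_gaussian(self, rng):
        """With J = 1 the mixture collapses: LL must equal the direct density."""
        n = 3
        model = ModeModel(
            ModeModelConfig(
                n_modes=1, n_channels=n, model_rnn_units=4,
                covariance_init="identity_jitter", seed=0,
            )
        )
        infnet = InferenceRNN(n, 1, n_units=4, seed=1)
        x = rng.standard_normal((2, 20, n))
        _, report = free_energy(x, model, infnet, annealing=0.0,
                                rng=np.random.default_rng(0))
        D = model.covariances[0]
        direct = sum(
            multivariate_normal.logpdf(x[b], np.zeros(n), D).sum()
            for b in range(2)
        )
        assert report.log_likelihood == pytest.approx(direct, rel=1e-6)

    def test_gradients_match_finite_differences(self, tiny_setup):
        """Autodiff gradient of F vs central differences on scalar params."""
        model, infnet, x = tiny_setup

        def fn():
            loss, _ = free_energy(x, model, infnet, annealing=0.8,
                                  rng=np.random.default_rng(42))
            return loss

        loss = fn()
        loss.backward()
        eps = 1e-5
        for param in [model.cholesky_flat, model._raw_temperature,
                      infnet.f_m.b, model.g_mu.W]:
            idx = tuple(0 for _ in param.value.shape)
            analytic = param.grad[idx]
            orig = param.value[idx]
            param.value[idx] = orig + eps
            f1 = float(fn().value)
            param.value[idx] = orig - eps
            f2 = float(fn().value)
            param.value[idx] = orig
            numeric = (f1 - f2) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-6)


class TestTraining:
    def test_loss_decreases_and_history_complete(self, small_hsmm_truth):
        cfg = TrainingConfig(
            n_modes=3, sequence_length=100, inference_units=16, model_units=16,
            n_epochs=10, kl_annealing_epochs=5, batch_size=8,
            learning_rate=0.01, seed=0,
        )
        trained = inference.train(small_hsmm_truth.data, cfg)
        h = trained.history
        assert list(h.columns) == [
            "epoch", "free_energy", "log_likelihood", "kl", "annealing"
        ]
        assert len(h) == 10
        assert h["free_energy"].iloc[-1] < h["free_energy"].iloc[0]

    def test_epoch_one_is_seed_deterministic(self, small_hsmm_truth):
        cfg = TrainingConfig(
            n_modes=3, sequence_length=100, inference_units=8, model_units=8,
            n_epochs=1, kl_annealing_epochs=1, batch_size=8, seed=123,
        )
        a = inference.train(small_hsmm_truth.data, cfg)
        b = inference.train(small_hsmm_truth.data, cfg)
        assert a.history["free_energy"].iloc[0] == b.history["free_energy"].iloc[0]

    def test_multi_start_returns_full_history(self, small_hsmm_truth):
        cfg = TrainingConfig(
            n_modes=3, sequence_length=100, inference_units=8, model_units=8,
            n_epochs=6, kl_annealing_epochs=3, batch_size=8,
            n_multi_starts=2, multi_start_epochs=2, seed=0,
        )
        trained = inference.train(small_hsmm_truth.data, cfg)
        assert len(trained.history) == 6

    def test_map_mixing_is_on_the_simplex(self, small_hsmm_truth):
        cfg = TrainingConfig(
            n_modes=3, sequence_length=100, inference_units=8, model_units=8,
            n_epochs=2, kl_annealing_epochs=1, batch_size=8, seed=0,
        )
        trained = inference.train(small_hsmm_truth.data, cfg)
        alpha = inference.map_mixing(
            trained.mode_model, trained.inference_rnn,
            small_hsmm_truth.data, 100,
        )
        assert alpha.shape == (4000, 3)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(alpha >= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_epochs=50, kl_annealing_epochs=100)
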