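"""Conditional VAE: reparameterization, KL closed form, training, decisions."""

import numpy as np
import pytest

from dermpipe.cvae import CVAE, CVAEConfig, LossBreakdown, kl_gaussian, reparameterize


def make_features(n_per_class=100, k=3, dim=8, sep=4.0, seed=3):
    """Class-conditional Gaussian features with means separated by ~sep sigma."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0, sep, (k, dim))
    y = np.repeat(np.arange(k), n_per_class)
    x = means[y] + rng.normal(0, 1.0, (y.size, dim))
    return x, y


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        mu = np.array([1.0, -2.0])
        assert np.array_equal(reparameterize(mu, np.ones(2), np.zeros(2)), mu)

    def test_standard_prior_returns_noise(self, rng):
        noise = rng.normal(size=5)
        assert np.allclose(reparameterize(np.zeros(5), np.ones(5), noise), noise)

    def test_sample_mean_clt_bound(self, rng):
        n = 100_000
        mu, s2 = 2.0, 4.0
        z = reparameterize(np.full(n, mu), np.full(n, s2), rng.normal(size=n))
        assert abs(z.mean() - mu) < 3 * np.sqrt(s2) / np.sqrt(n)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reparameterize(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2))


class TestKL:
    def test_prior_equals_posterior(self):
        assert kl_gaussian(np.zeros(7), np.ones(7)) == 0.0

    def test_unit_mean_single_dim(self):
        assert kl_gaussian(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_variance_four(self):
        expected = 0.5 * (4 - 1 - np.log(4))
        assert kl_gaussian(np.array([0.0]), np.array([4.0])) == pytest.approx(expected)

    def test_nonnegative_random(self, rng):
        for _ in range(50):
            mu = rng.normal(size=4)
            s2 = rng.uniform(0.1, 5.0, 4)
            assert kl_gaussian(mu, s2) >= 0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kl_gaussian(np.zeros(2), np.zeros(2))


class TestEncodeDecode:
    def setup_method(self):
        self.model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=16, seed=0))

    def test_variance_strictly_positive(self, rng):
        _, s2 = self.model.encode(rng.normal(size=8), 1)
        assert np.all(s2 > 0)

    def test_deterministic(self, rng):
        x = rng.normal(size=8)
        a = self.model.encode(x, 2)
        b = self.model.encode(x, 2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_out_of_range_class(self, rng):
        with pytest.raises(ValueError, match="class"):
            self.model.encode(rng.normal(size=8), 3)

    def test_latent_must_be_smaller_than_input(self):
        with pytest.raises(ValueError, match="latent"):
            CVAE(4, 2, CVAEConfig(latent_dim=4))

    def test_needs_two_classes(self):
        with pytest.raises(ValueError, match="classes"):
            CVAE(8, 1)

    def test_class_conditioning_after_training(self):
        # after training on class-separated data, conditioning on a different
        # class generally shifts the posterior mean and always shifts the
        # conditional objective (long training can squeeze the class signal
        # out of the encoder entirely, so the mean check is over many inputs)
        x, y = make_features(n_per_class=60, k=2, dim=6, seed=1)
        model = CVAE(6, 2, CVAEConfig(latent_dim=3, hidden_dim=32, epochs=10, seed=1))
        model.fit(x, y)
        mu_diffs = [
            np.abs(model.encode(xi, 0)[0] - model.encode(xi, 1)[0]).max() for xi in x[:10]
        ]
        assert max(mu_diffs) > 0
        score_gaps = [abs(np.diff(model.class_scores(xi))[0]) for xi in x[:10]]
        assert min(score_gaps) > 0


class TestLoss:
    def test_breakdown_total(self):
        lb = LossBreakdown(2.0, 0.5)
        assert lb.total == 2.5

    def test_kl_component_matches_closed_form(self, rng):
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, seed=2))
        x = rng.normal(size=8)
        mu, s2 = model.encode(x, 0)
        assert model.loss(x, 0).kl == pytest.approx(kl_gaussian(mu, s2))

    def test_gaussian_reconstruction_is_half_squared_error(self, rng):
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, seed=2))
        x = rng.normal(size=8)
        mu, s2 = model.encode(x, 1)
        z = reparameterize(mu, s2, np.zeros_like(mu))
        xhat = model.decode(z, 1)
        lb = model.loss(x, 1)
        assert lb.reconstruction == pytest.approx(0.5 * np.sum((x - xhat) ** 2))
        # term-by-term: total equals the hand-computed sum
        assert lb.total == pytest.approx(
            0.5 * np.sum((x - xhat) ** 2) + kl_gaussian(mu, s2)
        )

    def test_reconstruction_minimum_at_exact_reconstruction(self, rng):
        # the quadratic term is zero iff xhat == x and positive elsewhere
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, seed=2))
        x = rng.normal(size=8)
        assert model._recon_loss(x, x.copy()) == 0.0
        assert model._recon_loss(x, x + 0.1) > 0.0


class TestTraining:
    def test_history_length_equals_epochs(self):
        x, y = make_features(n_per_class=20, seed=5)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=16, epochs=7, seed=0))
        hist = model.fit(x, y)
        assert len(hist) == 7

    def test_loss_decreases(self):
        x, y = make_features(n_per_class=50, seed=6)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=32, epochs=25, seed=0))
        hist = model.fit(x, y)
        assert hist[-1]["total"] < hist[0]["total"]

    def test_two_runs_identical(self):
        x, y = make_features(n_per_class=20, seed=7)
        h1 = CVAE(8, 3, CVAEConfig(epochs=5, latent_dim=4, seed=9)).fit(x, y)
        h2 = CVAE(8, 3, CVAEConfig(epochs=5, latent_dim=4, seed=9)).fit(x, y)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        model = CVAE(8, 3, CVAEConfig(latent_dim=4))
        with pytest.raises(ValueError, match="nonempty"):
            model.fit(np.empty((0, 8)), np.empty(0, dtype=int))

    def test_bernoulli_decoder_trains(self, rng):
        x = rng.random((40, 6))
        y = rng.integers(0, 2, 40)
        model = CVAE(6, 2, CVAEConfig(latent_dim=3, epochs=5, decoder="bernoulli", seed=0))
        hist = model.fit(x, y)
        assert np.isfinite(hist[-1]["total"])


class TestClassification:
    def test_untrained_state_rejected(self, rng):
        model = CVAE(8, 3, CVAEConfig(latent_dim=4))
        with pytest.raises(RuntimeError, match="trained"):
            model.classify(rng.normal(size=8))

    def test_label_is_argmin_of_scores(self):
        x, y = make_features(n_per_class=30, seed=8)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=16, epochs=10, seed=0))
        model.fit(x, y)
        label, scores = model.classify(x[0])
        assert label == int(np.argmin(scores))
        assert scores.shape == (3,)

    def test_inference_deterministic(self):
        x, y = make_features(n_per_class=30, seed=8)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=16, epochs=10, seed=0))
        model.fit(x, y)
        assert np.array_equal(model.predict(x[:10]), model.predict(x[:10]))

    def test_accuracy_on_separated_classes(self):
        x, y = make_features(n_per_class=100, k=3, dim=8, sep=4.0, seed=3)
        rng = np.random.default_rng(0)
        idx = rng.permutation(y.size)
        tr, te = idx[:240], idx[240:]
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=32, epochs=50, seed=0))
        model.fit(x[tr], y[tr])
        acc = (model.predict(x[te]) == y[te]).mean()
        assert acc > 0.9


class TestSerialization:
    def test_save_load_predicts_identically(self, tmp_path):
        x, y = make_features(n_per_class=30, seed=10)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, hidden_dim=16, epochs=10, seed=0))
        model.fit(x, y)
        model.save(tmp_path / "ckpt")
        loaded = CVAE.load(tmp_path / "ckpt")
        assert np.array_equal(model.predict(x[:20]), loaded.predict(x[:20]))

    def test_training_log_csv(self, tmp_path):
        import pandas as pd

        x, y = make_features(n_per_class=10, seed=11)
        model = CVAE(8, 3, CVAEConfig(latent_dim=4, epochs=4, seed=0))
        model.fit(x, y)
        model.write_training_log(tmp_path / "log.csv")
        log = pd.read_csv(tmp_path / "log.csv")
        assert list(log.columns) == ["epoch", "reconstruction", "kl", "total"]
        assert len(log) == 4
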