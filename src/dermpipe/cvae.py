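"""Conditional variational autoencoder (CVAE) classifier over feature vectors.

The encoder q_phi(z | x, c) maps a feature vector x concatenated with the
one-hot class c to a diagonal Gaussian (mu, sigma^2) over a latent z of
smaller dimension than x; the decoder p_theta(x | z, c) reconstructs x from
z concatenated with the same one-hot class.  Training minimizes the negative
evidence lower bound

    L(theta, phi; x, c) = -E_{q_phi(z|x,c)}[log p_theta(x | z, c)]
                          + D_KL(q_phi(z|x,c) || N(0, I))

with the expectation approximated by a single reparameterized sample
z = mu + sigma * eps.  With the default unit-variance Gaussian decoder the
reconstruction term is the half squared error 0.5 * ||x - xhat||^2 (the
additive normalization constant is dropped); a Bernoulli decoder
(cross-entropy on [0,1] inputs) is available via ``decoder="bernoulli"``.

Classification evaluates the trained objective for every candidate class with
the noise pinned to zero and returns the argmin — the class under which the
observed features are most probable.  Ties break to the lowest class index.

Both networks are two-hidden-layer ReLU MLPs with inverted dropout, trained
by Adam with hand-written backpropagation; everything is seeded and exactly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

_LOGVAR_CLIP = 12.0  # keeps exp() finite early in training


@dataclass
class CVAEConfig:
    """Training hyperparameters (benchmark defaults: lr 0.01, 50 epochs,
    dropout 0.5, batch size 5; ReLU activations throughout)."""

    latent_dim: int = 8
    hidden_dim: int = 64
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 5
    dropout: float = 0.5
    seed: int = 0
    decoder: str = "gaussian"  # or "bernoulli"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.decoder not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown decoder family: {self.decoder}")


@dataclass
class LossBreakdown:
    reconstruction: float
    kl: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.kl


def reparameterize(mu: np.ndarray, sigma2: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """z = mu + sqrt(sigma^2) * noise, elementwise."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("variance must be strictly positive")
    return np.asarray(mu, dtype=float) + np.sqrt(sigma2) * np.asarray(noise, dtype=float)


def kl_gaussian(mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)) =
    0.5 * sum(mu^2 + sigma^2 - 1 - ln sigma^2); nonnegative, zero iff the
    posterior equals the prior."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("variance must be strictly positive")
    return float(0.5 * np.sum(mu**2 + sigma2 - 1.0 - np.log(sigma2)))


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class CVAE:
    """Conditional VAE over fixed-length feature vectors with K classes."""

    PARAM_NAMES = (
        "enc_w1", "enc_b1", "enc_w2", "enc_b2",
        "enc_wmu", "enc_bmu", "enc_wlv", "enc_blv",
        "dec_w1", "dec_b1", "dec_w2", "dec_b2",
        "dec_wout", "dec_bout",
    )

    def __init__(self, input_dim: int, n_classes: int, config: CVAEConfig | None = None):
        config = config or CVAEConfig()
        if n_classes < 2:
            raise ValueError(f"need at least 2 classes, got {n_classes}")
        if config.latent_dim >= input_dim:
            raise ValueError(
                f"latent dim ({config.latent_dim}) must be smaller than the "
                f"input dim ({input_dim})"
            )
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.config = config
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        h, d, k, ld = config.hidden_dim, input_dim, n_classes, config.latent_dim

        def he(fan_in, fan_out):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

        self.params = {
            "enc_w1": he(d + k, h), "enc_b1": np.zeros(h),
            "enc_w2": he(h, h), "enc_b2": np.zeros(h),
            "enc_wmu": he(h, ld) * 0.1, "enc_bmu": np.zeros(ld),
            "enc_wlv": he(h, ld) * 0.1, "enc_blv": np.zeros(ld),
            "dec_w1": he(ld + k, h), "dec_b1": np.zeros(h),
            "dec_w2": he(h, h), "dec_b2": np.zeros(h),
            "dec_wout": he(h, d) * 0.1, "dec_bout": np.zeros(d),
        }
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ utils
    def _one_hot(self, c: np.ndarray) -> np.ndarray:
        c = np.atleast_1d(np.asarray(c, dtype=np.int64))
        if c.min() < 0 or c.max() >= self.n_classes:
            raise ValueError(f"class labels must lie in 0..{self.n_classes - 1}")
        oh = np.zeros((c.size, self.n_classes))
        oh[np.arange(c.size), c] = 1.0
        return oh

    # ---------------------------------------------------------------- forward
    def _encode_batch(self, x: np.ndarray, c: np.ndarray, *, masks=None):
        p = self.params
        u = np.hstack([x, self._one_hot(c)])
        a1 = u @ p["enc_w1"] + p["enc_b1"]
        h1 = _relu(a1)
        if masks is not None:
            h1 = h1 * masks[0]
        a2 = h1 @ p["enc_w2"] + p["enc_b2"]
        h2 = _relu(a2)
        if masks is not None:
            h2 = h2 * masks[1]
        mu = h2 @ p["enc_wmu"] + p["enc_bmu"]
        lv = np.clip(h2 @ p["enc_wlv"] + p["enc_blv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return u, a1, h1, a2, h2, mu, lv

    def _decode_batch(self, z: np.ndarray, c: np.ndarray, *, masks=None):
        p = self.params
        v = np.hstack([z, self._one_hot(c)])
        a1 = v @ p["dec_w1"] + p["dec_b1"]
        g1 = _relu(a1)
        if masks is not None:
            g1 = g1 * masks[0]
        a2 = g1 @ p["dec_w2"] + p["dec_b2"]
        g2 = _relu(a2)
        if masks is not None:
            g2 = g2 * masks[1]
        out = g2 @ p["dec_wout"] + p["dec_bout"]
        if self.config.decoder == "bernoulli":
            out = _sigmoid(out)
        return v, a1, g1, a2, g2, out

    def encode(self, x: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma^2) for one feature vector; the
        variance is parameterized through the log so it is strictly positive."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("feature vector must be finite")
        *_, mu, lv = self._encode_batch(x, np.asarray([c]))
        return mu[0], np.exp(lv[0])

    def decode(self, z: np.ndarray, c: int) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self._decode_batch(z, np.asarray([c]))[-1][0]

    def _recon_loss(self, x: np.ndarray, xhat: np.ndarray) -> float:
        if self.config.decoder == "bernoulli":
            eps = 1e-9
            return float(
                -np.sum(x * np.log(xhat + eps) + (1 - x) * np.log(1 - xhat + eps))
            )
        return float(0.5 * np.sum((x - xhat) ** 2))

    def loss(self, x: np.ndarray, c: int, noise: np.ndarray | None = None) -> LossBreakdown:
        """Single-sample objective at (x, c); ``noise=None`` pins z = mu."""
        x = np.asarray(x, dtype=float).ravel()
        mu, sigma2 = self.encode(x, c)
        if noise is None:
            noise = np.zeros_like(mu)
        z = reparameterize(mu, sigma2, noise)
        xhat = self.decode(z, c)
        return LossBreakdown(self._recon_loss(x, xhat), kl_gaussian(mu, sigma2))

    # ----------------------------------------------------------------- training
    def fit(self, features: np.ndarray, labels: np.ndarray) -> list[dict]:
        """Train on (feature vector, class) pairs; returns per-epoch history
        rows (epoch, reconstruction, kl, total).  Reproducible under the
        config seed."""
        x_all = np.asarray(features, dtype=float)
        y_all = np.asarray(labels, dtype=np.int64)
        if x_all.ndim != 2 or x_all.shape[0] == 0:
            raise ValueError("training set must be a nonempty 2-D feature array")
        if x_all.shape[0] != y_all.shape[0]:
            raise ValueError("features and labels differ in length")
        self._one_hot(y_all)  # validates the label range
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        n = x_all.shape[0]
        self.history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_rec = ep_kl = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                rec, kl = self._train_step(x_all[idx], y_all[idx], rng)
                ep_rec += rec * idx.size
                ep_kl += kl * idx.size
            self.history.append(
                {
                    "epoch": epoch,
                    "reconstruction": ep_rec / n,
                    "kl": ep_kl / n,
                    "total": (ep_rec + ep_kl) / n,
                }
            )
        self.trained = True
        return self.history

    def _dropout_mask(self, shape, rng) -> np.ndarray:
        keep = 1.0 - self.config.dropout
        if keep >= 1.0:
            return np.ones(shape)
        return (rng.random(shape) < keep) / keep

    def _train_step(self, x, y, rng) -> tuple[float, float]:
        p = self.params
        bsz = x.shape[0]
        enc_masks = [self._dropout_mask((bsz, self.config.hidden_dim), rng) for _ in range(2)]
        dec_masks = [self._dropout_mask((bsz, self.config.hidden_dim), rng) for _ in range(2)]
        u, ea1, eh1, ea2, eh2, mu, lv = self._encode_batch(x, y, masks=enc_masks)
        eps = rng.normal(size=mu.shape)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * eps
        v, da1, g1, da2, g2, xhat = self._decode_batch(z, y, masks=dec_masks)

        rec = self._recon_loss(x, xhat) / bsz
        kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / bsz

        grads = {}
        # decoder backward; for both families d(loss)/d(pre-activation) = xhat - x
        dout = (xhat - x) / bsz
        grads["dec_wout"] = g2.T @ dout
        grads["dec_bout"] = dout.sum(axis=0)
        dg2 = (dout @ p["dec_wout"].T) * dec_masks[1] * (da2 > 0)
        grads["dec_w2"] = g1.T @ dg2
        grads["dec_b2"] = dg2.sum(axis=0)
        dg1 = (dg2 @ p["dec_w2"].T) * dec_masks[0] * (da1 > 0)
        grads["dec_w1"] = v.T @ dg1
        grads["dec_b1"] = dg1.sum(axis=0)
        dz = (dg1 @ p["dec_w1"].T)[:, : self.config.latent_dim]

        # KL gradients plus the reparameterization path
        dmu = dz + mu / bsz
        dlv = dz * eps * 0.5 * sigma + 0.5 * (np.exp(lv) - 1.0) / bsz

        grads["enc_wmu"] = eh2.T @ dmu
        grads["enc_bmu"] = dmu.sum(axis=0)
        grads["enc_wlv"] = eh2.T @ dlv
        grads["enc_blv"] = dlv.sum(axis=0)
        dh2 = (dmu @ p["enc_wmu"].T + dlv @ p["enc_wlv"].T) * enc_masks[1] * (ea2 > 0)
        grads["enc_w2"] = eh1.T @ dh2
        grads["enc_b2"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["enc_w2"].T) * enc_masks[0] * (ea1 > 0)
        grads["enc_w1"] = u.T @ dh1
        grads["enc_b1"] = dh1.sum(axis=0)

        self._adam_t += 1
        lr, b1, b2, adameps = self.config.learning_rate, 0.9, 0.999, 1e-8
        for name, g in grads.items():
            self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * g
            self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * g**2
            mhat = self._adam_m[name] / (1 - b1**self._adam_t)
            vhat = self._adam_v[name] / (1 - b2**self._adam_t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + adameps)
        return rec, kl

    # ---------------------------------------------------------------- inference
    def class_scores(self, x: np.ndarray) -> np.ndarray:
        """The objective evaluated under every candidate class (noise = 0)."""
        if not self.trained:
            raise RuntimeError("model must be trained before classification")
        x = np.asarray(x, dtype=float).ravel()
        return np.array([self.loss(x, c).total for c in range(self.n_classes)])

    def classify(self, x: np.ndarray) -> tuple[int, np.ndarray]:
        """Argmin-loss class (deterministic; ties break to the lowest index)."""
        scores = self.class_scores(x)
        return int(np.argmin(scores)), scores

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.array([self.classify(x)[0] for x in np.atleast_2d(features)])

    # ------------------------------------------------------------ serialization
    def save(self, path: str | Path) -> None:
        """Write parameters (npz) plus a JSON sidecar with the architecture."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
            "trained": self.trained,
            "config": asdict(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CVAE":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            sidecar["input_dim"], sidecar["n_classes"], CVAEConfig(**sidecar["config"])
        )
        with np.load(path.with_suffix(".npz")) as data:
            for name in cls.PARAM_NAMES:
                model.params[name] = data[name]
        model.trained = sidecar["trained"]
        return model

    def write_training_log(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.history).to_csv(path, index=False)
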