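"""The semi-supervised VAE: encoder, latent classifier and Bernoulli decoder.

The generative model assumes a standard-normal prior over a d-dimensional
latent z, a categorical subtype distribution Cat(y | pi(z)) and a factorised
Bernoulli likelihood over the [0,1]-scaled molecular features.  The encoder
amortises a diagonal-Gaussian posterior q(z|x) = N(mu(x), diag(sigma(x)^2)).
By default the latent dimension d equals the number of subtypes h, which is
what makes the individual latent components directly interpretable as
subtype axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Linear

__all__ = ["ModelConfig", "SemiSupervisedVAE", "sigmoid", "softmax"]

# Bernoulli parameters are kept away from exact {0,1} so log-likelihoods stay finite.
PROB_EPS = 1e-7
# Raw log-sigma head output is clipped to this range for numerical stability.
LOG_SIGMA_MIN = -8.0
LOG_SIGMA_MAX = 5.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``latent_dim`` defaults to ``n_subtypes`` (d = h). Decoder hidden widths
    default to the mirror image of the encoder's.
    """

    n_features: int
    n_subtypes: int
    latent_dim: int | None = None
    encoder_hidden: tuple = (128, 64)
    decoder_hidden: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")
        if self.latent_dim is None:
            self.latent_dim = self.n_subtypes
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        self.encoder_hidden = tuple(int(w) for w in self.encoder_hidden)
        if self.decoder_hidden is None:
            self.decoder_hidden = tuple(reversed(self.encoder_hidden))
        else:
            self.decoder_hidden = tuple(int(w) for w in self.decoder_hidden)

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_subtypes": self.n_subtypes,
            "latent_dim": self.latent_dim,
            "encoder_hidden": list(self.encoder_hidden),
            "decoder_hidden": list(self.decoder_hidden),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder_hidden"] = tuple(d["encoder_hidden"])
        d["decoder_hidden"] = tuple(d["decoder_hidden"])
        return cls(**d)


class SemiSupervisedVAE:
    """Encoder g_phi, classifier pi_theta and decoder f_theta in one bundle."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, d, h = config.n_features, config.latent_dim, config.n_subtypes
        self.encoder = MLP([D, *config.encoder_hidden, 2 * d], rng)
        self.decoder = MLP([d, *config.decoder_hidden, D], rng)
        self.classifier = Linear(d, h, rng, np.sqrt(1.0 / d))
        self.is_trained = False

    # -- forward contracts ------------------------------------------------

    def _check_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.n_features:
            raise ValueError(
                f"expected {self.config.n_features} features, got {X.shape[1]}")
        return X

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma) for each row of X."""
        X = self._check_x(X)
        out = self.encoder.forward(X)
        d = self.config.latent_dim
        mu = out[:, :d]
        log_sigma = np.clip(out[:, d:], LOG_SIGMA_MIN, LOG_SIGMA_MAX)
        return mu, np.exp(log_sigma)

    @staticmethod
    def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        """z = mu + sigma * eps with eps drawn standard normal."""
        eps = rng.standard_normal(np.shape(mu))
        return mu + sigma * eps

    def classify(self, z: np.ndarray) -> np.ndarray:
        """Subtype probabilities pi(z), softmax-normalised rows."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return softmax(self.classifier.forward(z))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Bernoulli means f_theta(z) in (0,1), eps-clamped."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        p = sigmoid(self.decoder.forward(z))
        return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)

    def decode_logits(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.decoder.forward(z)

    def predict_subtype(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Argmax class of pi(mu(x)); the posterior mean is used, not a draw.

        Ties break to the lowest class index. Requires a trained model.
        """
        if not self.is_trained:
            raise RuntimeError("model has not been trained")
        mu, _ = self.encode(X)
        pi = self.classify(mu)
        return pi.argmax(axis=1), pi

    # -- parameter plumbing ----------------------------------------------

    @property
    def params(self):
        return self.encoder.params + self.decoder.params + self.classifier.params

    @property
    def grads(self):
        return self.encoder.grads + self.decoder.grads + self.classifier.grads

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        self.decoder.zero_grad()
        self.classifier.zero_grad()

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, lin in enumerate(net.linears):
                out[f"{prefix}_{i}_W"] = lin.W
                out[f"{prefix}_{i}_b"] = lin.b
        out["cls_W"] = self.classifier.W
        out["cls_b"] = self.classifier.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, arr in self.get_weights().items():
            if key not in weights:
                raise KeyError(f"checkpoint missing weight array {key!r}")
            if weights[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            arr[...] = weights[key]
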