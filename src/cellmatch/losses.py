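"""The semi-supervised objective.

Per sample the loss is built from four terms, all in nats:

* ``recon``   negative Bernoulli log-likelihood of x under the decoder,
* ``kl``      closed-form KL(q(z|x) || N(0, I)),
* ``entropy`` H[p(y|z)] of the latent classifier, added as a regulariser so
              class boundaries avoid high-density latent regions,
* ``cls``     -log pi_y(z), the classification term (labelled samples only).

The unlabelled loss is U(x) = recon + kl + entropy; the labelled loss is
S(x, y) = U-terms + cls, with all terms evaluated on the same single
reparameterised draw z ~ q(z|x).  Mini-batch objectives are plain sums of
U over the unlabelled batch plus S over the labelled batch, with no term
weights.

This module also carries the fused forward/backward pass the trainer uses:
analytic gradients for the summed batch loss with respect to every
parameter of the encoder, decoder and classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (LOG_SIGMA_MAX, LOG_SIGMA_MIN, SemiSupervisedVAE, sigmoid,
                    softmax)

__all__ = [
    "LossBreakdown", "bernoulli_recon_loss", "kl_standard_normal",
    "categorical_entropy", "unsupervised_loss", "supervised_loss",
    "batch_loss", "loss_and_grads",
]

_LOG_EPS = 1e-12


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    entropy: float
    cls: float = 0.0

    @property
    def total(self) -> float:
        return self.recon + self.kl + self.entropy + self.cls


def bernoulli_recon_loss(x: np.ndarray, p: np.ndarray):
    """-sum_i [x_i ln p_i + (1-x_i) ln(1-p_i)]; cross-entropy for fractional x.

    Summed over the last axis: a scalar for a single profile, a per-sample
    vector for a batch.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    ll = x * np.log(p) + (1.0 - x) * np.log1p(-p)
    return -ll.sum(axis=-1)


def kl_standard_normal(mu: np.ndarray, sigma: np.ndarray):
    """Closed-form KL(N(mu, diag(sigma^2)) || N(0, I)), summed over the last axis."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=-1)


def categorical_entropy(pi: np.ndarray):
    """-sum_y pi_y ln pi_y with the 0 ln 0 = 0 convention."""
    pi = np.asarray(pi, dtype=float)
    terms = np.where(pi > 0, pi * np.log(np.maximum(pi, _LOG_EPS)), 0.0)
    return -terms.sum(axis=-1)


def _single_pass(model: SemiSupervisedVAE, x: np.ndarray,
                 rng: np.random.Generator):
    X = np.atleast_2d(np.asarray(x, dtype=float))
    mu, sigma = model.encode(X)
    z = model.reparameterize(mu, sigma, rng)
    p = model.decode(z)
    pi = model.classify(z)
    return X, mu, sigma, z, p, pi


def unsupervised_loss(x: np.ndarray, model: SemiSupervisedVAE,
                      rng: np.random.Generator) -> LossBreakdown:
    """U(x) for one sample or the summed batch, one z draw per sample."""
    X, mu, sigma, z, p, pi = _single_pass(model, x, rng)
    return LossBreakdown(
        recon=float(bernoulli_recon_loss(X, p).sum()),
        kl=float(kl_standard_normal(mu, sigma).sum()),
        entropy=float(categorical_entropy(pi).sum()),
    )


def supervised_loss(x: np.ndarray, y, model: SemiSupervisedVAE,
                    rng: np.random.Generator) -> LossBreakdown:
    """S(x, y) = U-terms - log pi_y(z) on the same z draw."""
    X, mu, sigma, z, p, pi = _single_pass(model, x, rng)
    y = np.atleast_1d(np.asarray(y, dtype=int))
    h = model.config.n_subtypes
    if y.min() < 0 or y.max() >= h:
        raise ValueError(f"label out of range [0, {h})")
    cls = -np.log(np.maximum(pi[np.arange(len(y)), y], _LOG_EPS))
    return LossBreakdown(
        recon=float(bernoulli_recon_loss(X, p).sum()),
        kl=float(kl_standard_normal(mu, sigma).sum()),
        entropy=float(categorical_entropy(pi).sum()),
        cls=float(cls.sum()),
    )


def batch_loss(cell_X: np.ndarray | None, tumour_X: np.ndarray | None,
               tumour_y, model: SemiSupervisedVAE,
               rng: np.random.Generator) -> tuple[float, LossBreakdown]:
    """Sum of U over the unlabelled batch plus S over the labelled batch."""
    empty_cells = cell_X is None or len(cell_X) == 0
    empty_tumours = tumour_X is None or len(tumour_X) == 0
    if empty_cells and empty_tumours:
        raise ValueError("both batches are empty")
    recon = kl = entropy = cls = 0.0
    if not empty_cells:
        u = unsupervised_loss(cell_X, model, rng)
        recon, kl, entropy = u.recon, u.kl, u.entropy
    if not empty_tumours:
        s = supervised_loss(tumour_X, tumour_y, model, rng)
        recon += s.recon
        kl += s.kl
        entropy += s.entropy
        cls = s.cls
    bd = LossBreakdown(recon=recon, kl=kl, entropy=entropy, cls=cls)
    return bd.total, bd


# -- fused forward + analytic backward for training -----------------------

def loss_and_grads(model: SemiSupervisedVAE, X: np.ndarray,
                   y: np.ndarray | None,
                   rng: np.random.Generator) -> LossBreakdown:
    """One seeded forward pass and full backpropagation for a batch.

    Accumulates gradients of the summed batch loss into the model's ``grads``
    buffers (call ``model.zero_grad()`` first). ``y`` is None for an
    unlabelled batch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = model.config.latent_dim

    enc_out = model.encoder.forward(X)
    mu = enc_out[:, :d]
    raw_ls = enc_out[:, d:]
    clip_mask = (raw_ls > LOG_SIGMA_MIN) & (raw_ls < LOG_SIGMA_MAX)
    log_sigma = np.clip(raw_ls, LOG_SIGMA_MIN, LOG_SIGMA_MAX)
    sigma = np.exp(log_sigma)
    eps = rng.standard_normal(mu.shape)
    z = mu + sigma * eps

    x_logits = model.decoder.forward(z)
    p = np.clip(sigmoid(x_logits), 1e-7, 1.0 - 1e-7)
    y_logits = model.classifier.forward(z)
    pi = softmax(y_logits)
    log_pi = np.log(np.maximum(pi, _LOG_EPS))

    recon = float(bernoulli_recon_loss(X, p).sum())
    kl = float(kl_standard_normal(mu, sigma).sum())
    ent_per = -(pi * log_pi).sum(axis=1)
    entropy = float(ent_per.sum())
    cls = 0.0

    # d/d x_logits of the summed Bernoulli cross-entropy
    d_xlogits = p - X
    dz = model.decoder.backward(d_xlogits)

    # entropy term: dH/da_j = -pi_j (log pi_j + H)
    d_ylogits = -pi * (log_pi + ent_per[:, None])
    if y is not None:
        y = np.asarray(y, dtype=int)
        cls = float(-log_pi[np.arange(len(y)), y].sum())
        onehot = np.zeros_like(pi)
        onehot[np.arange(len(y)), y] = 1.0
        d_ylogits = d_ylogits + (pi - onehot)
    dz = dz + model.classifier.backward(d_ylogits)

    dmu = dz + mu
    dls = dz * (sigma * eps) + (sigma ** 2 - 1.0)
    dls = np.where(clip_mask, dls, 0.0)
    model.encoder.backward(np.concatenate([dmu, dls], axis=1))

    return LossBreakdown(recon=recon, kl=kl, entropy=entropy, cls=cls)
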