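"""Semi-supervised training loop and evaluation.

Each optimisation step consumes one labelled (tumour) mini-batch and one
unlabelled (cell-line) mini-batch; their summed loss is minimised jointly
with Adam. The shorter stream is recycled within an epoch so every epoch
sees the full labelled set once. All randomness (init, shuffling,
reparameterisation draws) derives from a single seed, so runs are exactly
reproducible on one thread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)

from .losses import loss_and_grads
from .model import ModelConfig, SemiSupervisedVAE
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "EvalReport", "train", "evaluate_classification",
           "evaluate_reconstruction", "loss_term_correlations"]


@dataclass
class TrainingConfig:
    epochs: int = 300
    batch_size_labelled: int = 64
    batch_size_unlabelled: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    test_fraction: float = 0.2
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size_labelled < 1 \
                or self.batch_size_unlabelled < 1:
            raise ValueError("epochs and batch sizes must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.optimizer_name.lower() != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class EvalReport:
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "weighted_precision": self.weighted_precision,
                "weighted_recall": self.weighted_recall,
                "weighted_f1": self.weighted_f1,
                "confusion": self.confusion.to_dict()}


def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(X_lab: np.ndarray, y_lab: np.ndarray,
          X_unlab: np.ndarray | None,
          model_config: ModelConfig,
          training_config: TrainingConfig | None = None
          ) -> tuple[SemiSupervisedVAE, pd.DataFrame]:
    """Fit the model; returns it with a per-epoch loss ledger.

    The ledger columns (recon, kl, entropy, cls, total) are summed batch
    losses per epoch, ready for the loss-term correlation diagnostic.
    """
    cfg = training_config or TrainingConfig()
    X_lab = np.asarray(X_lab, dtype=float)
    y_lab = np.asarray(y_lab, dtype=int)
    if len(X_lab) == 0:
        raise ValueError("labelled set must be non-empty")
    if len(np.unique(y_lab)) < 2:
        raise ValueError("labelled set must contain at least 2 classes")
    has_unlab = X_unlab is not None and len(X_unlab) > 0
    if has_unlab:
        X_unlab = np.asarray(X_unlab, dtype=float)

    model = SemiSupervisedVAE(model_config)
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    history = []
    for epoch in range(cfg.epochs):
        lab_order = rng.permutation(len(X_lab))
        lab_batches = list(_batches(len(X_lab), cfg.batch_size_labelled,
                                    lab_order))
        if has_unlab:
            unlab_order = rng.permutation(len(X_unlab))
            unlab_batches = list(_batches(len(X_unlab),
                                          cfg.batch_size_unlabelled,
                                          unlab_order))
        sums = {"recon": 0.0, "kl": 0.0, "entropy": 0.0, "cls": 0.0}
        for step, idx_lab in enumerate(lab_batches):
            model.zero_grad()
            bd_s = loss_and_grads(model, X_lab[idx_lab], y_lab[idx_lab], rng)
            sums["recon"] += bd_s.recon
            sums["kl"] += bd_s.kl
            sums["entropy"] += bd_s.entropy
            sums["cls"] += bd_s.cls
            if has_unlab:
                idx_un = unlab_batches[step % len(unlab_batches)]
                bd_u = loss_and_grads(model, X_unlab[idx_un], None, rng)
                sums["recon"] += bd_u.recon
                sums["kl"] += bd_u.kl
                sums["entropy"] += bd_u.entropy
            opt.step(model.grads)
        total = sum(sums.values())
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: {sums}")
        history.append({"epoch": epoch, **sums, "total": total})
    model.is_trained = True
    return model, pd.DataFrame(history)


def evaluate_classification(model: SemiSupervisedVAE, X_test: np.ndarray,
                            y_test: np.ndarray,
                            class_names: list | None = None) -> EvalReport:
    """Held-out accuracy, weighted precision/recall/F1 and confusion matrix."""
    y_test = np.asarray(y_test, dtype=int)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    y_pred, _ = model.predict_subtype(X_test)
    labels = np.arange(model.config.n_subtypes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=labels, average="weighted", zero_division=0)
    cm = confusion_matrix(y_test, y_pred, labels=labels)
    names = class_names if class_names is not None else list(labels)
    return EvalReport(
        accuracy=float(accuracy_score(y_test, y_pred)),
        weighted_precision=float(prec),
        weighted_recall=float(rec),
        weighted_f1=float(f1),
        confusion=pd.DataFrame(cm, index=names, columns=names))


def sample_feature_correlation(X: np.ndarray, X_hat: np.ndarray) -> np.ndarray:
    """Per-sample Pearson correlation across features; NaN where undefined."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    out = np.full(len(X), np.nan)
    for i in range(len(X)):
        if np.std(X[i]) == 0 or np.std(X_hat[i]) == 0:
            continue
        out[i] = pearsonr(X[i], X_hat[i])[0]
    return out


def evaluate_reconstruction(model: SemiSupervisedVAE, X: np.ndarray,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """Input/output correlation per sample, histogram-ready.

    For each sample one latent is drawn from q(z|x); ``corr_sampled``
    correlates x with a Bernoulli draw from the decoder, ``corr_mean`` with
    the decoder means. Samples with constant input are reported as NaN.
    """
    if not model.is_trained:
        raise RuntimeError("model has not been trained")
    rng = rng or np.random.default_rng(0)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu, sigma = model.encode(X)
    z = model.reparameterize(mu, sigma, rng)
    p = model.decode(z)
    x_draw = (rng.random(p.shape) < p).astype(float)
    return pd.DataFrame({
        "corr_sampled": sample_feature_correlation(X, x_draw),
        "corr_mean": sample_feature_correlation(X, p),
    })


def loss_term_correlations(history: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the per-epoch loss-term series."""
    terms = history[["recon", "kl", "entropy", "cls"]]
    return terms.corr(method="pearson")
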