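"""End-to-end convenience pipeline: smooth -> assemble -> train -> evaluate.

Glues the library modules together for the common experiment: given a
cohort (real TSVs or a synthetic draw), smooth the DNA views over the
network, assemble and scale the features, train the semi-supervised VAE on
labelled tumours plus unlabelled cell lines, and evaluate held-out tumour
classification, cell-line label recovery (when truth is available),
reconstruction quality and the fidelity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features, fidelity, netsmooth, trainer
from .model import ModelConfig, SemiSupervisedVAE
from .synthdata import SynthCohort
from .trainer import EvalReport, TrainingConfig

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    model: SemiSupervisedVAE
    history: pd.DataFrame
    report: EvalReport                 # held-out tumour classification
    label_mapping: dict[str, int]
    profiles: pd.DataFrame             # all assembled profiles
    Z_tumour: pd.DataFrame
    Z_cell: pd.DataFrame
    dissimilarity: pd.DataFrame
    reconstruction: pd.DataFrame
    tumour_labels: pd.Series
    cell_line_predictions: pd.Series
    cell_line_accuracy: float | None   # only when hidden truth was supplied
    test_ids: pd.Index
    scaling: features.ScalingStats
    smoothed: tuple


def run_pipeline(cohort: SynthCohort,
                 seed: int = 0,
                 alpha: float = 0.5,
                 test_fraction: float = 0.2,
                 epochs: int = 200,
                 encoder_hidden: tuple = (128, 64),
                 batch_size_labelled: int = 64,
                 batch_size_unlabelled: int = 16,
                 learning_rate: float = 1e-3) -> PipelineResult:
    """Run the full matching workflow on one cohort, seeded end to end."""
    sm_mut, sm_cnv = netsmooth.smooth_alterations(
        cohort.mutations, cohort.cnv, cohort.network, alpha=alpha)
    rna_scaled, rna_stats = features.minmax_scale(cohort.rna)
    profiles = features.assemble_views(rna_scaled, sm_mut.values,
                                       sm_cnv.values)
    stats = features.ScalingStats(
        pd.Series(0.0, index=profiles.columns),
        pd.Series(1.0, index=profiles.columns))

    tumour_ids = cohort.tumour_ids
    cell_ids = cohort.cell_line_ids
    y_codes, mapping = features.encode_labels(cohort.tumour_labels)
    y = pd.Series(y_codes, index=tumour_ids)

    X_tu = profiles.loc[tumour_ids]
    X_cl = profiles.loc[cell_ids]
    X_tr, y_tr, X_te, y_te = features.split_train_test(
        X_tu, y, test_fraction=test_fraction, seed=seed)

    mcfg = ModelConfig(n_features=profiles.shape[1],
                       n_subtypes=len(mapping),
                       encoder_hidden=encoder_hidden, seed=seed)
    tcfg = TrainingConfig(epochs=epochs,
                          batch_size_labelled=batch_size_labelled,
                          batch_size_unlabelled=batch_size_unlabelled,
                          learning_rate=learning_rate, seed=seed,
                          test_fraction=test_fraction)
    model, history = trainer.train(X_tr.to_numpy(), y_tr.to_numpy(),
                                   X_cl.to_numpy(), mcfg, tcfg)

    names = sorted(mapping, key=mapping.get)
    report = trainer.evaluate_classification(
        model, X_te.to_numpy(), y_te.to_numpy(), class_names=names)

    Z_tu = fidelity.latent_embedding(model, X_tu.to_numpy(), index=tumour_ids)
    Z_cl = fidelity.latent_embedding(model, X_cl.to_numpy(), index=cell_ids)
    D = fidelity.cosine_dissimilarity(Z_cl, Z_tu)

    recon = trainer.evaluate_reconstruction(
        model, X_tu.to_numpy(), rng=np.random.default_rng(seed))

    pred_codes, _ = model.predict_subtype(X_cl.to_numpy())
    cl_pred = pd.Series([names[c] for c in pred_codes], index=cell_ids)
    cl_acc = None
    if cohort.cell_line_labels is not None:
        cl_acc = float((cl_pred == cohort.cell_line_labels).mean())

    return PipelineResult(
        model=model, history=history, report=report, label_mapping=mapping,
        profiles=profiles, Z_tumour=Z_tu, Z_cell=Z_cl, dissimilarity=D,
        reconstruction=recon, tumour_labels=cohort.tumour_labels,
        cell_line_predictions=cl_pred, cell_line_accuracy=cl_acc,
        test_ids=X_te.index, scaling=stats, smoothed=(sm_mut, sm_cnv))
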