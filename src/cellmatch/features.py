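"""Feature assembly and scaling for the combined RNA + DNA input views.

The model consumes per-sample profiles x = (x_DNA, x_RNA) with every feature
min-max scaled to [0, 1] on the training cohort. Feature names are
namespaced by view ("rna:GENE", "mut:GENE", "cnv:GENE") and the
concatenation order (rna, mut, cnv) is fixed so profiles are comparable
across cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = ["ScalingStats", "minmax_scale", "assemble_views",
           "split_train_test", "encode_labels"]


@dataclass
class ScalingStats:
    """Per-feature training minimum and maximum, reusable on query samples."""

    minimum: pd.Series
    maximum: pd.Series

    def __post_init__(self):
        if (self.maximum < self.minimum).any():
            raise ValueError("max < min in scaling stats")

    def to_dict(self) -> dict:
        return {"features": list(self.minimum.index),
                "minimum": self.minimum.tolist(),
                "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingStats":
        idx = pd.Index(d["features"])
        return cls(pd.Series(d["minimum"], index=idx),
                   pd.Series(d["maximum"], index=idx))


def minmax_scale(matrix: pd.DataFrame, stats: ScalingStats | None = None
                 ) -> tuple[pd.DataFrame, ScalingStats]:
    """Map each feature to (v - min) / (max - min).

    Without ``stats`` the extrema come from ``matrix`` itself (training
    mode); constant features map to 0. With ``stats`` (query mode) values
    are transformed with the stored extrema and clamped into [0, 1].
    """
    if matrix.isna().any().any():
        bad = matrix.columns[matrix.isna().any()][0]
        raise ValueError(f"NaN values in feature {bad!r}")
    if stats is None:
        lo = matrix.min(axis=0)
        hi = matrix.max(axis=0)
        stats = ScalingStats(lo, hi)
        clamp = False
    else:
        missing = matrix.columns.difference(stats.minimum.index)
        if len(missing):
            raise KeyError(f"features absent from scaling stats: "
                           f"{list(missing)[:5]}")
        lo = stats.minimum[matrix.columns]
        hi = stats.maximum[matrix.columns]
        clamp = True
    span = hi - lo
    scaled = (matrix - lo).div(span.where(span > 0, 1.0), axis=1)
    scaled.loc[:, (span == 0).to_numpy()] = 0.0
    if clamp:
        scaled = scaled.clip(0.0, 1.0)
    return scaled, stats


def inverse_minmax(scaled: pd.DataFrame, stats: ScalingStats) -> pd.DataFrame:
    """Undo ``minmax_scale`` for non-degenerate features."""
    lo = stats.minimum[scaled.columns]
    hi = stats.maximum[scaled.columns]
    return scaled.mul(hi - lo, axis=1).add(lo, axis=1)


def assemble_views(rna: pd.DataFrame, mut: pd.DataFrame, cnv: pd.DataFrame
                   ) -> pd.DataFrame:
    """Concatenate the scaled views into one profile matrix.

    Samples: intersection across views (exclusions logged). DNA modalities
    are aligned to the union of their gene sets; a gene missing from one
    modality is zero-filled there (absence of evidence of alteration).
    """
    shared = rna.index.intersection(mut.index).intersection(cnv.index)
    if len(shared) == 0:
        raise ValueError("no samples shared across RNA and DNA views")
    for name, df in (("rna", rna), ("mut", mut), ("cnv", cnv)):
        dropped = df.index.difference(shared)
        if len(dropped):
            logger.info("%s view: excluding %d sample(s) missing elsewhere",
                        name, len(dropped))
    dna_genes = mut.columns.union(cnv.columns, sort=True)
    if not (mut.columns.symmetric_difference(cnv.columns)).empty:
        logger.info("DNA gene sets differ; zero-filling to union of %d genes",
                    len(dna_genes))
    mut_a = mut.reindex(columns=dna_genes, fill_value=0.0)
    cnv_a = cnv.reindex(columns=dna_genes, fill_value=0.0)
    blocks = [rna.loc[shared].add_prefix("rna:"),
              mut_a.loc[shared].add_prefix("mut:"),
              cnv_a.loc[shared].add_prefix("cnv:")]
    out = pd.concat(blocks, axis=1)
    logger.info("assembled %d samples x %d features", *out.shape)
    return out


def split_train_test(X: pd.DataFrame, y: pd.Series, test_fraction: float = 0.2,
                     seed: int = 0):
    """Stratified, seeded train/test split of the labelled cohort.

    Subtypes represented by a single sample stay entirely in the training
    partition (with a warning) so stratification remains well defined.
    Returns (X_train, y_train, X_test, y_test).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = y.loc[X.index]
    counts = y.value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(
            f"subtype(s) {list(singletons)} have a single sample; "
            "kept entirely in the training set", UserWarning)
    splittable = ~y.isin(singletons)
    X_s, y_s = X.loc[splittable], y.loc[splittable]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X_s, y_s, test_size=test_fraction, stratify=y_s, random_state=seed)
    if len(singletons):
        X_tr = pd.concat([X_tr, X.loc[~splittable]])
        y_tr = pd.concat([y_tr, y.loc[~splittable]])
    return X_tr, y_tr, X_te, y_te


def encode_labels(labels: pd.Series) -> tuple[np.ndarray, dict[str, int]]:
    """Map subtype names to stable integer codes (sorted name order)."""
    mapping = {name: i for i, name in enumerate(sorted(labels.unique()))}
    return labels.map(mapping).to_numpy(dtype=int), mapping
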