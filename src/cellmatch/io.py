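"""Readers/writers for the TSV interchange formats and model checkpoints.

TSV is the primary interchange so every artefact stays inspectable at desk
scale: matrices carry a header row of gene identifiers and a first column of
sample identifiers; networks are two/three-column edge lists or SIF. A
checkpoint is a single .npz archive bundling weights, the model config, the
feature scaling statistics, the label dictionary and the diffusion
parameters, so prediction on new samples is self-contained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ScalingStats
from .model import ModelConfig, SemiSupervisedVAE
from .netsmooth import GeneNetwork

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = "1"

__all__ = ["read_matrix", "write_matrix", "read_network", "read_labels",
           "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION"]


def read_matrix(path: str | Path, kind: str = "numeric") -> pd.DataFrame:
    """Read a samples x genes TSV (gzip transparent, any line endings).

    ``kind="binary"`` additionally checks that all entries are 0/1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric value at sample {bad!r}, gene {col!r} in {path}")
    if kind == "binary" and not np.isin(df.to_numpy(), (0, 1)).all():
        raise ValueError(f"matrix {path} is not binary")
    logger.info("read %s: %d samples x %d features", path, *df.shape)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_network(path: str | Path) -> GeneNetwork:
    """Edge-list TSV (2 or 3 columns) or SIF (node relation node)."""
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if is_sif:
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: SIF needs 3 columns")
            edges.append((parts[0], parts[2]))
        elif len(parts) == 2:
            edges.append((parts[0], parts[1]))
        elif len(parts) >= 3:
            edges.append((parts[0], parts[1], float(parts[2])))
        else:
            raise ValueError(f"{path}:{line_no}: need at least 2 columns")
    net = GeneNetwork.from_edges(edges)
    logger.info("read network %s: %d nodes, %d edges", path,
                net.n_nodes, net.n_edges)
    return net


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV: sample_id <tab> subtype_name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"labels file {path} needs two columns")
    s = df.iloc[:, 0].astype(str)
    if s.index.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    return s


def save_checkpoint(path: str | Path, model: SemiSupervisedVAE,
                    scaling: ScalingStats | None = None,
                    label_mapping: dict[str, int] | None = None,
                    diffusion_params: dict | None = None) -> None:
    """Bundle weights and companion metadata into one .npz archive."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": model.config.to_dict(),
        "is_trained": model.is_trained,
        "scaling": scaling.to_dict() if scaling is not None else None,
        "label_mapping": label_mapping,
        "diffusion_params": diffusion_params,
    }
    arrays = {k: v for k, v in model.get_weights().items()}
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> dict:
    """Restore a checkpoint; forward outputs reproduce bit-for-bit.

    Returns a dict with keys: model, scaling, label_mapping,
    diffusion_params.
    """
    with np.load(path, allow_pickle=False) as npz:
        if "_meta" not in npz:
            raise ValueError(f"{path} is not a cellmatch checkpoint")
        meta = json.loads(str(npz["_meta"]))
        version = meta.get("version")
        if version != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {version!r} is not supported "
                f"(expected {CHECKPOINT_VERSION!r})")
        required = ("model_config", "is_trained")
        for key in required:
            if key not in meta or meta[key] is None:
                raise ValueError(f"checkpoint missing component {key!r}")
        model = SemiSupervisedVAE(ModelConfig.from_dict(meta["model_config"]))
        model.set_weights({k: npz[k] for k in npz.files if k != "_meta"})
        model.is_trained = bool(meta["is_trained"])
    scaling = (ScalingStats.from_dict(meta["scaling"])
               if meta.get("scaling") else None)
    return {"model": model, "scaling": scaling,
            "label_mapping": meta.get("label_mapping"),
            "diffusion_params": meta.get("diffusion_params")}
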