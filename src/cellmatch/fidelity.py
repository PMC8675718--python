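"""Cell-line-to-tumour fidelity scoring in the latent space.

The dissimilarity between a cell line c and a tumour t is one minus the
cosine of the angle between their latent representations,

    d(c, t) = 1 - (z_c . z_t) / (||z_c|| ||z_t||),

ranging from 0 (perfectly aligned) through 1 (orthogonal) to 2 (antipodal).
Embeddings use the posterior mean mu(x), never a draw, so a published
dissimilarity matrix is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["latent_embedding", "cosine_dissimilarity", "order_by_clustering",
           "best_cell_lines"]


def latent_embedding(model, X: np.ndarray, index=None) -> pd.DataFrame:
    """Posterior means mu(x), one row per sample, columns z1..zd."""
    if not model.is_trained:
        raise RuntimeError("model has not been trained")
    mu, _ = model.encode(X)
    cols = [f"z{i + 1}" for i in range(mu.shape[1])]
    return pd.DataFrame(mu, index=index, columns=cols)


def _unit_rows(Z: pd.DataFrame, role: str) -> np.ndarray:
    V = Z.to_numpy(dtype=float)
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        bad = Z.index[norms == 0][0]
        raise ValueError(f"zero-norm latent vector for {role} {bad!r}")
    return V / norms[:, None]


def cosine_dissimilarity(Z_cell: pd.DataFrame, Z_tumour: pd.DataFrame
                         ) -> pd.DataFrame:
    """Cell-lines x tumours matrix of d(c, t) in [0, 2]."""
    U = _unit_rows(Z_cell, "cell line")
    V = _unit_rows(Z_tumour, "tumour")
    D = 1.0 - U @ V.T
    return pd.DataFrame(np.clip(D, 0.0, 2.0),
                        index=Z_cell.index, columns=Z_tumour.index)


def _leaf_order(M: np.ndarray) -> np.ndarray:
    if len(M) < 2:
        return np.arange(len(M))
    return leaves_list(linkage(pdist(M, metric="cosine"), method="average"))


def order_by_clustering(D: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage leaf orders for heatmap rows and columns.

    Rows (cell lines) and columns (tumours) are clustered separately on the
    pairwise cosine distance of their dissimilarity profiles; deterministic.
    """
    if not np.isfinite(D.to_numpy()).all():
        raise ValueError("dissimilarity matrix contains non-finite values")
    return _leaf_order(D.to_numpy()), _leaf_order(D.to_numpy().T)


def best_cell_lines(D: pd.DataFrame, query: str, k: int = 5,
                    tumour_subtypes: pd.Series | None = None) -> pd.DataFrame:
    """Top-k cell lines for a tumour or a subtype, most similar first.

    A tumour query ranks by d(c, t); a subtype query ranks by the mean
    dissimilarity over that subtype's tumours. Ties break by cell-line
    identifier.
    """
    if query in D.columns:
        scores = D[query]
    elif tumour_subtypes is not None and (tumour_subtypes == query).any():
        cols = tumour_subtypes.index[tumour_subtypes == query]
        cols = D.columns.intersection(cols)
        if len(cols) == 0:
            raise KeyError(f"subtype {query!r} has no tumours in the matrix")
        scores = D[cols].mean(axis=1)
    else:
        raise KeyError(f"unknown tumour or subtype query {query!r}")
    # sort by identifier first, then stably by score: ties break by id
    ranked = scores.to_frame("dissimilarity").sort_index()
    ranked = ranked.sort_values("dissimilarity", kind="mergesort")
    return ranked.head(k)
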