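"""Network smoothing of binary mutation / CNV matrices.

Sparse per-gene alteration indicators are diffused over a gene-interaction
network by a random walk with restart,

    F_{k+1} = alpha * F_k @ W + (1 - alpha) * F0,

where W is the symmetrically degree-normalised adjacency D^{-1/2} A D^{-1/2}.
The fixed point equals the closed form (1 - alpha) * F0 @ (I - alpha W)^{-1},
so a signal hitting a single gene spreads to its network neighbourhood and
the very sparse binary matrices become dense, network-informed DNA features.
After smoothing, each gene is min-max rescaled to [0, 1] across samples and
the scaling statistics are retained for reuse on query cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["GeneNetwork", "SmoothedMatrix", "normalize_adjacency",
           "propagate", "smooth_matrix", "smooth_alterations"]


class GeneNetwork:
    """Undirected gene graph with optional positive edge weights.

    Self-loops are dropped on construction and duplicate edges collapse;
    node order is sorted for determinism.
    """

    def __init__(self, graph: nx.Graph):
        n_loops = nx.number_of_selfloops(graph)
        if n_loops:
            graph = graph.copy()
            graph.remove_edges_from(nx.selfloop_edges(graph))
            logger.warning("dropped %d self-loop(s) from network", n_loops)
        self.graph = graph
        self.nodes: list[str] = sorted(graph.nodes)

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "GeneNetwork":
        """Build from (u, v) or (u, v, weight) tuples, plus optional extra nodes."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for e in edges:
            if len(e) == 3:
                u, v, w = e
                w = float(w)
                if w <= 0:
                    raise ValueError(f"edge weight must be positive: {e}")
                g.add_edge(u, v, weight=w)
            else:
                u, v = e
                g.add_edge(u, v, weight=1.0)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (self.nodes == other.nodes
                and nx.utils.graphs_equal(self.graph, other.graph))


@dataclass
class SmoothedMatrix:
    """Dense DNA-view features after diffusion and per-gene rescaling."""

    values: pd.DataFrame          # samples x genes, in [0, 1]
    modality: str                 # "mutation" or "cnv"
    diffusion_params: dict
    scaling_min: pd.Series
    scaling_max: pd.Series
    n_iter: int = 0


def normalize_adjacency(network: GeneNetwork) -> sp.csr_matrix:
    """Symmetric normalisation W = D^{-1/2} A D^{-1/2}; isolated nodes get zero rows."""
    if network.n_nodes == 0 or network.n_edges == 0:
        raise ValueError("network must have at least one edge")
    A = nx.to_scipy_sparse_array(network.graph, nodelist=network.nodes,
                                 weight="weight", format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    D = sp.diags(dinv)
    return sp.csr_matrix(D @ A @ D)


def propagate(F0: np.ndarray, W: sp.spmatrix, alpha: float = 0.5,
              tol: float = 1e-6, max_iter: int = 1000
              ) -> tuple[np.ndarray, int]:
    """Iterate the restart diffusion to its fixed point.

    Returns the smoothed matrix and the iteration count. If the row-wise
    maximum change has not dropped below ``tol`` within ``max_iter``, a
    warning reports the final residual and the current iterate is returned.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    F0 = np.asarray(F0, dtype=float)
    F = F0.copy()
    restart = (1.0 - alpha) * F0
    for it in range(1, max_iter + 1):
        F_next = alpha * (F @ W) + restart
        resid = np.abs(F_next - F).max(initial=0.0)
        F = F_next
        if resid < tol:
            return F, it
    warnings.warn(
        f"diffusion did not converge in {max_iter} iterations "
        f"(residual {resid:.3e})", RuntimeWarning)
    return F, max_iter


def _minmax_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    lo = df.min(axis=0)
    hi = df.max(axis=0)
    span = hi - lo
    scaled = (df - lo).div(span.where(span > 0, 1.0), axis=1)
    scaled.loc[:, span == 0] = 0.0
    return scaled, lo, hi


def smooth_matrix(mat: pd.DataFrame, network: GeneNetwork, W: sp.csr_matrix,
                  modality: str, alpha: float, tol: float, max_iter: int,
                  off_network: str,
                  scaling: tuple[pd.Series, pd.Series] | None = None
                  ) -> SmoothedMatrix:
    """Diffuse one modality and rescale columns to [0, 1].

    ``scaling=(min, max)`` reuses training extrema (query mode, clamped)
    instead of refitting them on ``mat``.
    """
    genes = list(mat.columns)
    net_index = {g: i for i, g in enumerate(network.nodes)}
    on_net = [g for g in genes if g in net_index]
    off_net = [g for g in genes if g not in net_index]
    logger.info("%s: %d/%d genes on network", modality, len(on_net), len(genes))

    if not on_net:
        if off_network == "drop":
            raise ValueError(
                f"{modality}: no genes overlap the network (strict mode)")
        warnings.warn(
            f"{modality}: no genes overlap the network; passing all "
            "features through unsmoothed", RuntimeWarning)

    n_iter = 0
    smoothed_cols = {}
    if on_net:
        # seed the full network so signal can flow through unmeasured genes,
        # then read back only the measured columns
        F0 = np.zeros((len(mat), len(network.nodes)))
        cols = [net_index[g] for g in on_net]
        F0[:, cols] = mat[on_net].to_numpy(dtype=float)
        F, n_iter = propagate(F0, W, alpha=alpha, tol=tol, max_iter=max_iter)
        for g, c in zip(on_net, cols):
            smoothed_cols[g] = F[:, c]

    out = pd.DataFrame(index=mat.index)
    for g in genes:
        if g in smoothed_cols:
            out[g] = smoothed_cols[g]
        elif off_network == "keep":
            out[g] = mat[g].to_numpy(dtype=float)
    if scaling is None:
        scaled, lo, hi = _minmax_columns(out)
    else:
        lo, hi = scaling[0][out.columns], scaling[1][out.columns]
        span = hi - lo
        scaled = ((out - lo).div(span.where(span > 0, 1.0), axis=1)
                  .clip(0.0, 1.0))
        scaled.loc[:, (span == 0).to_numpy()] = 0.0
    return SmoothedMatrix(
        values=scaled, modality=modality,
        diffusion_params={"alpha": alpha, "tol": tol, "max_iter": max_iter,
                          "off_network": off_network},
        scaling_min=lo, scaling_max=hi, n_iter=n_iter)


def _check_binary(mat: pd.DataFrame, name: str) -> None:
    vals = mat.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} matrix must be strictly binary (0/1)")
    if mat.index.has_duplicates or mat.columns.has_duplicates:
        raise ValueError(f"{name} matrix has duplicate sample or gene ids")


def smooth_alterations(mutations: pd.DataFrame, cnv: pd.DataFrame,
                       network: GeneNetwork, alpha: float = 0.5,
                       tol: float = 1e-6, max_iter: int = 1000,
                       off_network: str = "keep"
                       ) -> tuple[SmoothedMatrix, SmoothedMatrix]:
    """Smooth both DNA modalities independently over the same network.

    Samples are restricted to the intersection of the two matrices (logged).
    Genes absent from the network pass through unsmoothed by default
    (``off_network="keep"``); ``"drop"`` discards them.
    """
    if off_network not in ("keep", "drop"):
        raise ValueError("off_network must be 'keep' or 'drop'")
    _check_binary(mutations, "mutation")
    _check_binary(cnv, "cnv")
    shared = mutations.index.intersection(cnv.index)
    if len(shared) < len(mutations) or len(shared) < len(cnv):
        logger.info("sample intersection: %d (mutations %d, cnv %d)",
                    len(shared), len(mutations), len(cnv))
    if len(shared) == 0:
        raise ValueError("mutation and cnv matrices share no samples")
    W = normalize_adjacency(network)
    sm_mut = smooth_matrix(mutations.loc[shared], network, W, "mutation",
                           alpha, tol, max_iter, off_network)
    sm_cnv = smooth_matrix(cnv.loc[shared], network, W, "cnv",
                           alpha, tol, max_iter, off_network)
    return sm_mut, sm_cnv
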