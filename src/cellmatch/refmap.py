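"""Reference-map geometry: corner layout and sample projection.

Each latent component becomes a corner of a 2D map. Component-to-component
distances are Euclidean distances between their standardized profile vectors
across the training tumours; classical (Torgerson) multidimensional scaling
places the h corners in the plane. A sample is then drawn as a superposition
of the corner positions weighted by its (non-negatively rescaled, sharpened)
latent component values, so every sample lands inside the corners' convex
hull. Corners are fit once on tumours and reused unchanged when cell lines
are projected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = ["ReferenceMap", "component_distance_matrix", "mds_corners",
           "project_samples", "density_summary", "build_reference_map"]


@dataclass
class ReferenceMap:
    corner_coords: np.ndarray        # h x 2, column-centred
    component_distances: np.ndarray  # h x h, symmetric, zero diagonal
    stress: float
    training_sample_coords: pd.DataFrame  # columns x, y, subtype


def component_distance_matrix(Z_train: np.ndarray,
                              metric: str = "euclidean") -> np.ndarray:
    """Distances between latent components as profiles over training samples.

    ``"euclidean"`` (default): Euclidean distance between z-scored columns;
    ``"correlation"``: 1 - Pearson correlation between columns.
    """
    Z = np.atleast_2d(np.asarray(Z_train, dtype=float))
    n, h = Z.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant latent component(s); "
            "standardization skipped for them", RuntimeWarning)
    U = (Z - mean) / np.where(constant, 1.0, sd)
    if metric == "euclidean":
        diff = U.T[:, None, :] - U.T[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
    elif metric == "correlation":
        D = 1.0 - (U.T @ U) / n
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    return 0.5 * (D + D.T)


def mds_corners(distmat: np.ndarray) -> tuple[np.ndarray, float]:
    """Classical MDS of the component distances to 2D corner coordinates.

    Deterministic: eigendecomposition with a fixed sign convention (corner 1
    has non-negative x, corner 2 non-negative y). Returns centred coords and
    the residual stress sqrt(sum (d_fit - d)^2 / sum d^2).
    """
    D = np.asarray(distmat, dtype=float)
    h = len(D)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if h < 3:
        warnings.warn("fewer than 3 components; corners placed on a line",
                      RuntimeWarning)
    J = np.eye(h) - np.full((h, h), 1.0 / h)
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < 2:  # h == 1 degenerate
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    coords = coords - coords.mean(axis=0)
    if coords[0, 0] < 0:
        coords[:, 0] *= -1
    if h > 1 and coords[1, 1] < 0:
        coords[:, 1] *= -1
    fit = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (D ** 2).sum()
    stress = float(np.sqrt(((fit - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    return coords, stress


def project_samples(Z: np.ndarray, corners: np.ndarray,
                    power: float = 2.0) -> np.ndarray:
    """Corner-weighted superposition coordinates for each sample.

    Weights are the per-sample min-max rescaled component values raised to
    ``power`` and normalised to sum one; a sample with all-equal components
    sits at the corner centroid.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    corners = np.asarray(corners, dtype=float)
    if Z.shape[1] != len(corners):
        raise ValueError("latent dimension does not match corner count")
    lo = Z.min(axis=1, keepdims=True)
    hi = Z.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    w = np.where(span > 0, (Z - lo) / np.where(span > 0, span, 1.0), 1.0)
    w = w ** power
    totals = w.sum(axis=1, keepdims=True)
    w = np.where(totals > 0, w / np.where(totals > 0, totals, 1.0),
                 1.0 / Z.shape[1])
    w[flat] = 1.0 / Z.shape[1]
    return w @ corners


def density_summary(sample_coords: np.ndarray, labels: pd.Series | np.ndarray,
                    grid_size: int = 50) -> dict[str, dict]:
    """Per-subtype Gaussian KDE on a shared grid, each integrating to one.

    Subtypes with fewer than 2 samples (or a degenerate point cloud) are
    skipped with a warning. Returns {subtype: {x, y, density}}.
    """
    coords = np.atleast_2d(np.asarray(sample_coords, dtype=float))
    labels = pd.Series(np.asarray(labels), index=range(len(coords)))
    pad = 0.05 * (coords.max(axis=0) - coords.min(axis=0) + 1e-9)
    xs = np.linspace(coords[:, 0].min() - pad[0], coords[:, 0].max() + pad[0],
                     grid_size)
    ys = np.linspace(coords[:, 1].min() - pad[1], coords[:, 1].max() + pad[1],
                     grid_size)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid_pts = np.vstack([gx.ravel(), gy.ravel()])
    cell_area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    out: dict[str, dict] = {}
    for subtype in sorted(pd.unique(labels)):
        pts = coords[labels.to_numpy() == subtype]
        if len(pts) < 2:
            warnings.warn(f"subtype {subtype!r} has <2 samples; skipped",
                          RuntimeWarning)
            continue
        try:
            kde = gaussian_kde(pts.T)
        except np.linalg.LinAlgError:
            warnings.warn(f"subtype {subtype!r} has a degenerate point "
                          "cloud; skipped", RuntimeWarning)
            continue
        dens = kde(grid_pts).reshape(grid_size, grid_size)
        total = dens.sum() * cell_area
        if total > 0:
            dens = dens / total
        out[subtype] = {"x": xs, "y": ys, "density": dens}
    return out


def build_reference_map(Z_train: pd.DataFrame, labels: pd.Series,
                        power: float = 2.0) -> ReferenceMap:
    """Fit the full tumour-derived map: distances, corners, projections."""
    Z = Z_train.to_numpy(dtype=float)
    distmat = component_distance_matrix(Z)
    corners, stress = mds_corners(distmat)
    coords = project_samples(Z, corners, power=power)
    df = pd.DataFrame(coords, index=Z_train.index, columns=["x", "y"])
    df["subtype"] = labels.loc[Z_train.index].to_numpy()
    return ReferenceMap(corner_coords=corners, component_distances=distmat,
                        stress=stress, training_sample_coords=df)
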