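"""Classical (Torgerson) multidimensional scaling of the network
dissimilarity matrix into a low-dimensional representation.

CMDS double-centers the squared dissimilarities, eigendecomposes the
resulting Gram matrix and scales the leading eigenvectors by the square
roots of their eigenvalues. For Euclidean-realizable dissimilarities the
original configuration is recovered exactly up to a rigid transform.
Negative eigenvalues (1 - A matrices are generally non-Euclidean) are
truncated and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Embedding3D:
    """CMDS embedding: coordinates (one row per item, axes ordered by
    descending eigenvalue, centroid at the origin), the full eigenvalue
    spectrum, and the fraction of positive-eigenvalue mass captured."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    positive_mass_fraction: float


def classical_mds(dissimilarity: pd.DataFrame, k: int = 3) -> Embedding3D:
    """Embed a symmetric, zero-diagonal, non-negative dissimilarity
    matrix into ``k`` dimensions.

    Axis signs are fixed deterministically: the largest-|coordinate|
    entry of each axis is made positive. If fewer than ``k`` eigenvalues
    are positive, fewer axes are returned with a warning.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        ids = dissimilarity.index
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        ids = pd.RangeIndex(d.shape[0])
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("dissimilarity must be non-negative")
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(n, 1) * np.abs(eigvals).max() * 1e-12 if eigvals.size else 0.0
    n_pos = int((eigvals > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {k_eff} axis/axes instead of {k}",
            stacklevel=2,
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    for axis in range(k_eff):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_mass = float(eigvals[eigvals > tol].sum())
    captured = float(eigvals[:k_eff].sum()) / pos_mass if pos_mass > 0 else 0.0
    frame = pd.DataFrame(coords, index=ids, columns=[f"axis{i + 1}" for i in range(k_eff)])
    return Embedding3D(coordinates=frame, eigenvalues=eigvals, positive_mass_fraction=captured)


def plot_embedding(embedding: Embedding3D, colors: pd.Series | None = None, path: str | None = None):
    """Static 3-D scatter of an embedding, optionally colored by module."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="3d")
    c = colors.reindex(coords.index).fillna("grey") if colors is not None else "steelblue"
    xyz = [coords.iloc[:, i] if coords.shape[1] > i else np.zeros(len(coords)) for i in range(3)]
    ax.scatter(*xyz, c=list(c) if colors is not None else c, s=8, alpha=0.7)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.set_zlabel("axis 3")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
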