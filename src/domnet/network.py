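"""Signed weighted correlation network: Pearson similarity, soft
thresholding, scale-free topology fit, module detection and module
eigenvalues (eigengenes).

The adjacency between two molecular features i and j is

    A_ij = (0.5 * (1 + cor_ij)) ** p

with ``cor`` the Pearson correlation of their relative-abundance
profiles across samples and ``p`` the soft-thresholding power (default
9). Anticorrelated features thus receive near-zero edge weights, which
makes the network *signed*. Modules are found by average-linkage
hierarchical clustering of node dissimilarities and named by size rank
using the conventional color palette; "grey" collects unassigned
features. Each module is summarised per sample by its eigenvalue
vector, the first principal component of the module's standardized
feature profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

#: Conventional module color order by descending module size; "grey" is
#: reserved for unassigned features.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
GREY = "grey"


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of network construction and module detection."""

    power: float = 9.0
    dissimilarity: str = "adjacency"  # "adjacency" (1 - A) or "tom" (1 - TOM)
    linkage_method: str = "average"
    min_module_size: int = 30
    cut_method: str = "height"  # "height" or "maxclust"
    cut_height_fraction: float = 0.995  # fraction of the tree's max merge height
    n_clusters: int = 10  # used only by the "maxclust" cut

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("soft-thresholding power must be positive")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be at least 2")
        if self.dissimilarity not in ("adjacency", "tom"):
            raise ValueError(f"unknown dissimilarity mode {self.dissimilarity!r}")
        if self.cut_method not in ("height", "maxclust"):
            raise ValueError(f"unknown cut method {self.cut_method!r}")


@dataclass
class ModuleSet:
    """Per-feature module assignment. ``labels`` maps feature id to a
    module color (size-ranked); grey features belong to no module."""

    labels: pd.Series

    @property
    def colors(self) -> list[str]:
        """Module colors, largest module first, grey excluded."""
        sizes = self.labels[self.labels != GREY].value_counts()
        return [c for c in MODULE_COLORS if c in sizes.index] + [
            c for c in sizes.index if c not in MODULE_COLORS
        ]

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, color: str) -> pd.Index:
        return self.labels.index[self.labels == color]


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all feature pairs (rows of ``matrix``).

    Zero-variance features have undefined correlations; they are dropped
    with a warning before computing the matrix.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate features")
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = matrix.index[~keep].tolist()
        warnings.warn(
            f"excluding {len(dropped)} zero-variance feature(s) from the correlation matrix",
            stacklevel=2,
        )
    ids = matrix.index[keep]
    cor = np.atleast_2d(np.corrcoef(values[keep]))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=ids, columns=ids)


def signed_adjacency(cor: pd.DataFrame, power: float = 9.0) -> pd.DataFrame:
    """Soft-thresholded signed adjacency A = (0.5 * (1 + cor)) ** power."""
    if power <= 0:
        raise ValueError("soft-thresholding power must be positive")
    values = cor.to_numpy(dtype=float) if isinstance(cor, pd.DataFrame) else np.asarray(cor, dtype=float)
    if values.size and (values.min() < -1 - 1e-12 or values.max() > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    adj = (0.5 * (1.0 + values)) ** power
    adj = np.clip(adj, 0.0, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix (unsigned TOM) of an adjacency matrix."""
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass(frozen=True)
class ScaleFreeFit:
    """Goodness of the scale-free topology fit: R^2 and slope of the
    log10 p(k) ~ log10 k regression over binned connectivities."""

    r_squared: float
    slope: float
    n_bins: int


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} A_ij."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adjacency.index, name="k")


def scale_free_fit_from_connectivity(k, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10 p(k) ~ log10 <k> over equal-width connectivity bins."""
    k = np.asarray(k, dtype=float)
    if k.size == 0:
        raise ValueError("empty connectivity vector")
    lo, hi = k.min(), k.max()
    if hi <= lo:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            means.append(k[mask].mean())
            freqs.append(mask.sum() / k.size)
    if len(means) < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins; fit undefined")
    res = linregress(np.log10(means), np.log10(freqs))
    return ScaleFreeFit(r_squared=float(res.rvalue**2), slope=float(res.slope), n_bins=len(means))


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of a network from its adjacency matrix."""
    return scale_free_fit_from_connectivity(connectivity(adjacency).to_numpy(), n_bins)


def detect_modules(adjacency: pd.DataFrame, params: NetworkParams = NetworkParams()) -> ModuleSet:
    """Cluster node dissimilarities into modules.

    Dissimilarity is 1 - A by default (1 - TOM optionally); the
    agglomerative tree is cut either at a constant height (a fraction of
    the maximum merge height) or into a fixed number of clusters.
    Clusters smaller than ``min_module_size`` are labelled grey; the
    rest are named by descending size using the conventional palette.
    """
    ids = adjacency.index
    n = len(ids)
    if params.min_module_size > n:
        warnings.warn("min_module_size exceeds the number of features; all grey", stacklevel=2)
        return ModuleSet(labels=pd.Series(GREY, index=ids, name="module"))
    if params.dissimilarity == "tom":
        diss = 1.0 - topological_overlap(adjacency).to_numpy()
    else:
        diss = 1.0 - adjacency.to_numpy(dtype=float)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    tree = linkage(squareform(diss, checks=False), method=params.linkage_method)
    if params.cut_method == "maxclust":
        raw = fcluster(tree, t=params.n_clusters, criterion="maxclust")
    else:
        height = params.cut_height_fraction * tree[:, 2].max()
        raw = fcluster(tree, t=height, criterion="distance")
    labels = pd.Series(raw, index=ids)
    sizes = labels.value_counts()
    kept = sizes[sizes >= params.min_module_size].sort_values(ascending=False)
    color_of = {}
    for rank, cluster_id in enumerate(kept.index):
        color_of[cluster_id] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    named = labels.map(lambda c: color_of.get(c, GREY))
    named.name = "module"
    return ModuleSet(labels=named)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return (values - mean) / std


@dataclass
class ModuleEigenvalues:
    """Module x sample eigenvalue matrix with per-module variance
    explained by the first principal component."""

    scores: pd.DataFrame
    variance_explained: pd.Series


def module_eigenvalues(matrix: pd.DataFrame, modules: ModuleSet) -> ModuleEigenvalues:
    """First-principal-component sample scores (eigenvalues) per module.

    Each module's features are standardized across samples; the
    eigenvalue vector is the first right singular vector of that block,
    scaled by sqrt(n_samples) so a rank-1 module returns its common
    standardized profile exactly. Signs are oriented so each vector
    correlates positively with the module's mean standardized profile.
    """
    n_samples = matrix.shape[1]
    rows, varexp = {}, {}
    for color in modules.colors:
        members = modules.members(color)
        members = members.intersection(matrix.index)
        block = _standardize_rows(matrix.loc[members].to_numpy(dtype=float))
        if block.shape[0] == 1:
            warnings.warn(f"module {color!r} has a single feature; returning its profile", stacklevel=2)
            rows[color] = block[0]
            varexp[color] = 1.0
            continue
        _, s, vt = np.linalg.svd(block, full_matrices=False)
        scores = np.sqrt(n_samples) * vt[0]
        mean_profile = block.mean(axis=0)
        if np.dot(scores, mean_profile) < 0:
            scores = -scores
        rows[color] = scores
        total = float((s**2).sum())
        varexp[color] = float(s[0] ** 2 / total) if total > 0 else 0.0
    scores_df = pd.DataFrame(rows, index=matrix.columns).T
    scores_df.index.name = "module"
    return ModuleEigenvalues(
        scores=scores_df, variance_explained=pd.Series(varexp, name="variance_explained")
    )


def to_graph(adjacency: pd.DataFrame, modules: ModuleSet | None = None, edge_threshold: float = 0.0) -> nx.Graph:
    """Build a weighted graph keeping edges with A >= ``edge_threshold``."""
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError("edge threshold must lie in [0, 1]")
    g = nx.Graph()
    ids = list(adjacency.index)
    labels = modules.labels if modules is not None else None
    for node in ids:
        g.add_node(str(node), module=str(labels[node]) if labels is not None else "")
    a = adjacency.to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(ids), k=1)
    keep = a[ii, jj] >= edge_threshold
    for i, j in zip(ii[keep], jj[keep]):
        g.add_edge(str(ids[i]), str(ids[j]), weight=float(a[i, j]))
    return g


def export_network(
    adjacency: pd.DataFrame,
    modules: ModuleSet | None = None,
    edge_threshold: float = 0.0,
    path: str | None = None,
) -> nx.Graph:
    """Export the thresholded network as GraphML (``.graphml``) or a
    3-column weighted edge list (any other extension)."""
    g = to_graph(adjacency, modules, edge_threshold)
    if path is not None:
        if str(path).endswith(".graphml"):
            nx.write_graphml(g, path)
        else:
            with open(path, "w") as fh:
                fh.write("source\ttarget\tweight\n")
                for u, v, data in g.edges(data=True):
                    fh.write(f"{u}\t{v}\t{data['weight']:.12g}\n")
    return g
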