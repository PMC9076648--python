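"""Convergence/divergence statistics: PCA trajectories of sample groups
over time and the percent change of between-group Euclidean
dissimilarity from the first to the last time point.

A positive percent change means the groups (litter types) diverged over
the decomposition series; a negative one means their profiles converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    """Sample scores, variance-explained fractions and per-group
    time-ordered centroid paths from a covariance PCA."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    paths: dict[str, pd.DataFrame]  # group -> day-ordered centroid path


def pca_trajectories(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_components: int = 2,
    group_col: str = "litter",
    day_col: str = "day",
) -> PCAResult:
    """PCA of samples (columns of ``matrix``) on the feature covariance,
    with per-group trajectories of the score centroids ordered by day.
    """
    if n_components < 2:
        raise ValueError("request at least 2 components")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating", stacklevel=2
        )
        n_components = rank
    total_var = float((s**2).sum())
    varexp = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[scores.index]
    paths = {}
    for group, sub in meta.groupby(group_col):
        centroids = (
            scores.loc[sub.index]
            .groupby(sub[day_col])
            .mean()
            .sort_index()
        )
        centroids.index.name = day_col
        paths[str(group)] = centroids
    return PCAResult(scores=scores, variance_explained=varexp, paths=paths)


@dataclass
class DistanceTrend:
    """Between-group Euclidean distances per time point.

    ``distances`` holds one row per (day, group pair); ``per_day`` the
    mean over pairs per day; ``percent_change`` is
    100 * (d_final - d_initial) / d_initial on those means.
    """

    distances: pd.DataFrame
    per_day: pd.Series
    percent_change: float
    mode: str


def _group_vectors(matrix: pd.DataFrame, samples: pd.Index) -> np.ndarray:
    return matrix[samples].to_numpy(dtype=float).T  # samples x features


def group_distance_trend(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "litter",
    day_col: str = "day",
    mode: str = "full",
) -> DistanceTrend:
    """Pairwise between-group Euclidean distance at every time point.

    ``mode="centroid"`` measures the distance between group centroids;
    ``mode="full"`` averages the distances over all cross-group sample
    pairs. Every group must be present at the first and last day.
    """
    if mode not in ("full", "centroid"):
        raise ValueError(f"unknown distance mode {mode!r}")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[matrix.columns]
    days = sorted(meta[day_col].unique())
    groups = sorted(meta[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for day in (days[0], days[-1]):
        present = set(meta.loc[meta[day_col] == day, group_col])
        absent = [g for g in groups if g not in present]
        if absent:
            raise ValueError(f"group(s) {absent} absent at required day {day}")
    rows = []
    for day in days:
        sub = meta[meta[day_col] == day]
        members = {g: sub.index[sub[group_col] == g] for g in groups if (sub[group_col] == g).any()}
        present = sorted(members)
        for i, ga in enumerate(present):
            for gb in present[i + 1 :]:
                va = _group_vectors(matrix, members[ga])
                vb = _group_vectors(matrix, members[gb])
                if mode == "centroid":
                    dist = float(np.linalg.norm(va.mean(axis=0) - vb.mean(axis=0)))
                else:
                    diffs = va[:, None, :] - vb[None, :, :]
                    dist = float(np.linalg.norm(diffs, axis=2).mean())
                rows.append({"day": day, "pair": f"{ga}-{gb}", "distance": dist})
    distances = pd.DataFrame(rows)
    per_day = distances.groupby("day")["distance"].mean()
    d0, d1 = per_day.loc[days[0]], per_day.loc[days[-1]]
    if d0 <= 0:
        raise ValueError("initial between-group distance is zero; percent change undefined")
    change = 100.0 * (d1 - d0) / d0
    return DistanceTrend(distances=distances, per_day=per_day, percent_change=float(change), mode=mode)
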