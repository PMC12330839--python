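"""Trajectory clustering: PAM over squared-difference dissimilarities.

Significant pairs' demeaned asymmetry trajectories are compared by the sum
of squared differences over a common age grid, clustered by the classical
Partition Around Medoids algorithm (BUILD + SWAP on the provided
dissimilarities, deterministic, ties broken by lowest item index), with the
cluster count chosen by mean silhouette width over k = 2..7.  For a
two-cluster solution the crossover age is the first intersection of the two
cluster-mean trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples


class ClusterError(ValueError):
    pass


def trajectory_dissimilarity(curves: pd.DataFrame) -> pd.DataFrame:
    """Sum-of-squared-differences dissimilarity between trajectory curves.

    ``curves``: one column per item (pair), one row per grid age; all
    columns must share the same grid (the row index).  Note squared
    distances do not satisfy the triangle inequality; PAM and silhouette
    use them directly, as provided.
    """
    x = np.asarray(curves, dtype=float).T  # items x grid
    if np.isnan(x).any():
        raise ClusterError("curves contain missing values")
    sq = np.sum(x**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=curves.columns, columns=curves.columns)


def _pam_build(d: np.ndarray, k: int, first: int | None = None) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1))) if first is None else int(first)]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, -1
        dist_to_med = d[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.sum(np.maximum(dist_to_med - d[:, j], 0.0))
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    return sorted(medoids)


def _pam_swap(d: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = d.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        current = d[:, medoids].min(axis=1).sum()
        best_delta, best_pair = -1e-12, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                cost = d[:, trial].min(axis=1).sum()
                delta = current - cost
                if delta > best_delta + 1e-12:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
    return sorted(medoids)


def pam(d: np.ndarray, k: int) -> tuple[np.ndarray, list[int], float]:
    """PAM (BUILD + SWAP) with deterministic multi-start.

    Single-start BUILD + SWAP — the classical algorithm — is a steepest
    -descent heuristic and lands in a local optimum on a non-negligible
    fraction of small problems (the reference R implementation behaves
    identically).  Here BUILD is restarted from every possible first medoid
    and the lowest-cost SWAP result is kept; deterministic, ties broken
    toward the lowest item index, and at this package's problem sizes (tens
    of trajectories) the extra factor of n is negligible.

    Returns ``(labels, medoid_indices, total_cost)``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if not 1 <= k < n:
        raise ClusterError(f"k={k} invalid for {n} items")
    best_cost, best_medoids = np.inf, None
    for first in range(n):
        medoids = _pam_swap(d, _pam_build(d, k, first=first))
        cost = float(d[:, medoids].min(axis=1).sum())
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, medoids
    medoids = best_medoids
    labels = np.argmin(d[:, medoids], axis=1)
    cost = float(d[np.arange(n), [medoids[j] for j in labels]].sum())
    return labels, medoids, cost


def mean_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed dissimilarity matrix."""
    return float(np.mean(silhouette_samples(d, labels, metric="precomputed")))


@dataclass
class ClusterSolution:
    """Chosen PAM partition of trajectory curves."""

    labels: pd.Series                 # pair id -> cluster id (0-based)
    medoids: list[str]
    k: int
    silhouette_by_k: dict[int, float]
    mean_silhouette: float
    cluster_means: pd.DataFrame       # grid x cluster mean trajectories
    crossover_age: float | None
    crossover_found: bool
    all_crossings: list[float]
    #: the two cluster ids whose mean trajectories define the crossover
    crossover_clusters: tuple[int, int] | None = None


class PAMClustering(BaseEstimator, ClusterMixin):
    """PAM with silhouette-based selection of the cluster count.

    Parameters
    ----------
    k_min, k_max : int
        Candidate range of cluster counts (k_max is clipped below the item
        count).

    Fitted attributes
    -----------------
    labels_ : ndarray of cluster ids
    medoid_indices_ : list of int
    k_ : chosen cluster count
    silhouette_by_k_ : dict k -> mean silhouette width
    mean_silhouette_ : silhouette of the chosen solution
    """

    def __init__(self, k_min: int = 2, k_max: int = 7):
        self.k_min = k_min
        self.k_max = k_max

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float)
        n = d.shape[0]
        if n <= 2:
            raise ClusterError("need at least 3 items to cluster")
        if d.shape != (n, n):
            raise ClusterError("X must be a square dissimilarity matrix")
        k_hi = min(self.k_max, n - 1)
        self.silhouette_by_k_ = {}
        solutions = {}
        for k in range(self.k_min, k_hi + 1):
            labels, medoids, cost = pam(d, k)
            if len(np.unique(labels)) < 2:
                continue
            self.silhouette_by_k_[k] = mean_silhouette(d, labels)
            solutions[k] = (labels, medoids)
        if not solutions:
            raise ClusterError("no valid clustering in the candidate range")
        self.k_ = max(self.silhouette_by_k_, key=lambda k: self.silhouette_by_k_[k])
        self.labels_, self.medoid_indices_ = solutions[self.k_]
        self.mean_silhouette_ = self.silhouette_by_k_[self.k_]
        return self


def crossover_age(cluster_means: pd.DataFrame) -> tuple[float | None, bool, list[float]]:
    """First intersection age of two cluster-mean trajectories.

    ``cluster_means``: index = age grid, exactly two columns.  Linear
    interpolation of the first sign change of their difference; returns
    ``(age_or_None, found_flag, all_crossing_ages)``.
    """
    if cluster_means.shape[1] != 2:
        raise ClusterError(
            f"crossover needs exactly 2 clusters, got {cluster_means.shape[1]}"
        )
    grid = cluster_means.index.to_numpy(dtype=float)
    diff = cluster_means.iloc[:, 0].to_numpy() - cluster_means.iloc[:, 1].to_numpy()
    crossings = []
    for i in range(len(diff) - 1):
        if diff[i] == 0.0:
            crossings.append(float(grid[i]))
        elif diff[i] * diff[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossings.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if diff[-1] == 0.0:
        crossings.append(float(grid[-1]))
    if not crossings:
        return None, False, []
    return crossings[0], True, crossings


def dice_overlap(labels_a, labels_b) -> float:
    """Sorensen-Dice index between two sets: 2|A&B| / (|A|+|B|).

    Defined as 1 when both sets are empty.
    """
    a, b = set(labels_a), set(labels_b)
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def cluster_trajectories(
    curves: pd.DataFrame, k_min: int = 2, k_max: int = 7
) -> ClusterSolution:
    """Full clustering stage on a (grid x pairs) curve table."""
    d = trajectory_dissimilarity(curves)
    model = PAMClustering(k_min=k_min, k_max=k_max).fit(d.to_numpy())
    pair_ids = list(curves.columns)
    labels = pd.Series(model.labels_, index=pair_ids, name="cluster")
    means = curves.T.groupby(labels).mean().T  # grid x cluster
    if model.k_ == 2:
        used = tuple(means.columns)
        age, found, all_cross = crossover_age(means)
    else:
        # more than two clusters (e.g. an extra flat group of weakly
        # changing pairs): the crossover is defined between the two main
        # drift clusters, taken as the two largest-amplitude means
        amplitude = means.max(axis=0) - means.min(axis=0)
        used = tuple(amplitude.sort_values(ascending=False).index[:2])
        age, found, all_cross = crossover_age(means[list(used)])
    return ClusterSolution(
        labels=labels,
        medoids=[pair_ids[i] for i in model.medoid_indices_],
        k=model.k_,
        silhouette_by_k=dict(model.silhouette_by_k_),
        mean_silhouette=model.mean_silhouette_,
        cluster_means=means,
        crossover_age=age,
        crossover_found=found,
        all_crossings=all_cross,
        crossover_clusters=used,
    )
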