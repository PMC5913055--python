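"""K-means clustering of probe expression profiles and late-pollen cluster selection.

Probes are clustered by their meta-expression profile (one column per sample
group) with Euclidean distance; cluster centroids are then scored for late
pollen preference: the mean centroid value over late-pollen groups minus the
maximum mean over every other tissue group. Clusters whose preference index
is at least ``tau`` log2 units (default 1.0, a 2-fold margin over the best
non-late tissue) are flagged late-preferred, and the union of their members
is the late pollen-preferred probe set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """K-means partition of probes.

    ``objective`` is the total within-cluster sum of squared Euclidean
    distances and is recomputable from ``assignment`` + ``centroids``.
    """

    assignment: dict[str, int]
    centroids: np.ndarray  # K x n_groups
    objective: float
    K: int
    seed: int
    n_restarts: int
    group_ids: list[str]

    def sizes(self) -> np.ndarray:
        counts = np.zeros(self.K, dtype=int)
        for c in self.assignment.values():
            counts[c] += 1
        return counts

    def members(self, cluster: int) -> set[str]:
        return {p for p, c in self.assignment.items() if c == cluster}

    def recompute_objective(self, matrix: ExpressionMatrix) -> float:
        labels = np.array([self.assignment[p] for p in matrix.probe_ids])
        diff = matrix.values - self.centroids[labels]
        return float(np.sum(diff * diff))


@dataclass
class ClusterPreference:
    """Late-pollen preference of one cluster centroid.

    ``preference_index`` is a log2 difference: mean centroid expression over
    late-pollen sample groups minus the maximum per-tissue-group mean over
    all other groups. ``is_late_preferred`` iff the index >= tau.
    """

    cluster: int
    preference_index: float
    is_late_preferred: bool


def kmeans(matrix: ExpressionMatrix, K: int, seed: int = 0,
           n_restarts: int = 10, max_iter: int = 300,
           tol: float = 1e-6) -> ClusterResult:
    """Cluster probe profiles into K groups by Euclidean k-means.

    Runs ``n_restarts`` k-means++ initializations from a seeded stream and
    keeps the restart with the minimal within-cluster sum of squares. The
    same seed yields an identical result.
    """
    n_probes = len(matrix.probe_ids)
    if n_probes == 0:
        raise ValidationError("cannot cluster an empty matrix")
    if K < 1 or K > n_probes:
        raise ValidationError(f"K={K} out of range [1, {n_probes}]")
    if matrix.has_missing():
        raise ValidationError("matrix contains NA values; preprocess first")

    if K == n_probes:
        # degenerate partition: every probe its own cluster, objective 0
        assignment = {p: i for i, p in enumerate(matrix.probe_ids)}
        return ClusterResult(assignment, matrix.values.copy(), 0.0, K, seed,
                             n_restarts, list(matrix.sample_ids))

    km = KMeans(n_clusters=K, init="k-means++", n_init=n_restarts,
                max_iter=max_iter, tol=tol, random_state=seed)
    labels = km.fit_predict(matrix.values)
    assignment = dict(zip(matrix.probe_ids, (int(c) for c in labels)))
    return ClusterResult(assignment, km.cluster_centers_, float(km.inertia_),
                         K, seed, n_restarts, list(matrix.sample_ids))


def score_cluster_preference(centroids: np.ndarray, group_meta: pd.DataFrame,
                             tau: float = 1.0) -> list[ClusterPreference]:
    """Score each centroid for late pollen preference.

    ``group_meta`` is the per-group metadata produced by
    ``preprocess.average_replicates`` (columns tissue_group, is_late_pollen,
    aligned with centroid columns). For each cluster the index is the mean
    over late-pollen group columns minus the maximum, over every non-late
    tissue group, of that tissue group's mean centroid value.
    """
    meta = group_meta.reset_index(drop=True)
    late_mask = meta["is_late_pollen"].to_numpy(dtype=bool)
    if not late_mask.any():
        raise ValidationError("no late-pollen sample groups in metadata")
    if late_mask.all():
        raise ValidationError("all sample groups are late-pollen; "
                              "no contrast tissue available")
    centroids = np.asarray(centroids, dtype=float)
    late_mean = centroids[:, late_mask].mean(axis=1)

    other_positions = np.flatnonzero(~late_mask)
    other_tissues = meta.loc[other_positions, "tissue_group"]
    other_group_means = []
    for _, cols in other_tissues.groupby(other_tissues).groups.items():
        idx = np.fromiter(cols, dtype=int)
        other_group_means.append(centroids[:, idx].mean(axis=1))
    best_other = np.max(np.column_stack(other_group_means), axis=1)

    prefs = []
    for k in range(centroids.shape[0]):
        index = float(late_mean[k] - best_other[k])
        prefs.append(ClusterPreference(k, index, index >= tau))
    return prefs


def select_late_probes(result: ClusterResult,
                       preferences: list[ClusterPreference]) -> set[str]:
    """Union of probes in clusters flagged late-preferred."""
    flagged = {p.cluster for p in preferences if p.is_late_preferred}
    if not flagged:
        logger.warning("no clusters flagged late pollen-preferred; "
                       "returning empty probe set")
        return set()
    return {probe for probe, c in result.assignment.items() if c in flagged}
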