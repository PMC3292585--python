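"""Mixing-matrix estimation by clustering of single-component points.

At an SCP the observed real 2-vector (reference value, test value) is
collinear with one column of the non-negative mixing matrix ``A``. The
column directions are therefore recovered by agglomerative clustering of
the oriented unit SCP vectors -- complete linkage under the cosine distance,
exactly M clusters -- and each cluster centre becomes one column of ``A``.
Hierarchical clustering is used (rather than k-means) because it is
deterministic: the same SCP set always yields the same mixing matrix.

Each column's mixing angle ``atan2(A[1, m], A[0, m])`` is measured from the
reference-sample axis (row 0 = reference, row 1 = test; fixed convention
throughout the package) and later drives automatic component selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .errors import ClusteringError
from .scp import ScpSet

__all__ = ["MixingEstimate", "orient_scp_vectors", "cluster_mixing", "mixing_angle"]

log = logging.getLogger(__name__)

#: inter-centroid cosine distance below which directions count as identical
_DIVERSITY_TOL = 1e-12


@dataclass
class MixingEstimate:
    """2 x M mixing matrix with unit-norm non-negative columns."""

    A: np.ndarray              # 2 x M
    angles: np.ndarray         # M mixing angles, degrees
    n_scps_used: int

    @property
    def n_components(self) -> int:
        return self.A.shape[1]


def orient_scp_vectors(rows: np.ndarray, scps: ScpSet) -> np.ndarray:
    """Unit 2-vectors of the SCP features, mapped to one half-plane.

    Takes the real 2-vector (reference value, test value) at each retained
    feature, normalizes it, and flips its sign when its larger-magnitude
    entry is negative, so antipodal directions (the "0 or pi" ambiguity)
    coincide before clustering. Zero-norm vectors are skipped.
    """
    rows = np.asarray(rows, dtype=float)
    vecs = rows[:, scps.indices].T  # J x 2
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > 0
    if not keep.all():
        log.debug("skipping %d zero-norm SCP vectors", int((~keep).sum()))
    vecs, norms = vecs[keep], norms[keep]
    vecs = vecs / norms[:, None]
    lead = vecs[np.arange(len(vecs)), np.argmax(np.abs(vecs), axis=1)]
    vecs[lead < 0] *= -1.0
    return vecs


def _thin(vectors: np.ndarray, max_points: int) -> np.ndarray:
    """Deterministically subsample to ``max_points``, evenly in angle order.

    The oriented vectors live on a half-circle, where the cosine metric is a
    monotone function of the 1-D angular separation; even thinning along the
    sorted angles preserves the complete-linkage cluster structure while
    bounding the O(J^2) linkage cost.
    """
    if len(vectors) <= max_points:
        return vectors
    order = np.argsort(np.arctan2(vectors[:, 1], vectors[:, 0]), kind="stable")
    pick = np.linspace(0, len(vectors) - 1, max_points).round().astype(int)
    return vectors[order[pick]]


def cluster_mixing(vectors: np.ndarray, M: int, *, method: str = "hierarchical",
                   max_cluster_points: int = 2000, strict_diversity: bool = True,
                   random_state: int = 0) -> MixingEstimate:
    """Cluster oriented SCP vectors into exactly M mixing columns.

    Default is complete-linkage agglomerative clustering under cosine
    distance. Each centroid is the arithmetic mean of its members, clipped
    to the non-negative orthant (baseline-corrected spectra can push a
    coordinate slightly negative) and renormalized to unit l2 norm.
    ``method="kmeans"`` is available for comparison but is not the default
    because its outcome depends on initialisation.

    With ``strict_diversity`` (default) an SCP set spanning fewer than M
    numerically distinct directions is an error; without it, clustering
    proceeds and may return (near-)duplicate mixing columns, which is how
    the decomposition pipeline treats samples whose SCPs happen to cover
    fewer directions than the postulated number of components.
    """
    vectors = np.asarray(vectors, dtype=float)
    n_total = len(vectors)
    if n_total < M:
        raise ClusteringError(
            f"too few SCPs for M components: J={n_total} < M={M}")
    work = _thin(vectors, max_cluster_points)
    if method == "hierarchical":
        if len(work) == 1:
            assignment = np.ones(1, dtype=int)
        else:
            z = linkage(work, method="complete", metric="cosine")
            assignment = fcluster(z, t=M, criterion="maxclust")
    elif method == "kmeans":
        km = KMeans(n_clusters=M, n_init=10, random_state=random_state)
        assignment = km.fit_predict(work) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    cluster_ids = list(np.unique(assignment))
    if len(cluster_ids) < M:
        if strict_diversity:
            raise ClusteringError(
                f"insufficient angular diversity: only {len(cluster_ids)} "
                f"distinct directions at the {M}-cluster cut")
        log.warning("only %d distinct directions for M=%d; duplicating columns",
                    len(cluster_ids), M)
        cluster_ids += [cluster_ids[i % len(cluster_ids)]
                        for i in range(M - len(cluster_ids))]
    centroids = np.stack([work[assignment == c].mean(axis=0) for c in cluster_ids])
    centroids = np.clip(centroids, 0.0, None)
    norms = np.linalg.norm(centroids, axis=1)
    if np.any(norms == 0):
        raise ClusteringError(
            "degenerate cluster centroid (zero norm after projection onto "
            "the non-negative orthant)")
    centroids /= norms[:, None]
    gram = centroids @ centroids.T
    off = gram[np.triu_indices(M, k=1)]
    if strict_diversity and np.any(1.0 - off < _DIVERSITY_TOL):
        raise ClusteringError(
            "insufficient angular diversity: two cluster centres coincide")
    a = centroids.T  # 2 x M
    angles = np.degrees(np.arctan2(a[1], a[0]))
    return MixingEstimate(A=a, angles=angles, n_scps_used=n_total)


def mixing_angle(column: np.ndarray) -> float:
    """Angle of a non-negative unit mixing column from the reference axis."""
    column = np.asarray(column, dtype=float)
    if np.any(column < 0):
        raise ValueError(f"mixing column must be non-negative, got {column}")
    return float(np.degrees(np.arctan2(column[1], column[0])))
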