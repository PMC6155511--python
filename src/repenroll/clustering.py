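"""Complete-linkage clustering, height cuts, silhouette widths and summaries.

Respondents are points in the standardized response space; the dissimilarity
between respondents i and j is the Euclidean distance

    d_ij = sqrt( sum_k ((x_jk - x_ik) / sigma_k)^2 )

computed on the already-standardized grid. Complete linkage merges, at each
step, the two clusters whose maximum inter-point distance is smallest; that
maximum becomes the dendrogram height of the merge. Cutting the dendrogram at
a height h assigns two respondents to the same cluster exactly when they were
joined at a height strictly below h. Cluster tightness is measured by the
silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a(i) is the
mean distance from i to the rest of its cluster and b(i) the mean distance to
the closest other cluster (the cluster minimizing that mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .survey_data import StandardizedMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "SilhouetteResult",
    "ClusterSummary",
    "pairwise_distances",
    "complete_linkage",
    "cut_at_height",
    "silhouette_widths",
    "cluster_summaries",
    "height_diagnostics",
]


@dataclass
class DistanceMatrix:
    """Symmetric N x N Euclidean distance matrix with zero diagonal."""

    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.isfinite(d).all():
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """Complete-linkage merge tree in scipy linkage-matrix form.

    ``z`` has N-1 rows (left, right, height, size); complete linkage is
    monotone so heights are nondecreasing in merge order.
    """

    z: np.ndarray
    n: int

    def heights(self) -> np.ndarray:
        return self.z[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, columns=["left", "right", "height", "size"])


@dataclass
class ClusterAssignment:
    """Flat clustering from cutting a dendrogram at a height h."""

    height: float
    labels: np.ndarray  # integers 1..C

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass
class SilhouetteResult:
    s: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class ClusterSummary:
    """Size N_c and average silhouette width ASW_c of one cluster."""

    cluster_id: int
    size: int
    asw: float
    members: np.ndarray


def pairwise_distances(m: StandardizedMatrix) -> DistanceMatrix:
    """Euclidean distances between all respondent pairs of a standardized matrix."""
    if not np.isfinite(m.values).all():
        raise ValueError("standardized matrix contains non-finite values")
    return DistanceMatrix(squareform(pdist(m.values)))


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate under complete linkage (merge minimizing the max within-cluster distance)."""
    if d.n < 2:
        raise ValueError("need at least 2 observations to cluster")
    z = linkage(d.condensed(), method="complete")
    return Dendrogram(z, d.n)


def cut_at_height(t: Dendrogram, h: float) -> ClusterAssignment:
    """Partition so that observations joined at a height strictly below h share a cluster."""
    if h <= 0:
        raise ValueError("cut height must be positive")
    # fcluster joins merges with height <= threshold; stepping the threshold
    # down one ulp turns that into the strict "< h" convention.
    labels = fcluster(t.z, t=np.nextafter(h, -np.inf), criterion="distance")
    return ClusterAssignment(height=float(h), labels=np.asarray(labels))


def silhouette_widths(d: DistanceMatrix, assign: ClusterAssignment) -> SilhouetteResult:
    """Per-observation silhouette widths s(i), with singleton members set to 0.

    b(i) averages distances to the *closest other cluster*, i.e. the cluster
    minimizing the mean distance to observation i. If only one cluster exists
    every s(i) is 0 by convention.
    """
    labels = np.asarray(assign.labels)
    if labels.shape[0] != d.n:
        raise ValueError("assignment and distance matrix sizes differ")
    uniq, idx = np.unique(labels, return_inverse=True)
    n, c = d.n, uniq.size
    if c == 1:
        zero = np.zeros(n)
        return SilhouetteResult(s=zero, a=zero.copy(), b=zero.copy())
    ind = np.zeros((n, c))
    ind[np.arange(n), idx] = 1.0
    sums = d.d @ ind                      # (i, cluster) -> total distance
    counts = ind.sum(axis=0)
    own_count = counts[idx]
    own_sum = sums[np.arange(n), idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own_count > 1, own_sum / np.maximum(own_count - 1, 1), 0.0)
        means = sums / counts
    means[np.arange(n), idx] = np.inf     # exclude own cluster from b(i)
    b = means.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / denom, 0.0)
    singleton = own_count == 1
    s[singleton] = 0.0
    a[singleton] = 0.0
    return SilhouetteResult(s=s, a=a, b=b)


def cluster_summaries(assign: ClusterAssignment, sil: SilhouetteResult) -> list[ClusterSummary]:
    """One (size, ASW, members) record per cluster; sizes sum to N."""
    labels = np.asarray(assign.labels)
    if labels.shape[0] != sil.s.shape[0]:
        raise ValueError("assignment and silhouette sizes differ")
    out = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                size=int(members.size),
                asw=float(sil.s[members].mean()),
                members=members,
            )
        )
    return out


def height_diagnostics(t: Dendrogram, d: DistanceMatrix, candidate_heights) -> pd.DataFrame:
    """ASW diagnostics over candidate cut heights, to support choosing h.

    Negative cluster ASWs at a height suggest that cut fits poorly; the
    height with few negative-ASW clusters (and an acceptable cluster count)
    is the natural choice.
    """
    candidate_heights = list(candidate_heights)
    if not candidate_heights:
        raise ValueError("need at least one candidate height")
    rows = []
    for h in candidate_heights:
        assign = cut_at_height(t, h)
        sil = silhouette_widths(d, assign)
        summ = cluster_summaries(assign, sil)
        asws = np.array([c.asw for c in summ])
        rows.append(
            {
                "height": h,
                "n_clusters": len(summ),
                "n_negative_asw": int((asws < 0).sum()),
                "min_asw": asws.min(),
                "median_asw": float(np.median(asws)),
                "max_asw": asws.max(),
            }
        )
    return pd.DataFrame(rows)
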