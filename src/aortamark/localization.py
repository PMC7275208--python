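"""Threshold-cluster-centroid extraction of landmarks from probability maps.

For each landmark class: select voxels with probability above a low
threshold (0.5), cluster their world positions with a distance-threshold
criterion (1.1 mm), keep the largest cluster, and report the unweighted
centroid of that cluster's high-confidence voxels (probability above
0.9). On a 1 mm isotropic grid the 1.1 mm threshold links exactly the
face-adjacent voxels (1 < 1.1 < sqrt(2)), so the clusters coincide with
6-connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .volumetric_io import (
    CLASS_CODES,
    LANDMARK_NAMES,
    GridSpec,
    LandmarkSet,
    voxel_to_world,
)

__all__ = [
    "LandmarkPrediction",
    "LandmarkDetectionError",
    "cluster_voxels",
    "extract_landmark",
    "detect_landmarks",
]


class LandmarkDetectionError(RuntimeError):
    """Raised when one or more landmark classes yield no prediction."""

    def __init__(self, failed_classes):
        self.failed_classes = tuple(failed_classes)
        super().__init__(
            "no voxel exceeded the selection threshold for class(es): "
            + ", ".join(self.failed_classes)
        )


@dataclass
class LandmarkPrediction:
    """One predicted landmark with post-processing diagnostics."""

    name: str
    point: np.ndarray
    n_selected: int
    n_clusters: int
    largest_cluster_size: int
    n_high_confidence: int
    fallback: bool

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        if not np.all(np.isfinite(self.point)):
            raise ValueError(f"non-finite prediction for {self.name}")


def cluster_voxels(points, threshold: float = 1.1) -> list[np.ndarray]:
    """Partition points so that two share a cluster iff chained by steps <= threshold.

    This is the single-linkage agglomerative dendrogram cut at ``threshold``
    (Euclidean distance criterion), computed as connected components of the
    threshold-neighbour graph — the partition is identical, unique, and
    independent of point order. Returns index arrays, one per cluster,
    ordered by smallest member index.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (N, 3) points, got shape {pts.shape}")
    n = len(pts)
    if n == 0:
        raise ValueError("cannot cluster an empty point set")
    if n == 1:
        return [np.array([0])]
    pairs = cKDTree(pts).query_pairs(r=threshold, output_type="ndarray")
    graph = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    clusters = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    clusters.sort(key=lambda c: int(c[0]))
    return clusters


def extract_landmark(
    class_map: np.ndarray,
    grid: GridSpec,
    low: float = 0.5,
    high: float = 0.9,
    threshold: float = 1.1,
    name: str = "?",
) -> LandmarkPrediction:
    """Run the threshold-cluster-centroid procedure on one class map.

    Voxels with probability > ``low`` are selected and clustered at
    ``threshold`` mm; from the largest cluster (ties broken by highest peak
    probability, then by lexicographically smallest voxel index) the
    unweighted centroid of the voxels with probability > ``high`` is the
    predicted point. If the largest cluster contains no voxel above
    ``high``, the whole-cluster centroid is returned with the fallback
    flag set. If no voxel exceeds ``low`` the prediction fails.
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    p = np.asarray(class_map, dtype=float)
    idx = np.argwhere(p > low)
    if len(idx) == 0:
        raise LandmarkDetectionError([name])
    world = voxel_to_world(grid, idx.astype(float))
    probs = p[tuple(idx.T)]
    clusters = cluster_voxels(world, threshold)

    sizes = np.array([len(c) for c in clusters])
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        peaks = np.array([probs[clusters[b]].max() for b in best])
        best = best[peaks == peaks.max()]
    if len(best) > 1:
        first_vox = [tuple(idx[clusters[b]].min(axis=0)) for b in best]
        best = [best[int(np.lexsort(np.array(first_vox).T[::-1])[0])]]
    chosen = clusters[int(best[0])]

    high_mask = probs[chosen] > high
    n_high = int(high_mask.sum())
    if n_high > 0:
        point = world[chosen][high_mask].mean(axis=0)
        fallback = False
    else:
        point = world[chosen].mean(axis=0)
        fallback = True
    return LandmarkPrediction(
        name=name,
        point=point,
        n_selected=len(idx),
        n_clusters=len(clusters),
        largest_cluster_size=len(chosen),
        n_high_confidence=n_high,
        fallback=fallback,
    )


def detect_landmarks(
    fused,
    low: float = 0.5,
    high: float = 0.9,
    threshold: float = 1.1,
) -> tuple[LandmarkSet, dict[str, LandmarkPrediction]]:
    """Extract all five landmarks from a fused probability map.

    Applies :func:`extract_landmark` to classes 1-5 (background ignored).
    Raises :class:`LandmarkDetectionError` naming every failing class if
    any class yields no selected voxel.
    """
    predictions: dict[str, LandmarkPrediction] = {}
    failed = []
    for lmname in LANDMARK_NAMES:
        code = CLASS_CODES[lmname]
        try:
            predictions[lmname] = extract_landmark(
                fused.class_map(code), fused.grid, low, high, threshold, name=lmname
            )
        except LandmarkDetectionError:
            failed.append(lmname)
    if failed:
        raise LandmarkDetectionError(failed)
    landmarks = LandmarkSet({nm: pr.point for nm, pr in predictions.items()})
    return landmarks, predictions
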