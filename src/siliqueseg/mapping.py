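"""Sparse-to-dense label mapping by Kd-tree radius search.

The segmentation network runs on a downsampled cloud (it cannot afford
the full ~250k-point scan), so its silique labels live on a sparse
subset. This stage recovers the dense canopy: every dense point within a
fixed radius (default 0.01, in the cloud's units) of at least one
silique-labeled sparse point is retained. Stem-labeled sparse points
play no role — only silique seeds expand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import PointCloud

__all__ = ["MappingParams", "radius_search", "map_sparse_to_dense"]

SILIQUE_LABEL = 1


@dataclass(frozen=True)
class MappingParams:
    """Radius of the dense-recovery ball, in cloud units.

    ``normalize`` rescales both clouds so the dense cloud's bounding-box
    diagonal is 1 before searching, for data whose units are unknown.
    """

    radius: float = 0.01
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def radius_search(tree: cKDTree, query: np.ndarray, radius: float) -> np.ndarray:
    """Indices of all tree points within the closed ball of ``radius``.

    Thin, validated wrapper over the Kd-tree ball query; returned indices
    are sorted ascending.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    idx = tree.query_ball_point(np.asarray(query, dtype=float), radius)
    return np.sort(np.asarray(idx, dtype=int))


def map_sparse_to_dense(sparse: PointCloud, dense: PointCloud,
                        params: MappingParams | None = None) -> PointCloud:
    """Recover the dense canopy from sparse silique labels.

    Returns the subset of ``dense`` lying within ``params.radius`` of at
    least one silique-labeled sparse point (union over seeds, each dense
    point at most once), labeled silique throughout. No silique seeds at
    all yields an empty cloud with a warning.
    """
    if not sparse.is_labeled:
        raise ValueError("sparse cloud must be labeled")
    params = params or MappingParams()
    seeds = sparse.coords[sparse.labels == SILIQUE_LABEL]
    if len(seeds) == 0:
        warnings.warn("map_sparse_to_dense: no silique-labeled sparse points; "
                      "empty result", stacklevel=2)
        return PointCloud(np.empty((0, 3)), np.empty(0, dtype=int))
    dense_coords = dense.coords
    radius = params.radius
    if params.normalize:
        span = dense_coords.max(axis=0) - dense_coords.min(axis=0)
        diag = float(np.linalg.norm(span))
        if diag > 0:
            scale = 1.0 / diag
            dense_coords = dense_coords * scale
            seeds = seeds * scale
    tree = cKDTree(dense_coords)
    hits = tree.query_ball_point(seeds, radius)
    idx = np.unique(np.concatenate([np.asarray(h, dtype=int) for h in hits])
                    if len(hits) else np.empty(0, dtype=int))
    out = dense.select(idx)
    out.labels = np.full(len(idx), SILIQUE_LABEL, dtype=int)
    return out
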