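"""Silique counting: Euclidean clustering + iterative RANSAC line fitting.

The dense canopy cloud (stems already removed) is split into connected
clusters at a distance tolerance; each cluster is then mined for straight
lines: a 2-point RANSAC proposes line hypotheses, the best consensus set
(points within the inlier band of the axis) is refit by least squares,
accepted if it has enough points and a plausible cross-sectional width,
removed from the cluster, and the search repeats until too few points
remain. Each accepted line is one silique; the count is the number of
accepted lines over all clusters.

Default thresholds are the ones measured on real pods: inlier band
0.018 m, model width 0.03-0.05 m, at least 200 points per line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import PointCloud

__all__ = [
    "CountingParams",
    "LineModel",
    "CountReport",
    "euclidean_cluster",
    "ransac_line",
    "count_siliques",
    "counting_metrics",
    "match_lines_to_truth",
]


@dataclass(frozen=True)
class CountingParams:
    """All counting-stage thresholds in one validated record (meters)."""

    cluster_tolerance: float = 0.02
    min_cluster_size: int = 200
    inlier_threshold: float = 0.018
    width_lo: float = 0.03
    width_hi: float = 0.05
    min_line_points: int = 200
    ransac_iterations: int = 1000
    max_axial_gap: float | None = None  # None -> cluster_tolerance
    max_length: float = 0.09
    core_median_fraction: float = 0.6
    direction_coherence_deg: float = 45.0
    seed: int = 0

    @property
    def axial_gap(self) -> float:
        """A silique is contiguous: inliers separated by more than this
        along the fitted axis belong to a different pod (collinear pods
        on opposite sides of the stem would otherwise merge)."""
        return self.max_axial_gap if self.max_axial_gap is not None \
            else self.cluster_tolerance

    def __post_init__(self) -> None:
        if self.inlier_threshold <= 0 or self.cluster_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.width_lo < self.width_hi:
            raise ValueError("require 0 < width_lo < width_hi")
        if min(self.min_cluster_size, self.min_line_points,
               self.ransac_iterations) < 1:
            raise ValueError("counts must be positive integers")


@dataclass
class LineModel:
    """One fitted silique: a line plus its supporting points.

    ``width`` is the bounding-cylinder diameter of the inliers around the
    refit axis (twice the maximum point-to-axis distance).
    """

    anchor: np.ndarray
    direction: np.ndarray
    inlier_indices: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=int)

    def point_distances(self, points: np.ndarray) -> np.ndarray:
        rel = points - self.anchor
        along = rel @ self.direction
        return np.linalg.norm(rel - along[:, None] * self.direction, axis=1)


def _line_distances(points: np.ndarray, anchor: np.ndarray,
                    direction: np.ndarray) -> np.ndarray:
    rel = points - anchor
    along = rel @ direction
    return np.linalg.norm(rel - along[:, None] * direction[None, :], axis=1)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def euclidean_cluster(cloud: PointCloud, tolerance: float,
                      min_size: int = 1) -> list[np.ndarray]:
    """Connected components of the <=tolerance proximity graph.

    Exact flood fill over a Kd-tree: two points share a cluster iff a
    chain of <=tolerance hops links them. Clusters below ``min_size`` are
    dropped. Returned index arrays are sorted and pairwise disjoint, in
    order of each cluster's lowest point index.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    coords = cloud.coords
    n = len(coords)
    if n == 0:
        return []
    # DBSCAN with min_samples=1 makes every point a core point, which is
    # exactly the connected components of the <=eps proximity graph.
    from sklearn.cluster import DBSCAN

    labels = DBSCAN(eps=tolerance, min_samples=1, algorithm="kd_tree",
                    n_jobs=1).fit(coords).labels_
    clusters = [np.flatnonzero(labels == lab) for lab in range(labels.max() + 1)]
    clusters = [c for c in clusters if len(c) >= min_size]
    clusters.sort(key=lambda c: int(c[0]))
    return clusters


# ---------------------------------------------------------------------------
# RANSAC line fitting
# ---------------------------------------------------------------------------

def local_directions(points: np.ndarray, scale: float = 0.012,
                     k: int = 6) -> np.ndarray:
    """Pod-scale local axis direction for every point.

    Principal component of ball neighbourhoods (radius ~1.7x the pod
    diameter ``scale``) computed on a random subsample for speed; every
    point inherits the direction of its nearest subsample point. Inside
    a silique the patch is elongated along that pod's axis. Used to keep
    a fitted line's support coherent — a crossing pod's points lie inside
    the line's distance band near the crossing but their local direction
    betrays them.
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    if m < 4:
        return np.tile([0.0, 0.0, 1.0], (m, 1))
    rng = np.random.default_rng(0)
    n_sub = min(m, max(500, m // 12))
    sub_idx = np.sort(rng.choice(m, n_sub, replace=False))
    sub = points[sub_idx]
    sub_tree = cKDTree(sub)
    neighbors = sub_tree.query_ball_point(sub, 1.7 * scale)
    dirs_sub = np.empty((n_sub, 3))
    for i, nb in enumerate(neighbors):
        patch = sub[nb]
        if len(patch) < 3:
            dirs_sub[i] = (0.0, 0.0, 1.0)
            continue
        centered = patch - patch.mean(axis=0)
        _, vecs = np.linalg.eigh(centered.T @ centered)
        dirs_sub[i] = vecs[:, 2]
    _, nearest = sub_tree.query(points, k=1)
    return dirs_sub[nearest]


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through the centroid (first principal axis)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    direction = vt[0]
    # canonical orientation: positive z, tie-broken lexicographically
    key = direction[2] if abs(direction[2]) > 1e-12 else (
        direction[0] if abs(direction[0]) > 1e-12 else direction[1])
    if key < 0:
        direction = -direction
    return centroid, direction / np.linalg.norm(direction)


def _sample_hypotheses(pts: np.ndarray, params: CountingParams,
                       rng: np.random.Generator,
                       baseline: tuple[float, float] = (0.012, 0.06),
                       ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Locally-sampled 2-point line hypotheses.

    The second sample point is drawn from a pod-scale annulus around the
    first, so in a cluster holding many siliques most hypotheses connect
    two points of the *same* pod. Uniform pairs would almost always
    straddle pods once a cluster holds a dozen of them, starving every
    individual pod of aligned hypotheses. Coincident pairs are redrawn;
    pairs with no annulus neighbour fall back to a uniform partner.
    """
    m = len(pts)
    iters = params.ransac_iterations
    ia = rng.integers(0, m, iters)
    tree = cKDTree(pts)
    k_cand = min(m, 128)
    dist, idx = tree.query(pts[ia], k=k_cand,
                           distance_upper_bound=baseline[1])
    valid = (dist >= baseline[0]) & np.isfinite(dist)
    # random valid candidate per row, via masked random keys
    keys = rng.random(valid.shape)
    keys[~valid] = -1.0
    pick = keys.argmax(axis=1)
    ib = idx[np.arange(iters), pick]
    starved = ~valid[np.arange(iters), pick]
    if starved.any():  # isolated points: uniform fallback partner
        ib[starved] = rng.integers(0, m, int(starved.sum()))
    dirs = pts[ib] - pts[ia]
    norms = np.linalg.norm(dirs, axis=1)
    ok = norms >= 1e-12
    if not ok.any():
        return None, None
    return pts[ia[ok]], dirs[ok] / norms[ok, None]


def ransac_line(points: np.ndarray, params: CountingParams,
                rng: np.random.Generator | None = None,
                local_dirs: np.ndarray | None = None) -> LineModel | None:
    """Best-consensus straight line through a point cluster, or None.

    2-point hypotheses for ``ransac_iterations`` rounds (coincident pairs
    are redrawn); the winner's consensus set is refit by least squares,
    inliers recomputed against the refit axis. Rejected (None) when the
    final support falls below ``min_line_points`` or the inlier width is
    outside [width_lo, width_hi] — too thin or too fat to be a silique.
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    if m < 2:
        return None
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if local_dirs is None:
        local_dirs = local_directions(points)
    # Hypothesis scoring runs on a bounded subsample: consensus ranking
    # is a statistic of the cluster, not of every point, and the full
    # cloud still decides the final support below.
    if m > 2500:
        score_idx = rng.choice(m, 2500, replace=False)
        score_pts = points[score_idx]
    else:
        score_pts = points
    anchors, dirs = _sample_hypotheses(score_pts, params, rng)
    if anchors is None:
        return None  # all points coincident
    core2 = np.float32((params.inlier_threshold / 4.0) ** 2)
    score32 = score_pts.astype(np.float32)
    dirs32 = dirs.astype(np.float32)
    anchors32 = anchors.astype(np.float32)
    # Soft consensus, weighted toward the axis core: a hypothesis
    # threading the dense core of one pod beats a longer line grazing the
    # flanks of two neighbouring pods. Scored in blocks to bound memory.
    ms = len(score32)
    all_scores = np.empty(len(dirs32), dtype=np.float32)
    block = max(1, int(4e6 // max(ms, 1)))
    for lo in range(0, len(dirs32), block):
        d = dirs32[lo:lo + block]
        a = anchors32[lo:lo + block]
        rel = score32[None, :, :] - a[:, None, :]
        along = np.einsum("hmk,hk->hm", rel, d)
        perp2 = np.einsum("hmk,hmk->hm", rel, rel) - along ** 2
        all_scores[lo:lo + block] = np.maximum(1.0 - perp2 / core2,
                                               0.0).sum(axis=1)
    # Model validation inside the search: refine the top-ranked
    # hypotheses in score order and return the first that yields a valid
    # silique model, so one degenerate refinement (a ghost line through
    # leftover fringe, an over-wide union) does not end the cluster.
    order = np.argsort(-all_scores)
    for best_i in order[:12]:
        model = _refine_hypothesis(points, anchors[best_i], dirs[best_i],
                                   params, local_dirs)
        if model is not None:
            return model
    return None


def _refine_hypothesis(points: np.ndarray, anchor0: np.ndarray,
                       dir0: np.ndarray, params: CountingParams,
                       local_dirs: np.ndarray) -> LineModel | None:
    """Refine one line hypothesis into a validated silique model.

    Starts from a strict core band (half the inlier band) so a collinear
    neighbour's flank points do not join before the first refit, then
    iterates: least-squares axis; bimodal cross-sections split with the
    dominant lobe kept; kinked or over-long supports cut at the best
    axial position; inliers re-gated at the full band but only within the
    support's axial extent (a silique is a finite rod — an infinite line
    would swallow collinear neighbours); trimmed to the largest
    contiguous run. The result must have enough points, a plausible
    width, and a centrally-dense (non-hollow) residual profile.
    """
    d0 = _line_distances(points, anchor0, dir0)
    support = np.flatnonzero(d0 <= 0.5 * params.inlier_threshold)
    if len(support) < 2:
        return None
    anchor = direction = None
    gap = params.axial_gap
    min_align = np.cos(np.deg2rad(params.direction_coherence_deg))
    for _ in range(4):
        anchor, direction = _principal_axis(points[support])
        support = _dominant_lobe(points, support, anchor, direction,
                                 params.inlier_threshold)
        if len(support) < 2:
            return None
        anchor, direction = _principal_axis(points[support])
        along_chk = (points[support] - anchor) @ direction
        overlong = along_chk.max() - along_chk.min() > params.max_length
        support = _split_misaligned(points, support, anchor, direction,
                                    force=overlong)
        if len(support) < 2:
            return None
        anchor, direction = _principal_axis(points[support])
        along_sup = (points[support] - anchor) @ direction
        lo_ext, hi_ext = along_sup.min() - gap, along_sup.max() + gap
        rel = points - anchor
        along = rel @ direction
        dists = np.linalg.norm(rel - along[:, None] * direction, axis=1)
        coherent = np.abs(local_dirs @ direction) >= min_align
        inliers = np.flatnonzero((dists <= params.inlier_threshold)
                                 & (along >= lo_ext) & (along <= hi_ext)
                                 & coherent)
        if len(inliers) < 2:
            return None
        support = _largest_axial_run(points, inliers, anchor, direction, gap)
    if len(support) < params.min_line_points:
        return None
    dists = _line_distances(points[support], anchor, direction)
    width = 2.0 * float(dists.max())
    if not params.width_lo <= width <= params.width_hi:
        return None
    # Hollow-support rejection: a real rod is densest at its axis, so the
    # median residual sits well inside the band. A "ghost" line threaded
    # through the leftover fringe of already-removed pods has its mass at
    # the rim instead and is discarded as a misidentification.
    if float(np.median(dists)) > params.core_median_fraction \
            * params.inlier_threshold:
        return None
    return LineModel(anchor, direction, support, width)


def _dominant_lobe(points: np.ndarray, support: np.ndarray,
                   anchor: np.ndarray, direction: np.ndarray,
                   threshold: float) -> np.ndarray:
    """Split a bimodal cross-section and keep the dominant lobe.

    Two near-parallel pods straddling a compromise axis leave two lobes
    in the plane perpendicular to it. 2-means on the cross-section
    coordinates separates them; the split is honoured only when the lobe
    centres are farther apart than the inlier band (a single pod's
    cross-section never is), so genuine rods are left intact.
    """
    rel = points[support] - anchor
    cross = rel - (rel @ direction)[:, None] * direction
    # 2D coordinates in the cross-section plane
    helper = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    xy = np.column_stack([cross @ e1, cross @ e2])
    # deterministic Lloyd iterations from the two extreme points
    spread = xy @ (xy.std(axis=0) + 1e-12)
    centers = xy[[int(np.argmin(spread)), int(np.argmax(spread))]]
    for _ in range(10):
        d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new = np.array([xy[assign == k].mean(axis=0) if (assign == k).any()
                        else centers[k] for k in (0, 1)])
        if np.allclose(new, centers):
            break
        centers = new
    if np.linalg.norm(centers[0] - centers[1]) <= 1.8 * threshold:
        return support
    keep = assign == (0 if (assign == 0).sum() >= (assign == 1).sum() else 1)
    return support[keep]


def _rod_rms(points: np.ndarray) -> float:
    centroid = points.mean(axis=0)
    _, s, _ = np.linalg.svd(points - centroid, full_matrices=False)
    # residual power orthogonal to the principal axis
    return float(np.sqrt((s[1] ** 2 + s[2] ** 2) / len(points)))


def _split_misaligned(points: np.ndarray, support: np.ndarray,
                      anchor: np.ndarray, direction: np.ndarray,
                      min_side: int = 50, improvement: float = 1.06,
                      force: bool = False) -> np.ndarray:
    """Detect a support made of two misaligned rods and keep the larger.

    Two pods meeting end-to-end at a shallow angle (a "V") produce one
    contiguous support whose single-line residual hides a kink. A
    two-piece refit at the right axial cut lowers the pooled RMS residual
    well below the single-line RMS; a genuine straight rod gains nothing.
    The cut is searched over axial quantiles; on a confirmed kink the
    larger side is kept (the smaller returns to the pool for its own fit).
    """
    if len(support) < 2 * min_side:
        return support
    pts = points[support]
    along = (pts - anchor) @ direction
    order = np.argsort(along)
    base = _rod_rms(pts)
    if base <= 0:
        return support
    best_rms, best_keep = np.inf, None
    n = len(order)
    for q in np.arange(0.2, 0.81, 0.1):
        cut = int(round(q * n))
        if cut < min_side or n - cut < min_side:
            continue
        left, right = order[:cut], order[cut:]
        rms = np.sqrt((cut * _rod_rms(pts[left]) ** 2
                       + (n - cut) * _rod_rms(pts[right]) ** 2) / n)
        if rms < best_rms:
            best_rms = rms
            best_keep = left if cut >= n - cut else right
    if best_keep is None:
        return support
    if not force and base / max(best_rms, 1e-12) < improvement:
        return support
    # the kept side must itself still look like a rod: a short, fat
    # fragment would hand the next refit a sideways principal axis
    kept = pts[best_keep]
    centered = kept - kept.mean(axis=0)
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    if not force and s[0] ** 2 < 4.0 * s[1] ** 2:
        return support
    return np.sort(support[best_keep])


def _largest_axial_run(points: np.ndarray, inliers: np.ndarray,
                       anchor: np.ndarray, direction: np.ndarray,
                       gap: float) -> np.ndarray:
    """Largest subset of inliers contiguous (gaps <= gap) along the axis."""
    along = (points[inliers] - anchor) @ direction
    order = np.argsort(along)
    breaks = np.flatnonzero(np.diff(along[order]) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(order)]])
    runs = ends - starts
    k = int(np.argmax(runs))
    return np.sort(inliers[order[starts[k]:ends[k]]])


def count_siliques(cloud: PointCloud, params: CountingParams | None = None,
                   ) -> list[LineModel]:
    """Count siliques in a canopy cloud; one LineModel per detection.

    Clusters the cloud, then repeatedly fits and removes lines inside
    each cluster until fewer than ``min_line_points`` points remain or a
    fit fails its support/width checks (that failed fit is discarded and
    the cluster's loop stops). Inlier indices refer to the input cloud
    and are pairwise disjoint across the returned lines.
    """
    params = params or CountingParams()
    if len(cloud) == 0:
        return []
    clusters = euclidean_cluster(cloud, params.cluster_tolerance,
                                 params.min_cluster_size)
    lines: list[LineModel] = []
    for ci, cluster in enumerate(clusters):
        remaining = cluster.copy()
        fit_i = 0
        cluster_dirs = local_directions(cloud.coords[cluster])
        pos = {int(g): i for i, g in enumerate(cluster)}
        while len(remaining) >= params.min_line_points:
            rng = np.random.default_rng([params.seed, ci, fit_i])
            sub_dirs = cluster_dirs[[pos[int(g)] for g in remaining]]
            model = ransac_line(cloud.coords[remaining], params, rng,
                                local_dirs=sub_dirs)
            if model is None:
                break
            global_inliers = remaining[model.inlier_indices]
            lines.append(LineModel(model.anchor, model.direction,
                                   global_inliers, model.width))
            keep = np.full(len(remaining), True)
            keep[model.inlier_indices] = False
            remaining = remaining[keep]
            fit_i += 1
    return _merge_fragments(lines, cloud.coords, params)


def _merge_fragments(lines: list[LineModel], coords: np.ndarray,
                     params: CountingParams) -> list[LineModel]:
    """Collapse two fits of the same rod into one.

    Sequential removal can leave a pod's far end to be fitted separately.
    Two lines are merged when their axes are nearly parallel, laterally
    coincident (offset below half the inlier band — distinct pods are
    separated by at least the full band) and their axial runs abut within
    the contiguity gap. Real collinear neighbours keep a wider axial gap
    and are never merged.
    """
    merged = True
    lines = list(lines)
    while merged:
        merged = False
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                a, b = lines[i], lines[j]
                if abs(float(a.direction @ b.direction)) < np.cos(np.deg2rad(20)):
                    continue
                if float(a.point_distances(b.anchor[None, :])[0]) \
                        > 0.5 * params.inlier_threshold:
                    continue
                along_a = (coords[a.inlier_indices] - a.anchor) @ a.direction
                along_b = (coords[b.inlier_indices] - a.anchor) @ a.direction
                if (along_b.min() > along_a.max() + params.axial_gap
                        or along_a.min() > along_b.max() + params.axial_gap):
                    continue
                union = np.union1d(a.inlier_indices, b.inlier_indices)
                anchor, direction = _principal_axis(coords[union])
                dists = _line_distances(coords[union], anchor, direction)
                width = 2.0 * float(dists.max())
                lines[i] = LineModel(anchor, direction, union, width)
                del lines[j]
                merged = True
                break
            if merged:
                break
    return lines


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class CountReport:
    """Per-plant and aggregate counting accuracy.

    ``per_plant`` rows are (plant_id, true, correct, missed, Pr%);
    ``totals`` sums the columns; ``mape_percent`` is the mean absolute
    percentage count error and ``r_squared`` the coefficient of
    determination of the identity prediction correct ~ true.
    """

    per_plant: list[tuple]
    totals: tuple
    mape_percent: float
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "per_plant": [
                {"plant_id": p, "true_count": t, "correct_count": c,
                 "missed_count": m, "precision_percent": round(pr, 2)}
                for p, t, c, m, pr in self.per_plant],
            "totals": {"true_count": self.totals[0],
                       "correct_count": self.totals[1],
                       "missed_count": self.totals[2],
                       "precision_percent": round(self.totals[3], 2)},
            "mape_percent": round(self.mape_percent, 2),
            "r_squared": round(self.r_squared, 4),
        }


def counting_metrics(per_plant_true: list[int], per_plant_correct: list[int],
                     plant_ids: list | None = None) -> CountReport:
    """Counting accuracy across plants.

    Per plant: Pr = 100 * correct / true, missed = true - correct.
    Aggregates: total Pr over summed counts, MAPE as the mean of the
    per-plant percentage errors, and R^2 = 1 - SS_res / SS_tot with the
    identity prediction (predicted count = true count).
    """
    true = np.asarray(per_plant_true, dtype=float)
    correct = np.asarray(per_plant_correct, dtype=float)
    if true.shape != correct.shape or true.ndim != 1 or len(true) == 0:
        raise ValueError("need equal-length non-empty count lists")
    if (true <= 0).any():
        raise ValueError("true counts must be positive")
    if (correct > true).any() or (correct < 0).any():
        raise ValueError("require 0 <= correct <= true per plant")
    if plant_ids is None:
        plant_ids = list(range(1, len(true) + 1))
    missed = true - correct
    pr = 100.0 * correct / true
    per_plant = [(plant_ids[i], int(true[i]), int(correct[i]),
                  int(missed[i]), float(pr[i])) for i in range(len(true))]
    totals = (int(true.sum()), int(correct.sum()), int(missed.sum()),
              100.0 * correct.sum() / true.sum())
    mape = float(np.mean(100.0 * missed / true))
    ss_res = float(((true - correct) ** 2).sum())
    ss_tot = float(((true - true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return CountReport(per_plant, totals, mape, r2)


def match_lines_to_truth(lines: list[LineModel],
                         point_silique_ids: np.ndarray) -> tuple[int, int]:
    """Score fitted lines against generator ground truth.

    Each line is attributed to the silique id holding the majority of its
    inliers; returns (recovered, spurious) where recovered counts distinct
    attributed siliques and spurious counts the remaining lines
    (duplicates of an already-attributed silique, or majority-stem).
    """
    ids = np.asarray(point_silique_ids)
    seen: set[int] = set()
    spurious = 0
    for line in lines:
        member_ids = ids[line.inlier_indices]
        member_ids = member_ids[member_ids >= 0]
        if len(member_ids) < len(line.inlier_indices) / 2 or len(member_ids) == 0:
            spurious += 1  # majority of support is stem or unknown
            continue
        vals, counts = np.unique(member_ids, return_counts=True)
        winner = int(vals[np.argmax(counts)])
        if winner in seen:
            spurious += 1
        else:
            seen.add(winner)
    return len(seen), spurious
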