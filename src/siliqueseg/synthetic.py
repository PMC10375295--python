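"""Ground-truthed synthetic inputs: plant point clouds and frame sequences.

Real scans of mature rapeseed are bulky and not redistributable, so every
stage of the pipeline is exercised against synthetic stand-ins whose
ground truth is known by construction:

* **plants** — a vertical stem (noisy cylinder shell) carrying N slender
  siliques: straight segments attached along the upper stem on a
  golden-angle spiral (the phyllotactic arrangement of a raceme), each
  sampled with Gaussian radial noise. A configurable fraction of
  siliques is placed crossing a neighbour to emulate pod adhesion.
* **frame sequences** — a textured scene under a slowly drifting
  similarity transform (rotation + shift per frame), with chosen frames
  Gaussian-blurred, for the keyframe stage.

Both are deterministic per seed and return their ground truth (labels,
true segments, blur sets, transform magnitudes) for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cloudio import PointCloud
from .keyframes import ImageFrame

__all__ = [
    "PlantSpec",
    "SyntheticPlant",
    "make_plant",
    "make_frame_sequence",
    "segment_segment_distance",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class PlantSpec:
    """Morphology and sampling budget of one synthetic plant.

    Defaults mimic the scale of real scans: ~260k points per plant,
    silique length 5-8 cm, stem ~1 m. ``silique_radius`` is the radial
    noise sigma; with the default 0.006 m, ~99% of a silique's points lie
    within the 0.018 m line-inlier band used by the counting stage.
    ``adhesion_fraction`` of the siliques are placed crossing a neighbour
    at 40-80 degrees, toward the outer part of both segments.
    """

    n_siliques: int = 120
    stem_height: float = 1.0
    stem_radius: float = 0.008
    silique_length_range: tuple[float, float] = (0.05, 0.08)
    silique_radius: float = 0.006
    points_per_silique: int = 2000
    stem_points: int = 20000
    adhesion_fraction: float = 0.0
    pedicel_range: tuple[float, float] = (0.02, 0.14)
    elevation_range_deg: tuple[float, float] = (5.0, 75.0)
    min_clearance: float = 0.036
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_siliques < 0:
            raise ValueError("n_siliques must be non-negative")
        for name in ("stem_height", "stem_radius", "silique_radius",
                     "points_per_silique", "stem_points", "min_clearance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.adhesion_fraction <= 1.0:
            raise ValueError("adhesion_fraction must lie in [0, 1]")
        lo, hi = self.silique_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid silique_length_range")


@dataclass
class SyntheticPlant:
    """A generated plant plus its full ground truth."""

    cloud: PointCloud                 # labels: 0 = stem, 1 = silique
    silique_ids: np.ndarray           # per point; -1 for stem points
    segments: list[tuple[np.ndarray, np.ndarray]]  # (base, tip) per silique
    spec: PlantSpec

    @property
    def canopy(self) -> PointCloud:
        """The silique-labeled subset (what the counting stage sees)."""
        return self.cloud.select(self.cloud.labels == 1)

    @property
    def canopy_silique_ids(self) -> np.ndarray:
        return self.silique_ids[self.cloud.labels == 1]


def segment_segment_distance(p1: np.ndarray, q1: np.ndarray,
                             p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    b, c = d1 @ d2, d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-18 else 0.0
    t = (b * s + f) / e if e > 1e-18 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-18 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-18 else 0.0
    diff = (p1 + s * d1) - (p2 + t * d2)
    return float(np.linalg.norm(diff))


def _direction(azimuth: float, elevation: float) -> np.ndarray:
    ce = np.cos(elevation)
    return np.array([ce * np.cos(azimuth), ce * np.sin(azimuth),
                     np.sin(elevation)])


def _clearance_ok(base: np.ndarray, tip: np.ndarray,
                  segments: list[tuple[np.ndarray, np.ndarray]],
                  min_clearance: float, skip: int | None = None) -> bool:
    for j, (b, t) in enumerate(segments):
        if j == skip:
            continue
        if segment_segment_distance(base, tip, b, t) < min_clearance:
            return False
    return True


def _place_segments(spec: PlantSpec, rng: np.random.Generator,
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Lay out silique axes: spiral attachment, rejection for clearance."""
    n = spec.n_siliques
    n_adhered = int(round(spec.adhesion_fraction * n))
    n_free = n - n_adhered
    elev_lo, elev_hi = np.deg2rad(spec.elevation_range_deg)
    z_lo, z_hi = 0.30 * spec.stem_height, 0.98 * spec.stem_height
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    max_retries = 800
    for i in range(n_free):
        z_slot = z_lo + (z_hi - z_lo) * (i + 0.5) / max(n_free, 1)
        azim0 = (i * GOLDEN_ANGLE) % (2 * np.pi)
        placed = False
        for attempt in range(max_retries):
            if attempt == 0:
                azim, z = azim0, z_slot
            else:  # redraw freely; the spiral is only a good starting guess
                azim = rng.uniform(0.0, 2 * np.pi)
                z = rng.uniform(z_lo, z_hi)
            elev = rng.uniform(elev_lo, elev_hi)
            direction = _direction(azim, elev)
            anchor = np.array([spec.stem_radius * np.cos(azim),
                               spec.stem_radius * np.sin(azim), z])
            base = anchor + rng.uniform(*spec.pedicel_range) * direction
            tip = base + rng.uniform(*spec.silique_length_range) * direction
            if _clearance_ok(base, tip, segments, spec.min_clearance):
                segments.append((base, tip))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place silique {i} with clearance "
                f"{spec.min_clearance}; spec too crowded")
    # Adhered siliques: cross an existing host toward its outer end.
    if n_adhered and not segments:
        raise ValueError("adhesion requires at least one free silique")
    host_order = list(rng.permutation(len(segments)))
    for a in range(n_adhered):
        placed = False
        for h_idx in host_order[a:] + host_order[:a]:
            if _try_place_crosser(segments, int(h_idx), spec, rng):
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place an adhered silique; "
                               "spec too crowded")
    return segments


def _try_place_crosser(segments, h_idx: int, spec: PlantSpec,
                       rng: np.random.Generator, attempts: int = 200) -> bool:
    """Try to thread one crossing silique through host ``h_idx``."""
    b_h, t_h = segments[h_idx]
    axis_h = t_h - b_h
    u_h = axis_h / np.linalg.norm(axis_h)
    for _ in range(attempts):
        u_frac = rng.uniform(0.55, 0.85)
        cross_pt = b_h + u_frac * axis_h
        angle = np.deg2rad(rng.uniform(40.0, 80.0))
        # random direction at the prescribed angle to the host axis
        perp = np.cross(u_h, rng.normal(size=3))
        norm = np.linalg.norm(perp)
        if norm < 1e-9:
            continue
        perp /= norm
        spin = rng.uniform(0, 2 * np.pi)
        perp = np.cos(spin) * perp + np.sin(spin) * np.cross(u_h, perp)
        perp /= np.linalg.norm(perp)
        direction = np.cos(angle) * u_h + np.sin(angle) * perp
        if direction[2] < -0.2:  # keep pods from diving downward
            direction = np.cos(angle) * u_h - np.sin(angle) * perp
        length = rng.uniform(*spec.silique_length_range)
        v_frac = rng.uniform(0.55, 0.85)
        base = cross_pt - v_frac * length * direction
        tip = base + length * direction
        if _clearance_ok(base, tip, segments, spec.min_clearance, skip=h_idx):
            segments.append((base, tip))
            return True
    return False


def _sample_silique(base: np.ndarray, tip: np.ndarray, n: int, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    axis = tip - base
    u = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    t = rng.uniform(0.0, 1.0, n)[:, None]
    radial = rng.normal(0.0, sigma, (n, 2))
    return base + t * axis + radial[:, :1] * v + radial[:, 1:] * w


def _sample_stem(spec: PlantSpec, rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(0.0, spec.stem_height, spec.stem_points)
    theta = rng.uniform(0.0, 2 * np.pi, spec.stem_points)
    r = spec.stem_radius + rng.normal(0.0, 0.15 * spec.stem_radius,
                                      spec.stem_points)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_plant(spec: PlantSpec) -> SyntheticPlant:
    """Generate one plant: stem shell + N noisy silique segments.

    Deterministic per ``spec.seed``. Non-adhered silique axes keep a
    pairwise clearance of at least ``spec.min_clearance`` (default twice
    the counting stage's 0.018 m inlier band); infeasibly crowded specs
    raise after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    segments = _place_segments(spec, rng)
    stem = _sample_stem(spec, rng)
    coords = [stem]
    ids = [np.full(spec.stem_points, -1)]
    for i, (base, tip) in enumerate(segments):
        pts = _sample_silique(base, tip, spec.points_per_silique,
                              spec.silique_radius, rng)
        coords.append(pts)
        ids.append(np.full(spec.points_per_silique, i))
    coords = np.vstack(coords)
    silique_ids = np.concatenate(ids)
    labels = (silique_ids >= 0).astype(int)
    return SyntheticPlant(PointCloud(coords, labels), silique_ids,
                          segments, spec)


# ---------------------------------------------------------------------------
# Frame sequences
# ---------------------------------------------------------------------------

def _make_texture(rng: np.random.Generator, size: int) -> np.ndarray:
    """Blobby high-contrast texture with plenty of corner features."""
    coarse = rng.random((size // 8, size // 8))
    field_img = ndimage.zoom(coarse, 8, order=1)[:size, :size]
    blobs = (field_img > np.median(field_img)).astype(float)
    # sprinkle small bright squares for additional corners
    for _ in range(60):
        r, c = rng.integers(0, size - 8, 2)
        blobs[r:r + 6, c:c + 6] = rng.random() > 0.5
    smooth = ndimage.gaussian_filter(blobs, 0.8)
    return (smooth * 255).clip(0, 255)


def make_frame_sequence(n_frames: int,
                        blur_indices: set[int] | None = None,
                        texture_seed: int = 0,
                        frame_size: int = 128,
                        rotation_per_frame_deg: float = 1.2,
                        shift_per_frame: float = 0.6,
                        blur_sigma: float = 3.0,
                        ) -> tuple[list[ImageFrame], dict]:
    """Render a drifting textured scene; blur the frames in ``blur_indices``.

    Returns the frames plus ground truth: the blurred index set and each
    frame's cumulative transform magnitude (degrees rotated). Similarity
    between frames decays with their transform distance, so consecutive
    frames match far better than distant ones.
    """
    from skimage.transform import AffineTransform, warp

    blur_indices = set(blur_indices or ())
    if blur_indices and (min(blur_indices) < 0 or max(blur_indices) >= n_frames):
        raise ValueError("blur_indices out of range")
    rng = np.random.default_rng(texture_seed)
    canvas = _make_texture(rng, frame_size * 2)
    center = frame_size  # canvas center
    lo = frame_size // 2
    frames: list[ImageFrame] = []
    rotations = []
    for i in range(n_frames):
        angle = np.deg2rad(rotation_per_frame_deg * i)
        shift = shift_per_frame * i
        tf = (AffineTransform(translation=(-center, -center))
              + AffineTransform(rotation=angle)
              + AffineTransform(translation=(center + shift, center)))
        img = warp(canvas, tf.inverse, order=1, mode="reflect")
        view = img[lo:lo + frame_size, lo:lo + frame_size]
        if i in blur_indices:
            view = ndimage.gaussian_filter(view, blur_sigma)
        frames.append(ImageFrame(i, view.clip(0, 255).astype(np.uint8)))
        rotations.append(rotation_per_frame_deg * i)
    truth = {"blur_indices": sorted(blur_indices),
             "rotation_deg": rotations,
             "shift_px": [shift_per_frame * i for i in range(n_frames)]}
    return frames, truth
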