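"""Keyframe selection from circling-camera plant videos.

A hand-held video of a plant yields hundreds of frames, many blurred by
camera shake and most redundant with their neighbours. Reconstruction
wants a sharp, evenly-overlapping subset. Two measurements drive the
selection:

* **sharpness** — the variance of the Laplacian of the (bilateral-filtered,
  grayscale) image; blur removes high-frequency content, so low variance
  flags a blurry frame;
* **similarity** — 100 * MatchNum / Matches, where Matches counts 2-NN
  feature-descriptor correspondences between two frames and MatchNum the
  correspondences surviving Lowe's ratio test.

The selection loop walks the sequence with stride ``interval_k``,
skipping blurred frames, and accepts a candidate when its similarity to
the previous accepted keyframe lies in the band [s1, s2]; above the band
(too redundant) the candidate advances by ``step_i``, below it (too
little overlap) it retreats by ``step_i``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import ORB
from skimage.restoration import denoise_bilateral

__all__ = [
    "ImageFrame",
    "MatchResult",
    "KeyframeParams",
    "BilateralConfig",
    "sharpness_score",
    "frame_similarity",
    "select_keyframes",
]

#: 4-neighbour Laplacian template used for the sharpness convolution.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

#: ITU-R BT.601 luma weights for the colour->grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BilateralConfig:
    """Edge-preserving denoise applied before the Laplacian.

    Window diameter 9 with wide range/space sigmas: effectively a strong
    local smooth that still respects edges, so sensor noise does not
    masquerade as sharpness.
    """

    win_size: int = 9
    sigma_color: float = 75.0 / 255.0
    sigma_spatial: float = 75.0


@dataclass
class ImageFrame:
    """One video frame: index in the sequence, pixels, cached sharpness."""

    index: int
    pixels: np.ndarray
    sharpness: float | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D or 3D array")

    def ensure_sharpness(self, config: BilateralConfig | None = None) -> float:
        if self.sharpness is None:
            self.sharpness = sharpness_score(self.pixels, config)
        return self.sharpness


@dataclass(frozen=True)
class MatchResult:
    """Feature-matching outcome between two frames."""

    matches: int
    match_num: int
    similarity: float

    def __post_init__(self) -> None:
        if not 0 <= self.match_num <= self.matches:
            raise ValueError("require 0 <= match_num <= matches")
        if not 0.0 <= self.similarity <= 100.0:
            raise ValueError("similarity must lie in [0, 100]")


@dataclass(frozen=True)
class KeyframeParams:
    """Knobs of the selection loop.

    ``s1``/``s2`` bound the acceptable similarity to the previous
    keyframe; ``interval_k`` is the coarse stride and ``step_i`` the fine
    adjustment; frames scoring below ``blur_threshold`` are skipped
    (None = sequence-relative, the 10th percentile of the sequence's
    sharpness scores).
    """

    interval_k: int = 8
    s1: float = 25.0
    s2: float = 65.0
    step_i: int = 1
    blur_threshold: float | None = None
    ratio_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.interval_k < 1 or self.step_i < 1:
            raise ValueError("interval_k and step_i must be positive")
        if self.step_i >= self.interval_k:
            raise ValueError("step_i must be smaller than interval_k")
        if not 0.0 <= self.s1 < self.s2 <= 100.0:
            raise ValueError("require 0 <= s1 < s2 <= 100")
        if not 0.0 < self.ratio_threshold <= 1.0:
            raise ValueError("ratio_threshold must lie in (0, 1]")

    @classmethod
    def for_sequence(cls, n_frames: int, **overrides) -> "KeyframeParams":
        """Defaults scaled to sequence length: K ~ n/120, I ~ K/5."""
        k = overrides.pop("interval_k", max(1, n_frames // 120))
        i = overrides.pop("step_i", max(1, k // 5))
        if i >= k:
            i = max(1, k - 1) if k > 1 else 1
            k = max(k, i + 1)
        return cls(interval_k=k, step_i=i, **overrides)


# ---------------------------------------------------------------------------
# Sharpness
# ---------------------------------------------------------------------------

def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion; grayscale input passes through as float."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        return pixels[..., :3] @ LUMA_WEIGHTS
    return pixels


def sharpness_score(pixels: np.ndarray,
                    config: BilateralConfig | None = None) -> float:
    """Variance of the Laplacian of the denoised grayscale image.

    Steps: bilateral filter (noise would otherwise inflate the score),
    grayscale conversion, 4-neighbour Laplacian convolution with reflect
    borders, then the population variance of the response. Zero for a
    constant image; monotonically degraded by blurring.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim not in (2, 3) or pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("image must be at least 3x3 pixels")
    config = config or BilateralConfig()
    img = pixels.astype(float) / 255.0
    filtered = denoise_bilateral(
        img, win_size=config.win_size, sigma_color=config.sigma_color,
        sigma_spatial=config.sigma_spatial,
        channel_axis=-1 if img.ndim == 3 else None)
    gray = to_grayscale(filtered * 255.0)
    lap = ndimage.convolve(gray, LAPLACIAN_KERNEL, mode="reflect")
    return float(np.mean((lap - lap.mean()) ** 2))


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _detect_orb(gray: np.ndarray, n_keypoints: int) -> np.ndarray | None:
    orb = ORB(n_keypoints=n_keypoints)
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # skimage raises when no keypoints survive
        return None
    if orb.descriptors is None or len(orb.descriptors) == 0:
        return None
    return orb.descriptors  # (n, 256) bool


def frame_similarity(frame_a: ImageFrame, frame_b: ImageFrame,
                     ratio_threshold: float = 0.7,
                     n_keypoints: int = 400) -> MatchResult:
    """Feature-matching similarity between two frames.

    Detects ORB keypoints on both grayscale images, matches descriptors
    a->b with 2-nearest-neighbour Hamming search, applies the ratio test
    at ``ratio_threshold``, and reports Similarity = 100*MatchNum/Matches.
    Frames with no detectable features yield MatchResult(0, 0, 0) with a
    warning rather than an error.
    """
    gray_a = to_grayscale(frame_a.pixels) / 255.0
    gray_b = to_grayscale(frame_b.pixels) / 255.0
    desc_a = _detect_orb(gray_a, n_keypoints)
    desc_b = _detect_orb(gray_b, n_keypoints)
    if desc_a is None or desc_b is None or len(desc_b) < 2:
        warnings.warn("frame_similarity: too few features detected; "
                      "similarity reported as 0", stacklevel=2)
        return MatchResult(0, 0, 0.0)
    # Hamming distances between binary descriptors.
    dist = (desc_a[:, None, :] != desc_b[None, :, :]).sum(axis=2)
    part = np.partition(dist, 1, axis=1)
    d1, d2 = part[:, 0].astype(float), part[:, 1].astype(float)
    matches = len(desc_a)  # candidate 2-NN pairs, before the ratio test
    # Ratio test (d1 <= r * d2); a perfect duplicate pair (0, 0) passes.
    keep = d1 <= ratio_threshold * d2
    match_num = int(keep.sum())
    return MatchResult(matches, match_num, 100.0 * match_num / matches)


# ---------------------------------------------------------------------------
# Selection loop
# ---------------------------------------------------------------------------

def _resolve_blur_threshold(frames: list[ImageFrame],
                            params: KeyframeParams,
                            config: BilateralConfig | None) -> float:
    scores = np.array([f.ensure_sharpness(config) for f in frames])
    if params.blur_threshold is not None:
        return params.blur_threshold
    return float(np.percentile(scores, 10.0))


def select_keyframes(frames: list[ImageFrame],
                     params: KeyframeParams | None = None,
                     bilateral: BilateralConfig | None = None,
                     similarity_fn=None) -> list[int]:
    """Select a sharp, evenly-overlapping keyframe subset.

    Returns strictly increasing frame indices. The first keyframe is the
    earliest non-blurred frame; each subsequent candidate starts
    ``interval_k`` frames after the last accepted keyframe, skips blurred
    frames, and is accepted when its similarity to the last keyframe
    falls inside [s1, s2]. Out-of-band candidates are nudged by
    ``step_i`` (forward when too similar, backward when too dissimilar);
    an oscillation guard skips ahead by ``interval_k`` if the nudging
    revisits an index, so the loop always terminates.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    if params is None:
        params = KeyframeParams.for_sequence(len(frames))
    if similarity_fn is None:
        similarity_fn = lambda a, b: frame_similarity(
            a, b, ratio_threshold=params.ratio_threshold).similarity
    n = len(frames)
    blur_threshold = _resolve_blur_threshold(frames, params, bilateral)
    sharp = [frames[i].ensure_sharpness(bilateral) >= blur_threshold
             for i in range(n)]

    def next_sharp(i: int) -> int | None:
        while i < n and not sharp[i]:
            i += 1
        return i if i < n else None

    start = next_sharp(0)
    if start is None:
        warnings.warn("select_keyframes: every frame is below the blur "
                      "threshold; nothing selected", stacklevel=2)
        return []
    selected = [start]
    scan_base = start + params.interval_k
    while scan_base < n:
        anchor = selected[-1]
        tested: set[int] = set()
        cand = next_sharp(scan_base)
        accepted = None
        # Fine adjustment: nudge by +/- step_i until in band. Revisiting a
        # tested index (or retreating onto the anchor) means no in-band
        # frame is reachable here -> fall through to the guard below.
        while cand is not None and cand not in tested and cand > anchor:
            tested.add(cand)
            sim = similarity_fn(frames[anchor], frames[cand])
            if params.s1 <= sim <= params.s2:
                accepted = cand
                break
            nxt = cand + (params.step_i if sim > params.s2 else -params.step_i)
            cand = next_sharp(nxt) if nxt >= 0 else None
        if accepted is not None:
            selected.append(accepted)
            scan_base = accepted + params.interval_k
        elif tested:
            # Oscillation guard: skip one coarse interval past the furthest
            # frame examined. scan_base strictly increases, so this terminates.
            scan_base = max(tested) + params.interval_k
        else:
            break  # only blurred frames remain
    return selected


# ---------------------------------------------------------------------------
# Frame I/O
# ---------------------------------------------------------------------------

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def load_frames(path: str) -> list[ImageFrame]:
    """Load a frame sequence from a directory of PNG/JPEG images.

    Files are ordered by name; the resulting frame indices are their
    positions in that ordering. Video files must be pre-extracted to
    frames (no video decoder ships with this package).
    """
    import imageio.v3 as iio

    if os.path.isfile(path):
        raise ValueError(
            f"{path!r} is a file; extract video frames to an image directory "
            "first (e.g. with ffmpeg) and pass that directory")
    names = sorted(f for f in os.listdir(path)
                   if f.lower().endswith(_IMAGE_EXTS))
    if not names:
        raise ValueError(f"no PNG/JPEG frames found in {path!r}")
    return [ImageFrame(i, iio.imread(os.path.join(path, name)))
            for i, name in enumerate(names)]


def save_keyframes(frames: list[ImageFrame], indices: list[int],
                   out_dir: str) -> str:
    """Write selected keyframes as numbered PNGs plus a JSON manifest.

    The manifest records, per keyframe, its source index, sharpness and
    similarity to the previous keyframe. Returns the manifest path.
    """
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    prev = None
    for rank, idx in enumerate(indices):
        frame = frames[idx]
        name = f"keyframe_{rank:04d}.png"
        iio.imwrite(os.path.join(out_dir, name),
                    np.asarray(frame.pixels, dtype=np.uint8))
        sim = None
        if prev is not None:
            sim = frame_similarity(frames[prev], frame).similarity
        manifest.append({"file": name, "source_index": int(idx),
                         "sharpness": float(frame.ensure_sharpness()),
                         "similarity_to_previous": sim})
        prev = idx
    manifest_path = os.path.join(out_dir, "keyframes.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
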