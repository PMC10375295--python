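"""Point-cloud containers and I/O.

Clouds are plain coordinate arrays (meters) with optional integer class
labels and 8-bit colors. Three on-disk dialects are supported:

* whitespace-delimited TXT ``x y z [label] [r g b]`` (the CloudCompare
  labeling export dialect; labels round-trip exactly),
* PLY, ascii or binary little-endian, with an optional integer ``label``
  vertex property,
* PCD ascii v0.7 with fields ``x y z`` and optional ``label``.

The passthrough filter and the two downsamplers (farthest-point and
random) used ahead of segmentation also live here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "PointCloud",
    "PassthroughRange",
    "CloudIOError",
    "EmptyCloudError",
    "read_cloud",
    "write_cloud",
    "passthrough",
    "downsample",
    "farthest_point_indices",
]


class CloudIOError(ValueError):
    """Raised for unreadable or malformed cloud files."""


class EmptyCloudError(ValueError):
    """Raised when an operation would produce or read an empty cloud."""


@dataclass
class PointCloud:
    """N x 3 coordinates with optional per-point labels and colors.

    Labels are small non-negative integers; the semantic-segmentation
    convention is 0 = stem, 1 = silique, while per-silique instance
    output uses one distinct integer per fitted silique.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.coords),):
                raise ValueError("labels length must match coords")
            if self.labels.size and self.labels.min() < 0:
                raise ValueError("labels must be non-negative")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8)
            if self.colors.shape != (len(self.coords), 3):
                raise ValueError("colors must be (N, 3)")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset by integer or boolean index, carrying labels/colors along."""
        return PointCloud(
            self.coords[index],
            None if self.labels is None else self.labels[index],
            None if self.colors is None else self.colors[index],
        )


@dataclass(frozen=True)
class PassthroughRange:
    """Axis-aligned interval for the passthrough background filter."""

    axis: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y", "z"):
            raise ValueError(f"axis must be one of x/y/z, got {self.axis!r}")
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def axis_index(self) -> int:
        return "xyz".index(self.axis)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("ply", "pcd", "txt")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("xyz",):
        ext = "txt"
    if ext not in _FORMATS:
        raise CloudIOError(f"cannot infer cloud format from extension of {path!r}")
    return ext


def read_cloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud from PLY / PCD / labeled TXT.

    TXT rows with four or more columns carry a label in column 4 and
    optional ``r g b`` in columns 5-7.
    """
    if format == "auto":
        format = _infer_format(path)
    if format not in _FORMATS:
        raise CloudIOError(f"unknown format {format!r}")
    if not os.path.exists(path):
        raise CloudIOError(f"no such file: {path}")
    if format == "txt":
        cloud = _read_txt(path)
    elif format == "pcd":
        cloud = _read_pcd(path)
    else:
        cloud = _read_ply(path)
    if len(cloud) == 0:
        raise EmptyCloudError(f"{path}: cloud has no points")
    return cloud


def write_cloud(path: str, cloud: PointCloud, format: str = "auto",
                binary: bool = False) -> None:
    if format == "auto":
        format = _infer_format(path)
    if format == "txt":
        _write_txt(path, cloud)
    elif format == "pcd":
        _write_pcd(path, cloud)
    elif format == "ply":
        _write_ply(path, cloud, binary=binary)
    else:
        raise CloudIOError(f"unknown format {format!r}")


def _read_txt(path: str) -> PointCloud:
    coords, labels, colors = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if ncols is None:
                ncols = len(parts)
                if ncols not in (3, 4, 6, 7):
                    raise CloudIOError(
                        f"{path}:{lineno}: expected 3, 4, 6 or 7 columns, got {ncols}")
            if len(parts) != ncols:
                raise CloudIOError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})")
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise CloudIOError(f"{path}:{lineno}: {exc}") from None
            coords.append(vals[:3])
            if ncols in (4, 7):
                labels.append(int(vals[3]))
            if ncols == 6:
                colors.append(vals[3:6])
            elif ncols == 7:
                colors.append(vals[4:7])
    if not coords:
        raise EmptyCloudError(f"{path}: no points")
    return PointCloud(
        np.asarray(coords),
        np.asarray(labels, dtype=int) if labels else None,
        np.asarray(colors, dtype=np.uint8) if colors else None,
    )


def _write_txt(path: str, cloud: PointCloud) -> None:
    cols = [cloud.coords]
    fmt = ["%.17g"] * 3
    if cloud.labels is not None:
        cols.append(cloud.labels[:, None].astype(float))
        fmt.append("%d")
    if cloud.colors is not None:
        cols.append(cloud.colors.astype(float))
        fmt += ["%d"] * 3
    np.savetxt(path, np.hstack(cols), fmt=" ".join(fmt).split())


def _read_ply(path: str) -> PointCloud:
    try:
        mesh = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise CloudIOError(f"{path}: PLY parse failed: {exc}") from exc
    if not hasattr(mesh, "vertices"):
        raise EmptyCloudError(f"{path}: PLY has 0 vertices")
    verts = np.asarray(mesh.vertices, dtype=float)
    if verts.size == 0:
        raise EmptyCloudError(f"{path}: PLY has 0 vertices")
    labels = None
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is not None:
        names = raw.dtype.names if hasattr(raw, "dtype") and raw.dtype.names \
            else (raw.keys() if hasattr(raw, "keys") else ())
        if "label" in names:
            labels = np.asarray(raw["label"], dtype=int).ravel()
    colors = None
    if isinstance(mesh, trimesh.PointCloud) and mesh.colors is not None \
            and len(mesh.colors) == len(verts):
        colors = np.asarray(mesh.colors)[:, :3].astype(np.uint8)
    return PointCloud(verts, labels, colors)


def _write_ply(path: str, cloud: PointCloud, binary: bool = False) -> None:
    n = len(cloud)
    props = ["property float x", "property float y", "property float z"]
    if cloud.colors is not None:
        props += ["property uchar red", "property uchar green", "property uchar blue"]
    if cloud.labels is not None:
        props.append("property int label")
    header = "\n".join(
        ["ply",
         "format binary_little_endian 1.0" if binary else "format ascii 1.0",
         f"element vertex {n}", *props, "end_header", ""])
    if binary:
        dt = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
        if cloud.colors is not None:
            dt += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        if cloud.labels is not None:
            dt += [("label", "<i4")]
        rec = np.empty(n, dtype=dt)
        rec["x"], rec["y"], rec["z"] = cloud.coords.astype(np.float32).T
        if cloud.colors is not None:
            rec["red"], rec["green"], rec["blue"] = cloud.colors.T
        if cloud.labels is not None:
            rec["label"] = cloud.labels
        with open(path, "wb") as fh:
            fh.write(header.encode())
            rec.tofile(fh)
        return
    with open(path, "w") as fh:
        fh.write(header)
        for i in range(n):
            row = ["%.9g" % v for v in cloud.coords[i].astype(np.float32)]
            if cloud.colors is not None:
                row += [str(int(v)) for v in cloud.colors[i]]
            if cloud.labels is not None:
                row.append(str(int(cloud.labels[i])))
            fh.write(" ".join(row) + "\n")


def _read_pcd(path: str) -> PointCloud:
    fields: list[str] = []
    n_expected = None
    data_started = False
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not data_started:
                key, *rest = line.split()
                key = key.upper()
                if key == "FIELDS":
                    fields = rest
                elif key == "POINTS":
                    n_expected = int(rest[0])
                elif key == "DATA":
                    if rest and rest[0] != "ascii":
                        raise CloudIOError(
                            f"{path}:{lineno}: only ascii PCD is supported")
                    data_started = True
                continue
            parts = line.split()
            if len(parts) != len(fields):
                raise CloudIOError(
                    f"{path}:{lineno}: expected {len(fields)} values, got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise CloudIOError(f"{path}:{lineno}: {exc}") from None
    if not data_started or not fields:
        raise CloudIOError(f"{path}: missing PCD header")
    for ax in ("x", "y", "z"):
        if ax not in fields:
            raise CloudIOError(f"{path}: PCD lacks field {ax!r}")
    if not rows:
        raise EmptyCloudError(f"{path}: no points")
    if n_expected is not None and n_expected != len(rows):
        raise CloudIOError(
            f"{path}: POINTS says {n_expected} but {len(rows)} rows present")
    arr = np.asarray(rows)
    coords = arr[:, [fields.index(a) for a in "xyz"]]
    labels = None
    if "label" in fields:
        labels = arr[:, fields.index("label")].astype(int)
    return PointCloud(coords, labels)


def _write_pcd(path: str, cloud: PointCloud) -> None:
    fields = ["x", "y", "z"] + (["label"] if cloud.labels is not None else [])
    n = len(cloud)
    types = ["F", "F", "F"] + (["I"] if cloud.labels is not None else [])
    sizes = ["4"] * len(fields)
    counts = ["1"] * len(fields)
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write("FIELDS " + " ".join(fields) + "\n")
        fh.write("SIZE " + " ".join(sizes) + "\n")
        fh.write("TYPE " + " ".join(types) + "\n")
        fh.write("COUNT " + " ".join(counts) + "\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {n}\nDATA ascii\n")
        for i in range(n):
            row = ["%.9g" % v for v in cloud.coords[i].astype(np.float32)]
            if cloud.labels is not None:
                row.append(str(int(cloud.labels[i])))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def passthrough(cloud: PointCloud, rng: PassthroughRange) -> PointCloud:
    """Keep points whose coordinate on one axis lies in [lo, hi] (closed).

    The standard background-removal step: everything outside the band
    (pot, floor, backdrop) is dropped.
    """
    vals = cloud.coords[:, rng.axis_index]
    mask = (vals >= rng.lo) & (vals <= rng.hi)
    if not mask.any():
        raise EmptyCloudError(
            f"passthrough on {rng.axis} in [{rng.lo}, {rng.hi}] removed every point")
    return cloud.select(mask)


def farthest_point_indices(coords: np.ndarray, target_n: int, seed: int = 0,
                           start_index: int | None = None) -> np.ndarray:
    """Greedy farthest-point sampling; the seed picks the starting point
    unless ``start_index`` fixes it.

    Each iteration adds the point farthest (Euclidean) from the set
    selected so far, preserving shape far better than random subsampling
    at equal budget.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if not 1 <= target_n <= n:
        raise ValueError(f"target_n must be in [1, {n}], got {target_n}")
    rng = np.random.default_rng(seed)
    chosen = np.empty(target_n, dtype=int)
    chosen[0] = start_index if start_index is not None else rng.integers(n)
    d2 = np.sum((coords - coords[chosen[0]]) ** 2, axis=1)
    for i in range(1, target_n):
        nxt = int(np.argmax(d2))
        chosen[i] = nxt
        np.minimum(d2, np.sum((coords - coords[nxt]) ** 2, axis=1), out=d2)
    return chosen


def downsample(cloud: PointCloud, target_n: int, method: str = "fps",
               seed: int = 0) -> PointCloud:
    """Reduce the cloud to exactly ``target_n`` of its own points.

    ``fps`` (farthest-point, default) preserves thin structures such as
    siliques; ``random`` is a uniform subsample. Deterministic per seed.
    """
    if target_n > len(cloud):
        raise ValueError(
            f"target_n {target_n} exceeds cloud size {len(cloud)}")
    if method == "fps":
        idx = farthest_point_indices(cloud.coords, target_n, seed)
    elif method == "random":
        idx = np.random.default_rng(seed).choice(len(cloud), size=target_n,
                                                 replace=False)
    else:
        raise ValueError(f"unknown downsample method {method!r}")
    return cloud.select(np.sort(idx))
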