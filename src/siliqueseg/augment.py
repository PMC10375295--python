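"""Training-set augmentation and splitting for the segmentation network.

Each labeled cloud is expanded ``copies``-fold (default 6, so 90 base
clouds become 540) by drawing, per copy, one random translation vector
with components in [-0.2, 0.2] and three per-axis scale factors in
[0.65, 1.7]; points are scaled then translated, labels untouched. The
augmented pool is split 70/15/15 into train/validation/test, keeping all
copies of one source plant inside a single partition so no plant leaks
across splits.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np

from .cloudio import PointCloud, read_cloud, write_cloud

__all__ = ["AugmentParams", "augment_cloud", "draw_transforms",
           "split_dataset", "split_sizes"]


@dataclass(frozen=True)
class AugmentParams:
    translation_range: tuple[float, float] = (-0.2, 0.2)
    scale_range: tuple[float, float] = (0.65, 1.7)
    copies: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        t_lo, t_hi = self.translation_range
        s_lo, s_hi = self.scale_range
        if t_lo > t_hi or s_lo > s_hi:
            raise ValueError("ranges must be non-empty intervals")
        if s_lo <= 0:
            raise ValueError("scale_range must be strictly positive")
        if self.copies < 1:
            raise ValueError("copies must be positive")


def draw_transforms(params: AugmentParams) -> list[tuple[np.ndarray, np.ndarray]]:
    """The (scale, translation) draws augment_cloud will apply, in order.

    Exposed so the applied arithmetic can be audited: copy ``i`` maps a
    point p to ``p * scale_i + translation_i`` (component-wise).
    """
    rng = np.random.default_rng(params.seed)
    out = []
    for _ in range(params.copies):
        scale = rng.uniform(*params.scale_range, 3)
        translation = rng.uniform(*params.translation_range, 3)
        out.append((scale, translation))
    return out


def augment_cloud(cloud: PointCloud, params: AugmentParams) -> list[PointCloud]:
    """Random anisotropic scaling + translation copies of a labeled cloud.

    Transform order is scale-then-translate. Deterministic per
    ``params.seed``; labels and colors are carried through unchanged.
    """
    if not cloud.is_labeled:
        raise ValueError("augment_cloud requires a labeled cloud")
    return [PointCloud(cloud.coords * scale + translation,
                       cloud.labels.copy(),
                       None if cloud.colors is None else cloud.colors.copy())
            for scale, translation in draw_transforms(params)]


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Partition sizes: val/test round half-down, remainder to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = _round_half_down(n * fractions[1])
    n_test = _round_half_down(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"cannot split {n} clouds into three non-empty parts")
    return n_train, n_val, n_test


def split_dataset(clouds: list, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0, groups: list | None = None,
                  ) -> tuple[list, list, list]:
    """Shuffle and partition into (train, val, test).

    With ``groups`` (one hashable id per cloud, e.g. the source plant of
    each augmented copy), whole groups are assigned to one partition, by
    group count, so augmented copies never straddle a split.
    """
    n = len(clouds)
    if n < 3:
        raise ValueError("need at least 3 clouds to split")
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(n)
        n_train, n_val, n_test = split_sizes(n, fractions)
        train_idx = order[:n_train]
        val_idx = order[n_train:n_train + n_val]
        test_idx = order[n_train + n_val:]
    else:
        if len(groups) != n:
            raise ValueError("groups must be one id per cloud")
        uniq = sorted(set(groups), key=str)
        g_order = rng.permutation(len(uniq))
        g_train, g_val, g_test = split_sizes(len(uniq), fractions)
        part_of = {}
        for rank, gi in enumerate(g_order):
            part = 0 if rank < g_train else (1 if rank < g_train + g_val else 2)
            part_of[uniq[gi]] = part
        buckets: tuple[list, list, list] = ([], [], [])
        for i, g in enumerate(groups):
            buckets[part_of[g]].append(i)
        train_idx, val_idx, test_idx = (np.array(b, dtype=int) for b in buckets)
    pick = lambda idx: [clouds[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def augment_directory(in_dir: str, out_dir: str, params: AugmentParams,
                      fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                      ) -> str:
    """Augment every labeled TXT cloud in ``in_dir`` and write a split.

    Writes the augmented copies as TXT plus ``manifest.json`` naming the
    members of each split. Returns the manifest path.
    """
    names = sorted(f for f in os.listdir(in_dir) if f.endswith(".txt"))
    if not names:
        raise ValueError(f"no .txt clouds in {in_dir!r}")
    os.makedirs(out_dir, exist_ok=True)
    entries, groups = [], []
    for gi, name in enumerate(names):
        cloud = read_cloud(os.path.join(in_dir, name))
        if not cloud.is_labeled:
            raise ValueError(f"{name} has no labels")
        sub = AugmentParams(params.translation_range, params.scale_range,
                            params.copies, params.seed + gi)
        for ci, copy in enumerate(augment_cloud(cloud, sub)):
            out_name = f"{os.path.splitext(name)[0]}_aug{ci}.txt"
            write_cloud(os.path.join(out_dir, out_name), copy)
            entries.append(out_name)
            groups.append(name)
    train, val, test = split_dataset(entries, fractions, seed=params.seed,
                                     groups=groups)
    manifest = {"train": train, "val": val, "test": test}
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
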