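"""Disk-referenced intensity normalization and GrowCut marrow segmentation.

T1 marrow signal is only interpretable relative to an internal
reference; here each volume is normalized by subtracting the mean
intensity of the annulus fibrosus of the most cranial non-degenerated
intervertebral disk, which removes per-scanner global intensity
offsets.  Marrow is then segmented with a 3D GrowCut cellular
automaton: seeded cells iteratively conquer neighbors whose intensity
is similar, with conquest strength attenuated by the intensity
difference.  Updates are synchronous (Jacobi-style) so the result is
independent of voxel visit order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .phantom import AnatomyLabels, SpineVolume, BACKGROUND, DISK_BASE, OTHER_TISSUE

__all__ = [
    "DiskROI",
    "SeedSet",
    "MarrowMask",
    "select_reference_disk",
    "split_disk_regions",
    "annulus_mask",
    "normalize_by_disk",
    "auto_seeds",
    "growcut_segment",
    "save_seeds",
    "load_seeds",
    "dice_coefficient",
    "FOREGROUND",
    "BACKGROUND_SEED",
]

FOREGROUND = 1
BACKGROUND_SEED = 2

_EPS = 1e-6  # attack-function clip: keeps seed strength 1 unbeatable


@dataclass
class DiskROI:
    """One intervertebral disk selected as the normalization reference."""

    disk_level: int
    mask: np.ndarray  # 3D boolean
    ap_axis: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("DiskROI mask is empty")


@dataclass
class SeedSet:
    """Labeled seed voxels driving GrowCut; initial strength is 1."""

    coordinates: np.ndarray  # (k, 3) int voxel indices
    labels: np.ndarray  # (k,) in {FOREGROUND, BACKGROUND_SEED}

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.intp)
        self.labels = np.asarray(self.labels)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (k, 3)")
        if self.coordinates.shape[0] != self.labels.shape[0]:
            raise ValueError("coordinates/labels length mismatch")
        for lbl in (FOREGROUND, BACKGROUND_SEED):
            if not np.any(self.labels == lbl):
                raise ValueError("need at least one seed per label")

    def validate_bounds(self, shape) -> None:
        if np.any(self.coordinates < 0) or np.any(
            self.coordinates >= np.asarray(shape)
        ):
            raise ValueError("seed coordinates outside volume bounds")


@dataclass
class MarrowMask:
    """GrowCut output: binary marrow mask plus convergence bookkeeping."""

    mask: np.ndarray
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# reference disk and normalization


def select_reference_disk(labels: AnatomyLabels) -> DiskROI:
    """Most cranial (superior) disk whose degeneration flag is False.

    Cranial order is determined geometrically by the disk centroid row
    (rows increase superior to inferior).
    """
    candidates = []
    for code, degenerated in labels.degeneration_flags.items():
        mask = labels.labels == code
        if not mask.any():
            continue
        mean_row = np.nonzero(mask)[1].mean()
        candidates.append((mean_row, code, degenerated, mask))
    candidates.sort(key=lambda t: (t[0], t[1]))
    for _, code, degenerated, mask in candidates:
        if not degenerated:
            return DiskROI(disk_level=code - DISK_BASE, mask=mask)
    raise ValueError("no reference disk: all intervertebral disks are degenerated")


def split_disk_regions(roi: DiskROI) -> tuple[list[np.ndarray], np.ndarray]:
    """Partition a disk into 5 equal-width bins along the AP axis.

    Returns the five bin masks (anterior to posterior) and the annulus
    mask (union of bins 1 and 5).  Bins are disjoint and cover the ROI
    exactly.
    """
    coords = np.nonzero(roi.mask)[roi.ap_axis]
    cmin, cmax = int(coords.min()), int(coords.max())
    extent = cmax - cmin + 1
    if extent < 5:
        raise ValueError(
            f"disk AP extent {extent} voxels is too small to split into 5 regions"
        )
    axis_coord = np.arange(roi.mask.shape[roi.ap_axis])
    rel = np.clip(((axis_coord - cmin) * 5) // extent, 0, 4)
    shape = [1, 1, 1]
    shape[roi.ap_axis] = -1
    rel = rel.reshape(shape)
    bins = [roi.mask & (rel == k) for k in range(5)]
    annulus = bins[0] | bins[4]
    return bins, annulus


def annulus_mask(roi: DiskROI) -> np.ndarray:
    return split_disk_regions(roi)[1]


def normalize_by_disk(volume: SpineVolume, roi: DiskROI) -> SpineVolume:
    """Subtract the scalar mean of the reference annulus from every voxel.

    After normalization the annulus mean is 0, so the map is idempotent
    and invariant to global intensity offsets.
    """
    annulus = annulus_mask(roi)
    if not annulus.any():
        raise ValueError("annulus region is empty")
    mean = float(volume.voxels[annulus].mean())
    return SpineVolume(volume.voxels - mean, volume.spacing)


# ---------------------------------------------------------------------------
# seeding


def auto_seeds(labels: AnatomyLabels, erosion_radius: int = 1) -> SeedSet:
    """Deterministic seeds from ground-truth anatomy.

    Foreground seeds: each vertebral level's marrow label eroded by
    ``erosion_radius``.  Background seeds: erosion of the non-marrow
    region (background, disks, other tissue).  Erosion keeps seeds away
    from boundaries, which is what an interactive user would do.
    """
    struct = None  # 6-connected cross, applied `radius` times
    fg = np.zeros(labels.labels.shape, dtype=bool)
    for level in range(1, labels.n_levels + 1):
        m = labels.body_mask(level)
        if erosion_radius > 0:
            m = binary_erosion(m, structure=struct, iterations=erosion_radius)
        if not m.any():
            raise ValueError(
                f"vertebral level {level} vanished under erosion radius "
                f"{erosion_radius}"
            )
        fg |= m
    bg_region = ~labels.marrow_mask()
    if erosion_radius > 0:
        bg = binary_erosion(bg_region, structure=struct, iterations=erosion_radius)
    else:
        bg = bg_region
    if not bg.any():
        raise ValueError("background region vanished under erosion")
    coords = np.vstack([np.argwhere(fg), np.argwhere(bg)])
    labs = np.concatenate(
        [
            np.full(int(fg.sum()), FOREGROUND),
            np.full(int(bg.sum()), BACKGROUND_SEED),
        ]
    )
    return SeedSet(coords, labs)


# ---------------------------------------------------------------------------
# GrowCut


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    if connectivity == 6:
        return [
            (1, 0, 0),
            (-1, 0, 0),
            (0, 1, 0),
            (0, -1, 0),
            (0, 0, 1),
            (0, 0, -1),
        ]
    if connectivity == 26:
        return [
            (dz, dr, dc)
            for dz in (-1, 0, 1)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dz, dr, dc) != (0, 0, 0)
        ]
    raise ValueError("connectivity must be 6 or 26")


def _shift(a: np.ndarray, off: tuple[int, int, int], fill) -> np.ndarray:
    """Value of the neighbor at offset ``off`` for every voxel (edge -> fill)."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for d, size in zip(off, a.shape):
        if d >= 0:
            src.append(slice(d, size))
            dst.append(slice(0, size - d))
        else:
            src.append(slice(0, size + d))
            dst.append(slice(-d, size))
    out[tuple(dst)] = a[tuple(src)]
    return out


def growcut_segment(
    volume: SpineVolume,
    seeds: SeedSet,
    max_iters: int = 200,
    connectivity: int = 26,
    max_intensity_diff: float | None = None,
) -> MarrowMask:
    """Seeded cellular-automaton segmentation (GrowCut).

    Each voxel p carries a label l_p and strength theta_p in [0, 1].
    Per iteration, neighbor q conquers p when
    ``g(|I_p - I_q|) * theta_q > theta_p`` with
    ``g(x) = clip(1 - x / max_intensity_diff, eps, 1 - eps)``;
    p then adopts l_q and strength ``g * theta_q``.  Updates are
    synchronous; iteration stops at the first pass with no label
    change, or at ``max_iters`` (then ``converged=False``).
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    I = volume.voxels
    seeds.validate_bounds(I.shape)
    if max_intensity_diff is None:
        rng_ = float(I.max() - I.min())
        if rng_ == 0.0:
            raise ValueError("zero intensity range: cannot normalize attack function")
        max_intensity_diff = rng_
    if max_intensity_diff <= 0:
        raise ValueError("max_intensity_diff must be > 0")

    label = np.zeros(I.shape, dtype=np.int8)
    theta = np.zeros(I.shape, dtype=np.float64)
    z, r, c = seeds.coordinates.T
    label[z, r, c] = seeds.labels
    theta[z, r, c] = 1.0

    offsets = _neighbor_offsets(connectivity)
    iterations = 0
    converged = False
    for iterations in range(1, max_iters + 1):
        best_attack = np.zeros_like(theta)
        best_label = np.zeros_like(label)
        for off in offsets:
            Iq = _shift(I, off, fill=np.inf)  # edge neighbors can never attack
            thq = _shift(theta, off, fill=0.0)
            lq = _shift(label, off, fill=0)
            with np.errstate(invalid="ignore"):
                g = 1.0 - np.abs(I - Iq) / max_intensity_diff
            g = np.clip(np.nan_to_num(g, nan=-np.inf), _EPS, 1.0 - _EPS)
            attack = g * thq
            attack[lq == 0] = 0.0
            better = attack > best_attack
            best_attack[better] = attack[better]
            best_label[better] = lq[better]
        conquered = best_attack > theta
        new_label = np.where(conquered, best_label, label)
        changed = np.any(new_label != label)
        theta = np.where(conquered, best_attack, theta)
        label = new_label
        if not changed:
            converged = True
            break

    return MarrowMask(mask=label == FOREGROUND, iterations=iterations,
                      converged=converged)


def save_seeds(seeds: SeedSet, path) -> None:
    """Seed voxels as JSON: [{"coord": [z, r, c], "label": l}, ...]."""
    import json
    from pathlib import Path

    payload = [
        {"coord": [int(v) for v in coord], "label": int(lbl)}
        for coord, lbl in zip(seeds.coordinates, seeds.labels)
    ]
    Path(path).write_text(json.dumps(payload))


def load_seeds(path) -> SeedSet:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    coords = np.array([e["coord"] for e in payload], dtype=np.intp)
    labels = np.array([e["label"] for e in payload])
    return SeedSet(coords, labels)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
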