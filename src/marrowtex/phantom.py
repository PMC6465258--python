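"""Synthetic sagittal spine-MRI phantoms with known marrow disease labels.

The generator emulates the statistical structure a marrow texture
classifier exploits on T1-weighted lumbar-spine images: on T1, normal
adult (fatty) marrow is bright while diffusely infiltrated marrow is
darker and more heterogeneous.  A phantom is a stylized 2D-extruded
spine — a stack of rectangular vertebral bodies (S1 at the bottom,
ascending to L1) separated by lens-shaped intervertebral disks whose
bright nucleus pulposus is flanked, in the anterior and posterior
fifths, by a darker annulus fibrosus.  Marrow texture is a spatially
correlated Gaussian random field whose mean and dispersion depend on
disease status; scanner ("vendor") heterogeneity is a per-subject
global affine intensity map, plus i.i.d. Gaussian acquisition noise.
Optional focal confounds (fracture-like collapse, hemangioma-like
bright blob, Modic-like endplate band) can be injected.

All randomness flows through :class:`numpy.random.Generator` streams
derived from explicit seeds, so cohorts are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "SpineVolume",
    "AnatomyLabels",
    "SubjectRecord",
    "generate_subject",
    "generate_cohort",
    "inject_focal_lesion",
    "save_subject",
    "load_subject",
    "save_cohort",
    "load_cohort",
    "BACKGROUND",
    "OTHER_TISSUE",
    "DISK_BASE",
]

#: label codes
BACKGROUND = 0
OTHER_TISSUE = 200
DISK_BASE = 100  # disk above vertebral level i carries code DISK_BASE + i

#: intensity of the posterior soft-tissue band (arbitrary units)
_OTHER_TISSUE_MEAN = 55.0
#: default voxel spacing (slice, row, col) in mm, typical of 2D sagittal T1 TSE
_DEFAULT_SPACING = (3.3, 0.55, 0.55)

LESION_TYPES = ("fracture", "hemangioma", "modic")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cohort generator.

    Intensities are arbitrary units on the scale of a raw T1 image;
    only contrasts (marrow vs. disk vs. noise) matter downstream
    because every volume is disk-normalized before analysis.
    """

    image_shape: tuple[int, int, int] = (9, 256, 192)  # (slices, rows, cols)
    n_levels: int = 6  # vertebral bodies, S1 -> L1
    marrow_mean_normal: float = 100.0
    marrow_mean_diseased: float = 70.0
    marrow_texture_sd_normal: float = 5.0
    marrow_texture_sd_diseased: float = 12.0
    texture_corr_len: float = 2.0  # voxels
    disk_nucleus_mean: float = 120.0
    annulus_mean: float = 40.0
    vendor_offset_range: tuple[float, float] = (-20.0, 20.0)
    vendor_scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 3.0
    lesion_probs: dict[str, float] = field(
        default_factory=lambda: {"fracture": 0.0, "hemangioma": 0.0, "modic": 0.0}
    )
    seed: int = 0

    def validate(self) -> None:
        s, r, c = self.image_shape
        if s < 1 or r < 1 or c < 1:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        for name in (
            "marrow_texture_sd_normal",
            "marrow_texture_sd_diseased",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.texture_corr_len < 0:
            raise ValueError("texture_corr_len must be >= 0")
        for k, p in self.lesion_probs.items():
            if k not in LESION_TYPES:
                raise ValueError(f"unknown lesion type {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"lesion_probs[{k!r}] must be in [0, 1]")


@dataclass
class SpineVolume:
    """A 3D scalar intensity volume.

    Axis convention: (slice, row, col); rows increase superior to
    inferior, columns anterior to posterior, slice 0 is the leftmost
    sagittal slice.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = _DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-dimensional")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy(self) -> "SpineVolume":
        return SpineVolume(self.voxels.copy(), self.spacing)


@dataclass
class AnatomyLabels:
    """Ground-truth integer label volume co-registered with a SpineVolume.

    Codes: 0 background, 1..n_levels vertebral marrow (1 = S1),
    101.. intervertebral disks (100+i = disk superior to body i),
    200 other tissue.  ``degeneration_flags`` maps disk code -> bool.
    """

    labels: np.ndarray
    degeneration_flags: dict[int, bool]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def n_levels(self) -> int:
        codes = np.unique(self.labels)
        body = codes[(codes >= 1) & (codes < DISK_BASE)]
        return int(body.max()) if body.size else 0

    def body_mask(self, level: int) -> np.ndarray:
        return self.labels == level

    def disk_mask(self, level: int) -> np.ndarray:
        return self.labels == DISK_BASE + level

    def marrow_mask(self) -> np.ndarray:
        return (self.labels >= 1) & (self.labels < DISK_BASE)

    def copy(self) -> "AnatomyLabels":
        return AnatomyLabels(self.labels.copy(), dict(self.degeneration_flags))


@dataclass
class SubjectRecord:
    """One synthetic subject: image, ground truth, and disease status."""

    volume: SpineVolume
    labels: AnatomyLabels
    disease_status: int
    confounds: set[str] = field(default_factory=set)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.disease_status not in (0, 1):
            raise ValueError("disease_status must be 0 or 1")
        if self.volume.voxels.shape != self.labels.labels.shape:
            raise ValueError("volume and labels shapes differ")

    def copy(self) -> "SubjectRecord":
        return SubjectRecord(
            self.volume.copy(),
            self.labels.copy(),
            self.disease_status,
            set(self.confounds),
            self.subject_id,
        )


# ---------------------------------------------------------------------------
# geometry


def _build_geometry(config: PhantomConfig) -> AnatomyLabels:
    """Deterministic stylized anatomy: labels only, no intensities."""
    S, R, C = config.image_shape
    n = config.n_levels
    labels = np.zeros((S, R, C), dtype=np.int16)

    margin = max(1, round(0.06 * R))
    usable = R - 2 * margin
    unit = usable // (4 * n)
    if unit < 1:
        raise ValueError(
            f"image_shape rows={R} too small for {n} vertebral levels"
        )
    body_h = 3 * unit
    disk_h = unit

    c0 = round(0.18 * C)
    width = max(5, round(0.42 * C))
    c1 = min(C, c0 + width)
    if c1 - c0 < 5:
        raise ValueError(f"image_shape cols={C} too narrow for a spine band")

    row = margin
    # stack from cranial (top) to caudal: disk_n, body_n, ..., disk_1, body_1
    for level in range(n, 0, -1):
        labels[:, row : row + disk_h, c0:c1] = DISK_BASE + level
        _taper_disk(labels, row, disk_h, c0, c1, DISK_BASE + level)
        row += disk_h
        labels[:, row : row + body_h, c0:c1] = level
        row += body_h

    gap = max(1, round(0.03 * C))
    o0 = min(C, c1 + gap)
    o1 = min(C, o0 + round(0.20 * C))
    if o1 > o0:
        post = labels[:, margin : R - margin, o0:o1]
        post[post == 0] = OTHER_TISSUE

    flags = {DISK_BASE + level: False for level in range(1, n + 1)}
    return AnatomyLabels(labels, flags)


def _taper_disk(labels, row, disk_h, c0, c1, code) -> None:
    """Lens shape: trim outer-fifth columns to the central disk rows."""
    if disk_h < 2:
        return
    extent = c1 - c0
    fifth = max(1, extent // 5)
    keep = max(1, int(np.ceil(disk_h * 0.6)))
    trim = disk_h - keep
    top = trim // 2
    bot = trim - top
    for cols in (slice(c0, c0 + fifth), slice(c1 - fifth, c1)):
        if top:
            labels[:, row : row + top, cols] = 0
        if bot:
            labels[:, row + disk_h - bot : row + disk_h, cols] = 0


def _disk_compartments(disk: np.ndarray, ap_axis: int = 2):
    """Split one disk mask into annulus (outer AP fifths) and nucleus."""
    cols = np.nonzero(disk)[ap_axis]
    cmin, cmax = cols.min(), cols.max()
    extent = cmax - cmin + 1
    coord = np.arange(disk.shape[ap_axis])
    rel = np.clip(((coord - cmin) * 5) // extent, 0, 4)
    band = rel[np.newaxis, np.newaxis, :] if ap_axis == 2 else None
    annulus = disk & ((band == 0) | (band == 4))
    nucleus = disk & ~((band == 0) | (band == 4))
    return annulus, nucleus


# ---------------------------------------------------------------------------
# generation


def _correlated_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD stationary Gaussian random field with controllable granularity."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pathological tiny volume
        return np.zeros(shape)
    return smooth / sd


def generate_subject(
    config: PhantomConfig,
    disease_status: int,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "",
) -> SubjectRecord:
    """Render one synthetic subject.

    Marrow voxels are a correlated Gaussian field with mean/SD set by
    ``disease_status``; disks get a bright nucleus and darker annulus;
    a per-subject affine intensity perturbation and additive Gaussian
    noise are applied to the whole volume.  Labels are exact.
    """
    config.validate()
    if disease_status not in (0, 1):
        raise ValueError("disease_status must be 0 or 1")
    rng = np.random.default_rng(rng)

    anatomy = _build_geometry(config)
    lab = anatomy.labels
    vol = np.zeros(config.image_shape, dtype=np.float64)

    vol[lab == OTHER_TISSUE] = _OTHER_TISSUE_MEAN
    for level in range(1, config.n_levels + 1):
        disk = anatomy.disk_mask(level)
        if not disk.any():
            continue
        annulus, nucleus = _disk_compartments(disk)
        vol[nucleus] = config.disk_nucleus_mean
        vol[annulus] = config.annulus_mean

    if disease_status:
        mean, sd = config.marrow_mean_diseased, config.marrow_texture_sd_diseased
    else:
        mean, sd = config.marrow_mean_normal, config.marrow_texture_sd_normal
    marrow = anatomy.marrow_mask()
    field_ = _correlated_field(config.image_shape, config.texture_corr_len, rng)
    vol[marrow] = mean + sd * field_[marrow]

    offset = rng.uniform(*config.vendor_offset_range)
    scale = rng.uniform(*config.vendor_scale_range)
    vol = scale * vol + offset
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)

    record = SubjectRecord(
        SpineVolume(vol), anatomy, int(disease_status), set(), subject_id
    )
    for lesion in LESION_TYPES:
        p = config.lesion_probs.get(lesion, 0.0)
        u = rng.uniform()
        if u < p:
            record = inject_focal_lesion(record, lesion, rng)
    return record


def generate_cohort(
    config: PhantomConfig,
    n_control: int,
    n_diseased: int,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Generate ``n_control + n_diseased`` subjects on independent RNG streams.

    Each subject gets a child stream spawned from ``seed``, so the
    cohort is reproducible as a whole and per subject.
    """
    if n_control < 0 or n_diseased < 0:
        raise ValueError("cohort counts must be >= 0")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_control + n_diseased)
    records = []
    for i in range(n_control):
        records.append(
            generate_subject(
                config, 0, np.random.default_rng(children[i]), f"C{i + 1:04d}"
            )
        )
    for j in range(n_diseased):
        records.append(
            generate_subject(
                config,
                1,
                np.random.default_rng(children[n_control + j]),
                f"D{j + 1:04d}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# focal confounds


def inject_focal_lesion(
    record: SubjectRecord,
    lesion_type: str,
    rng: np.random.Generator | int | None = None,
) -> SubjectRecord:
    """Insert one focal confound into a randomly chosen vertebral level.

    fracture: vertical collapse of the body (row extent shrinks) with an
    intensity drop; hemangioma: small blob strictly brighter than the
    level's pre-injection maximum; modic: darkened band adjacent to one
    endplate.  Returns a modified copy; ``confounds`` is updated.
    """
    if lesion_type not in LESION_TYPES:
        raise ValueError(f"unknown lesion_type {lesion_type!r}")
    n_levels = record.labels.n_levels
    if n_levels < 1:
        raise ValueError("record has no vertebral levels")
    rng = np.random.default_rng(rng)
    out = record.copy()
    level = int(rng.integers(1, n_levels + 1))
    body = out.labels.body_mask(level)
    vox = out.volume.voxels
    lab = out.labels.labels
    rows = np.nonzero(body)[1]
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    height = r1 - r0

    if lesion_type == "fracture":
        new_h = max(1, int(round(0.6 * height)))
        vacate = height - new_h
        if vacate > 0:
            gone = body & (
                np.arange(lab.shape[1])[np.newaxis, :, np.newaxis] < r0 + vacate
            )
            bg = vox[lab == BACKGROUND]
            fill = float(np.median(bg)) if bg.size else 0.0
            vox[gone] = fill
            lab[gone] = BACKGROUND
        remaining = lab == level
        vox[remaining] *= 0.7
    elif lesion_type == "hemangioma":
        pre_max = vox[body].max()
        sl = np.nonzero(body)
        k = int(rng.integers(sl[0].size))
        cs, cr, cc = sl[0][k], sl[1][k], sl[2][k]
        zz, rr, cc2 = np.ogrid[
            0 : lab.shape[0], 0 : lab.shape[1], 0 : lab.shape[2]
        ]
        blob = ((zz - cs) ** 2 + (rr - cr) ** 2 + (cc2 - cc) ** 2) <= 4
        blob &= body
        vox[blob] = pre_max * 1.15 + 5.0
    else:  # modic
        depth = max(1, height // 4)
        top = bool(rng.integers(2))
        rows_idx = np.arange(lab.shape[1])[np.newaxis, :, np.newaxis]
        band = (rows_idx < r0 + depth) if top else (rows_idx >= r1 - depth)
        band = band & body
        vox[band] *= 0.7

    out.confounds.add(lesion_type)
    return out


# ---------------------------------------------------------------------------
# persistence (NIfTI + JSON sidecar)


def save_subject(record: SubjectRecord, path: str | Path) -> None:
    """Write ``<path>.nii.gz``, ``<path>_labels.nii.gz`` and ``<path>.json``."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(record.volume.spacing) + [1.0])
    nib.save(
        nib.Nifti1Image(record.volume.voxels.astype(np.float32), affine),
        str(path) + ".nii.gz",
    )
    nib.save(
        nib.Nifti1Image(record.labels.labels.astype(np.int16), affine),
        str(path) + "_labels.nii.gz",
    )
    meta = {
        "subject_id": record.subject_id,
        "disease_status": record.disease_status,
        "confounds": sorted(record.confounds),
        "spacing": list(record.volume.spacing),
        "degeneration_flags": {
            str(k): bool(v) for k, v in record.labels.degeneration_flags.items()
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_subject(path: str | Path) -> SubjectRecord:
    """Inverse of :func:`save_subject`; raises ``IOError`` naming a bad file."""
    import nibabel as nib

    path = Path(path)
    vol_file = str(path) + ".nii.gz"
    lab_file = str(path) + "_labels.nii.gz"
    meta_file = str(path) + ".json"
    try:
        vol_img = nib.load(vol_file)
        voxels = np.asarray(vol_img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise IOError(f"cannot read volume {vol_file}: {exc}") from exc
    try:
        lab_img = nib.load(lab_file)
        labels = np.asarray(lab_img.dataobj).astype(np.int16)
    except Exception as exc:
        raise IOError(f"cannot read labels {lab_file}: {exc}") from exc
    try:
        meta = json.loads(Path(meta_file).read_text())
    except Exception as exc:
        raise IOError(f"cannot read sidecar {meta_file}: {exc}") from exc
    spacing = tuple(meta.get("spacing", _DEFAULT_SPACING))
    flags = {int(k): bool(v) for k, v in meta.get("degeneration_flags", {}).items()}
    return SubjectRecord(
        SpineVolume(voxels, spacing),  # type: ignore[arg-type]
        AnatomyLabels(labels, flags),
        int(meta["disease_status"]),
        set(meta.get("confounds", [])),
        meta.get("subject_id", ""),
    )


def save_cohort(records: Sequence[SubjectRecord], directory: str | Path) -> Path:
    """Save every subject plus a ``manifest.csv``; returns the manifest path."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        prefix = directory / rec.subject_id
        save_subject(rec, prefix)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "disease_status": rec.disease_status,
                "confounds": ";".join(sorted(rec.confounds)),
                "path": str(prefix),
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(directory: str | Path) -> list[SubjectRecord]:
    import pandas as pd

    manifest = Path(directory) / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest)
    return [load_subject(p) for p in df["path"]]
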