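"""Raw-pixel window features from segmented, disk-normalized volumes.

The classifier input is deliberately unprocessed: for each of the six
vertebral bodies (S1 to L1) a rectangular window of fixed,
population-minimal size is read from the normalized image — all pixels
inside the window, flattened and concatenated into one vector per
subject.  No derived texture descriptors are computed; the kernel
machine does its own implicit feature selection.  The window size is
the smallest per-level in-slice bounding box observed in the cohort,
so every subject's marrow fits the same geometry.

Feature dimension is ``n_levels * height * width * n_slices`` with
``n_slices`` in {1, 3, 9} consecutive sagittal slices centered on the
mid-sagittal slice.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phantom import AnatomyLabels, SpineVolume, SubjectRecord
from .preprocess import MarrowMask

__all__ = [
    "WindowSpec",
    "FeatureVector",
    "FeatureMatrix",
    "compute_min_window",
    "extract_feature_vector",
    "assemble_matrix",
    "minmax_scale",
    "save_matrix_csv",
    "load_matrix_csv",
    "dump_svmlight",
]

_ORDERING = "level-major,slice-major,row-major"


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular window geometry shared by the whole cohort."""

    height: int
    width: int
    n_levels: int = 6
    n_slices: int = 1
    cohort_hash: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("window height and width must be >= 1")
        if self.n_slices % 2 != 1:
            raise ValueError("n_slices must be odd")

    @property
    def dimension(self) -> int:
        return self.n_levels * self.height * self.width * self.n_slices


@dataclass
class FeatureVector:
    """One subject's concatenated raw-pixel vector."""

    values: np.ndarray
    subject_id: str = ""
    ordering: str = _ORDERING

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def dimension(self) -> int:
        return self.values.size


@dataclass
class FeatureMatrix:
    """Subjects x pixel-features matrix with labels and scaling state."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    scaled: bool = False
    col_min: np.ndarray | None = None
    col_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count and label count differ")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def dimension(self) -> int:
        return self.X.shape[1]


def _level_mid_slice_mask(
    labels: AnatomyLabels, mask: MarrowMask | None, level: int, mid: int
) -> np.ndarray:
    m2d = labels.labels[mid] == level
    if mask is not None:
        m2d = m2d & mask.mask[mid]
    return m2d


def compute_min_window(
    records: Sequence[SubjectRecord],
    masks: Sequence[MarrowMask] | None = None,
    n_slices: int = 1,
) -> WindowSpec:
    """Population-minimal window: the smallest per-level in-slice
    bounding box (height and width minimized independently) over all
    subjects and all vertebral levels, measured on the mid-sagittal
    slice of the segmented marrow."""
    if not records:
        raise ValueError("empty cohort")
    n_levels = records[0].labels.n_levels
    min_h = None
    min_w = None
    for i, rec in enumerate(records):
        mask = masks[i] if masks is not None else None
        mid = rec.volume.shape[0] // 2
        for level in range(1, n_levels + 1):
            m2d = _level_mid_slice_mask(rec.labels, mask, level, mid)
            if not m2d.any():
                raise ValueError(
                    f"subject {rec.subject_id or i}: level {level} has no "
                    "marrow voxels in the mid-sagittal slice"
                )
            rows, cols = np.nonzero(m2d)
            h = int(rows.max() - rows.min() + 1)
            w = int(cols.max() - cols.min() + 1)
            min_h = h if min_h is None else min(min_h, h)
            min_w = w if min_w is None else min(min_w, w)
    digest = hashlib.md5(
        "|".join(r.subject_id for r in records).encode()
    ).hexdigest()[:12]
    return WindowSpec(
        height=int(min_h),
        width=int(min_w),
        n_levels=n_levels,
        n_slices=n_slices,
        cohort_hash=digest,
    )


def _clamp(lo: int, size: int, bound: int) -> int:
    if size > bound:
        raise ValueError(f"window size {size} exceeds image extent {bound}")
    return min(max(lo, 0), bound - size)


def extract_feature_vector(
    volume: SpineVolume,
    labels: AnatomyLabels,
    spec: WindowSpec,
    mask: MarrowMask | None = None,
    subject_id: str = "",
) -> FeatureVector:
    """Read the per-level windows from a (disk-normalized) volume.

    For each level 1..n_levels and each of ``n_slices`` consecutive
    slices centered on the mid-sagittal slice, the height x width
    window centered on the level's mid-slice marrow centroid is read
    (all pixels, not masked to marrow), flattened row-major, and
    concatenated level-major then slice-major.  Windows and the slice
    stack are clamped to the image bounds (with a warning) so the
    declared dimension is always realized.
    """
    S, R, C = volume.shape
    if spec.n_slices > S:
        raise ValueError(
            f"n_slices={spec.n_slices} exceeds available slices ({S})"
        )
    mid = S // 2
    s0 = mid - spec.n_slices // 2
    s0c = min(max(s0, 0), S - spec.n_slices)
    if s0c != s0:
        warnings.warn("slice stack clamped to volume edge", stacklevel=2)
    blocks = []
    for level in range(1, spec.n_levels + 1):
        m2d = _level_mid_slice_mask(labels, mask, level, mid)
        if not m2d.any():
            raise ValueError(
                f"subject {subject_id}: level {level} empty in mid-sagittal slice"
            )
        rows, cols = np.nonzero(m2d)
        cr = int(round(rows.mean()))
        cc = int(round(cols.mean()))
        r0 = _clamp(cr - spec.height // 2, spec.height, R)
        c0 = _clamp(cc - spec.width // 2, spec.width, C)
        for s in range(s0c, s0c + spec.n_slices):
            blocks.append(
                volume.voxels[s, r0 : r0 + spec.height, c0 : c0 + spec.width].ravel()
            )
    return FeatureVector(np.concatenate(blocks), subject_id=subject_id)


def assemble_matrix(
    vectors: Sequence[FeatureVector], labels: Sequence[int]
) -> FeatureMatrix:
    """Stack per-subject vectors into an (unscaled) feature matrix."""
    if len(vectors) != len(labels):
        raise ValueError("vector count and label count differ")
    if not vectors:
        return FeatureMatrix(np.empty((0, 0)), np.empty((0,), dtype=int), [])
    dim = vectors[0].dimension
    for v in vectors:
        if v.dimension != dim:
            raise ValueError(
                f"subject {v.subject_id!r}: dimension {v.dimension} != {dim}"
            )
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary")
    X = np.vstack([v.values for v in vectors])
    return FeatureMatrix(X, y, [v.subject_id for v in vectors])


def minmax_scale(
    train: FeatureMatrix, others: Sequence[FeatureMatrix] = ()
) -> tuple[FeatureMatrix, list[FeatureMatrix]]:
    """Per-column [0, 1] scaling fitted on the training matrix only.

    The train min/max are reused for every other matrix, so test values
    can fall outside [0, 1] (preserved, not clipped).  Constant train
    columns map to 0 everywhere.
    """
    if train.n_subjects == 0:
        raise ValueError("training matrix is empty")
    lo = train.X.min(axis=0)
    hi = train.X.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)

    def _apply(m: FeatureMatrix) -> FeatureMatrix:
        Xs = (m.X - lo) / safe
        Xs[:, span == 0] = 0.0
        return FeatureMatrix(
            Xs, m.y.copy(), list(m.subject_ids), scaled=True,
            col_min=lo.copy(), col_max=hi.copy(),
        )

    return _apply(train), [_apply(m) for m in others]


# ---------------------------------------------------------------------------
# persistence


def save_matrix_csv(matrix: FeatureMatrix, path) -> None:
    """CSV with subject_id, label, then one column per feature index;
    scaling parameters go to a JSON sidecar when present."""
    import json
    import pandas as pd
    from pathlib import Path

    df = pd.DataFrame(matrix.X, columns=[f"f{j}" for j in range(matrix.dimension)])
    df.insert(0, "label", matrix.y)
    df.insert(0, "subject_id", matrix.subject_ids or ["" for _ in range(matrix.n_subjects)])
    df.to_csv(path, index=False)
    if matrix.scaled and matrix.col_min is not None:
        side = {
            "col_min": matrix.col_min.tolist(),
            "col_max": matrix.col_max.tolist(),
        }
        Path(str(path) + ".scaling.json").write_text(json.dumps(side))


def load_matrix_csv(path) -> FeatureMatrix:
    import json
    import pandas as pd
    from pathlib import Path

    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    y = df["label"].to_numpy(dtype=int)
    X = df.drop(columns=["subject_id", "label"]).to_numpy(dtype=float)
    sidecar = Path(str(path) + ".scaling.json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        return FeatureMatrix(
            X, y, ids, scaled=True,
            col_min=np.asarray(side["col_min"]),
            col_max=np.asarray(side["col_max"]),
        )
    return FeatureMatrix(X, y, ids)


def dump_svmlight(matrix: FeatureMatrix, path) -> None:
    """LIBSVM sparse text format, for interoperability with libsvm tools."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(matrix.X, matrix.y, path, zero_based=False)
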