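"""CT volume / label mask I/O, co-registration checks and grid resampling.

Conventions
-----------
Voxel arrays are indexed ``[z, y, x]`` (axis 0 is the slice axis; the axial
x-y plane is the in-plane grid), while physical metadata — ``spacing`` and
``origin`` — is stored in ``(x, y, z)`` order in millimetres, matching the
ITK/NIfTI world-coordinate convention.  Volumes read from disk are
canonicalized to LPS axis orientation before any processing, so downstream
code can assume axis 0 iterates over axial slices.

The canonical analysis grid is 1 x 1 x 5 mm: CT values are interpolated
linearly, label masks with nearest neighbours so the label set {0 background,
1 pancreas, 2 tumor} is preserved exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import SimpleITK as sitk

from .errors import CoRegistrationError, InputFormatError, MetadataError

PANCREAS_LABEL = 1
TUMOR_LABEL = 2
VALID_LABELS = frozenset({0, PANCREAS_LABEL, TUMOR_LABEL})

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass
class CTVolume:
    """A gridded CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values; must be finite.
    spacing : tuple of float
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    origin : tuple of float
        Physical coordinates of voxel (0, 0, 0) in mm, ``(x, y, z)``.
    direction : tuple of float
        Row-major 3x3 direction cosines (ITK convention).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MetadataError(f"expected 3D voxel array, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise MetadataError("voxel array contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # (nz, ny, nx)

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent per physical axis (x, y, z) in mm: shape * spacing."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.spacing
        return (nx * sx, ny * sy, nz * sz)


@dataclass
class LabelMask:
    """Integer segmentation on the same grid as its paired :class:`CTVolume`.

    Labels: 0 background, 1 pancreas, 2 tumor.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise MetadataError(f"expected 3D label array, got ndim={self.labels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be strictly positive, got {self.spacing}")
        extra = set(np.unique(self.labels)) - VALID_LABELS
        if extra:
            raise MetadataError(f"label values outside {{0,1,2}}: {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.labels.any())


@dataclass(frozen=True)
class ResampleSpec:
    """Target grid for the canonical analysis resolution.

    Defaults follow the pipeline's fixed working grid (1 x 1 x 5 mm, linear
    interpolation for the image, nearest-neighbour for labels).
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    image_interpolation: str = "linear"
    label_interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise MetadataError("target spacing must be strictly positive")


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------

def _to_sitk(voxels: np.ndarray, spacing, origin, direction) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    img.SetDirection(tuple(float(d) for d in direction))
    return img


def _volume_from_sitk(img: sitk.Image) -> CTVolume:
    return CTVolume(
        voxels=sitk.GetArrayFromImage(img),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _mask_from_sitk(img: sitk.Image) -> LabelMask:
    return LabelMask(
        labels=sitk.GetArrayFromImage(img).astype(np.uint8),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM-series directory.

    DICOM stored values are converted to HU via the series' rescale
    slope/intercept (applied by the reader).  The volume is canonicalized to
    LPS orientation so axis 0 is the slice axis.
    """
    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        ids = reader.GetGDCMSeriesIDs(str(path))
        if not ids:
            raise InputFormatError(f"no DICOM series found in {path}")
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path), ids[0]))
        try:
            img = reader.Execute()
        except RuntimeError as exc:  # pragma: no cover - reader-specific
            raise InputFormatError(f"failed to read DICOM series {path}: {exc}") from exc
    else:
        if not path.exists():
            raise InputFormatError(f"no such file: {path}")
        if path.stat().st_size == 0:
            raise InputFormatError(f"empty file: {path}")
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise InputFormatError(f"failed to read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise MetadataError(f"expected a 3D image, got {img.GetDimension()}D")
    img = sitk.DICOMOrient(img, "LPS")
    img = sitk.Cast(img, sitk.sitkFloat32)
    return _volume_from_sitk(img)


def read_mask(path: str | os.PathLike) -> LabelMask:
    """Read a label mask from a NIfTI file (nearest-neighbour semantics)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputFormatError(f"unreadable mask file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise InputFormatError(f"failed to read {path}: {exc}") from exc
    img = sitk.DICOMOrient(img, "LPS")
    arr = sitk.GetArrayFromImage(img)
    return LabelMask(
        labels=np.rint(arr).astype(np.uint8),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI preserving the physical frame."""
    sitk.WriteImage(_to_sitk(volume.voxels.astype(np.float32), volume.spacing,
                             volume.origin, volume.direction), str(path))


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    sitk.WriteImage(_to_sitk(mask.labels.astype(np.uint8), mask.spacing,
                             mask.origin, mask.direction), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_grid(volume: CTVolume, spec: ResampleSpec) -> tuple[tuple[int, int, int], tuple]:
    """Output size per axis = round(extent / target_spacing), at least 1."""
    ext_x, ext_y, ext_z = volume.physical_extent()
    tx, ty, tz = spec.target_spacing
    size = (
        max(1, int(round(ext_x / tx))),
        max(1, int(round(ext_y / ty))),
        max(1, int(round(ext_z / tz))),
    )  # (x, y, z) in ITK order
    return size, (tx, ty, tz)


def _frames_overlap(volume: CTVolume, mask: LabelMask) -> bool:
    """Check that the axis-aligned physical bounding boxes intersect."""
    for axis in range(3):
        v0 = volume.origin[axis]
        v1 = v0 + volume.physical_extent()[axis]
        m0 = mask.origin[axis]
        m_ext = (mask.shape[2 - axis]) * mask.spacing[axis]
        m1 = m0 + m_ext
        lo, hi = sorted((v0, v1))
        mlo, mhi = sorted((m0, m1))
        if mhi < lo or mlo > hi:
            return False
    return True


def resample_pair(volume: CTVolume, mask: LabelMask,
                  spec: ResampleSpec = ResampleSpec()) -> tuple[CTVolume, LabelMask]:
    """Resample a co-registered (volume, mask) pair onto the target grid.

    The image is interpolated linearly and the mask with nearest neighbours,
    both onto the identical grid anchored at the volume's origin, so the
    output pair stays voxel-aligned and the mask label set is preserved.
    """
    if not _frames_overlap(volume, mask):
        raise CoRegistrationError("volume and mask physical extents are disjoint")

    size, spacing = _target_grid(volume, spec)
    vol_img = _to_sitk(volume.voxels.astype(np.float32), volume.spacing,
                       volume.origin, volume.direction)
    mask_img = _to_sitk(mask.labels.astype(np.uint8), mask.spacing,
                        mask.origin, mask.direction)

    resampler = sitk.ResampleImageFilter()
    resampler.SetSize(size)
    resampler.SetOutputSpacing(spacing)
    resampler.SetOutputOrigin(volume.origin)
    resampler.SetOutputDirection(volume.direction)
    resampler.SetDefaultPixelValue(float(volume.voxels.min()))

    resampler.SetInterpolator(sitk.sitkLinear)
    out_vol = _volume_from_sitk(resampler.Execute(vol_img))

    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    resampler.SetDefaultPixelValue(0)
    out_mask = _mask_from_sitk(resampler.Execute(mask_img))
    return out_vol, out_mask


# ---------------------------------------------------------------------------
# ROI definition
# ---------------------------------------------------------------------------

def roi_union(mask: LabelMask) -> LabelMask:
    """Binary union of pancreas and tumor labels (the VOI/ROI).

    An all-background input yields an empty union; callers should check
    ``result.is_empty`` and exclude the study (mirroring the upstream
    segmentation-failure exclusion rule) rather than treat it as an error.
    """
    union = np.isin(mask.labels, (PANCREAS_LABEL, TUMOR_LABEL)).astype(np.uint8)
    return LabelMask(labels=union, spacing=mask.spacing,
                     origin=mask.origin, direction=mask.direction)


@dataclass
class ExclusionRecord:
    """One excluded study, serializable as a JSON line."""

    study_id: str
    reason: str

    def to_json(self) -> str:
        return json.dumps({"study_id": self.study_id, "reason": self.reason})


def log_exclusions(records: Iterable[ExclusionRecord], path: str | os.PathLike) -> None:
    with open(path, "a") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
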