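"""Sliding-window patch generation over the segmented pancreas ROI.

Each axial slice is covered by 20x20-pixel windows on a stride-5 lattice
(0-based, half-open).  A window is a *valid* patch when strictly more than
5% of its 400 pixels (i.e. > 20 pixels) overlap the ROI.  Windows are
clipped to the slice interior — no padding — and a final window flush with
the right/bottom border is added when the lattice does not reach it, so ROI
near the edge stays covered.

For training, a patch is labeled cancerous when it contains at least one
tumor pixel ("any portion" rule), non-cancerous otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .volume import LabelMask, TUMOR_LABEL

PATCH_SIZE = 20
STRIDE = 5
MIN_ROI_PIXELS = 20  # strict: valid iff overlap > 20 of 400 (5%)

CANCEROUS = "cancerous"
NON_CANCEROUS = "non-cancerous"


@dataclass
class Patch:
    """One 20x20 window: top-left (x0, y0), 0-based, half-open."""

    slice_index: int
    x0: int
    y0: int
    roi_pixels: np.ndarray  # bool (size, size)
    label: Optional[str] = None
    probability: Optional[float] = None


@dataclass
class PatchSet:
    """Ordered patches of one study plus the grid metadata for heatmaps."""

    patches: list[Patch]
    study_id: str
    n_slices: int
    slice_shape: tuple[int, int]  # (ny, nx)
    pixel_area_mm2: float = 1.0
    patch_size: int = PATCH_SIZE
    stride: int = STRIDE

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def all_scored(self) -> bool:
        return all(p.probability is not None for p in self.patches)

    def to_frame(self) -> pd.DataFrame:
        """Tabular audit form (study_id, slice, x0, y0, label, probability)."""
        return pd.DataFrame({
            "study_id": self.study_id,
            "slice": [p.slice_index for p in self.patches],
            "x0": [p.x0 for p in self.patches],
            "y0": [p.y0 for p in self.patches],
            "label": [p.label for p in self.patches],
            "probability": [p.probability for p in self.patches],
        })


def _lattice(extent: int, size: int, stride: int) -> list[int]:
    """Stride lattice of window starts, plus a flush-edge window if needed."""
    if extent < size:
        return []
    starts = list(range(0, extent - size + 1, stride))
    if starts[-1] != extent - size:
        starts.append(extent - size)
    return starts


def generate_patches(roi: LabelMask, study_id: str = "",
                     patch_size: int = PATCH_SIZE, stride: int = STRIDE,
                     min_roi_pixels: int = MIN_ROI_PIXELS) -> PatchSet:
    """Enumerate valid patches of a resampled binary ROI mask.

    Ordering is deterministic: (slice, y0, x0).  An empty ROI yields an
    empty PatchSet (the study simply contributes no patches).
    """
    if patch_size <= 0 or stride <= 0:
        raise ConfigurationError("patch size and stride must be positive")
    mask = roi.labels > 0
    nz, ny, nx = mask.shape
    sx, sy, _ = roi.spacing
    ys = _lattice(ny, patch_size, stride)
    xs = _lattice(nx, patch_size, stride)
    out: list[Patch] = []
    for z in range(nz):
        sl = mask[z]
        if not sl.any():
            continue
        # integral image for O(1) window overlap counts
        integral = np.zeros((ny + 1, nx + 1), dtype=np.int64)
        integral[1:, 1:] = sl.cumsum(0).cumsum(1)
        for y0 in ys:
            for x0 in xs:
                cnt = (integral[y0 + patch_size, x0 + patch_size]
                       - integral[y0, x0 + patch_size]
                       - integral[y0 + patch_size, x0]
                       + integral[y0, x0])
                if cnt > min_roi_pixels:
                    out.append(Patch(
                        slice_index=z, x0=x0, y0=y0,
                        roi_pixels=sl[y0:y0 + patch_size, x0:x0 + patch_size].copy(),
                    ))
    return PatchSet(patches=out, study_id=study_id, n_slices=nz,
                    slice_shape=(ny, nx), pixel_area_mm2=float(sx * sy),
                    patch_size=patch_size, stride=stride)


def label_patches(patchset: PatchSet, mask: LabelMask) -> PatchSet:
    """Assign cancer labels: cancerous iff >= 1 tumor pixel in the window."""
    tumor = mask.labels == TUMOR_LABEL
    size = patchset.patch_size
    labeled = []
    for p in patchset.patches:
        window = tumor[p.slice_index, p.y0:p.y0 + size, p.x0:p.x0 + size]
        labeled.append(replace(p, label=CANCEROUS if window.any() else NON_CANCEROUS))
    return replace(patchset, patches=labeled)


def set_probabilities(patchset: PatchSet, probabilities: np.ndarray) -> PatchSet:
    """Attach model probabilities (aligned with patch order)."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (len(patchset),):
        raise ConfigurationError(
            f"expected {len(patchset)} probabilities, got {probs.shape}")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    new = [replace(p, probability=float(q))
           for p, q in zip(patchset.patches, probs)]
    return replace(patchset, patches=new)
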