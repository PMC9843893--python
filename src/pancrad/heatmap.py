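"""Heatmap aggregation of patch probabilities and the high-risk-area statistic.

Each covered pixel of an axial slice takes the arithmetic mean of the
predicted probabilities of every valid patch whose window contains it.
The 2D branch's study-level output is the area (mm^2) of the largest
contiguous region of pixels whose heatmap value exceeds a threshold,
maximised over axial planes (components are 8-connected in-plane by
default; an experimental 26-connected 3D mode is available).

The pixel threshold is chosen on a validation cohort by scanning
0.05..0.95 in steps of 0.01 (91 grid points) and keeping the value whose
area statistic best separates cancer studies from controls by AUC (ties
resolved toward the smallest threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import ConfigurationError, StateError
from .patches import PatchSet

THRESHOLD_GRID = np.round(np.arange(5, 96) / 100.0, 2)  # 0.05..0.95, 91 points


@dataclass
class Heatmap:
    """Per-study probability heatmap.

    ``values`` is NaN where no patch covers the pixel; ``coverage`` counts
    contributing patches per pixel.
    """

    values: np.ndarray  # float (nz, ny, nx), NaN where uncovered
    coverage: np.ndarray  # int (nz, ny, nx)
    pixel_area_mm2: float = 1.0

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0


@dataclass
class HighRiskResult:
    """Largest contiguous high-risk region at one threshold."""

    threshold: float
    area_mm2: float
    pixel_count: int
    slice_index: int | None  # None when no pixel exceeds the threshold
    pixels: np.ndarray | None = None  # (k, 2) in-plane coordinates, optional


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    aucs: np.ndarray
    selected: float

    @property
    def selected_auc(self) -> float:
        return float(self.aucs[np.argwhere(self.thresholds == self.selected)[0, 0]])


def build_heatmap(patchset: PatchSet) -> Heatmap:
    """Mean-aggregate scored patches into per-slice probability maps."""
    if not patchset.all_scored:
        raise StateError("all valid patches must be scored before aggregation")
    nz = patchset.n_slices
    ny, nx = patchset.slice_shape
    acc = np.zeros((nz, ny, nx), dtype=float)
    cov = np.zeros((nz, ny, nx), dtype=np.int64)
    s = patchset.patch_size
    for p in patchset.patches:
        acc[p.slice_index, p.y0:p.y0 + s, p.x0:p.x0 + s] += p.probability
        cov[p.slice_index, p.y0:p.y0 + s, p.x0:p.x0 + s] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return Heatmap(values=vals, coverage=cov,
                   pixel_area_mm2=patchset.pixel_area_mm2)


def largest_high_risk_area(heatmap: Heatmap, threshold: float,
                           connectivity: str = "8") -> HighRiskResult:
    """Area of the largest contiguous region with value > threshold.

    ``connectivity``: '8' (default) or '4' for in-plane components taking
    the maximum over axial planes; '3d' links components across slices with
    26-connectivity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError("threshold must lie in [0, 1]")
    hot = np.nan_to_num(heatmap.values, nan=-1.0) > threshold
    if connectivity == "3d":
        lab = measure.label(hot, connectivity=3)
        if lab.max() == 0:
            return HighRiskResult(threshold, 0.0, 0, None)
        sizes = np.bincount(lab.ravel())[1:]
        best = int(sizes.argmax()) + 1
        zs = np.argwhere(lab == best)[:, 0]
        return HighRiskResult(threshold, float(sizes.max() * heatmap.pixel_area_mm2),
                              int(sizes.max()), int(zs[0]))
    if connectivity not in ("4", "8"):
        raise ConfigurationError(f"unknown connectivity {connectivity!r}")
    conn = 2 if connectivity == "8" else 1
    best_count, best_slice, best_pixels = 0, None, None
    for z in range(hot.shape[0]):
        if not hot[z].any():
            continue
        lab = measure.label(hot[z], connectivity=conn)
        sizes = np.bincount(lab.ravel())[1:]
        k = int(sizes.max())
        if k > best_count:
            best_count = k
            best_slice = z
            best_pixels = np.argwhere(lab == int(sizes.argmax()) + 1)
    return HighRiskResult(threshold=float(threshold),
                          area_mm2=float(best_count * heatmap.pixel_area_mm2),
                          pixel_count=best_count, slice_index=best_slice,
                          pixels=best_pixels)


def area_profile(heatmap: Heatmap, thresholds=THRESHOLD_GRID,
                 connectivity: str = "8") -> np.ndarray:
    """Largest-region area at each threshold (non-increasing in t)."""
    return np.asarray([largest_high_risk_area(heatmap, t, connectivity).area_mm2
                       for t in thresholds])


def search_area_threshold(heatmaps: list[Heatmap], labels,
                          thresholds=THRESHOLD_GRID,
                          connectivity: str = "8") -> ThresholdSearchResult:
    """Pick the pixel threshold whose area statistic maximises AUC.

    ``labels``: 1 for cancer studies, 0 for controls; both classes must be
    present.  Ties go to the smallest threshold.
    """
    from .diagnostics import auc_point  # local import to avoid cycle

    labels = np.asarray(labels, dtype=int)
    if len(heatmaps) != len(labels):
        raise ConfigurationError("one label per heatmap required")
    if labels.min() == labels.max():
        raise ConfigurationError("threshold search needs both classes")
    thresholds = np.asarray(thresholds, dtype=float)
    areas = np.stack([area_profile(h, thresholds, connectivity) for h in heatmaps])
    aucs = np.asarray([auc_point(areas[:, j], labels) for j in range(len(thresholds))])
    best = int(np.argmax(aucs))  # argmax returns the first (smallest t) on ties
    return ThresholdSearchResult(thresholds=thresholds, aucs=aucs,
                                 selected=float(thresholds[best]))


def heatmap_to_volume(heatmap: Heatmap, fill: float = 0.0) -> np.ndarray:
    """Heatmap as a dense array (uncovered pixels set to ``fill``), e.g. for
    writing a NIfTI overlay next to the source volume."""
    return np.nan_to_num(heatmap.values, nan=fill)
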