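"""Feature manifests and extraction of named radiomic feature vectors.

A *manifest* is an ordered list of ``(filter_id, family, feature)`` triples;
the emitted vector has one scalar per entry, named
``"<filter_id>_<family>_<feature>"``, in manifest order.  Manifests are
config-driven: the defaults below document their own counts and users can
supply any cross-product of the implemented filters, families and features.

3D extraction operates on the whole-pancreas VOI of a resampled volume; 2D
extraction operates per 20x20 patch, with filters applied to the full axial
slice once and features computed on the patch's ROI pixels.

Texture features are computed on gray levels discretized with the fixed
bin width (default 16 HU) anchored at the region minimum; first-order
features use the raw HU values.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import texture
from .errors import ConfigurationError
from .filters import FilterSpec, apply_filter
from .volume import CTVolume, LabelMask

DEFAULT_BIN_WIDTH = 16.0

# feature ids implemented per family (texture.family_features emits these)
FAMILY_FEATURES = {
    "firstorder": ("mean", "median", "minimum", "maximum", "range", "variance",
                   "skewness", "mean_absolute_deviation", "energy",
                   "root_mean_squared"),
    "glcm": ("correlation", "imc2", "inverse_variance", "contrast",
             "joint_entropy", "joint_energy"),
    "glrlm": ("long_run_emphasis", "short_run_emphasis",
              "run_length_nonuniformity", "gray_level_nonuniformity"),
    "glszm": ("large_area_emphasis", "small_area_emphasis",
              "size_zone_nonuniformity", "zone_entropy"),
    "gldm": ("small_dependence_emphasis", "large_dependence_emphasis",
             "gray_level_variance", "dependence_entropy",
             "dependence_nonuniformity"),
    "ngtdm": ("coarseness", "busyness", "contrast"),
}

# fallbacks reported for a degenerate (empty / sub-minimal) region
_DEGENERATE_FALLBACKS = {
    ("glcm", "correlation"): 1.0,
    ("ngtdm", "coarseness"): texture.COARSENESS_CAP,
}


@dataclass(frozen=True)
class ManifestEntry:
    filter_id: str
    family: str
    feature: str

    @property
    def name(self) -> str:
        return f"{self.filter_id}_{self.family}_{self.feature}"

    def validate(self, ndim: int) -> None:
        if self.family not in FAMILY_FEATURES:
            raise ConfigurationError(f"unknown family: {self.family}")
        if self.feature not in FAMILY_FEATURES[self.family]:
            raise ConfigurationError(
                f"unknown feature {self.feature!r} for family {self.family}")
        spec = FilterSpec(self.filter_id)
        if spec.kind == "wavelet" and len(spec.wavelet_band) != ndim:
            raise ConfigurationError(
                f"wavelet band {spec.wavelet_band!r} does not match {ndim}D mode")


@dataclass
class FeatureManifest:
    """Ordered feature manifest; ``dimensionality`` is 2 or 3."""

    entries: list[ManifestEntry]
    dimensionality: int
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ConfigurationError("dimensionality must be 2 or 3")
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate manifest entries")
        for e in self.entries:
            e.validate(self.dimensionality)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps({
            "dimensionality": self.dimensionality,
            "bin_width": self.bin_width,
            "entries": [[e.filter_id, e.family, e.feature] for e in self.entries],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureManifest":
        obj = json.loads(text)
        return cls(entries=[ManifestEntry(*e) for e in obj["entries"]],
                   dimensionality=int(obj["dimensionality"]),
                   bin_width=float(obj.get("bin_width", DEFAULT_BIN_WIDTH)))


def _expand(filter_id: str, families: dict[str, tuple[str, ...] | str]) -> list[ManifestEntry]:
    out = []
    for fam, feats in families.items():
        if feats == "all":
            feats = FAMILY_FEATURES[fam]
        out.extend(ManifestEntry(filter_id, fam, f) for f in feats)
    return out


def default_manifest_3d() -> FeatureManifest:
    """Default whole-VOI manifest: 4 filters x all families (128 features)."""
    entries: list[ManifestEntry] = []
    for filt in ("original", "wavelet-LLL", "wavelet-HHH", "log-sigma-3-0-mm"):
        entries.extend(_expand(filt, {fam: "all" for fam in FAMILY_FEATURES}))
    return FeatureManifest(entries, dimensionality=3)


def default_manifest_2d() -> FeatureManifest:
    """Default patch manifest (41 features).

    All families on the original channel; first-order summaries on the
    wavelet detail/approximation bands.  Kept compact because it is evaluated
    once per 20x20 patch.
    """
    entries = _expand("original", {fam: "all" for fam in FAMILY_FEATURES})
    entries += _expand("wavelet-LL", {"firstorder": ("mean", "median",
                                                     "mean_absolute_deviation")})
    for band in ("wavelet-LH", "wavelet-HL", "wavelet-HH"):
        entries += _expand(band, {"firstorder": ("mean_absolute_deviation",
                                                 "variance")})
    return FeatureManifest(entries, dimensionality=2)


@dataclass
class FeatureVector:
    """Named feature values for one VOI or one patch."""

    values: "OrderedDict[str, float]"
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.values.values()), dtype=float)


def _degenerate_vector(manifest: FeatureManifest) -> FeatureVector:
    vals = OrderedDict()
    for e in manifest.entries:
        vals[e.name] = _DEGENERATE_FALLBACKS.get((e.family, e.feature), 0.0)
    return FeatureVector(values=vals, degenerate=True)


def _extract_from_array(image: np.ndarray, roi: np.ndarray, spacing,
                        manifest: FeatureManifest) -> FeatureVector:
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 2:
        return _degenerate_vector(manifest)
    by_filter: dict[str, list[ManifestEntry]] = {}
    for e in manifest.entries:
        by_filter.setdefault(e.filter_id, []).append(e)
    computed: dict[str, float] = {}
    for filter_id, entries in by_filter.items():
        channel = apply_filter(image, FilterSpec(filter_id), spacing)
        for fam in {e.family for e in entries}:
            feats = texture.family_features(fam, channel, roi, manifest.bin_width)
            for name, val in feats.items():
                computed[f"{filter_id}_{fam}_{name}"] = val
    vals = OrderedDict((e.name, float(computed[e.name])) for e in manifest.entries)
    return FeatureVector(values=vals)


def extract_feature_vector(volume: CTVolume, roi: LabelMask,
                           manifest: FeatureManifest) -> FeatureVector:
    """Whole-VOI 3D feature vector on a resampled (volume, binary ROI) pair."""
    if manifest.dimensionality != 3:
        raise ConfigurationError("3D extraction requires a 3D manifest")
    if volume.shape != roi.shape:
        raise ConfigurationError("volume and ROI grids differ")
    sx, sy, sz = volume.spacing
    return _extract_from_array(volume.voxels, roi.labels > 0, (sz, sy, sx), manifest)


def extract_patch_features(volume: CTVolume, patchset,
                           manifest: FeatureManifest) -> pd.DataFrame:
    """2D feature table for every patch in a :class:`~pancrad.patches.PatchSet`.

    Filters are applied to each full axial slice once; per-patch features are
    then computed on the filtered window restricted to the patch's ROI
    pixels.  Row order follows the patch ordering (slice, y, x).
    """
    if manifest.dimensionality != 2:
        raise ConfigurationError("patch extraction requires a 2D manifest")
    sx, sy, _ = volume.spacing
    by_filter: dict[str, list[ManifestEntry]] = {}
    for e in manifest.entries:
        by_filter.setdefault(e.filter_id, []).append(e)

    rows: list[list[float]] = []
    channel_cache: dict[tuple[int, str], np.ndarray] = {}
    size = patchset.patch_size
    for patch in patchset.patches:
        roi = patch.roi_pixels
        if roi.sum() < 2:
            rows.append(list(_degenerate_vector(manifest).values.values()))
            continue
        computed: dict[str, float] = {}
        for filter_id, entries in by_filter.items():
            key = (patch.slice_index, filter_id)
            if key not in channel_cache:
                sl = volume.voxels[patch.slice_index].astype(float)
                channel_cache[key] = apply_filter(sl, FilterSpec(filter_id), (sy, sx))
            window = channel_cache[key][patch.y0:patch.y0 + size,
                                        patch.x0:patch.x0 + size]
            for fam in {e.family for e in entries}:
                feats = texture.family_features(fam, window, roi, manifest.bin_width)
                for name, val in feats.items():
                    computed[f"{filter_id}_{fam}_{name}"] = val
        rows.append([float(computed[e.name]) for e in manifest.entries])
    return pd.DataFrame(rows, columns=manifest.names)
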