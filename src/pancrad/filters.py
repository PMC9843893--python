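"""Image filters producing the derived channels used for feature extraction.

Two filter classes are supported, mirroring the common radiomics platforms:

* a single-level undecimated (stationary) wavelet decomposition with the
  ``coif1`` mother wavelet, yielding 4 sub-bands in 2D (LL, LH, HL, HH) and
  8 in 3D (LLL ... HHH), each at the input resolution;
* a Laplacian-of-Gaussian with sigma given in physical millimetres, converted
  to per-axis voxel sigmas via the grid spacing.

Band naming: one letter per array axis, in array index order — e.g. for a
2D slice indexed ``[y, x]`` the band "HL" is high-pass along y, low-pass
along x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .errors import ConfigurationError, FilterSupportError

WAVELET = "coif1"


@dataclass(frozen=True)
class FilterSpec:
    """Identifier of one filtered channel.

    ``filter_id`` is ``"original"``, ``"wavelet-<band>"`` (band of 'L'/'H'
    letters, one per axis) or ``"log-sigma-<s>-mm"`` with sigma in mm.
    """

    filter_id: str

    @property
    def kind(self) -> str:
        if self.filter_id == "original":
            return "original"
        if self.filter_id.startswith("wavelet-"):
            return "wavelet"
        if self.filter_id.startswith("log-sigma-"):
            return "log"
        raise ConfigurationError(f"unknown filter id: {self.filter_id}")

    @property
    def wavelet_band(self) -> str:
        if self.kind != "wavelet":
            raise ConfigurationError(f"{self.filter_id} is not a wavelet filter")
        band = self.filter_id.split("-", 1)[1]
        if not band or set(band) - {"L", "H"}:
            raise ConfigurationError(f"bad wavelet band: {band!r}")
        return band

    @property
    def log_sigma_mm(self) -> float:
        if self.kind != "log":
            raise ConfigurationError(f"{self.filter_id} is not a LoG filter")
        token = self.filter_id[len("log-sigma-"):].removesuffix("-mm")
        try:
            sigma = float(token.replace("-", "."))
        except ValueError as exc:
            raise ConfigurationError(f"bad LoG sigma in {self.filter_id}") from exc
        if sigma <= 0:
            raise ConfigurationError("LoG sigma must be positive")
        return sigma


def wavelet_bands(image: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level stationary wavelet decomposition into all sub-bands.

    Returns a dict keyed by band name ('L'/'H' per axis in array-axis order).
    Axes of odd length are edge-padded to even length for the transform and
    the output cropped back, so every band has the input shape.
    """
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2:
        raise FilterSupportError(f"image shape {image.shape} below wavelet support")
    pad = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pad, mode="edge")
    coeffs = pywt.swtn(padded, WAVELET, level=1, start_level=0)[0]
    out: dict[str, np.ndarray] = {}
    crop = tuple(slice(0, s) for s in image.shape)
    for key, arr in coeffs.items():
        band = key.replace("a", "L").replace("d", "H")
        out[band] = arr[crop]
    return out


def inverse_wavelet(bands: dict[str, np.ndarray]) -> np.ndarray:
    """Inverse stationary wavelet transform from a full set of sub-bands.

    Missing bands are treated as zero (e.g. reconstruct from LL only).
    """
    shapes = {b.shape for b in bands.values()}
    if len(shapes) != 1:
        raise ConfigurationError("all bands must share a shape")
    shape = shapes.pop()
    ndim = len(shape)
    pad = [(0, s % 2) for s in shape]
    full = {}
    for letters in np.ndindex(*(2,) * ndim):
        band = "".join("LH"[i] for i in letters)
        key = band.replace("L", "a").replace("H", "d")
        arr = bands.get(band, np.zeros(shape))
        full[key] = np.pad(np.asarray(arr, dtype=float), pad, mode="edge")
    rec = pywt.iswtn([full], WAVELET)
    return rec[tuple(slice(0, s) for s in shape)]


def laplacian_of_gaussian(image: np.ndarray, spacing_mm, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response with sigma in physical mm.

    ``spacing_mm`` gives the voxel spacing per array axis (same order as the
    array axes), so anisotropic grids are smoothed isotropically in physical
    space.
    """
    image = np.asarray(image, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (image.ndim,):
        raise ConfigurationError(
            f"spacing has {spacing.shape} entries for a {image.ndim}D image")
    sigma_vox = sigma_mm / spacing
    if min(image.shape) < 3:
        raise FilterSupportError(f"image shape {image.shape} below LoG support")
    return ndimage.gaussian_laplace(image, sigma=sigma_vox, mode="nearest")


def apply_filter(image: np.ndarray, spec: FilterSpec, spacing_mm=None) -> np.ndarray:
    """Compute one filtered channel of ``image`` (array-axis order preserved)."""
    kind = spec.kind
    if kind == "original":
        return np.asarray(image, dtype=float)
    if kind == "wavelet":
        band = spec.wavelet_band
        if len(band) != image.ndim:
            raise ConfigurationError(
                f"band {band!r} has {len(band)} letters for a {image.ndim}D image")
        return wavelet_bands(image)[band]
    if spacing_mm is None:
        spacing_mm = np.ones(image.ndim)
    return laplacian_of_gaussian(image, spacing_mm, spec.log_sigma_mm)
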