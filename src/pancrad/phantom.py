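"""Synthetic pancreas-CT phantom cohorts for exercising the full pipeline.

No deposited imaging data accompanies the problem, so the pipeline is
developed and validated on seeded phantom cohorts that emulate the two
image properties the 2D/3D analyses exploit on real CT: pancreatic tumors
present as *hypodense* masses (lower HU than surrounding parenchyma) that
are *texturally busier* (stronger high-frequency intensity variation).

Each study is a small axial volume on the canonical 1 x 1 x 5 mm grid:

* the pancreas is an ellipsoid with a smoothly deformed boundary, filled
  with a correlated Gaussian texture (correlation length ~3 mm) around a
  portal-venous parenchyma level of ~100 HU;
* in cancer studies a tumor ellipsoid (in-plane diameter drawn per study)
  is intersected with an eroded pancreas so it never touches the boundary;
  tumor voxels get a negative median HU shift and an amplified
  high-frequency noise component;
* HU values are rounded to integers to mimic CT storage.

Matched case/control pairs share the seed, hence the identical pancreas and
texture field; only the tumor modification differs.  Tumor size strata use
the clinical cuts (<2 cm, 2-4 cm, >4 cm) on the drawn in-plane diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .diagnostics import assign_size_stratum
from .errors import ConfigurationError
from .volume import CTVolume, LabelMask, PANCREAS_LABEL, TUMOR_LABEL, write_mask, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of one phantom cohort."""

    n_cases: int = 10
    n_controls: int = 10
    shape: tuple[int, int, int] = (12, 56, 56)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)  # (sx, sy, sz) mm
    pancreas_radii_mm: tuple[float, float, float] = (20.0, 15.0, 9.0)  # (x, y, z)
    base_hu: float = 100.0
    noise_sd: float = 12.0
    correlation_mm: float = 3.0
    tumor_diameter_range_mm: tuple[float, float] = (12.0, 30.0)
    tumor_hu_shift: float = -40.0
    tumor_heterogeneity: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tumor_diameter_range_mm
        if not 0 < lo <= hi:
            raise ConfigurationError("bad tumor diameter range")
        min_inplane = min(self.pancreas_radii_mm[0], self.pancreas_radii_mm[1])
        if hi > 2 * min_inplane:
            raise ConfigurationError(
                f"max tumor diameter {hi} mm exceeds the pancreas "
                f"(min in-plane radius {min_inplane} mm)")
        if self.tumor_heterogeneity <= 1:
            raise ConfigurationError("tumor heterogeneity multiplier must be > 1")
        if self.tumor_hu_shift >= 0:
            raise ConfigurationError("tumor HU shift must be negative (hypodense)")


@dataclass
class PhantomStudy:
    study_id: str
    volume: CTVolume
    mask: LabelMask
    has_tumor: bool
    tumor_diameter_mm: float  # 0 for controls
    stratum: str | None
    seed: int


@dataclass
class PhantomCohort:
    studies: list[PhantomStudy]
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.studies)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "study_id": [s.study_id for s in self.studies],
            "label": [int(s.has_tumor) for s in self.studies],
            "tumor_diameter_mm": [s.tumor_diameter_mm for s in self.studies],
            "stratum": [s.stratum for s in self.studies],
            "seed": [s.seed for s in self.studies],
        })


def _smooth_field(rng: np.random.Generator, shape, spacing, corr_mm) -> np.ndarray:
    """Unit-variance Gaussian random field with ~corr_mm correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]  # array-axis order (z, y, x)
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(shape, spacing_zyx, center_vox, radii_mm, warp=None) -> np.ndarray:
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    sz, sy, sx = spacing_zyx
    rz, ry, rx = radii_mm
    d2 = (((z - center_vox[0]) * sz / rz) ** 2
          + ((y - center_vox[1]) * sy / ry) ** 2
          + ((x - center_vox[2]) * sx / rx) ** 2)
    if warp is not None:
        d2 = d2 * (1.0 + warp)
    return d2 <= 1.0


def generate_study(spec: PhantomSpec, study_seed: int, has_tumor: bool,
                   study_id: str) -> PhantomStudy:
    """Generate one study; the same seed yields the identical pancreas and
    texture field with and without the tumor modification."""
    rng = np.random.default_rng(study_seed)
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    spacing_zyx = (sz, sy, sx)

    center = (nz / 2 + rng.uniform(-0.5, 0.5),
              ny / 2 + rng.uniform(-2, 2),
              nx / 2 + rng.uniform(-2, 2))
    rx, ry, rz = spec.pancreas_radii_mm
    jitter = rng.uniform(0.92, 1.08, size=3)
    radii_zyx = (rz * jitter[2], ry * jitter[1], rx * jitter[0])
    # smooth boundary deformation makes the organ non-ellipsoidal
    warp = 0.25 * _smooth_field(rng, spec.shape, spacing_zyx, 3 * spec.correlation_mm)
    pancreas = _ellipsoid(spec.shape, spacing_zyx, center, radii_zyx, warp)

    field = _smooth_field(rng, spec.shape, spacing_zyx, spec.correlation_mm)
    hf_noise = rng.standard_normal(spec.shape)  # high-frequency component

    hu = np.full(spec.shape, -60.0)  # surrounding fat/soft tissue
    hu += 8.0 * _smooth_field(rng, spec.shape, spacing_zyx, spec.correlation_mm)
    hu[pancreas] = (spec.base_hu + spec.noise_sd * field[pancreas]
                    + 0.25 * spec.noise_sd * hf_noise[pancreas])

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[pancreas] = PANCREAS_LABEL

    # tumor geometry is drawn from the same stream for cases and controls so
    # matched pairs differ only by the applied modification
    diameter = float(rng.uniform(*spec.tumor_diameter_range_mm))
    tumor_center_jitter = rng.uniform(-0.25, 0.25, size=3)

    tumor_diameter = 0.0
    stratum = None
    if has_tumor:
        tumor_diameter = diameter
        r_inplane = diameter / 2.0
        r_z = min(r_inplane, 0.8 * radii_zyx[0])
        # place at the organ centre (jittered) and keep off the boundary
        t_center = (center[0] + tumor_center_jitter[0] * radii_zyx[0] * sz / sz / 4,
                    center[1] + tumor_center_jitter[1] * ry / sy,
                    center[2] + tumor_center_jitter[2] * rx / sx)
        tumor = _ellipsoid(spec.shape, spacing_zyx, t_center,
                           (r_z, r_inplane, r_inplane))
        interior = ndimage.binary_erosion(pancreas, iterations=1)
        tumor &= interior
        if tumor.any():
            # the tumor replaces the smooth parenchymal enhancement pattern
            # with fine-grained heterogeneity: its high-frequency noise is
            # amplified by the heterogeneity multiplier while the smooth
            # large-scale component collapses.  Locally the tumor is rougher
            # (neighbour differences ~2x) without a wider overall histogram,
            # which is the regime in which gray-tone-difference busyness is
            # elevated for hypodense masses
            hu[tumor] = (spec.base_hu + spec.tumor_hu_shift
                         + spec.tumor_heterogeneity * 0.25 * spec.noise_sd
                         * hf_noise[tumor])
            labels[tumor] = TUMOR_LABEL
        stratum = assign_size_stratum(diameter)

    hu = np.rint(hu).astype(np.int16).astype(np.float32)
    vol = CTVolume(voxels=hu, spacing=spec.spacing)
    mask = LabelMask(labels=labels, spacing=spec.spacing)
    return PhantomStudy(study_id=study_id, volume=vol, mask=mask,
                        has_tumor=has_tumor, tumor_diameter_mm=tumor_diameter,
                        stratum=stratum, seed=study_seed)


def generate_cohort(spec: PhantomSpec, out_dir: str | Path | None = None) -> PhantomCohort:
    """Generate a seeded cohort of cases then controls.

    With ``out_dir`` set, NIfTI volume/mask pairs and the manifest CSV are
    written alongside the in-memory cohort.
    """
    studies: list[PhantomStudy] = []
    root = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in root.spawn(spec.n_cases + spec.n_controls)]
    for i in range(spec.n_cases):
        studies.append(generate_study(spec, seeds[i], True, f"case{i:04d}"))
    for i in range(spec.n_controls):
        studies.append(generate_study(spec, seeds[spec.n_cases + i], False,
                                      f"ctrl{i:04d}"))
    cohort = PhantomCohort(studies=studies, spec=spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in studies:
            write_volume(s.volume, out / f"{s.study_id}_ct.nii.gz")
            write_mask(s.mask, out / f"{s.study_id}_mask.nii.gz")
        cohort.manifest().to_csv(out / "manifest.csv", index=False)
    return cohort


def generate_matched_pair(spec: PhantomSpec, pair_seed: int
                          ) -> tuple[PhantomStudy, PhantomStudy]:
    """A (tumor, control) pair sharing geometry and texture field."""
    case = generate_study(spec, pair_seed, True, f"pair{pair_seed}_case")
    ctrl = generate_study(spec, pair_seed, False, f"pair{pair_seed}_ctrl")
    return case, ctrl
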