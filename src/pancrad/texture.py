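"""Gray-level texture matrices and radiomic feature formulas.

All texture families operate on a *level image*: an integer array in which
voxels outside the region of interest are 0 and voxels inside carry a
discretized gray level in ``1..Ng``.  Discretization uses a fixed bin width
anchored at the region minimum:

    level(v) = floor((v - min) / bin_width) + 1

which makes every texture feature invariant to adding a constant to the HU
values (the anchor shifts with them).

Neighbourhood conventions
-------------------------
* 2D arrays are indexed ``[y, x]`` and use the 4 in-plane angle offsets
  (distance 1); full neighbourhoods are the 8 surrounding pixels.
* 3D arrays are indexed ``[z, y, x]`` and use 13 unique angle offsets
  (26-neighbourhood halved by symmetry); full neighbourhoods are the 26
  surrounding voxels.
* Neighbours outside the region are excluded everywhere.

Per-angle families (GLCM, GLRLM) compute the feature per angle and average;
GLSZM, GLDM and NGTDM build a single matrix.

Degenerate conventions (single gray level / tiny region), matching the
dominant open-source radiomics platform: GLCM correlation -> 1, IMC2 -> 0,
NGTDM busyness -> 0, coarseness -> 1e6 (capped), first-order skewness -> 0.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptyROIError

COARSENESS_CAP = 1e6  # returned when sum(p_i * s_i) == 0


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(values: np.ndarray, bin_width: float = 16.0) -> tuple[np.ndarray, int]:
    """Map region values to gray-level indices 1..Ng with a fixed bin width.

    Returns ``(indices, n_levels)``.  A constant region maps to a single
    level 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyROIError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ConfigurationError("bin width must be positive")
    idx = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return idx, int(idx.max())


def level_image(image: np.ndarray, roi: np.ndarray, bin_width: float = 16.0) -> np.ndarray:
    """Discretize ``image`` inside ``roi`` into a level image (0 outside)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyROIError("empty ROI")
    levels = np.zeros(image.shape, dtype=np.int64)
    idx, _ = discretize(np.asarray(image, dtype=float)[roi], bin_width)
    levels[roi] = idx
    return levels


# ---------------------------------------------------------------------------
# Offsets
# ---------------------------------------------------------------------------

def angle_offsets(ndim: int) -> list[tuple[int, ...]]:
    """Unique distance-1 angle offsets: 4 in 2D, 13 in 3D."""
    if ndim not in (2, 3):
        raise ConfigurationError(f"unsupported dimensionality {ndim}")
    offs = [o for o in product((-1, 0, 1), repeat=ndim) if o > (0,) * ndim]
    return offs  # lexicographically positive half of the neighbourhood


def full_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All distance-1 neighbour offsets: 8 in 2D, 26 in 3D."""
    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def _shift_views(arr: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Views (center, neighbour) such that neighbour = arr[p + offset]."""
    sc, sn = [], []
    for dim, d in enumerate(offset):
        n = arr.shape[dim]
        if d == 0:
            sc.append(slice(0, n))
            sn.append(slice(0, n))
        elif d > 0:
            sc.append(slice(0, max(0, n - d)))
            sn.append(slice(d, n))
        else:
            sc.append(slice(-d, n))
            sn.append(slice(0, max(0, n + d)))
    return arr[tuple(sc)], arr[tuple(sn)]


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, n_levels: int | None = None) -> list[np.ndarray]:
    """Symmetrized, normalized co-occurrence matrix per angle offset.

    Angles with no valid pair yield a zero matrix (skipped by the feature
    averaging).
    """
    ng = n_levels or int(levels.max())
    mats = []
    for off in angle_offsets(levels.ndim):
        c, n = _shift_views(levels, off)
        valid = (c > 0) & (n > 0)
        a = c[valid] - 1
        b = n[valid] - 1
        mat = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        mat = mat + mat.T
        total = mat.sum()
        if total > 0:
            mat /= total
        mats.append(mat)
    return mats


def glrlm_matrices(levels: np.ndarray, n_levels: int | None = None) -> list[np.ndarray]:
    """Run-length count matrix N(level, run_length) per angle offset."""
    ng = n_levels or int(levels.max())
    ndim = levels.ndim
    max_run = max(levels.shape)
    mats = []
    for off in angle_offsets(ndim):
        counts = np.zeros((ng, max_run), dtype=float)
        # run starts: ROI voxels whose predecessor along -off differs
        prev = np.zeros(levels.shape, dtype=bool)
        c, n = _shift_views(levels, tuple(-d for d in off))
        cont_view, _ = _shift_views(prev, tuple(-d for d in off))
        same = (c > 0) & (c == n)
        cont_view[...] = same  # voxel continues a run begun at its predecessor
        starts = np.argwhere((levels > 0) & ~prev)
        if starts.size:
            pos = starts.copy()
            lev = levels[tuple(starts.T)]
            length = np.ones(len(starts), dtype=np.int64)
            active = np.ones(len(starts), dtype=bool)
            off_arr = np.asarray(off)
            while active.any():
                nxt = pos[active] + off_arr
                inside = np.all((nxt >= 0) & (nxt < levels.shape), axis=1)
                same_lev = np.zeros(len(nxt), dtype=bool)
                if inside.any():
                    same_lev[inside] = levels[tuple(nxt[inside].T)] == lev[active][inside]
                # record finished runs
                idx_active = np.flatnonzero(active)
                done = idx_active[~same_lev]
                np.add.at(counts, (lev[done] - 1, length[done] - 1), 1.0)
                go = idx_active[same_lev]
                pos[go] += off_arr
                length[go] += 1
                active[:] = False
                active[go] = True
        mats.append(counts)
    return mats


def glszm_matrix(levels: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Size-zone count matrix Z(level, zone_size); full connectivity zones."""
    ng = n_levels or int(levels.max())
    structure = np.ones((3,) * levels.ndim, dtype=int)
    max_size = int((levels > 0).sum())
    counts = np.zeros((ng, max(max_size, 1)), dtype=float)
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    return counts


def gldm_matrix(levels: np.ndarray, n_levels: int | None = None,
                alpha: int = 0) -> np.ndarray:
    """Dependence count matrix D(level, dependence).

    The dependence of a voxel is 1 (itself) plus the number of in-region
    neighbours whose level differs by at most ``alpha``.
    """
    ng = n_levels or int(levels.max())
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in full_offsets(levels.ndim):
        c, n = _shift_views(levels, off)
        view, _ = _shift_views(dep, off)
        view += ((c > 0) & (n > 0) & (np.abs(c - n) <= alpha)).astype(np.int64)
    dep += 1  # the voxel itself
    roi = levels > 0
    max_dep = int(dep[roi].max()) if roi.any() else 1
    counts = np.zeros((ng, max_dep), dtype=float)
    np.add.at(counts, (levels[roi] - 1, dep[roi] - 1), 1.0)
    return counts


def ngtdm_table(levels: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Neighbourhood gray-tone difference table: rows (n_i, p_i, s_i).

    Only voxels with at least one in-region neighbour contribute.  Returns a
    ``(Ng, 3)`` array indexed by level-1.
    """
    ng = n_levels or int(levels.max())
    nbr_sum = np.zeros(levels.shape, dtype=float)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in full_offsets(levels.ndim):
        c, n = _shift_views(levels, off)
        s_view, _ = _shift_views(nbr_sum, off)
        c_view, _ = _shift_views(nbr_cnt, off)
        inroi = (c > 0) & (n > 0)
        s_view += np.where(inroi, n, 0)
        c_view += inroi.astype(np.int64)
    valid = (levels > 0) & (nbr_cnt > 0)
    table = np.zeros((ng, 3), dtype=float)
    if not valid.any():
        return table
    lev = levels[valid]
    diff = np.abs(lev - nbr_sum[valid] / nbr_cnt[valid])
    np.add.at(table[:, 0], lev - 1, 1.0)
    np.add.at(table[:, 2], lev - 1, diff)
    table[:, 1] = table[:, 0] / table[:, 0].sum()
    return table


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features(mats: list[np.ndarray]) -> dict[str, float]:
    """Angle-averaged GLCM features from normalized symmetric matrices."""
    per_angle: dict[str, list[float]] = {}
    for P in mats:
        if P.sum() == 0:
            continue
        ng = P.shape[0]
        i = np.arange(1, ng + 1)
        px = P.sum(axis=1)
        mu = float((i * px).sum())
        sigma2 = float(((i - mu) ** 2 * px).sum())
        ii, jj = np.meshgrid(i, i, indexing="ij")
        vals: dict[str, float] = {}
        if sigma2 > 0:
            vals["correlation"] = float(((ii * jj * P).sum() - mu * mu) / sigma2)
        else:
            vals["correlation"] = 1.0
        hxy = _entropy2(P.ravel())
        pxy = np.outer(px, px)
        hxy2 = _entropy2(pxy.ravel())
        vals["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        offdiag = ii != jj
        vals["inverse_variance"] = float(
            (P[offdiag] / (ii[offdiag] - jj[offdiag]) ** 2).sum())
        vals["contrast"] = float(((ii - jj) ** 2 * P).sum())
        vals["joint_entropy"] = hxy
        vals["joint_energy"] = float((P ** 2).sum())
        for k, v in vals.items():
            per_angle.setdefault(k, []).append(v)
    if not per_angle:
        return {k: fb for k, fb in [("correlation", 1.0), ("imc2", 0.0),
                                    ("inverse_variance", 0.0), ("contrast", 0.0),
                                    ("joint_entropy", 0.0), ("joint_energy", 0.0)]}
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


def glrlm_features(mats: list[np.ndarray]) -> dict[str, float]:
    """Angle-averaged run-length features from count matrices."""
    per_angle: dict[str, list[float]] = {}
    for N in mats:
        nr = N.sum()
        if nr == 0:
            continue
        r = np.arange(1, N.shape[1] + 1)
        run_sums = N.sum(axis=0)
        level_sums = N.sum(axis=1)
        vals = {
            "long_run_emphasis": float((run_sums * r ** 2).sum() / nr),
            "short_run_emphasis": float((run_sums / r ** 2).sum() / nr),
            "run_length_nonuniformity": float((run_sums ** 2).sum() / nr),
            "gray_level_nonuniformity": float((level_sums ** 2).sum() / nr),
        }
        for k, v in vals.items():
            per_angle.setdefault(k, []).append(v)
    if not per_angle:
        return {k: 0.0 for k in ("long_run_emphasis", "short_run_emphasis",
                                 "run_length_nonuniformity", "gray_level_nonuniformity")}
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


def glszm_features(Z: np.ndarray) -> dict[str, float]:
    nz = Z.sum()
    names = ("large_area_emphasis", "small_area_emphasis",
             "size_zone_nonuniformity", "zone_entropy")
    if nz == 0:
        return {k: 0.0 for k in names}
    s = np.arange(1, Z.shape[1] + 1)
    size_sums = Z.sum(axis=0)
    p = Z / nz
    return {
        "large_area_emphasis": float((size_sums * s ** 2).sum() / nz),
        "small_area_emphasis": float((size_sums / s ** 2).sum() / nz),
        "size_zone_nonuniformity": float((size_sums ** 2).sum() / nz),
        "zone_entropy": _entropy2(p.ravel()),
    }


def gldm_features(D: np.ndarray) -> dict[str, float]:
    nd = D.sum()
    names = ("small_dependence_emphasis", "large_dependence_emphasis",
             "gray_level_variance", "dependence_entropy",
             "dependence_nonuniformity")
    if nd == 0:
        return {k: 0.0 for k in names}
    i = np.arange(1, D.shape[0] + 1)
    j = np.arange(1, D.shape[1] + 1)
    P = D / nd
    dep_sums = D.sum(axis=0)
    level_p = P.sum(axis=1)
    mu = float((i * level_p).sum())
    return {
        "small_dependence_emphasis": float((dep_sums / nd / j ** 2).sum()),
        "large_dependence_emphasis": float((dep_sums / nd * j ** 2).sum()),
        "gray_level_variance": float(((i - mu) ** 2 * level_p).sum()),
        "dependence_entropy": _entropy2(P.ravel()),
        "dependence_nonuniformity": float((dep_sums ** 2).sum() / nd),
    }


def ngtdm_features(table: np.ndarray) -> dict[str, float]:
    """Coarseness, busyness and contrast from the NGTDM table."""
    n_i, p_i, s_i = table[:, 0], table[:, 1], table[:, 2]
    present = p_i > 0
    nvp = n_i.sum()
    out = {"coarseness": COARSENESS_CAP, "busyness": 0.0, "contrast": 0.0}
    if nvp == 0:
        return out
    ps = float((p_i * s_i).sum())
    if ps > 0:
        out["coarseness"] = float(min(1.0 / ps, COARSENESS_CAP))
    i = np.arange(1, table.shape[0] + 1, dtype=float)
    ip = i[present] * p_i[present]
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
    if denom > 0:
        out["busyness"] = ps / denom
    ngp = int(present.sum())
    if ngp > 1:
        pij = np.outer(p_i[present], p_i[present])
        dij2 = (i[present][:, None] - i[present][None, :]) ** 2
        out["contrast"] = float((pij * dij2).sum() / (ngp * (ngp - 1))
                                * s_i.sum() / nvp)
    return out


def first_order_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics on the raw (undiscretized) region values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyROIError("empty region")
    mean = float(v.mean())
    sd = float(v.std())
    out = {
        "mean": mean,
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": float(v.var()),
        "mean_absolute_deviation": float(np.abs(v - mean).mean()),
        "energy": float((v ** 2).sum()),
        "root_mean_squared": float(np.sqrt((v ** 2).mean())),
    }
    out["skewness"] = float(((v - mean) ** 3).mean() / sd ** 3) if sd > 0 else 0.0
    return out


FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


def family_features(family: str, image: np.ndarray, roi: np.ndarray,
                    bin_width: float = 16.0) -> dict[str, float]:
    """Compute all features of one family on ``image`` restricted to ``roi``."""
    roi = np.asarray(roi, dtype=bool)
    if family == "firstorder":
        return first_order_features(np.asarray(image, dtype=float)[roi])
    levels = level_image(image, roi, bin_width)
    ng = int(levels.max())
    if family == "glcm":
        return glcm_features(glcm_matrices(levels, ng))
    if family == "glrlm":
        return glrlm_features(glrlm_matrices(levels, ng))
    if family == "glszm":
        return glszm_features(glszm_matrix(levels, ng))
    if family == "gldm":
        return gldm_features(gldm_matrix(levels, ng))
    if family == "ngtdm":
        return ngtdm_features(ngtdm_table(levels, ng))
    raise ConfigurationError(f"unknown texture family: {family}")
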