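"""Independent brute-force oracles used by the tests.

Everything here is written as plain loops directly from the defining
formulas, deliberately sharing no code with the package implementation.
Level images use 0 for outside-ROI and 1..Ng inside.
"""

import math
from itertools import product

import numpy as np


def _coords(shape):
    return list(product(*[range(s) for s in shape]))


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def _neighbors(ndim):
    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def _angles(ndim):
    return [o for o in product((-1, 0, 1), repeat=ndim) if o > (0,) * ndim]


# -- GLCM -------------------------------------------------------------------

def naive_glcm(levels, offset, ng):
    """Symmetrized normalized co-occurrence matrix for one offset."""
    mat = np.zeros((ng, ng))
    for p in _coords(levels.shape):
        if levels[p] == 0:
            continue
        q = tuple(c + d for c, d in zip(p, offset))
        if _inside(levels.shape, q) and levels[q] > 0:
            mat[levels[p] - 1, levels[q] - 1] += 1
            mat[levels[q] - 1, levels[p] - 1] += 1
    if mat.sum() > 0:
        mat = mat / mat.sum()
    return mat


def naive_glcm_features(levels, ng):
    per_angle = {}
    for off in _angles(levels.ndim):
        P = naive_glcm(levels, off, ng)
        if P.sum() == 0:
            continue
        mu = sum((i + 1) * P[i, j] for i in range(ng) for j in range(ng))
        sig2 = sum(((i + 1) - mu) ** 2 * P[i, j]
                   for i in range(ng) for j in range(ng))
        vals = {}
        if sig2 > 0:
            cov = sum((i + 1) * (j + 1) * P[i, j]
                      for i in range(ng) for j in range(ng)) - mu * mu
            vals["correlation"] = cov / sig2
        else:
            vals["correlation"] = 1.0
        hxy = -sum(P[i, j] * math.log2(P[i, j])
                   for i in range(ng) for j in range(ng) if P[i, j] > 0)
        px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
        hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                    for i in range(ng) for j in range(ng)
                    if px[i] * px[j] > 0)
        vals["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
        vals["inverse_variance"] = sum(P[i, j] / (i - j) ** 2
                                       for i in range(ng) for j in range(ng)
                                       if i != j)
        vals["contrast"] = sum((i - j) ** 2 * P[i, j]
                               for i in range(ng) for j in range(ng))
        vals["joint_entropy"] = hxy
        vals["joint_energy"] = sum(P[i, j] ** 2
                                   for i in range(ng) for j in range(ng))
        for k, v in vals.items():
            per_angle.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


# -- GLRLM ------------------------------------------------------------------

def naive_glrlm(levels, offset, ng, max_run):
    counts = np.zeros((ng, max_run))
    shape = levels.shape
    for p in _coords(shape):
        if levels[p] == 0:
            continue
        prev = tuple(c - d for c, d in zip(p, offset))
        if _inside(shape, prev) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = tuple(c + d for c, d in zip(p, offset))
        while _inside(shape, q) and levels[q] == levels[p]:
            length += 1
            q = tuple(c + d for c, d in zip(q, offset))
        counts[levels[p] - 1, length - 1] += 1
    return counts


def naive_glrlm_features(levels, ng):
    max_run = max(levels.shape)
    per_angle = {}
    for off in _angles(levels.ndim):
        N = naive_glrlm(levels, off, ng, max_run)
        nr = N.sum()
        if nr == 0:
            continue
        vals = {
            "long_run_emphasis": sum(N[i, r] * (r + 1) ** 2
                                     for i in range(ng)
                                     for r in range(max_run)) / nr,
            "short_run_emphasis": sum(N[i, r] / (r + 1) ** 2
                                      for i in range(ng)
                                      for r in range(max_run)) / nr,
            "run_length_nonuniformity": sum(
                sum(N[i, r] for i in range(ng)) ** 2
                for r in range(max_run)) / nr,
            "gray_level_nonuniformity": sum(
                sum(N[i, r] for r in range(max_run)) ** 2
                for i in range(ng)) / nr,
        }
        for k, v in vals.items():
            per_angle.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


# -- GLSZM ------------------------------------------------------------------

def naive_glszm(levels, ng):
    """Zone sizes by BFS flood fill with full (diagonal) connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    max_size = int((levels > 0).sum())
    counts = np.zeros((ng, max(max_size, 1)))
    nbrs = _neighbors(levels.ndim)
    for p in _coords(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack, zone = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            zone += 1
            for off in nbrs:
                q = tuple(c + d for c, d in zip(cur, off))
                if _inside(shape, q) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        counts[g - 1, zone - 1] += 1
    return counts


def naive_glszm_features(levels, ng):
    Z = naive_glszm(levels, ng)
    nz = Z.sum()
    ns = Z.shape[1]
    p = Z / nz
    return {
        "large_area_emphasis": sum(Z[i, s] * (s + 1) ** 2
                                   for i in range(ng) for s in range(ns)) / nz,
        "small_area_emphasis": sum(Z[i, s] / (s + 1) ** 2
                                   for i in range(ng) for s in range(ns)) / nz,
        "size_zone_nonuniformity": sum(
            sum(Z[i, s] for i in range(ng)) ** 2 for s in range(ns)) / nz,
        "zone_entropy": -sum(p[i, s] * math.log2(p[i, s])
                             for i in range(ng) for s in range(ns)
                             if p[i, s] > 0),
    }


# -- GLDM -------------------------------------------------------------------

def naive_gldm(levels, ng, alpha=0):
    shape = levels.shape
    deps = []
    for p in _coords(shape):
        if levels[p] == 0:
            continue
        d = 1
        for off in _neighbors(levels.ndim):
            q = tuple(c + o for c, o in zip(p, off))
            if (_inside(shape, q) and levels[q] > 0
                    and abs(int(levels[q]) - int(levels[p])) <= alpha):
                d += 1
        deps.append((levels[p], d))
    max_dep = max(d for _, d in deps)
    counts = np.zeros((ng, max_dep))
    for g, d in deps:
        counts[g - 1, d - 1] += 1
    return counts


def naive_gldm_features(levels, ng):
    D = naive_gldm(levels, ng)
    nd = D.sum()
    nj = D.shape[1]
    P = D / nd
    mu = sum((i + 1) * P[i, j] for i in range(ng) for j in range(nj))
    return {
        "small_dependence_emphasis": sum(P[i, j] / (j + 1) ** 2
                                         for i in range(ng) for j in range(nj)),
        "large_dependence_emphasis": sum(P[i, j] * (j + 1) ** 2
                                         for i in range(ng) for j in range(nj)),
        "gray_level_variance": sum(((i + 1) - mu) ** 2 * P[i, j]
                                   for i in range(ng) for j in range(nj)),
        "dependence_entropy": -sum(P[i, j] * math.log2(P[i, j])
                                   for i in range(ng) for j in range(nj)
                                   if P[i, j] > 0),
        "dependence_nonuniformity": sum(
            sum(D[i, j] for i in range(ng)) ** 2 for j in range(nj)) / nd,
    }


# -- NGTDM ------------------------------------------------------------------

def naive_ngtdm_features(levels, ng, coarseness_cap=1e6):
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in _coords(shape):
        if levels[p] == 0:
            continue
        nb = [levels[tuple(c + o for c, o in zip(p, off))]
              for off in _neighbors(levels.ndim)
              if _inside(shape, tuple(c + o for c, o in zip(p, off)))
              and levels[tuple(c + o for c, o in zip(p, off))] > 0]
        if not nb:
            continue
        n[levels[p] - 1] += 1
        s[levels[p] - 1] += abs(levels[p] - sum(nb) / len(nb))
    nvp = n.sum()
    out = {"coarseness": coarseness_cap, "busyness": 0.0, "contrast": 0.0}
    if nvp == 0:
        return out
    p_i = n / nvp
    ps = sum(p_i[i] * s[i] for i in range(ng))
    if ps > 0:
        out["coarseness"] = min(1.0 / ps, coarseness_cap)
    denom = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                for i in range(ng) for j in range(ng)
                if p_i[i] > 0 and p_i[j] > 0)
    if denom > 0:
        out["busyness"] = ps / denom
    present = [i for i in range(ng) if p_i[i] > 0]
    if len(present) > 1:
        ngp = len(present)
        c1 = sum(p_i[i] * p_i[j] * (i - j) ** 2
                 for i in present for j in present) / (ngp * (ngp - 1))
        out["contrast"] = c1 * s.sum() / nvp
    return out


# -- misc -------------------------------------------------------------------

def naive_auc(scores, labels):
    """Pairwise O(n^2) Mann-Whitney AUC with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def naive_mannwhitney_u(x, y):
    """Brute-force U statistic of sample x vs y (ties half)."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u
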