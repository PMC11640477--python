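"""Independent brute-force oracles used to check the package's geometry ops.

These deliberately avoid the implementation's code paths (distance
transforms, KD-trees, vectorized extent logic): membership and distances are
computed directly from voxel indices, with plain loops or explicit distance
matrices.
"""

from __future__ import annotations

import math

import numpy as np


def centers(vox: np.ndarray, spacing, origin) -> np.ndarray:
    idx = np.argwhere(vox)
    return np.asarray(origin) + idx * np.asarray(spacing)


def oracle_volume_mm3(vox: np.ndarray, spacing) -> float:
    count = 0
    for v in vox.ravel():
        if v:
            count += 1
    return count * spacing[0] * spacing[1] * spacing[2]


def oracle_centroid(vox: np.ndarray, spacing, origin) -> np.ndarray:
    total = np.zeros(3)
    count = 0
    for i in range(vox.shape[0]):
        for j in range(vox.shape[1]):
            for k in range(vox.shape[2]):
                if vox[i, j, k]:
                    total += np.asarray(origin) + np.array([i, j, k]) * np.asarray(spacing)
                    count += 1
    return total / count


def oracle_dice_jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na = nb = ninter = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        na += bool(va)
        nb += bool(vb)
        ninter += bool(va) and bool(vb)
    nunion = na + nb - ninter
    return 2.0 * ninter / (na + nb), ninter / nunion


def oracle_boundary(vox: np.ndarray) -> np.ndarray:
    """Occupied voxels with >=1 face neighbor unoccupied (grid edge counts)."""
    out = np.zeros_like(vox, dtype=bool)
    nx, ny, nz = vox.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not vox[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                   (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                        out[i, j, k] = True
                        break
                    if not vox[ni, nj, nk]:
                        out[i, j, k] = True
                        break
    return out


def oracle_mda(a: np.ndarray, b: np.ndarray, spacing, origin=(0, 0, 0)) -> float:
    """Symmetric mean surface distance via an explicit all-pairs matrix."""
    pa = centers(oracle_boundary(a), spacing, origin)
    pb = centers(oracle_boundary(b), spacing, origin)
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    d_ab = dmat.min(axis=1)
    d_ba = dmat.min(axis=0)
    return float(np.concatenate([d_ab, d_ba]).mean())


def oracle_expand_isotropic(vox: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Include every voxel whose center is within margin of an occupied center."""
    occ = centers(vox, spacing, (0, 0, 0))
    out = np.zeros_like(vox, dtype=bool)
    sp = np.asarray(spacing, float)
    for i in range(vox.shape[0]):
        for j in range(vox.shape[1]):
            for k in range(vox.shape[2]):
                c = np.array([i, j, k]) * sp
                d2 = ((occ - c) ** 2).sum(axis=1)
                if d2.min() <= (margin + 1e-9) ** 2:
                    out[i, j, k] = True
    return out


def oracle_expand_anisotropic(vox: np.ndarray, spacing, margins: dict) -> np.ndarray:
    """Scatter version of the direction-dependent box dilation.

    Every occupied voxel paints the index box reachable by growing toward R
    by r voxel steps, toward L by l steps, etc. (floor of margin/spacing).
    Canonical axis order: x R->L, y A->P, z I->S.
    """
    sp = spacing
    n = {
        d: int(math.floor(margins[d] / sp[ax] + 1e-9))
        for d, ax in (("r", 0), ("l", 0), ("a", 1), ("p", 1), ("i", 2), ("s", 2))
    }
    out = np.zeros_like(vox, dtype=bool)
    nx, ny, nz = vox.shape
    for i, j, k in np.argwhere(vox):
        out[
            max(0, i - n["r"]): min(nx, i + n["l"] + 1),
            max(0, j - n["a"]): min(ny, j + n["p"] + 1),
            max(0, k - n["i"]): min(nz, k + n["s"] + 1),
        ] = True
    return out


def oracle_margins(itv2: np.ndarray, itv1: np.ndarray, spacing) -> dict:
    """Clipped per-direction face-extent differences, from raw index scans."""
    i2 = np.argwhere(itv2)
    i1 = np.argwhere(itv1)
    out = {}
    for axis, (neg, pos) in enumerate([("r", "l"), ("a", "p"), ("i", "s")]):
        sp = spacing[axis]
        # face coordinates: center -/+ half a voxel
        lo2 = i2[:, axis].min() * sp - sp / 2
        hi2 = i2[:, axis].max() * sp + sp / 2
        lo1 = i1[:, axis].min() * sp - sp / 2
        hi1 = i1[:, axis].max() * sp + sp / 2
        out[neg] = max(0.0, lo2 - lo1)
        out[pos] = max(0.0, hi1 - hi2)
    return out


def oracle_median(values) -> float:
    s = sorted(values)
    n = len(s)
    if n % 2:
        return float(s[n // 2])
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def oracle_tukey_flags(values, k=1.5):
    """Tukey fences with linear-interpolation quartiles."""
    s = sorted(values)
    n = len(s)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [v < q1 - k * iqr or v > q3 + k * iqr for v in values]


def oracle_mean_sd(values) -> tuple[float, float | None]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def oracle_paired_t(x, y) -> tuple[float, float]:
    """Closed-form paired t; p via the regularized incomplete beta function."""
    from scipy.special import betainc

    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    df = n - 1
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, float(p)
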