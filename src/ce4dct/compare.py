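"""ITV-vs-ITV geometric comparison and six-direction margin derivation.

Masks are compared by volume, centroid shift, Dice, Jaccard, and mean
distance agreement (MDA, the symmetric mean surface distance).  The margin
method is a per-direction bounding-extent difference on patient axes: for
each of R/L/A/P/S/I, the margin is how much further the reference volume's
outermost occupied-voxel face reaches in that direction, clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    MarginVector,
    VoxelMask,
    _require_same_grid,
    expand_anisotropic,
)

__all__ = [
    "ComparisonReport",
    "centroid",
    "centroid_shift",
    "overlap_indices",
    "mean_distance_agreement",
    "pct_volume_difference",
    "compare_masks",
    "derive_margins",
    "evaluate_with_margins",
    "EncompassmentError",
]


class EncompassmentError(ValueError):
    """Margin-expanded volume fails to reach the reference extremes."""


@dataclass(frozen=True)
class ComparisonReport:
    """Volume/overlap/distance battery for a mask pair (1 = reference)."""

    vol1_cc: float
    vol2_cc: float
    pct_diff: float
    centroid_shift_mm: float
    dice: float
    jaccard: float
    mda_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "vol1_cc": self.vol1_cc,
            "vol2_cc": self.vol2_cc,
            "pct_diff": self.pct_diff,
            "centroid_shift_mm": self.centroid_shift_mm,
            "dice": self.dice,
            "jaccard": self.jaccard,
            "mda_mm": self.mda_mm,
        }


def centroid(mask: VoxelMask) -> np.ndarray:
    """Unweighted mean of occupied voxel centers, in patient mm (canonical)."""
    if mask.is_empty():
        raise ValueError("centroid undefined for an empty mask")
    return mask.voxel_centers().mean(axis=0)


def centroid_shift(m1: VoxelMask, m2: VoxelMask) -> float:
    """Euclidean distance between the two centroids, mm."""
    return float(np.linalg.norm(centroid(m1) - centroid(m2)))


def overlap_indices(m1: VoxelMask, m2: VoxelMask) -> tuple[float, float]:
    """(Dice, Jaccard).  Two empty masks agree perfectly by convention."""
    a, b = _require_same_grid(m1, m2)
    n1 = int(a.voxels.sum())
    n2 = int(b.voxels.sum())
    if n1 == 0 and n2 == 0:
        warnings.warn("overlap of two empty masks defined as perfect agreement",
                      stacklevel=2)
        return 1.0, 1.0
    inter = int((a.voxels & b.voxels).sum())
    union = n1 + n2 - inter
    return 2.0 * inter / (n1 + n2), inter / union


def _boundary_centers(mask: VoxelMask) -> np.ndarray:
    """Patient-mm centers of boundary voxels (face-connectivity; grid edge
    counts as unoccupied)."""
    from scipy import ndimage

    m = mask.canonicalized()
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m.voxels, structure=structure, border_value=0)
    boundary = m.voxels & ~eroded
    idx = np.argwhere(boundary)
    return m.origin + idx * np.asarray(m.spacing)


def mean_distance_agreement(m1: VoxelMask, m2: VoxelMask) -> float:
    """Symmetric mean surface distance between two masks, mm.

    Both directions' nearest boundary-to-boundary distances are pooled and
    averaged.  Boundary voxels are occupied voxels with at least one
    unoccupied face neighbor.
    """
    if m1.is_empty() or m2.is_empty():
        raise ValueError("MDA undefined for an empty mask")
    b1 = _boundary_centers(m1)
    b2 = _boundary_centers(m2)
    d12 = cKDTree(b2).query(b1)[0]
    d21 = cKDTree(b1).query(b2)[0]
    return float(np.concatenate([d12, d21]).mean())


def pct_volume_difference(vol2: float, vol1: float) -> float:
    """(vol2 - vol1) / vol1 * 100, the signed difference relative to volume 1."""
    if vol1 <= 0:
        raise ValueError(f"reference volume must be > 0, got {vol1}")
    return (vol2 - vol1) / vol1 * 100.0


def compare_masks(itv1: VoxelMask, itv2: VoxelMask) -> ComparisonReport:
    """Full comparison battery with ``itv1`` as the reference volume."""
    a, b = _require_same_grid(itv1, itv2)
    dice, jaccard = overlap_indices(a, b)
    return ComparisonReport(
        vol1_cc=a.volume_cc,
        vol2_cc=b.volume_cc,
        pct_diff=pct_volume_difference(b.volume_mm3, a.volume_mm3),
        centroid_shift_mm=centroid_shift(a, b),
        dice=dice,
        jaccard=jaccard,
        mda_mm=mean_distance_agreement(a, b),
    )


def derive_margins(itv2: VoxelMask, itv1: VoxelMask) -> MarginVector:
    """Six-direction margins required for ``itv2`` to reach ``itv1``.

    For each patient direction the margin is the clipped difference between
    the reference's outermost occupied-voxel face coordinate and ``itv2``'s,
    measured outward along that direction.
    """
    a, b = _require_same_grid(itv2, itv1)
    if a.is_empty() or b.is_empty():
        raise ValueError("margins undefined for an empty mask")
    e2 = a.direction_extents()
    e1 = b.direction_extents()
    return MarginVector(
        r=max(0.0, e2["R"] - e1["R"]),
        l=max(0.0, e1["L"] - e2["L"]),
        a=max(0.0, e2["A"] - e1["A"]),
        p=max(0.0, e1["P"] - e2["P"]),
        s=max(0.0, e1["S"] - e2["S"]),
        i=max(0.0, e2["I"] - e1["I"]),
    )


def evaluate_with_margins(
    itv2: VoxelMask, margins: MarginVector, itv1: VoxelMask, strict: bool = False
) -> ComparisonReport:
    """Comparison report for the margin-expanded ``itv2`` against ``itv1``.

    Additionally checks that the expansion reaches the reference's six
    extreme face coordinates (encompassment at extremes).  A shortfall beyond
    numerical tolerance — possible when margins were not derived from this
    pair, or when the expansion was clipped at the grid boundary — warns, or
    raises :class:`EncompassmentError` when ``strict``.
    """
    expanded = expand_anisotropic(itv2, margins)
    e_exp = expanded.direction_extents()
    e_ref = itv1.canonicalized().direction_extents()
    tol = 1e-6
    shortfalls = {}
    for d in ("L", "P", "S"):
        if e_exp[d] < e_ref[d] - tol:
            shortfalls[d] = round(e_ref[d] - e_exp[d], 6)
    for d in ("R", "A", "I"):
        if e_exp[d] > e_ref[d] + tol:
            shortfalls[d] = round(e_exp[d] - e_ref[d], 6)
    if shortfalls:
        msg = f"expanded volume misses the reference extremes by {shortfalls} mm"
        if strict:
            raise EncompassmentError(msg)
        warnings.warn(msg, stacklevel=2)
    return compare_masks(itv1, expanded)
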