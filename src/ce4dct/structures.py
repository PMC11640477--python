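"""Binary structure masks on physical voxel grids with patient-axis semantics.

The internal canonical frame orders grid axes as (x, y, z) with increasing
index running R->L, A->P, I->S (an LPS-style frame).  Voxel coordinates refer
to voxel centers; a voxel at index ``i`` along an axis with spacing ``s`` and
origin ``o`` is centered at ``o + i*s`` and occupies the half-open physical
extent ``[o + i*s - s/2, o + i*s + s/2)``.

Only axis-aligned (non-oblique) grids are supported: directional margins are
defined on patient axes, and oblique support would require resampling.
"""

from __future__ import annotations

import dataclasses
import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelMask",
    "MarginVector",
    "GridMismatchError",
    "ExpansionClippedWarning",
    "union_phases",
    "expand_isotropic",
    "expand_anisotropic",
    "read_mask",
    "write_mask",
]

#: patient axis index for each direction code
_PAIR_AXIS = {"R": 0, "L": 0, "A": 1, "P": 1, "I": 2, "S": 2}
#: direction codes whose positive sense matches the canonical frame
_POSITIVE = {"L", "P", "S"}
_OPPOSITE = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}

_TOL = 1e-9


class GridMismatchError(ValueError):
    """Two masks do not share dims/spacing/origin/axis labels."""


class ExpansionClippedWarning(UserWarning):
    """A margin expansion reached the grid boundary and was clipped."""


@dataclass(frozen=True)
class MarginVector:
    """Non-negative margins (mm) along the six patient directions."""

    r: float = 0.0
    l: float = 0.0
    a: float = 0.0
    p: float = 0.0
    s: float = 0.0
    i: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "l", "a", "p", "s", "i"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"margin {name!r} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def as_array(self) -> np.ndarray:
        """Order (R, L, A, P, S, I) — the reporting convention."""
        return np.array([self.r, self.l, self.a, self.p, self.s, self.i], float)

    @classmethod
    def zeros(cls) -> "MarginVector":
        return cls()


@dataclass
class VoxelMask:
    """A binary structure on a regular, axis-aligned voxel grid.

    Parameters
    ----------
    voxels
        Boolean occupancy array, one element per voxel.
    spacing
        Physical voxel size in mm per grid axis.
    origin
        Patient-space (canonical frame) coordinate of the center of voxel
        (0, 0, 0), in mm, expressed along the patient axes matching
        ``axis_labels`` pair assignment.
    axis_labels
        Direction of *increasing* index per grid axis, e.g. ``("L","P","S")``
        (the canonical frame).  Must cover all three anatomical pairs.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ("L", "P", "S")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.voxels.dtype != bool:
            uniq = np.unique(self.voxels)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(
                    "non-binary voxel payload; threshold before constructing a mask"
                )
            self.voxels = self.voxels.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_labels = tuple(str(c).upper() for c in self.axis_labels)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        pairs = sorted(_PAIR_AXIS[c] for c in self.axis_labels)
        if len(self.axis_labels) != 3 or pairs != [0, 1, 2]:
            raise ValueError(
                f"axis_labels must name one direction per anatomical pair, "
                f"got {self.axis_labels}"
            )

    # ------------------------------------------------------------------ basics

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3

    @property
    def volume_cc(self) -> float:
        return self.volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def copy(self) -> "VoxelMask":
        return VoxelMask(self.voxels.copy(), self.spacing, self.origin, self.axis_labels)

    def is_canonical(self) -> bool:
        return self.axis_labels == ("L", "P", "S")

    def canonicalized(self) -> "VoxelMask":
        """Return an equivalent mask with axes ordered/flipped to (L, P, S)."""
        if self.is_canonical():
            return self
        perm = [0, 0, 0]
        for grid_ax, code in enumerate(self.axis_labels):
            perm[_PAIR_AXIS[code]] = grid_ax
        vox = np.transpose(self.voxels, perm)
        spacing = [self.spacing[perm[a]] for a in range(3)]
        origin = [self.origin[perm[a]] for a in range(3)]
        labels = [self.axis_labels[perm[a]] for a in range(3)]
        for a in range(3):
            if labels[a] not in _POSITIVE:
                vox = np.flip(vox, axis=a)
                # coordinate of new index j: old origin - (n-1)*s + j*s
                origin[a] = origin[a] - (vox.shape[a] - 1) * spacing[a]
                labels[a] = _OPPOSITE[labels[a]]
        return VoxelMask(np.ascontiguousarray(vox), tuple(spacing), tuple(origin),
                         ("L", "P", "S"))

    # ------------------------------------------------------------- geometry

    def voxel_centers(self) -> np.ndarray:
        """(n, 3) patient-space centers of occupied voxels (canonical frame)."""
        m = self.canonicalized()
        idx = np.argwhere(m.voxels)
        return m.origin + idx * np.asarray(m.spacing)

    def direction_extents(self) -> dict[str, float]:
        """Outermost occupied-voxel *face* coordinate per patient direction.

        Returns mm coordinates keyed by direction code; e.g. ``extents["S"]``
        is the superior face of the most superior occupied voxel.
        """
        m = self.canonicalized()
        if m.is_empty():
            raise ValueError("extents undefined for an empty mask")
        idx = np.argwhere(m.voxels)
        lo = m.origin + idx.min(axis=0) * np.asarray(m.spacing) - np.asarray(m.spacing) / 2
        hi = m.origin + idx.max(axis=0) * np.asarray(m.spacing) + np.asarray(m.spacing) / 2
        return {"R": lo[0], "L": hi[0], "A": lo[1], "P": hi[1], "I": lo[2], "S": hi[2]}


def _require_same_grid(a: VoxelMask, b: VoxelMask) -> tuple[VoxelMask, VoxelMask]:
    a, b = a.canonicalized(), b.canonicalized()
    if a.dims != b.dims:
        raise GridMismatchError(f"dims differ: {a.dims} vs {b.dims}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise GridMismatchError(f"spacing differs: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, atol=1e-6):
        raise GridMismatchError(f"origin differs: {a.origin} vs {b.origin}")
    return a, b


# ---------------------------------------------------------------------- ops


def union_phases(masks: Sequence[VoxelMask]) -> VoxelMask:
    """Voxelwise OR of co-registered phase masks (the ITV construction)."""
    if len(masks) == 0:
        raise ValueError("union_phases requires at least one mask")
    first = masks[0].canonicalized()
    out = first.voxels.copy()
    for m in masks[1:]:
        _, mc = _require_same_grid(first, m)
        out |= mc.voxels
    return VoxelMask(out, first.spacing, first.origin, first.axis_labels)


def expand_isotropic(mask: VoxelMask, margin_mm: float) -> VoxelMask:
    """Euclidean-distance dilation: include voxels within ``margin_mm`` of the set.

    Distances are physical mm (exact on anisotropic spacing, via distance
    transform).  A margin of 0 returns the input unchanged.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    m = mask.canonicalized()
    if margin_mm == 0 or m.is_empty():
        return m.copy()
    dt = ndimage.distance_transform_edt(~m.voxels, sampling=m.spacing)
    out = dt <= margin_mm + _TOL
    _warn_if_clipped(m, out, margin_mm)
    return VoxelMask(out, m.spacing, m.origin, m.axis_labels)


def expand_anisotropic(mask: VoxelMask, margins: MarginVector) -> VoxelMask:
    """Direction-dependent box dilation on patient axes.

    A voxel joins the output iff the original set intersects the axis-aligned
    box around it whose extent toward each signed direction is that
    direction's margin (growth toward R by ``r``, toward L by ``l``, ...).
    Membership uses voxel centers.
    """
    m = mask.canonicalized()
    if m.is_empty():
        return m.copy()
    out = m.voxels
    # (negative-direction margin, positive-direction margin) per canonical axis
    per_axis = [(margins.r, margins.l), (margins.a, margins.p), (margins.i, margins.s)]
    clipped = False
    for axis, (m_neg, m_pos) in enumerate(per_axis):
        sp = m.spacing[axis]
        n_neg = int(np.floor(m_neg / sp + _TOL))
        n_pos = int(np.floor(m_pos / sp + _TOL))
        if n_neg == 0 and n_pos == 0:
            continue
        acc = out.copy()
        for d in range(1, n_pos + 1):  # growth toward the positive face
            acc[_sl(axis, d, None)] |= out[_sl(axis, None, -d)]
        for d in range(1, n_neg + 1):  # growth toward the negative face
            acc[_sl(axis, None, -d)] |= out[_sl(axis, d, None)]
        # occupancy at the boundary face before growth means the expansion
        # would have left the grid
        if n_pos and out[_sl(axis, -n_pos, None)].any():
            clipped = True
        if n_neg and out[_sl(axis, None, n_neg)].any():
            clipped = True
        out = acc
    if clipped:
        warnings.warn(
            "anisotropic expansion reached the grid boundary and was clipped",
            ExpansionClippedWarning,
            stacklevel=2,
        )
    return VoxelMask(out, m.spacing, m.origin, m.axis_labels)


def _sl(axis: int, start, stop) -> tuple[slice, ...]:
    s = [slice(None)] * 3
    s[axis] = slice(start, stop)
    return tuple(s)


def _warn_if_clipped(m: VoxelMask, out: np.ndarray, margin_mm: float) -> None:
    idx = np.argwhere(m.voxels)
    lo = idx.min(axis=0) * np.asarray(m.spacing)
    hi = (np.asarray(m.dims) - 1 - idx.max(axis=0)) * np.asarray(m.spacing)
    if (lo < margin_mm - _TOL).any() or (hi < margin_mm - _TOL).any():
        warnings.warn(
            f"isotropic expansion by {margin_mm} mm reached the grid boundary "
            "and was clipped",
            ExpansionClippedWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------- I/O


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension.

    NIfTI is written with a RAS+ affine; NRRD with LPS space metadata.
    """
    path = Path(path)
    m = mask.canonicalized()
    if path.name.endswith((".nii", ".nii.gz")):
        _write_nifti(m, path)
    elif path.suffix == ".nrrd":
        _write_nrrd(m, path)
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path: str | Path, threshold: float | None = None) -> VoxelMask:
    """Read a NIfTI or NRRD mask; returns a canonicalized VoxelMask.

    Non-binary payloads are rejected unless ``threshold`` is given, in which
    case values ``> threshold`` become occupied.  Oblique affines are rejected.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data, spacing, origin, labels = _read_nifti(path)
    elif path.suffix == ".nrrd":
        data, spacing, origin, labels = _read_nrrd(path)
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    if threshold is not None:
        data = data > threshold
    else:
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"{path.name}: non-binary payload (values {uniq[:8]}...); "
                "pass a threshold to binarize"
            )
        data = data.astype(bool)
    return VoxelMask(data, spacing, origin, labels).canonicalized()


def _write_nifti(m: VoxelMask, path: Path) -> None:
    import nibabel as nib

    # canonical frame is LPS-style; NIfTI affines are RAS+ (negate x, y)
    affine = np.diag([-m.spacing[0], -m.spacing[1], m.spacing[2], 1.0])
    affine[:3, 3] = [-m.origin[0], -m.origin[1], m.origin[2]]
    img = nib.Nifti1Image(m.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    affine = np.asarray(img.affine, float)
    data = np.asarray(img.dataobj)
    rot = affine[:3, :3]
    if np.count_nonzero(np.abs(rot) > 1e-6) != 3:
        raise ValueError(f"{path.name}: oblique affine not supported")
    spacing, origin, labels = [0.0] * 3, [0.0] * 3, [""] * 3
    ras_codes = {0: ("L", "R"), 1: ("P", "A"), 2: ("I", "S")}  # (neg, pos) in RAS
    for grid_ax in range(3):
        pat_ax = int(np.argmax(np.abs(rot[:, grid_ax])))
        step = rot[pat_ax, grid_ax]
        spacing[grid_ax] = abs(step)
        labels[grid_ax] = ras_codes[pat_ax][1] if step > 0 else ras_codes[pat_ax][0]
        # RAS -> canonical LPS-style coordinates: negate x and y
        sign = -1.0 if pat_ax in (0, 1) else 1.0
        origin[grid_ax] = sign * affine[pat_ax, 3]
    return data, tuple(spacing), tuple(origin), tuple(labels)


# Minimal NRRD support (raw / text encodings, axis-aligned space directions).
# pynrrd is not a hard dependency; the subset written here round-trips itself
# and reads standard single-volume detached-header-free NRRD files.

_NRRD_SPACES = {
    "left-posterior-superior": ("L", "P", "S"),
    "right-anterior-superior": ("R", "A", "S"),
    "LPS": ("L", "P", "S"),
    "RAS": ("R", "A", "S"),
}

_NRRD_DTYPES = {
    "uint8": np.uint8, "unsigned char": np.uint8, "uchar": np.uint8,
    "int16": np.int16, "short": np.int16, "uint16": np.uint16,
    "int32": np.int32, "int": np.int32, "float": np.float32,
    "double": np.float64,
}


def _write_nrrd(m: VoxelMask, path: Path) -> None:
    dirs = " ".join(
        "(" + ",".join(f"{m.spacing[a] if a == ax else 0:g}" for a in range(3)) + ")"
        for ax in range(3)
    )
    header = (
        "NRRD0004\n"
        "type: uint8\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {m.dims[0]} {m.dims[1]} {m.dims[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({m.origin[0]:g},{m.origin[1]:g},{m.origin[2]:g})\n"
        "\n"
    )
    # NRRD is fastest-axis-first; numpy C-order has the last axis fastest
    payload = np.ascontiguousarray(m.voxels.astype(np.uint8).transpose(2, 1, 0))
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload.tobytes())


def _parse_nrrd_vectors(text: str) -> list[list[float]]:
    vecs = []
    for chunk in text.replace(") (", ")(").split(")("):
        chunk = chunk.strip().strip("()")
        vecs.append([float(v) for v in chunk.split(",")])
    return vecs


def _read_nrrd(path: Path):
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path.name}: malformed NRRD header")
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    fields: dict[str, str] = {}
    for line in header_lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"{path.name}: only 3-D NRRD supported")
    sizes = [int(v) for v in fields["sizes"].split()]
    dtype = _NRRD_DTYPES[fields.get("type", "uint8")]
    encoding = fields.get("encoding", "raw").lower()
    space = fields.get("space", "left-posterior-superior")
    if space not in _NRRD_SPACES:
        raise ValueError(f"{path.name}: unsupported NRRD space {space!r}")
    space_signs = _NRRD_SPACES[space]

    body = raw[end + 2:]
    if encoding == "raw":
        data = np.frombuffer(body, dtype=dtype)
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(body), dtype=dtype)
    elif encoding in ("txt", "text", "ascii"):
        data = np.array(body.decode("ascii").split(), dtype=dtype)
    else:
        raise ValueError(f"{path.name}: unsupported NRRD encoding {encoding!r}")
    data = data[: int(np.prod(sizes))].reshape(sizes[::-1]).transpose(2, 1, 0)

    dirs = _parse_nrrd_vectors(fields["space directions"])
    origin_vec = _parse_nrrd_vectors(fields.get("space origin", "(0,0,0)"))[0]
    spacing, origin, labels = [0.0] * 3, [0.0] * 3, [""] * 3
    # map the stated space axes onto canonical LPS-style patient axes
    lps_codes = {0: ("R", "L"), 1: ("A", "P"), 2: ("I", "S")}  # (neg, pos) in LPS
    for grid_ax in range(3):
        vec = np.asarray(dirs[grid_ax], float)
        if np.count_nonzero(np.abs(vec) > 1e-6) != 1:
            raise ValueError(f"{path.name}: oblique space directions not supported")
        sp_ax = int(np.argmax(np.abs(vec)))
        step = vec[sp_ax]
        # flip sign where the file's space axis opposes the canonical sense
        flip = -1.0 if space_signs[sp_ax] in ("R", "A") else 1.0
        canon_step = step * flip
        spacing[grid_ax] = abs(step)
        labels[grid_ax] = lps_codes[sp_ax][1] if canon_step > 0 else lps_codes[sp_ax][0]
        origin[grid_ax] = origin_vec[sp_ax] * flip
    return data, tuple(spacing), tuple(origin), tuple(labels)
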