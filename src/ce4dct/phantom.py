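"""Synthetic 4DCT-like data: a moving lesion split into respiratory phases,
an enhancing aorta with first-pass/plateau kinetics, slice timestamps for a
slow helical acquisition, and ground-truth ITV pairs for margin recovery
tests.

Everything is deterministic for a fixed seed.  The respiratory displacement
profile is cos^4-weighted over the phase index (more time spent at exhale),
and contrast kinetics follow a gamma-variate first pass that blends into a
constant recirculation plateau.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinetics import TimeDensityCurve
from .structures import MarginVector, VoxelMask, union_phases

__all__ = [
    "ContrastKinetics",
    "PhantomSpec",
    "BreathingTrace",
    "TimeDensityCurve",
    "PhantomConfigurationError",
    "kinetics_curve",
    "generate_phase_masks",
    "generate_aorta_tdc",
    "generate_slice_timestamps",
    "generate_breathing_trace",
    "generate_aorta_slices",
    "generate_itv_pair",
]


class PhantomConfigurationError(ValueError):
    """The requested phantom geometry does not fit the grid."""


@dataclass(frozen=True)
class ContrastKinetics:
    """Aortic enhancement model: gamma-variate first pass + washout plateau.

    The noiseless curve is ``baseline_hu`` before ``arrival_time``, rises
    along a normalized gamma-variate scaled by ``peak_scale`` (analytic
    maximum at ``arrival_time + gamma_alpha * gamma_beta``), and blends over
    ``blend_width`` seconds into a constant ``plateau_hu`` from
    ``plateau_onset`` onward.

    Defaults are tuned so the noiseless peak sits near 54.5 s at ~292 HU with
    a ~169 HU plateau from ~70 s.
    """

    baseline_hu: float = 50.0
    arrival_time: float = 10.0
    gamma_alpha: float = 3.0
    gamma_beta: float = 14.8
    peak_scale: float = 242.0
    plateau_hu: float = 169.0
    plateau_onset: float = 70.3
    blend_width: float = 8.0

    def __post_init__(self) -> None:
        if self.gamma_alpha <= 0 or self.gamma_beta <= 0:
            raise ValueError("gamma_alpha and gamma_beta must be > 0")
        if not (self.peak_hu > self.plateau_hu > self.baseline_hu):
            raise ValueError(
                "require peak HU > plateau HU > baseline HU, got "
                f"{self.peak_hu} / {self.plateau_hu} / {self.baseline_hu}"
            )
        if self.blend_width <= 0:
            raise ValueError("blend_width must be > 0")
        if self.plateau_onset - self.blend_width <= self.peak_time:
            raise ValueError("blend window must start after the first-pass peak")

    @property
    def peak_time(self) -> float:
        """Analytic time of the noiseless maximum."""
        return self.arrival_time + self.gamma_alpha * self.gamma_beta

    @property
    def peak_hu(self) -> float:
        return self.baseline_hu + self.peak_scale


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the digital phantom."""

    grid_dims: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    lesion_center: tuple[float, float, float] = (24.0, 24.0, 40.0)
    lesion_radii: tuple[float, float, float] = (8.0, 8.0, 8.0)
    motion_amplitude: tuple[float, float, float] = (0.0, 0.0, 12.0)
    n_phases: int = 10
    breathing_period: float = 4.0
    aorta_center_xy: tuple[float, float] = (10.0, 24.0)
    aorta_diameter: float = 20.0
    kinetics: ContrastKinetics = field(default_factory=ContrastKinetics)
    scan_start_offset: float = 0.0
    slice_interval: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0 per axis")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.aorta_diameter <= 0:
            raise ValueError("aorta_diameter must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_lesion_fits(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        if "kinetics" in payload:
            payload["kinetics"] = ContrastKinetics(**payload["kinetics"])
        for key in ("grid_dims", "spacing", "lesion_center", "lesion_radii",
                    "motion_amplitude", "aorta_center_xy"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass(frozen=True)
class BreathingTrace:
    """Surrogate respiratory signal (illustrative; no clinical trace model)."""

    times: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        d = np.asarray(self.displacement, float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and displacement must be equal-length 1-D arrays")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.isfinite(t).all() and np.isfinite(d).all()):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacement", d)


# ----------------------------------------------------------------- internals


def _phase_profile(n_phases: int) -> np.ndarray:
    """cos^4 displacement weight per phase index, in [0, 1]."""
    p = np.arange(n_phases)
    return np.cos(np.pi * p / n_phases) ** 4


def _check_lesion_fits(spec: PhantomSpec) -> None:
    center = np.asarray(spec.lesion_center, float)
    radii = np.asarray(spec.lesion_radii, float)
    amp = np.asarray(spec.motion_amplitude, float)
    dims = np.asarray(spec.grid_dims, float)
    spacing = np.asarray(spec.spacing, float)
    lo = np.minimum(center, center + amp) - radii
    hi = np.maximum(center, center + amp) + radii
    grid_lo = -spacing / 2
    grid_hi = (dims - 1) * spacing + spacing / 2
    if (lo < grid_lo - 1e-9).any() or (hi > grid_hi + 1e-9).any():
        raise PhantomConfigurationError(
            "lesion ellipsoid plus motion extent leaves the grid: "
            f"needs [{lo}, {hi}] mm but grid spans [{grid_lo}, {grid_hi}] mm"
        )


def _ellipsoid_mask(spec: PhantomSpec, center: np.ndarray) -> np.ndarray:
    coords = [
        np.arange(spec.grid_dims[a]) * spec.spacing[a] for a in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    rx, ry, rz = spec.lesion_radii
    val = (
        ((xx - center[0]) / rx) ** 2
        + ((yy - center[1]) / ry) ** 2
        + ((zz - center[2]) / rz) ** 2
    )
    return val <= 1.0 + 1e-12


# ----------------------------------------------------------------------- ops


def generate_phase_masks(spec: PhantomSpec) -> list[VoxelMask]:
    """Lesion masks per respiratory phase, displaced by the cos^4 profile."""
    profile = _phase_profile(spec.n_phases)
    center0 = np.asarray(spec.lesion_center, float)
    amp = np.asarray(spec.motion_amplitude, float)
    masks = []
    for w in profile:
        vox = _ellipsoid_mask(spec, center0 + amp * w)
        if not vox.any():
            raise PhantomConfigurationError("phase mask is empty; radii below spacing?")
        masks.append(VoxelMask(vox, spec.spacing))
    return masks


def kinetics_curve(kinetics: ContrastKinetics, times: np.ndarray) -> np.ndarray:
    """Noiseless aortic HU at the given times since injection (vectorized)."""
    t = np.asarray(times, float)
    hu = np.full(t.shape, kinetics.baseline_hu, float)

    tau = t - kinetics.arrival_time
    rising = tau > 0
    ab = kinetics.gamma_alpha * kinetics.gamma_beta
    # gamma-variate normalized to 1 at tau = alpha*beta
    with np.errstate(invalid="ignore"):
        g = np.where(
            rising,
            (np.maximum(tau, 1e-300) / ab) ** kinetics.gamma_alpha
            * np.exp(kinetics.gamma_alpha - np.maximum(tau, 0.0) / kinetics.gamma_beta),
            0.0,
        )
    first_pass = kinetics.baseline_hu + kinetics.peak_scale * g
    hu = np.where(rising, first_pass, hu)

    # smoothstep blend into the constant plateau over the blend window
    b0 = kinetics.plateau_onset - kinetics.blend_width
    w = np.clip((t - b0) / kinetics.blend_width, 0.0, 1.0)
    w = w * w * (3.0 - 2.0 * w)
    blend = t > b0
    hu = np.where(blend, (1.0 - w) * hu + w * kinetics.plateau_hu, hu)
    hu = np.where(t >= kinetics.plateau_onset, kinetics.plateau_hu, hu)
    return hu


def generate_aorta_tdc(
    kinetics: ContrastKinetics,
    sample_times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeDensityCurve:
    """Sample the aortic enhancement model, optionally with Gaussian HU noise."""
    t = np.asarray(sample_times, float)
    if t.size == 0:
        raise ValueError("sample_times is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    hu = kinetics_curve(kinetics, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd, size=t.shape)
    return TimeDensityCurve(t, hu)


def generate_slice_timestamps(
    scan_length_mm: float,
    slice_thickness_mm: float,
    duration_s: float,
    start_time_s: float = 0.0,
) -> np.ndarray:
    """Uniform per-slice acquisition times for a constant-speed helical scan.

    The slice count is ``ceil(length / thickness)``; the first slice is
    acquired at ``start_time_s`` and the last at ``start_time_s + duration_s``.
    """
    if scan_length_mm <= 0:
        raise ValueError("scan_length_mm must be > 0")
    if slice_thickness_mm <= 0:
        raise ValueError("slice_thickness_mm must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(np.ceil(scan_length_mm / slice_thickness_mm - 1e-9))
    if n == 1:
        return np.array([start_time_s], float)
    return start_time_s + np.linspace(0.0, duration_s, n)


def generate_breathing_trace(
    duration_s: float,
    period_s: float = 4.0,
    amplitude_mm: float = 12.0,
    dt_s: float = 0.1,
) -> BreathingTrace:
    """Illustrative cos^4 surrogate signal (exhale baseline at 0)."""
    if duration_s <= 0 or period_s <= 0 or dt_s <= 0:
        raise ValueError("duration, period and dt must be > 0")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    disp = amplitude_mm * np.cos(np.pi * t / period_s) ** 4
    return BreathingTrace(t, disp)


def generate_aorta_slices(
    spec: PhantomSpec,
    slice_times: Sequence[float],
    t_delay: float,
    t0: float | None = None,
    background_hu: float = 40.0,
) -> np.ndarray:
    """Per-slice axial HU images of an enhancing aortic cylinder.

    Slice ``k`` (acquired at ``slice_times[k]``) shows the aorta disc at the
    HU given by the kinetics model evaluated at the post-injection time
    ``t_delay + (slice_times[k] - t0)``.  Returns an array indexed
    ``[slice, ix, iy]`` matching the grid's in-plane axes.
    """
    st = np.asarray(slice_times, float)
    if t0 is None:
        t0 = float(st[0]) if st.size else 0.0
    nx, ny = spec.grid_dims[0], spec.grid_dims[1]
    x = np.arange(nx) * spec.spacing[0]
    y = np.arange(ny) * spec.spacing[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    cx, cy = spec.aorta_center_xy
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= (spec.aorta_diameter / 2) ** 2
    inj_times = t_delay + (st - t0)
    hu_t = kinetics_curve(spec.kinetics, inj_times)
    out = np.full((st.size, nx, ny), background_hu, float)
    for k in range(st.size):
        out[k][disc] = hu_t[k]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def _extent_margins(itv2: VoxelMask, itv1: VoxelMask) -> MarginVector:
    """Brute-force per-direction extent comparison (index-loop oracle).

    Independent of :func:`ce4dct.compare.derive_margins`: works directly on
    occupied-index minima/maxima of the two canonical arrays.
    """
    a = itv2.canonicalized()
    b = itv1.canonicalized()
    sp = a.spacing
    ia = np.argwhere(a.voxels)
    ib = np.argwhere(b.voxels)
    out = {}
    for axis, (neg, pos) in enumerate([("r", "l"), ("a", "p"), ("i", "s")]):
        lo2, hi2 = ia[:, axis].min(), ia[:, axis].max()
        lo1, hi1 = ib[:, axis].min(), ib[:, axis].max()
        out[neg] = max(0.0, (lo2 - lo1) * sp[axis])
        out[pos] = max(0.0, (hi1 - hi2) * sp[axis])
    return MarginVector(**out)


def generate_itv_pair(
    spec: PhantomSpec,
    dropout_phases: Sequence[int] = (),
    known_shift_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[VoxelMask, VoxelMask, MarginVector]:
    """Ground-truth ITV pair for margin-recovery tests.

    ``itv1`` is the union of all phases; ``itv2`` is the union excluding
    ``dropout_phases``, then translated by ``known_shift_mm`` (rounded to a
    whole number of voxels per axis).  ``expected_margins`` come from a
    brute-force per-direction extent comparison.
    """
    dropout = set(int(p) for p in dropout_phases)
    if not dropout <= set(range(spec.n_phases)):
        raise ValueError(f"dropout_phases outside 0..{spec.n_phases - 1}: {dropout}")
    if len(dropout) == spec.n_phases:
        raise ValueError("cannot drop every phase")
    masks = generate_phase_masks(spec)
    itv1 = union_phases(masks)
    kept = [m for p, m in enumerate(masks) if p not in dropout]
    itv2 = union_phases(kept)

    shift_vox = [int(round(known_shift_mm[a] / spec.spacing[a])) for a in range(3)]
    if any(shift_vox):
        vox = itv2.voxels
        for axis, sv in enumerate(shift_vox):
            if sv == 0:
                continue
            rolled = np.zeros_like(vox)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sv > 0:
                dst[axis], src[axis] = slice(sv, None), slice(None, -sv)
                if vox[tuple(_edge(axis, slice(-sv, None)))].any():
                    raise PhantomConfigurationError("shift pushes itv2 off the grid")
            else:
                dst[axis], src[axis] = slice(None, sv), slice(-sv, None)
                if vox[tuple(_edge(axis, slice(None, -sv)))].any():
                    raise PhantomConfigurationError("shift pushes itv2 off the grid")
            rolled[tuple(dst)] = vox[tuple(src)]
            vox = rolled
        itv2 = VoxelMask(vox, itv2.spacing, itv2.origin, itv2.axis_labels)

    return itv1, itv2, _extent_margins(itv2, itv1)


def _edge(axis: int, sl: slice) -> list[slice]:
    s = [slice(None)] * 3
    s[axis] = sl
    return s
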