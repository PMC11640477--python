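"""Personalized injection-delay computation and contrast protocol arithmetic.

The scan needs ``t_scan = (t1 + t2)/2 - t0`` seconds to reach the tumor's
craniocaudal center, where ``t0`` is the first absolute slice time and
``t1``/``t2`` the first/last tumor-containing slice times.  To image the
tumor at the desired post-injection time ``t_phase``, the injection leads the
scan by ``t_delay = t_phase - t_scan``: non-negative delays are synchronized
automatically by the scanner countdown, negative delays require manual
(stopwatch) synchronization because the scan must start first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import ARTERIAL_T_PHASE_S, PORTAL_T_PHASE_S
from .structures import VoxelMask, union_phases

__all__ = [
    "PhaseTiming",
    "ContrastProtocol",
    "SyncMode",
    "TumorNotFoundError",
    "MAX_CONTRAST_VOLUME_ML",
    "DEFAULT_FLOW_RATE_ML_S",
    "compute_t_scan",
    "compute_t_delay",
    "compute_contrast_volume",
    "locate_tumor_slices",
    "plan_timing",
]

MAX_CONTRAST_VOLUME_ML = 140.0
DEFAULT_FLOW_RATE_ML_S = 2.5
VOLUME_FACTOR_RANGE = (1.8, 2.0)

AUTOMATED = "automated"
MANUAL = "manual"
SyncMode = str


class TumorNotFoundError(ValueError):
    """No slice intersects the tumor; fall back to manual anatomical review."""


@dataclass(frozen=True)
class PhaseTiming:
    """The complete per-patient timing record."""

    t0: float
    t1: float
    t2: float
    t_phase: float
    t_scan: float
    t_delay: float
    sync_mode: SyncMode

    @classmethod
    def from_slice_times(
        cls, t0: float, t1: float, t2: float, t_phase: float
    ) -> "PhaseTiming":
        t_scan = compute_t_scan(t0, t1, t2)
        t_delay, mode = compute_t_delay(t_phase, t_scan)
        return cls(t0=float(t0), t1=float(t1), t2=float(t2), t_phase=float(t_phase),
                   t_scan=t_scan, t_delay=t_delay, sync_mode=mode)

    def as_dict(self) -> dict:
        return {
            "t0_s": self.t0, "t1_s": self.t1, "t2_s": self.t2,
            "t_phase_s": self.t_phase, "t_scan_s": self.t_scan,
            "t_delay_s": self.t_delay, "sync_mode": self.sync_mode,
        }


@dataclass(frozen=True)
class ContrastProtocol:
    """Weight-based contrast volume at a fixed flow rate."""

    weight_kg: float
    volume_factor: float
    volume_ml: float
    flow_rate: float = DEFAULT_FLOW_RATE_ML_S

    @classmethod
    def for_patient(
        cls,
        weight_kg: float,
        volume_factor: float = 1.9,
        flow_rate: float = DEFAULT_FLOW_RATE_ML_S,
    ) -> "ContrastProtocol":
        if flow_rate <= 0:
            raise ValueError("flow_rate must be > 0")
        volume = compute_contrast_volume(weight_kg, volume_factor)
        return cls(weight_kg=float(weight_kg), volume_factor=float(volume_factor),
                   volume_ml=volume, flow_rate=float(flow_rate))

    @property
    def injection_duration_s(self) -> float:
        return self.volume_ml / self.flow_rate

    def as_dict(self) -> dict:
        return {
            "weight_kg": self.weight_kg, "volume_factor_ml_per_kg": self.volume_factor,
            "volume_ml": self.volume_ml, "flow_rate_ml_s": self.flow_rate,
            "injection_duration_s": self.injection_duration_s,
        }


def compute_t_scan(t0: float, t1: float, t2: float) -> float:
    """Time from scan start to the tumor's craniocaudal center: (t1+t2)/2 - t0."""
    if t1 < t0:
        raise ValueError(f"t1 ({t1}) precedes t0 ({t0})")
    if t2 < t1:
        raise ValueError(f"t2 ({t2}) precedes t1 ({t1})")
    return (t1 + t2) / 2.0 - t0


def compute_t_delay(t_phase: float, t_scan: float) -> tuple[float, SyncMode]:
    """Injection-to-scan offset and its synchronization mode.

    ``t_delay >= 0``: injection starts first, synchronized automatically with
    the scanner countdown.  ``t_delay < 0``: the scan must start before the
    injection, requiring manual stopwatch synchronization.
    """
    if t_scan < 0:
        raise ValueError(f"t_scan must be >= 0, got {t_scan}")
    t_delay = t_phase - t_scan
    return t_delay, (AUTOMATED if t_delay >= 0 else MANUAL)


def compute_contrast_volume(weight_kg: float, volume_factor: float) -> float:
    """Weight-scaled contrast volume in mL, capped at 140 mL."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    lo, hi = VOLUME_FACTOR_RANGE
    if not (lo <= volume_factor <= hi):
        raise ValueError(
            f"volume_factor {volume_factor} outside the protocol range [{lo}, {hi}]"
        )
    return min(weight_kg * volume_factor, MAX_CONTRAST_VOLUME_ML)


def locate_tumor_slices(
    phase_masks: Sequence[VoxelMask], timestamps: Sequence[float]
) -> tuple[float, float, float]:
    """(t0, t1, t2) from phase masks and per-slice acquisition times.

    Tumor-containing slices are taken on the union of all phase masks (the
    full respiratory extent); slices run along the S/I grid axis.
    """
    ts = np.asarray(timestamps, float)
    itv = union_phases(phase_masks).canonicalized()
    n_slices = itv.dims[2]
    if len(ts) != n_slices:
        raise ValueError(
            f"timestamps cover {len(ts)} slices but the grid has {n_slices}"
        )
    occupied = np.flatnonzero(itv.voxels.any(axis=(0, 1)))
    if occupied.size == 0:
        raise TumorNotFoundError(
            "tumor not found in any slice; identify it from anatomical markers "
            "and supply t1/t2 manually"
        )
    return float(ts[0]), float(ts[occupied[0]]), float(ts[occupied[-1]])


def plan_timing(
    t0: float,
    t1: float,
    t2: float,
    phase: str = "arterial",
    t_phase: float | None = None,
    weight_kg: float | None = None,
    volume_factor: float = 1.9,
    flow_rate: float = DEFAULT_FLOW_RATE_ML_S,
) -> tuple[PhaseTiming, ContrastProtocol | None]:
    """One-call planning: timing record plus (optionally) the contrast protocol."""
    if t_phase is None:
        if phase == "arterial":
            t_phase = ARTERIAL_T_PHASE_S
        elif phase == "portal":
            t_phase = PORTAL_T_PHASE_S
        else:
            raise ValueError(
                f"phase must be 'arterial' or 'portal' (or pass t_phase), got {phase!r}"
            )
    timing = PhaseTiming.from_slice_times(t0, t1, t2, t_phase)
    protocol = None
    if weight_kg is not None:
        protocol = ContrastProtocol.for_patient(weight_kg, volume_factor, flow_rate)
    return timing, protocol
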