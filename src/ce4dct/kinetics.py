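"""Aortic contrast-kinetics analysis.

Builds circular aortic ROIs under the geometric rules (>= 5 mm diameter, >= 2
mm inside the vessel edge), extracts mean-HU time-density curves on the
post-injection timeline, detects the first-pass peak and the washout plateau,
and aggregates per-patient summaries into population statistics used to
refine the target contrast-phase time.

Plateau detection is a trailing-window least-squares slope test (the source
protocol reads the plateau off the plotted curve without a stated criterion;
both the slope threshold and the window length are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AortaROI",
    "TimeDensityCurve",
    "KineticsSummary",
    "PopulationSummary",
    "NoEnhancementError",
    "PlateauNotReachedError",
    "ARTERIAL_T_PHASE_S",
    "PORTAL_T_PHASE_S",
    "build_aorta_roi",
    "extract_tdc",
    "detect_peak",
    "detect_plateau",
    "summarize_tdc",
    "summarize_population",
    "refine_t_phase",
]

#: radiologist-recommended defaults used before any population data exist
ARTERIAL_T_PHASE_S = 50.0
PORTAL_T_PHASE_S = 70.0

MIN_ROI_DIAMETER_MM = 5.0
EDGE_MARGIN_MM = 2.0


class NoEnhancementError(ValueError):
    """The curve shows no enhancement (constant signal)."""


class PlateauNotReachedError(ValueError):
    """No sufficiently flat trailing window exists after the peak."""


@dataclass(frozen=True)
class TimeDensityCurve:
    """Mean ROI attenuation (HU) vs. time since contrast injection (s).

    Times must be strictly increasing; negative times denote pre-injection
    samples and are permitted.
    """

    times: np.ndarray
    mean_hu: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        h = np.asarray(self.mean_hu, float)
        if t.ndim != 1 or t.shape != h.shape:
            raise ValueError("times and mean_hu must be equal-length 1-D arrays")
        if len(t) == 0:
            raise ValueError("empty time-density curve")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(h).all():
            raise ValueError("mean_hu must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean_hu", h)

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "mean_hu": self.mean_hu}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeDensityCurve":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        tcol = cols.get("time_s", df.columns[0])
        vcol = cols.get("mean_hu", cols.get("value", df.columns[1]))
        return cls(df[tcol].to_numpy(float), df[vcol].to_numpy(float))


@dataclass(frozen=True)
class AortaROI:
    """Circular axial-plane ROI on the aorta."""

    slice_index: int
    center: tuple[float, float]  # mm, in-plane (x, y)
    diameter: float  # mm

    def __post_init__(self) -> None:
        if self.diameter < MIN_ROI_DIAMETER_MM:
            raise ValueError(
                f"ROI diameter {self.diameter} mm below the "
                f"{MIN_ROI_DIAMETER_MM} mm minimum"
            )


@dataclass(frozen=True)
class KineticsSummary:
    """Peak/plateau characterization of one patient's curve."""

    t_peak: float
    hu_peak: float
    t_plateau: float
    hu_plateau: float
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.t_plateau < self.t_peak:
            raise ValueError("t_plateau must be >= t_peak")
        if self.hu_peak < self.hu_plateau:
            raise ValueError("hu_peak must be >= hu_plateau")


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort statistics of peak/plateau timing and enhancement."""

    n: int
    n_outliers: int
    t_peak_median: float
    t_peak_range: tuple[float, float]
    t_plateau_median: float
    t_plateau_range: tuple[float, float]
    hu_peak_mean: float
    hu_peak_sd: float | None
    hu_plateau_mean: float
    hu_plateau_sd: float | None
    outliers_excluded: bool


def build_aorta_roi(
    aorta_diameter: float,
    slice_index: int = 0,
    aorta_center: tuple[float, float] = (0.0, 0.0),
) -> AortaROI:
    """Size a circular ROI to the vessel: diameter - 2*2 mm, minimum 5 mm.

    Vessels narrower than 9 mm cannot satisfy both the 5 mm ROI minimum and
    the 2 mm edge margin; these are rejected for manual review.
    """
    if aorta_diameter <= 0:
        raise ValueError(f"aorta_diameter must be > 0, got {aorta_diameter}")
    admissible = aorta_diameter - 2 * EDGE_MARGIN_MM
    if admissible < MIN_ROI_DIAMETER_MM - 1e-12:
        raise ValueError(
            f"aorta diameter {aorta_diameter} mm admits at most {admissible:.1f} mm "
            f"of ROI, below the {MIN_ROI_DIAMETER_MM} mm minimum — review manually"
        )
    return AortaROI(slice_index=slice_index, center=tuple(aorta_center),
                    diameter=admissible)


def extract_tdc(
    hu_slices: np.ndarray | Sequence[np.ndarray],
    rois: Sequence[AortaROI],
    slice_times: Sequence[float],
    t_delay: float,
    t0: float | None = None,
    spacing_xy: tuple[float, float] = (1.0, 1.0),
    origin_xy: tuple[float, float] = (0.0, 0.0),
) -> TimeDensityCurve:
    """Mean HU inside each ROI, on the seconds-since-injection time axis.

    The time of the sample from slice ``k`` is ``t_delay + (slice_times[k] -
    t0)``; negative values (pre-injection slices) are allowed.  A voxel
    belongs to an ROI iff its in-plane center lies within the ROI disc.

    ``hu_slices`` is indexed ``[slice][ix, iy]`` with in-plane coordinates
    ``origin_xy + index * spacing_xy``.
    """
    st = np.asarray(slice_times, float)
    if len(rois) != len(st):
        raise ValueError(
            f"need one ROI per analyzed slice: {len(rois)} ROIs vs {len(st)} times"
        )
    if t0 is None:
        t0 = float(st[0])
    values = np.empty(len(rois), float)
    for k, roi in enumerate(rois):
        img = np.asarray(hu_slices[roi.slice_index], float)
        nx, ny = img.shape
        x = origin_xy[0] + np.arange(nx) * spacing_xy[0]
        y = origin_xy[1] + np.arange(ny) * spacing_xy[1]
        xx, yy = np.meshgrid(x, y, indexing="ij")
        inside = (xx - roi.center[0]) ** 2 + (yy - roi.center[1]) ** 2 <= (
            roi.diameter / 2
        ) ** 2 + 1e-9
        if not inside.any():
            raise ValueError(
                f"ROI at slice {roi.slice_index} contains no voxel centers "
                f"(diameter {roi.diameter} mm under-resolved for spacing {spacing_xy})"
            )
        values[k] = img[inside].mean()
    times = t_delay + (st - t0)
    order = np.argsort(times)
    return TimeDensityCurve(times[order], values[order])


def detect_peak(
    tdc: TimeDensityCurve, smoothing_window: int = 3
) -> tuple[float, float]:
    """Contrast-peak time and HU: argmax of the moving-average-smoothed curve.

    Returns the unsmoothed HU at the selected sample; ties resolve to the
    earliest time.
    """
    if len(tdc) < 5:
        raise ValueError(f"need at least 5 samples, got {len(tdc)}")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    hu = tdc.mean_hu
    if np.ptp(hu) == 0:
        raise NoEnhancementError("no enhancement detected: curve is constant")
    w = min(smoothing_window, len(hu))
    kernel = np.ones(w) / w
    # centered moving average with edge-shrunk windows
    smoothed = np.convolve(hu, kernel, mode="same")
    counts = np.convolve(np.ones_like(hu), kernel, mode="same")
    smoothed = smoothed / counts
    idx = int(np.argmax(smoothed))  # argmax returns the first maximum
    return float(tdc.times[idx]), float(hu[idx])


def detect_plateau(
    tdc: TimeDensityCurve,
    t_peak: float,
    slope_threshold: float = 0.5,
    window: float = 10.0,
) -> tuple[float, float]:
    """Washout-plateau time and HU by a trailing-window flatness test.

    Scans sample times after the peak and returns the earliest time ``t`` at
    which the least-squares slope of the curve over ``[t - window, t]`` has
    magnitude <= ``slope_threshold`` HU/s.  The plateau HU is the mean over
    that window.
    """
    t, hu = tdc.times, tdc.mean_hu
    if not (t[0] <= t_peak <= t[-1]):
        raise ValueError(f"t_peak {t_peak} outside curve support [{t[0]}, {t[-1]}]")
    if slope_threshold < 0 or window <= 0:
        raise ValueError("slope_threshold must be >= 0 and window > 0")
    for k in range(len(t)):
        if t[k] <= t_peak or t[k] - window < t[0] - 1e-9 or t[k] - window < t_peak - 1e-9:
            continue
        sel = (t >= t[k] - window - 1e-9) & (t <= t[k] + 1e-9)
        if sel.sum() < 2:
            continue
        slope = np.polyfit(t[sel], hu[sel], 1)[0]
        if abs(slope) <= slope_threshold:
            return float(t[k]), float(hu[sel].mean())
    raise PlateauNotReachedError("plateau not reached within scan")


def summarize_tdc(
    tdc: TimeDensityCurve,
    smoothing_window: int = 3,
    slope_threshold: float = 0.5,
    plateau_window: float = 10.0,
) -> KineticsSummary:
    """Peak + plateau characterization of a single curve."""
    t_peak, hu_peak = detect_peak(tdc, smoothing_window)
    t_plateau, hu_plateau = detect_plateau(tdc, t_peak, slope_threshold, plateau_window)
    return KineticsSummary(
        t_peak=t_peak,
        hu_peak=hu_peak,
        t_plateau=t_plateau,
        hu_plateau=min(hu_plateau, hu_peak),
    )


def _tukey_outliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def summarize_population(
    summaries: Sequence[KineticsSummary], exclude_outliers: bool = True
) -> PopulationSummary:
    """Cohort medians/ranges of timing and mean±SD of enhancement.

    Outliers are flagged by Tukey fences (1.5·IQR) on the peak time; with
    ``exclude_outliers`` they are removed before computing the statistics
    (the flagging itself always happens on the full cohort).
    """
    if len(summaries) == 0:
        raise ValueError("empty population")
    t_peak = np.array([s.t_peak for s in summaries], float)
    flagged = _tukey_outliers(t_peak)
    keep = ~flagged if exclude_outliers else np.ones(len(summaries), bool)
    if not keep.any():  # pathological: everything flagged
        keep = np.ones(len(summaries), bool)
    tp = t_peak[keep]
    tpl = np.array([s.t_plateau for s in summaries], float)[keep]
    hp = np.array([s.hu_peak for s in summaries], float)[keep]
    hpl = np.array([s.hu_plateau for s in summaries], float)[keep]
    n = int(keep.sum())
    sd = (lambda v: float(np.std(v, ddof=1))) if n > 1 else (lambda v: None)
    return PopulationSummary(
        n=n,
        n_outliers=int(flagged.sum()),
        t_peak_median=float(np.median(tp)),
        t_peak_range=(float(tp.min()), float(tp.max())),
        t_plateau_median=float(np.median(tpl)),
        t_plateau_range=(float(tpl.min()), float(tpl.max())),
        hu_peak_mean=float(hp.mean()),
        hu_peak_sd=sd(hp),
        hu_plateau_mean=float(hpl.mean()),
        hu_plateau_sd=sd(hpl),
        outliers_excluded=bool(exclude_outliers),
    )


def flag_outliers(summaries: Sequence[KineticsSummary]) -> list[KineticsSummary]:
    """Return copies with the ``outlier`` field set by Tukey fences on t_peak."""
    t_peak = np.array([s.t_peak for s in summaries], float)
    flagged = _tukey_outliers(t_peak)
    return [
        KineticsSummary(s.t_peak, s.hu_peak, s.t_plateau, s.hu_plateau, bool(f))
        for s, f in zip(summaries, flagged)
    ]


def refine_t_phase(
    summaries: Sequence[KineticsSummary] | None, phase: str
) -> float:
    """Population-refined contrast-phase time.

    Arterial: outlier-excluded median peak time.  Portal: outlier-excluded
    median plateau time.  Without data, the radiologist defaults (50 s / 70 s)
    apply.
    """
    if phase not in ("arterial", "portal"):
        raise ValueError(f"phase must be 'arterial' or 'portal', got {phase!r}")
    if not summaries:
        return ARTERIAL_T_PHASE_S if phase == "arterial" else PORTAL_T_PHASE_S
    pop = summarize_population(summaries, exclude_outliers=True)
    return pop.t_peak_median if phase == "arterial" else pop.t_plateau_median
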