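"""Region-of-interest placement and the five image-quality metrics.

One ROI is placed per (step, half) — 18 per radiograph for the nine-step
wedge.  From each ROI the mean gray value (MGV) and the sample standard
deviation are extracted, and five half-plate metrics are computed:

brightness
    mean of the nine step MGVs;
contrast
    mean absolute MGV difference over the eight adjacent step pairs;
CNR
    per adjacent pair, ``(MGVb - MGVa) / ((SDa + SDb) / 2)``; the
    half-plate value is the mean of the absolute pair CNRs;
SNR
    mean over steps of ``MGV / SD``;
saturation
    number of steps with MGV >= 254 (bright) and MGV <= 1 (dark).

Saturation thresholds apply to the un-rounded ROI *means*, i.e. the
study counts saturated steps, not saturated pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, UndefinedMetricError
from .geometry import HALVES, PhantomGeometry, Rect
from .simulate import Radiograph

__all__ = [
    "ROI",
    "RoiStats",
    "HalfPlateMetrics",
    "METRIC_NAMES",
    "place_rois",
    "roi_stats",
    "brightness",
    "contrast",
    "cnr_adjacent",
    "cnr",
    "snr",
    "saturation_counts",
    "measure_half",
    "measure_radiograph",
]

N_STEPS = 9
BRIGHT_SAT_MGV = 254.0
DARK_SAT_MGV = 1.0
METRIC_NAMES = ("brightness", "contrast", "cnr", "snr",
                "n_bright_sat", "n_dark_sat")


@dataclass(frozen=True)
class ROI:
    """One rectangular region of interest inside a step/half cell."""

    rect: Rect
    step_index: int  # 1-based, in thickness order
    half: str

    def __post_init__(self) -> None:
        if self.half not in HALVES:
            raise GeometryError(f"unknown half {self.half!r}")


@dataclass(frozen=True)
class RoiStats:
    """Pixel statistics of one ROI (ImageJ-style sample SD, n-1)."""

    mgv: float
    sd: float
    n_px: int


@dataclass(frozen=True)
class HalfPlateMetrics:
    """The five image-quality metrics of one lateral half.

    ``cnr``/``snr`` are NaN when their formula is undefined (a zero-SD
    ROI, which only occurs on noise-free renders).
    """

    brightness: float
    contrast: float
    cnr: float
    snr: float
    n_bright_sat: int
    n_dark_sat: int
    per_step: tuple[RoiStats, ...]

    def as_dict(self) -> dict[str, float]:
        return {
            "brightness": self.brightness,
            "contrast": self.contrast,
            "cnr": self.cnr,
            "snr": self.snr,
            "n_bright_sat": float(self.n_bright_sat),
            "n_dark_sat": float(self.n_dark_sat),
        }


def place_rois(geometry: PhantomGeometry, margin_px: int = 4) -> list[ROI]:
    """One centred ROI per (step, half): the step-half intersection
    inset by ``margin_px`` on all sides.  Raises if any ROI is empty."""
    if margin_px < 0:
        raise GeometryError("margin_px must be >= 0")
    rois: list[ROI] = []
    for k, step in enumerate(geometry.step_regions_px, start=1):
        for half in HALVES:
            cell = step.intersect(geometry.half_rect(half))
            roi_rect = cell.inset(margin_px)
            if roi_rect.is_empty:
                raise GeometryError(
                    f"margin {margin_px} px leaves no pixels in step {k}, "
                    f"{half} half"
                )
            rois.append(ROI(rect=roi_rect, step_index=k, half=half))
    return rois


def roi_stats(image: Radiograph | np.ndarray, roi: ROI) -> RoiStats:
    """MGV and sample SD (n-1 denominator) of the ROI pixels."""
    pixels = image.pixels if isinstance(image, Radiograph) else np.asarray(image)
    patch = pixels[roi.rect.as_slices()]
    if patch.size != roi.rect.n_px:
        raise GeometryError("ROI extends outside the image")
    if patch.size < 2:
        raise GeometryError("degenerate ROI: fewer than 2 pixels")
    arr = patch.astype(np.float64)
    return RoiStats(mgv=float(arr.mean()), sd=float(arr.std(ddof=1)),
                    n_px=int(arr.size))


def _require_nine(per_step) -> tuple[RoiStats, ...]:
    per_step = tuple(per_step)
    if len(per_step) != N_STEPS:
        raise ValueError(f"expected {N_STEPS} per-step entries, got {len(per_step)}")
    return per_step


def brightness(per_step) -> float:
    """Mean of the nine step MGVs."""
    per_step = _require_nine(per_step)
    return float(np.mean([s.mgv for s in per_step]))


def contrast(per_step) -> float:
    """Mean absolute MGV difference over the 8 adjacent step pairs.

    Differences are taken unsigned: with monotone step MGVs this equals
    the signed convention, while under saturation or noise it keeps the
    metric sensitive to every step boundary instead of telescoping to
    the two end steps.
    """
    per_step = _require_nine(per_step)
    mgvs = np.array([s.mgv for s in per_step])
    return float(np.mean(np.abs(np.diff(mgvs))))


def cnr_adjacent(a: RoiStats, b: RoiStats) -> float:
    """Contrast-to-noise ratio of one adjacent step pair:
    ``(MGVb - MGVa) / ((SDa + SDb) / 2)``."""
    denom = (a.sd + b.sd) / 2.0
    if denom == 0:
        raise UndefinedMetricError("CNR undefined: both ROI SDs are zero")
    return (b.mgv - a.mgv) / denom


def cnr(per_step) -> float:
    """Half-plate CNR: mean of |pair CNR| over the 8 adjacent pairs."""
    per_step = _require_nine(per_step)
    values = [abs(cnr_adjacent(a, b)) for a, b in zip(per_step, per_step[1:])]
    return float(np.mean(values))


def snr(per_step) -> float:
    """Mean over the nine steps of MGV / SD."""
    per_step = _require_nine(per_step)
    if any(s.sd == 0 for s in per_step):
        raise UndefinedMetricError("SNR undefined: a ROI has zero SD")
    return float(np.mean([s.mgv / s.sd for s in per_step]))


def saturation_counts(per_step) -> tuple[int, int]:
    """(bright, dark) saturated step counts on the un-rounded MGVs:
    bright if MGV >= 254, dark if MGV <= 1."""
    per_step = _require_nine(per_step)
    n_bright = sum(1 for s in per_step if s.mgv >= BRIGHT_SAT_MGV)
    n_dark = sum(1 for s in per_step if s.mgv <= DARK_SAT_MGV)
    return n_bright, n_dark


def measure_half(radiograph: Radiograph, half: str,
                 margin_px: int = 4) -> HalfPlateMetrics:
    """All five metrics on one lateral half of a radiograph.

    CNR/SNR become NaN (rather than raising) when undefined, so that
    noise-free degenerate renders flow through aggregation as missing
    values.
    """
    rois = [r for r in place_rois(radiograph.geometry, margin_px)
            if r.half == half]
    rois.sort(key=lambda r: r.step_index)
    per_step = tuple(roi_stats(radiograph, r) for r in rois)

    try:
        cnr_val = cnr(per_step)
    except UndefinedMetricError:
        cnr_val = math.nan
    try:
        snr_val = snr(per_step)
    except UndefinedMetricError:
        snr_val = math.nan
    n_bright, n_dark = saturation_counts(per_step)
    return HalfPlateMetrics(
        brightness=brightness(per_step),
        contrast=contrast(per_step),
        cnr=cnr_val,
        snr=snr_val,
        n_bright_sat=n_bright,
        n_dark_sat=n_dark,
        per_step=per_step,
    )


def measure_radiograph(radiograph: Radiograph,
                       margin_px: int = 4) -> dict[str, HalfPlateMetrics]:
    """Metrics for both halves, keyed by half label."""
    return {half: measure_half(radiograph, half, margin_px) for half in HALVES}
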