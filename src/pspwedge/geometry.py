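"""Step-wedge phantom geometry on the pixel grid.

The phantom is an aluminium step-wedge with nine steps of strictly
increasing thickness (1 mm increments by default) laid longitudinally
across the plate: each step is a horizontal band of rows spanning the
wedge columns.  Ambient light exposure splits the plate *laterally* into
two column ranges — a covered (non-exposed) half and an exposed half —
so every step crosses both halves and supports one region of interest
per half.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import GeometryError

HALVES = ("non_exposed", "exposed")


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def n_rows(self) -> int:
        return max(0, self.row_stop - self.row_start)

    @property
    def n_cols(self) -> int:
        return max(0, self.col_stop - self.col_start)

    @property
    def n_px(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def is_empty(self) -> bool:
        return self.n_px == 0

    def as_slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop),
                slice(self.col_start, self.col_stop))

    def intersect(self, other: "Rect") -> "Rect":
        return Rect(
            max(self.row_start, other.row_start),
            min(self.row_stop, other.row_stop),
            max(self.col_start, other.col_start),
            min(self.col_stop, other.col_stop),
        )

    def inset(self, margin: int) -> "Rect":
        return Rect(
            self.row_start + margin,
            self.row_stop - margin,
            self.col_start + margin,
            self.col_stop - margin,
        )

    def overlaps(self, other: "Rect") -> bool:
        shared = self.intersect(other)
        return not shared.is_empty

    def inside(self, shape: tuple[int, int]) -> bool:
        rows, cols = shape
        return (0 <= self.row_start <= self.row_stop <= rows
                and 0 <= self.col_start <= self.col_stop <= cols)


@dataclass(frozen=True)
class PhantomGeometry:
    """Pixel layout of the step-wedge phantom on the plate.

    Parameters
    ----------
    image_shape_px
        (rows, cols) of the 8-bit image.
    step_thicknesses_mm
        Aluminium thickness of each step, strictly increasing, in step
        order (step 1 = thinnest).
    step_regions_px
        One pixel rectangle per step, pairwise disjoint, inside the
        image.  Pixels outside every step are treated as bare plate
        (0 mm of aluminium).
    non_exposed_half, exposed_half
        Column ranges [start, stop) of the covered and the
        light-exposed lateral halves.  Together they partition the
        image columns.
    """

    image_shape_px: tuple[int, int]
    step_thicknesses_mm: tuple[float, ...]
    step_regions_px: tuple[Rect, ...]
    non_exposed_half: tuple[int, int]
    exposed_half: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.image_shape_px
        if rows < 1 or cols < 1:
            raise GeometryError(f"degenerate image shape {self.image_shape_px}")
        if len(self.step_thicknesses_mm) != len(self.step_regions_px):
            raise GeometryError("one thickness per step region required")
        th = self.step_thicknesses_mm
        if any(b <= a for a, b in zip(th, th[1:])):
            raise GeometryError("step thicknesses must be strictly increasing")
        if any(t < 0 for t in th):
            raise GeometryError("negative step thickness")
        for i, rect in enumerate(self.step_regions_px):
            if rect.is_empty or not rect.inside(self.image_shape_px):
                raise GeometryError(f"step {i + 1} region empty or outside image")
        for (i, a), (j, b) in combinations(enumerate(self.step_regions_px), 2):
            if a.overlaps(b):
                raise GeometryError(f"step regions {i + 1} and {j + 1} overlap")
        halves = sorted([self.non_exposed_half, self.exposed_half])
        if not (halves[0][0] == 0 and halves[0][1] == halves[1][0]
                and halves[1][1] == cols and halves[0][0] < halves[0][1] < halves[1][1]):
            raise GeometryError("halves must partition the image columns")

    @property
    def n_steps(self) -> int:
        return len(self.step_thicknesses_mm)

    def half_col_range(self, half: str) -> tuple[int, int]:
        if half == "non_exposed":
            return self.non_exposed_half
        if half == "exposed":
            return self.exposed_half
        raise GeometryError(f"unknown half {half!r}")

    def half_rect(self, half: str) -> Rect:
        c0, c1 = self.half_col_range(half)
        return Rect(0, self.image_shape_px[0], c0, c1)

    def thickness_map(self) -> np.ndarray:
        """Per-pixel aluminium thickness (mm); 0 outside the wedge."""
        out = np.zeros(self.image_shape_px, dtype=np.float64)
        for rect, t in zip(self.step_regions_px, self.step_thicknesses_mm):
            out[rect.as_slices()] = t
        return out


def build_geometry(
    rows: int = 300,
    cols: int = 540,
    wedge_row_start: int = 15,
    step_height_px: int = 30,
    wedge_col_start: int = 30,
    wedge_col_stop: int = 510,
    n_steps: int = 9,
    thickness_increment_mm: float = 1.0,
) -> PhantomGeometry:
    """Construct the default plate layout: a centred stack of horizontal
    step bands with the exposed half occupying the right columns."""
    steps = tuple(
        Rect(wedge_row_start + k * step_height_px,
             wedge_row_start + (k + 1) * step_height_px,
             wedge_col_start, wedge_col_stop)
        for k in range(n_steps)
    )
    split = cols // 2
    return PhantomGeometry(
        image_shape_px=(rows, cols),
        step_thicknesses_mm=tuple(thickness_increment_mm * (k + 1) for k in range(n_steps)),
        step_regions_px=steps,
        non_exposed_half=(0, split),
        exposed_half=(split, cols),
    )
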