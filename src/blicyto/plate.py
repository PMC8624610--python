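"""12x8 ROI-grid quantification of plate image stacks.

A fixed grid of 96 square regions of interest, one per well, is placed over
the plate image from declared geometry (no registration from image content)
and the same grid is applied to every frame of the stack. The total signal
(photons/s) per ROI per frame is collected into a tidy well x time table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ImageStack, PlateGeometry, validate_layout, well_name

__all__ = ["ROIGrid", "build_grid", "quantify_stack"]

N_ROWS, N_COLS = 8, 12

#: default ROI side as a fraction of the well pitch, keeping squares disjoint
ROI_SIDE_FRACTION = 0.93


@dataclass(frozen=True)
class ROIGrid:
    """96 square, pairwise-disjoint ROIs with half-open 0-based pixel bounds.

    ``bounds[i] = (row_start, row_end, col_start, col_end)`` for well
    ``well_ids[i]``; A1 is top-left, H12 bottom-right (configurable flips at
    build time since the imaging orientation is a convention).
    """

    bounds: np.ndarray  # (96, 4) int
    well_ids: tuple[str, ...]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.well_ids) != N_ROWS * N_COLS or self.bounds.shape != (96, 4):
            raise ValueError("ROIGrid must contain exactly 96 ROIs")

    @property
    def side(self) -> int:
        r0, r1, c0, c1 = self.bounds[0]
        return int(r1 - r0)

    def area(self) -> int:
        return self.side * self.side


def build_grid(
    image_shape: tuple[int, int],
    geometry: PlateGeometry,
    side: int | None = None,
    flip_rows: bool = False,
    flip_cols: bool = False,
) -> ROIGrid:
    """Place the 12x8 grid of square ROIs over a plate image.

    Each ROI is a square of ``side`` pixels (default floor(0.93 * pitch),
    which keeps neighbours disjoint) centered on its well's grid position.
    The grid is deterministic and is meant to be computed once per stack and
    reused for every frame. Raises ValueError naming the first offending
    well if any ROI falls outside the image.
    """
    if side is None:
        side = int(math.floor(ROI_SIDE_FRACTION * geometry.pitch))
    if side < 1:
        raise ValueError(f"ROI side must be >= 1 pixel, got {side}")
    if side > geometry.pitch:
        raise ValueError(
            f"ROI side {side} exceeds the well pitch {geometry.pitch}; squares overlap"
        )
    h, w = image_shape
    bounds = np.empty((N_ROWS * N_COLS, 4), dtype=int)
    well_ids = []
    offenders = []
    half = side // 2
    for i in range(N_ROWS):
        for j in range(N_COLS):
            gi = N_ROWS - 1 - i if flip_rows else i
            gj = N_COLS - 1 - j if flip_cols else j
            cy, cx = geometry.center(gi, gj)
            r0 = int(round(cy)) - half
            c0 = int(round(cx)) - half
            r1, c1 = r0 + side, c0 + side
            wid = well_name(i, j)
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                offenders.append(wid)
            bounds[i * N_COLS + j] = (r0, r1, c0, c1)
            well_ids.append(wid)
    if offenders:
        raise ValueError(
            f"ROIs exceed image bounds {image_shape} for wells: "
            + ", ".join(offenders)
        )
    return ROIGrid(bounds, tuple(well_ids), (h, w))


def _roi_sums(frame: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """Total signal per ROI via a summed-area table (one pass per frame)."""
    sat = np.zeros((frame.shape[0] + 1, frame.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(frame, axis=0), axis=1, out=sat[1:, 1:])
    r0, r1, c0, c1 = grid.bounds.T
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def quantify_stack(
    stack: ImageStack,
    grid: ROIGrid,
    background: str = "none",
    layout: pd.DataFrame | None = None,
    constant: float = 0.0,
) -> pd.DataFrame:
    """Extract the total signal per ROI per frame into a tidy table.

    ``total_flux`` is the raw sum of pixel values inside each ROI;
    ``background_corrected_flux`` subtracts a per-pixel background estimate
    times the ROI area. Background strategies:

    * ``"none"`` — no subtraction (corrected equals total);
    * ``"blank-wells"`` — per-frame mean per-pixel flux over the ROIs of
      wells with role ``blank`` in ``layout`` (required);
    * ``"constant"`` — the fixed per-pixel value ``constant``.

    Returns a table with columns well_id, time_min, total_flux,
    background_corrected_flux — one row per (well, frame).
    """
    if grid.image_shape != stack.image_shape:
        raise ValueError(
            f"grid built for image shape {grid.image_shape} but stack frames "
            f"are {stack.image_shape}"
        )
    if background not in ("none", "blank-wells", "constant"):
        raise ValueError(f"unknown background strategy {background!r}")

    blank_idx: np.ndarray | None = None
    if background == "blank-wells":
        if layout is None:
            raise ValueError("background='blank-wells' requires a plate layout")
        lay = validate_layout(layout)
        blanks = set(lay.loc[lay["role"] == "blank", "well_id"])
        blank_idx = np.array([i for i, w in enumerate(grid.well_ids) if w in blanks])
        if blank_idx.size == 0:
            raise ValueError("background='blank-wells' but layout has no blank wells")

    area = grid.area()
    records = []
    for frame, t in zip(stack.frames, stack.times):
        totals = _roi_sums(np.asarray(frame, dtype=np.float64), grid)
        if background == "none":
            per_pixel_bg = 0.0
        elif background == "constant":
            per_pixel_bg = constant
        else:
            per_pixel_bg = float(np.mean(totals[blank_idx])) / area
        corrected = totals - per_pixel_bg * area
        for wid, tot, cor in zip(grid.well_ids, totals, corrected):
            records.append(
                {
                    "well_id": wid,
                    "time_min": float(t),
                    "total_flux": float(tot),
                    "background_corrected_flux": float(cor),
                }
            )
    return pd.DataFrame(records)
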