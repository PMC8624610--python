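"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognized plate-layout roles.
ROLES = ("control", "treated", "blank", "max_release", "spontaneous")

#: Roles whose wells carry luciferase+ cells and are imaged.
IMAGED_ROLES = ("control", "treated")

LAYOUT_COLUMNS = ("well_id", "role", "et_ratio", "n_cells")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate well id, A1 top-left ... H12 bottom-right."""
    return f"{chr(ord('A') + row)}{col + 1}"


def well_index(well_id: str) -> tuple[int, int]:
    """Plate well id -> 0-based (row, col). Inverse of :func:`well_name`."""
    row = ord(well_id[0].upper()) - ord("A")
    col = int(well_id[1:]) - 1
    if not (0 <= row < 8 and 0 <= col < 12):
        raise ValueError(f"well id {well_id!r} outside the 8x12 plate")
    return row, col


@dataclass(frozen=True)
class PlateGeometry:
    """Pixel geometry of the imaged plate: A1 center and inter-well pitch."""

    origin_row: float
    origin_col: float
    pitch: float

    def center(self, row: int, col: int) -> tuple[float, float]:
        return self.origin_row + row * self.pitch, self.origin_col + col * self.pitch


@dataclass
class ImageStack:
    """Ordered plate frames (photons/s/pixel) with acquisition timestamps."""

    frames: np.ndarray  # (n_times, height, width) float32
    times: np.ndarray  # minutes after effector addition
    geometry: PlateGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, row, col) array")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {len(self.times)} timestamps"
            )

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check a plate-layout table and return it with normalized dtypes.

    Required columns: well_id, role, et_ratio, n_cells. Raises ValueError on
    missing columns, unknown roles, duplicate wells, or malformed well ids.
    """
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout missing columns: {missing}")
    out = layout.copy()
    out["well_id"] = out["well_id"].astype(str)
    bad_roles = sorted(set(out["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"layout has unknown roles: {bad_roles}")
    dupes = out["well_id"][out["well_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"layout has duplicate wells: {dupes}")
    for wid in out["well_id"]:
        well_index(wid)  # raises on malformed ids
    out["et_ratio"] = pd.to_numeric(out["et_ratio"]).astype(float)
    out["n_cells"] = pd.to_numeric(out["n_cells"]).astype(float)
    return out
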