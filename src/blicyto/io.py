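"""File-format plumbing: TIFF stacks with JSON sidecars, layout and table CSV.

Image stacks are multi-page 32-bit float TIFFs (one page per acquisition,
pixel units photons/s) with acquisition timestamps and plate geometry in a
JSON sidecar next to the TIFF. Tables are plain CSV; an optional header
comment line carries the run's configuration hash for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import ImageStack, PlateGeometry, validate_layout

__all__ = [
    "write_stack",
    "read_stack",
    "sidecar_path",
    "write_layout",
    "read_layout",
    "write_table",
    "read_table",
]


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stack(stack: ImageStack, tiff_path: str | Path) -> Path:
    """Write frames as a multi-page float32 TIFF plus a JSON sidecar."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, stack.frames, dtype=np.float32)
    meta = {
        "times_min": stack.times.tolist(),
        "geometry": {
            "origin_row": stack.geometry.origin_row,
            "origin_col": stack.geometry.origin_col,
            "pitch": stack.geometry.pitch,
        },
        "pixel_units": "photons/s",
    }
    sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1))
    return tiff_path


def read_stack(tiff_path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    if not tiff_path.exists():
        raise FileNotFoundError(f"image stack not found: {tiff_path}")
    side = sidecar_path(tiff_path)
    if not side.exists():
        raise FileNotFoundError(f"stack sidecar not found: {side}")
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    meta = json.loads(side.read_text())
    geom = meta["geometry"]
    return ImageStack(
        frames,
        np.asarray(meta["times_min"], dtype=float),
        PlateGeometry(geom["origin_row"], geom["origin_col"], geom["pitch"]),
    )


def write_layout(layout: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_layout(layout).to_csv(path, index=False)
    return path


def read_layout(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plate layout not found: {path}")
    return validate_layout(pd.read_csv(path, comment="#"))


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> Path:
    """Write a CSV, optionally prefixed with a ``# config_hash=...`` comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, comment="#")
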