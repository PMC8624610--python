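"""Synthetic data generator for the bioluminescence cytotoxicity pipeline.

Emulates the three readouts of an NK-versus-tumor-cell killing experiment:

* time-lapse photon-emission image stacks of a 96-well plate in which
  luciferase+ target cells are killed by NK effectors at graded E:T ratios;
* a chromium-release cpm table with spontaneous- and maximum-release wells;
* a flow-cytometry event table with CFSE / CD56 / 7-AAD / FSC / SSC channels.

The per-well signal model is the product of a killing curve (first-order
decay toward a resistant floor, rate saturating in the E:T ratio) and a
Bateman per-cell emission curve (luciferin uptake minus substrate decay,
uptake permeabilization-boosted by effector contact). Time zero is effector
addition; per-cell emission starts at zero then, reproducing the transient
rise in the first ~10 minutes before killing dominates.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import IMAGED_ROLES, ImageStack, PlateGeometry, well_index, well_name
from .params import (
    DEFAULT_ET_RATIOS,
    AcquisitionSchedule,
    CRASimParams,
    FlowSimParams,
    KillingModelParams,
    LuminescenceParams,
    RenderParams,
    check,
)

__all__ = [
    "live_cells",
    "per_cell_emission",
    "bateman_peak_time",
    "simulate_well_curve",
    "default_plate_layout",
    "render_stack",
    "simulate_cra_counts",
    "simulate_flow_events",
    "simulate_dilution_series",
]

FLOW_CHANNELS = ("CFSE", "CD56", "7AAD", "FSC", "SSC")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise factors with sd/mean exactly ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def live_cells(t, r: float, p: KillingModelParams) -> np.ndarray | float:
    """Live target cells per well at time ``t`` (min) and E:T ratio ``r``.

    N(t) = n0 * (f_res + (1 - f_res) * exp(-k(r) t)), k(r) = k_max r/(r+r50).
    Deterministic; non-increasing in t and (for t > 0) in r.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if r < 0:
        raise ValueError("E:T ratio must be non-negative")
    k = p.rate(r)
    n = p.n0 * (p.f_res + (1.0 - p.f_res) * np.exp(-k * t_arr))
    return float(n) if np.isscalar(t) else n


def bateman_peak_time(k_up: float, k_deg: float) -> float:
    """Peak time of the Bateman curve: ln(k_up/k_deg)/(k_up - k_deg)."""
    if k_up == k_deg:
        raise ValueError("Bateman peak time undefined for k_up == k_deg")
    return math.log(k_up / k_deg) / (k_up - k_deg)


def per_cell_emission(
    t,
    r: float,
    lp: LuminescenceParams,
    kp: KillingModelParams,
    *,
    limiting_form: bool = False,
) -> np.ndarray | float:
    """Per-cell photon emission (photons/s/cell) at time ``t`` after effector
    addition, for a well at E:T ratio ``r``.

    Bateman form L(t) = amp * k'/(k' - k_deg) * (exp(-k_deg t) - exp(-k' t))
    with permeabilization-boosted uptake k' = k_up (1 + alpha_perm r/(r+r50)).
    L(0) = 0; single interior maximum at ln(k'/k_deg)/(k' - k_deg).

    The singular case k' == k_deg raises unless ``limiting_form`` is set, in
    which case the limit amp * k_deg * t * exp(-k_deg t) is returned.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if r < 0:
        raise ValueError("E:T ratio must be non-negative")
    ku = lp.uptake_rate(r, kp.r50)
    if math.isclose(ku, lp.k_deg, rel_tol=1e-12, abs_tol=0.0):
        if not limiting_form:
            raise ValueError(
                "singular luminescence parameters: boosted uptake rate equals "
                "k_deg; pass limiting_form=True for the degenerate Bateman limit"
            )
        out = lp.amp * lp.k_deg * t_arr * np.exp(-lp.k_deg * t_arr)
    else:
        out = (
            lp.amp
            * ku
            / (ku - lp.k_deg)
            * (np.exp(-lp.k_deg * t_arr) - np.exp(-ku * t_arr))
        )
    return float(out) if np.isscalar(t) else out


def simulate_well_curve(
    r: float,
    schedule: AcquisitionSchedule,
    kp: KillingModelParams,
    lp: LuminescenceParams,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Total well flux S(t) (photons/s) on the acquisition schedule.

    S(t) = N(t) * L(t) * (1 + eps_t) with i.i.d. mean-zero multiplicative
    (log-normal) noise of coefficient of variation ``noise_cv``; noise_cv=0
    gives the exact deterministic product. Seed-reproducible.
    """
    check(schedule)
    times = schedule.times
    signal = live_cells(times, r, kp) * per_cell_emission(times, r, lp, kp)
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv == 0:
        return signal
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return signal * _lognormal_factors(rng, noise_cv, len(times))


def default_plate_layout(
    et_ratios: Sequence[float] = DEFAULT_ET_RATIOS,
    replicates: int = 3,
    n_cells: float = 5e4,
    n_blanks: int = 3,
) -> pd.DataFrame:
    """Imaging-plate layout: control (0:1) and treated conditions down plate
    columns, ``replicates`` wells each, plus blank wells for background.

    Returns a table with columns well_id, role, et_ratio, n_cells.
    """
    conditions = [0.0] + sorted(float(r) for r in et_ratios)
    if len(conditions) * replicates + n_blanks > 96:
        raise ValueError("layout does not fit on a 96-well plate")
    rows = []
    idx = 0
    for r in conditions:
        for _ in range(replicates):
            wid = well_name(idx % 8, idx // 8)
            rows.append(
                {
                    "well_id": wid,
                    "role": "control" if r == 0 else "treated",
                    "et_ratio": r,
                    "n_cells": n_cells,
                }
            )
            idx += 1
    for _ in range(n_blanks):
        rows.append(
            {
                "well_id": well_name(idx % 8, idx // 8),
                "role": "blank",
                "et_ratio": 0.0,
                "n_cells": 0.0,
            }
        )
        idx += 1
    return pd.DataFrame(rows)


def _gaussian_pixel_masses(center: float, lo: int, hi: int, sigma: float) -> np.ndarray:
    """Integral of a unit 1-D Gaussian over each pixel [i, i+1), i in [lo, hi)."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = ndtr((edges - center - 0.5) / sigma)  # pixel i spans centers i +/- 0.5
    return np.diff(cdf)


def render_stack(
    layout: pd.DataFrame,
    schedule: AcquisitionSchedule,
    kp: KillingModelParams,
    lp: LuminescenceParams,
    rp: RenderParams,
    noise_cv: float = 0.0,
) -> ImageStack:
    """Render a time-lapse plate image stack from a layout.

    Each imaged well contributes an isotropic Gaussian spot at its grid
    center whose discrete pixel integral equals the well's total flux (the
    spot is truncated beyond ~8 sigma; the lost mass is < 1e-14). Blank and
    non-imaged wells contribute nothing beyond ``background_flux``. Per-well
    flux noise uses ``noise_cv`` (the kinetic-model noise); pixel-level
    multiplicative noise uses ``rp.noise_cv``. Seeded by ``rp.seed``.
    """
    check(schedule)
    check(rp)
    errors = kp.validate() + lp.validate()
    if errors:
        raise ValueError("; ".join(errors))
    h, w = rp.image_shape
    orow, ocol = rp.origin()
    geometry = PlateGeometry(orow, ocol, rp.well_pitch_px)

    n_t = len(schedule)
    frames = np.full((n_t, h, w), rp.background_flux, dtype=np.float64)

    # independent, order-stable substreams: per-well noise then pixel noise
    root = np.random.SeedSequence(rp.seed)
    well_seeds, pixel_seed = root.spawn(2)

    imaged = layout[layout["role"].isin(IMAGED_ROLES)].reset_index(drop=True)
    halfwidth = int(math.ceil(8 * rp.well_sigma_px))
    for i, rec in imaged.iterrows():
        row, col = well_index(rec["well_id"])
        if not (row < rp.n_rows and col < rp.n_cols):
            raise ValueError(
                f"well {rec['well_id']} outside the {rp.n_rows}x{rp.n_cols} grid"
            )
        cy, cx = geometry.center(row, col)
        rng = np.random.default_rng(well_seeds.spawn(1)[0]) if noise_cv else None
        scale = rec["n_cells"] / kp.n0 if kp.n0 else 0.0
        flux = scale * simulate_well_curve(
            rec["et_ratio"], schedule, kp, lp, noise_cv, rng
        )
        rlo, rhi = max(0, int(cy) - halfwidth), min(h, int(cy) + halfwidth + 1)
        clo, chi = max(0, int(cx) - halfwidth), min(w, int(cx) + halfwidth + 1)
        mrow = _gaussian_pixel_masses(cy, rlo, rhi, rp.well_sigma_px)
        mcol = _gaussian_pixel_masses(cx, clo, chi, rp.well_sigma_px)
        spot = np.outer(mrow, mcol)  # unit mass
        frames[:, rlo:rhi, clo:chi] += flux[:, None, None] * spot[None, :, :]

    if rp.noise_cv > 0:
        rng = np.random.default_rng(pixel_seed)
        frames *= _lognormal_factors(rng, rp.noise_cv, frames.shape)

    return ImageStack(frames.astype(np.float32), schedule.times.copy(), geometry)


def simulate_cra_counts(
    lysed_frac: Mapping[float, float],
    p: CRASimParams,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Chromium-release cpm table for the given per-condition lysed fractions.

    Experimental wells have mean cpm = spont + lysed_frac * (max - spont)
    with spont = spont_frac * max_cpm; spontaneous- and maximum-release
    control wells are included. At ``cpm_cv=0`` the table is noise-free and
    the specific-lysis formula recovers ``100 * lysed_frac`` exactly.

    Returns a table with columns well_id, role, et_ratio, cpm.
    """
    check(p)
    for r, f in lysed_frac.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"lysed fraction for r={r} must be in [0, 1], got {f!r}")
    rng = np.random.default_rng(seed)
    spont = p.spont_frac * p.max_cpm
    rows = []
    idx = 0

    def add_wells(role: str, r: float, mean_cpm: float) -> None:
        nonlocal idx
        noise = _lognormal_factors(rng, p.cpm_cv, p.replicates)
        for k in range(p.replicates):
            rows.append(
                {
                    "well_id": well_name(idx % 8, idx // 8),
                    "role": role,
                    "et_ratio": r,
                    "cpm": mean_cpm * noise[k],
                }
            )
            idx += 1

    for r in sorted(lysed_frac):
        add_wells("treated", r, spont + lysed_frac[r] * (p.max_cpm - spont))
    add_wells("spontaneous", 0.0, spont)
    add_wells("max_release", 0.0, p.max_cpm)
    return pd.DataFrame(rows)


def simulate_flow_events(dead_frac_targets: float, p: FlowSimParams) -> pd.DataFrame:
    """Flow-cytometry event table for one co-culture condition.

    Target events are CFSE-high / CD56-low; their 7-AAD-high (dead) fraction
    is ``baseline_dead_frac + (1 - baseline_dead_frac) * dead_frac_targets``.
    Effector events are CD56-high / CFSE-low / 7-AAD-low. Targets sit higher
    in FSC/SSC than effectors, so the populations are morphologically
    separable. Channels are log10-normal; seeded by ``p.seed``.

    Returns a table with columns event_id, population, CFSE, CD56, 7AAD,
    FSC, SSC (``population`` is simulation ground truth, not a gate).
    """
    check(p)
    if not 0.0 <= dead_frac_targets <= 1.0:
        raise ValueError(
            f"dead_frac_targets must be in [0, 1], got {dead_frac_targets!r}"
        )
    rng = np.random.default_rng(p.seed)
    p_dead = p.baseline_dead_frac + (1.0 - p.baseline_dead_frac) * dead_frac_targets
    n_dead = rng.binomial(p.n_targets, p_dead) if p.n_targets else 0

    blocks = []
    specs = [
        ("target_live", p.n_targets - n_dead, "target", None),
        ("target_dead", n_dead, "target", "target_dead"),
        ("effector", p.n_effectors, "effector", None),
    ]
    for label, n, pop, override in specs:
        if n == 0:
            continue
        data = {"population": np.repeat(label, n)}
        for ch in FLOW_CHANNELS:
            loc = p.channel_means[pop][ch]
            if override is not None and ch in p.channel_means.get(override, {}):
                loc = p.channel_means[override][ch]
            sd = p.channel_cvs[ch]
            data[ch] = 10.0 ** rng.normal(loc, sd, size=n)
        blocks.append(pd.DataFrame(data))
    if not blocks:
        events = pd.DataFrame(
            {"population": pd.Series(dtype=str)}
            | {ch: pd.Series(dtype=float) for ch in FLOW_CHANNELS}
        )
    else:
        events = pd.concat(blocks, ignore_index=True)
        events = events.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
            drop=True
        )
    events.insert(0, "event_id", np.arange(len(events)))
    return events


def simulate_dilution_series(
    cell_counts: Sequence[float] = (2.5e5, 1e5, 5e4, 1e4, 5e3, 1e3, 5e2, 1e2),
    replicates: int = 3,
    flux_per_cell: float = 2.0,
    noise_cv: float = 0.02,
    seed: int | None = 1,
) -> pd.DataFrame:
    """Single-read luciferase dilution series: flux linear in cell number.

    Emulates the plate-setup experiment establishing that total emission is
    proportional to the number of plated luciferase+ cells, with
    multiplicative read noise of coefficient of variation ``noise_cv``.

    Returns a table with columns n_cells, replicate, total_flux.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    counts = np.asarray(cell_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in counts:
        noise = _lognormal_factors(rng, noise_cv, replicates)
        for k in range(replicates):
            rows.append(
                {
                    "n_cells": c,
                    "replicate": k,
                    "total_flux": c * flux_per_cell * noise[k],
                }
            )
    return pd.DataFrame(rows)
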