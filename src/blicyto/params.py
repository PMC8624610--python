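"""Parameter blocks for the synthetic cytotoxicity-assay generator.

Each block is a plain dataclass with a ``validate`` method returning a list
of human-readable violation messages (empty when the block is valid), so a
configuration loader can report every problem at once. Constructors do not
raise; call :func:`check` (or ``validate``) where hard failure is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: E:T ratios used throughout: effector NK cells per luciferase+ target cell.
DEFAULT_ET_RATIOS: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0)


def _positive(name: str, value: float, errors: list[str], strict: bool = True) -> None:
    ok = value > 0 if strict else value >= 0
    if not ok:
        errors.append(f"{name} must be {'> 0' if strict else '>= 0'}, got {value!r}")


@dataclass
class KillingModelParams:
    """First-order killing toward a resistant floor, rate saturating in E:T.

    The per-well live-cell count follows
    ``N(t) = n0 * (f_res + (1 - f_res) * exp(-k(r) * t))`` with a
    Michaelis-type dose dependence ``k(r) = k_max * r / (r + r50)``.

    Attributes
    ----------
    n0 : initial live target cells per well.
    k_max : maximal killing rate at saturating effector dose (1/min).
    r50 : E:T ratio giving half-maximal killing rate.
    f_res : fraction of targets resistant to lysis, in [0, 1).
    """

    n0: float = 5e4
    k_max: float = 0.012
    r50: float = 40.0
    f_res: float = 0.1

    def rate(self, r: float) -> float:
        """Killing rate k(r) in 1/min."""
        return self.k_max * r / (r + self.r50)

    def validate(self) -> list[str]:
        errors: list[str] = []
        _positive("KillingModelParams.n0", self.n0, errors)
        _positive("KillingModelParams.k_max", self.k_max, errors, strict=False)
        _positive("KillingModelParams.r50", self.r50, errors)
        if not 0 <= self.f_res < 1:
            errors.append(
                f"KillingModelParams.f_res must be in [0, 1), got {self.f_res!r}"
            )
        return errors


@dataclass
class LuminescenceParams:
    """Bateman (difference-of-exponentials) per-cell photon emission.

    Luciferin is taken up at rate ``k_up`` and lost (substrate decay) at
    ``k_deg``; per-cell emission is zero at substrate addition, rises to a
    single interior peak and decays. Effector contact permeabilizes the
    target membrane, multiplying the uptake rate by
    ``1 + alpha_perm * r / (r + r50)`` (saturating in the E:T ratio ``r``).

    Attributes
    ----------
    amp : asymptotic per-cell emission scale (photons/s/cell).
    k_up : luciferin uptake rate (1/min); must exceed ``k_deg``.
    k_deg : substrate decay rate (1/min).
    alpha_perm : fractional uptake-rate increase at saturating effector dose.
    """

    amp: float = 2.0
    k_up: float = 0.5
    k_deg: float = 0.01
    alpha_perm: float = 10.0

    def uptake_rate(self, r: float, r50: float) -> float:
        """Permeabilization-boosted uptake rate k'_up at E:T ratio r."""
        return self.k_up * (1.0 + self.alpha_perm * r / (r + r50))

    def validate(self) -> list[str]:
        errors: list[str] = []
        _positive("LuminescenceParams.amp", self.amp, errors)
        if not self.k_up > self.k_deg > 0:
            errors.append(
                "LuminescenceParams requires k_up > k_deg > 0, got "
                f"k_up={self.k_up!r}, k_deg={self.k_deg!r}"
            )
        if self.alpha_perm < 0:
            errors.append(
                f"LuminescenceParams.alpha_perm must be >= 0, got {self.alpha_perm!r}"
            )
        return errors


@dataclass
class AcquisitionSchedule:
    """Ordered acquisition timestamps in minutes after effector addition.

    Default mirrors a live-imaging run: every 2 min for the first hour,
    then every 5 min up to 4 h (67 frames).
    """

    times: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.arange(0, 61, 2), np.arange(65, 241, 5)]
        ).astype(float)
    )

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def validate(self) -> list[str]:
        errors: list[str] = []
        if len(self.times) == 0:
            errors.append("AcquisitionSchedule.times must be non-empty")
            return errors
        if np.any(self.times < 0):
            errors.append("AcquisitionSchedule.times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            errors.append("AcquisitionSchedule.times must be strictly increasing")
        return errors


@dataclass
class RenderParams:
    """Geometry and noise of the rendered plate image stack.

    Wells are drawn as isotropic Gaussian spots (integral = well flux) on a
    12x8 grid of centers with spacing ``well_pitch_px``, starting at
    ``origin_px`` (row, col) for well A1; ``None`` centers the grid.
    """

    image_shape: tuple[int, int] = (256, 384)
    well_pitch_px: float = 30.0
    well_sigma_px: float = 3.0
    background_flux: float = 1.0
    noise_cv: float = 0.0
    origin_px: tuple[float, float] | None = None
    seed: int = 0

    n_rows: int = 8
    n_cols: int = 12

    def origin(self) -> tuple[float, float]:
        if self.origin_px is not None:
            return float(self.origin_px[0]), float(self.origin_px[1])
        h, w = self.image_shape
        span_r = (self.n_rows - 1) * self.well_pitch_px
        span_c = (self.n_cols - 1) * self.well_pitch_px
        return (h - span_r) / 2.0, (w - span_c) / 2.0

    def validate(self) -> list[str]:
        errors: list[str] = []
        if len(self.image_shape) != 2 or any(s <= 0 for s in self.image_shape):
            errors.append(
                f"RenderParams.image_shape must be two positive ints, got {self.image_shape!r}"
            )
            return errors
        _positive("RenderParams.well_pitch_px", self.well_pitch_px, errors)
        _positive("RenderParams.well_sigma_px", self.well_sigma_px, errors)
        if self.background_flux < 0:
            errors.append("RenderParams.background_flux must be >= 0")
        if self.noise_cv < 0:
            errors.append("RenderParams.noise_cv must be >= 0")
        orow, ocol = self.origin()
        h, w = self.image_shape
        if not (
            0 <= orow
            and orow + (self.n_rows - 1) * self.well_pitch_px < h
            and 0 <= ocol
            and ocol + (self.n_cols - 1) * self.well_pitch_px < w
        ):
            errors.append(
                "RenderParams: 12x8 grid of well centers does not fit inside "
                f"image_shape={self.image_shape!r} (origin={(orow, ocol)!r}, "
                f"pitch={self.well_pitch_px!r})"
            )
        return errors


@dataclass
class CRASimParams:
    """Chromium-release assay count simulation.

    Experimental wells release ``spont + lysed_frac * (max - spont)`` counts
    on average, where ``spont = spont_frac * max_cpm``; replicate counts get
    multiplicative noise with coefficient of variation ``cpm_cv``.
    """

    max_cpm: float = 1.0e4
    spont_frac: float = 0.15
    cpm_cv: float = 0.08
    replicates: int = 3

    def validate(self) -> list[str]:
        errors: list[str] = []
        _positive("CRASimParams.max_cpm", self.max_cpm, errors)
        if not 0 <= self.spont_frac < 1:
            errors.append(
                f"CRASimParams.spont_frac must be in [0, 1), got {self.spont_frac!r}"
            )
        if self.cpm_cv < 0:
            errors.append("CRASimParams.cpm_cv must be >= 0")
        if self.replicates < 1:
            errors.append("CRASimParams.replicates must be >= 1")
        return errors


#: log10 channel locations per population; dead targets override 7AAD only.
_DEFAULT_CHANNEL_MEANS: dict[str, dict[str, float]] = {
    "target": {"CFSE": 4.0, "CD56": 1.0, "7AAD": 1.0, "FSC": 4.3, "SSC": 4.0},
    "effector": {"CFSE": 1.0, "CD56": 3.8, "7AAD": 1.0, "FSC": 3.8, "SSC": 3.5},
    "target_dead": {"7AAD": 3.5},
}

_DEFAULT_CHANNEL_CVS: dict[str, float] = {
    "CFSE": 0.15,
    "CD56": 0.15,
    "7AAD": 0.15,
    "FSC": 0.08,
    "SSC": 0.10,
}


@dataclass
class FlowSimParams:
    """Flow-cytometry event-table simulation (CFSE / CD56 / 7-AAD / FSC / SSC).

    Channels are log10-normal per population; CFSE-labelled targets are
    larger (FSC/SSC) than CD56+ effectors, and dead targets shift only their
    7-AAD location. ``baseline_dead_frac`` is the 7-AAD+ target fraction
    without any effectors (dye toxicity background).
    """

    n_targets: int = 50_000
    n_effectors: int = 50_000
    channel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CHANNEL_MEANS.items()}
    )
    channel_cvs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHANNEL_CVS)
    )
    baseline_dead_frac: float = 0.05
    seed: int = 0

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.n_targets < 0 or self.n_effectors < 0:
            errors.append("FlowSimParams event counts must be >= 0")
        if not 0 <= self.baseline_dead_frac < 1:
            errors.append(
                "FlowSimParams.baseline_dead_frac must be in [0, 1), got "
                f"{self.baseline_dead_frac!r}"
            )
        for pop in ("target", "effector"):
            if pop not in self.channel_means:
                errors.append(f"FlowSimParams.channel_means missing population {pop!r}")
        return errors


def check(params) -> None:
    """Raise ValueError listing every invariant violation of a param block."""
    errors = params.validate()
    if errors:
        raise ValueError("; ".join(errors))


def validate_all(blocks: Sequence) -> list[str]:
    """Collect validation messages from several parameter blocks."""
    errors: list[str] = []
    for block in blocks:
        errors.extend(block.validate())
    return errors
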