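"""Time-intensity curve statistics for kinetic cytotoxicity readouts.

From the tidy well x time flux table this module builds per-condition
replicate-averaged curves and extracts the kinetic features of the killing
assay: peak intensity and its time, the intersection time T_int at which a
treated curve falls to the untreated control curve, the 4-h endpoint
signal, percent signal loss versus control, signal-vs-cell-number linearity
and ordered dose-response summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import validate_layout

__all__ = [
    "TimeIntensityCurve",
    "KineticSummary",
    "build_curves",
    "peak",
    "intersection_time",
    "endpoint",
    "fit_linearity",
    "summarize_conditions",
    "dose_response",
]


@dataclass
class TimeIntensityCurve:
    """Replicate-averaged flux curve for one condition (E:T ratio ``r``)."""

    r: float
    times: np.ndarray  # min, strictly increasing
    mean: np.ndarray  # photons/s
    sem: np.ndarray  # standard error of the mean; 0 when n == 1
    n: int  # replicate wells

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.times) == len(self.mean) == len(self.sem)):
            raise ValueError("times, mean and sem must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


@dataclass
class KineticSummary:
    """Per-condition kinetic features of a killing-assay curve."""

    r: float
    peak_intensity: float  # photons/s
    time_to_peak: float  # min
    t_int: float  # min; last acquisition time when censored
    t_int_censored: bool
    endpoint_signal: float  # photons/s at the endpoint sample
    pct_signal_loss: float  # percent vs control at the endpoint


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available samples."""
    if window <= 1:
        return values
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def build_curves(
    table: pd.DataFrame,
    layout: pd.DataFrame,
    smoothing: int = 1,
    flux_column: str = "background_corrected_flux",
) -> dict[float, TimeIntensityCurve]:
    """Average replicate wells of each E:T condition into one curve.

    Only wells with role ``control`` or ``treated`` enter; wells of the same
    ``et_ratio`` are averaged pointwise and the standard error is the sample
    standard deviation over replicates divided by sqrt(n) (0 when n = 1).
    ``smoothing`` > 1 applies a centered moving average of that many samples.

    Raises ValueError when a well's time series is incomplete (listing the
    gaps) or when no analyzable wells exist.
    """
    layout = validate_layout(layout)
    wells = layout[layout["role"].isin(("control", "treated"))]
    if wells.empty:
        raise ValueError("layout contains no control or treated wells")
    if flux_column not in table.columns:
        raise ValueError(f"table lacks flux column {flux_column!r}")

    all_times = np.unique(table["time_min"].to_numpy(dtype=float))
    pivot = table.pivot_table(index="time_min", columns="well_id", values=flux_column)

    curves: dict[float, TimeIntensityCurve] = {}
    for r, grp in wells.groupby("et_ratio"):
        series = []
        for wid in grp["well_id"]:
            if wid not in pivot.columns:
                raise ValueError(f"well {wid} missing from the time-intensity table")
            col = pivot[wid].reindex(all_times)
            gaps = all_times[col.isna().to_numpy()]
            if gaps.size:
                raise ValueError(
                    f"well {wid} has missing time points: {gaps.tolist()}"
                )
            series.append(col.to_numpy(dtype=float))
        data = np.vstack(series)
        n = data.shape[0]
        mean = data.mean(axis=0)
        sem = data.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
        curves[float(r)] = TimeIntensityCurve(
            float(r), all_times, _smooth(mean, smoothing), sem, n
        )
    return curves


def peak(curve: TimeIntensityCurve) -> tuple[float, float]:
    """Peak intensity = maximum reached sampled signal, and its time.

    Ties are broken toward the earliest time; no interpolation between
    samples.
    """
    if len(curve.mean) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.mean))  # argmax returns the first maximum
    return float(curve.mean[i]), float(curve.times[i])


def intersection_time(
    curve: TimeIntensityCurve,
    control: TimeIntensityCurve,
    sustain: int = 2,
    t_min: float | None = None,
) -> tuple[float, bool]:
    """Time at which a treated curve falls to the control curve (T_int).

    The difference D(t) = treated - control is evaluated at the shared
    samples. Starting at ``t_min`` (default: the treated curve's own time to
    peak, so crossings during the permeabilization-driven rise are ignored),
    T_int is the linearly interpolated zero of D between the last sample
    with D >= 0 and the first of ``sustain`` consecutive samples with
    D < 0. If no sustained-negative run exists the value is censored at the
    last acquisition time and the censored flag is returned True.
    """
    if len(curve.times) != len(control.times) or np.any(curve.times != control.times):
        raise ValueError("treated and control curves must share the same schedule")
    if sustain < 1:
        raise ValueError("sustain must be >= 1")
    t = curve.times
    if t_min is None:
        t_min = peak(curve)[1]
    d = curve.mean - control.mean
    start = int(np.searchsorted(t, t_min))
    neg = d < 0
    for i in range(start, len(t)):
        if neg[i] and i + sustain <= len(t) and neg[i : i + sustain].all():
            if i > 0 and d[i - 1] >= 0:
                # linear zero between the bracketing samples
                frac = d[i - 1] / (d[i - 1] - d[i])
                return float(t[i - 1] + frac * (t[i] - t[i - 1])), False
            return float(t[i]), False
    return float(t[-1]), True


def endpoint(
    curve: TimeIntensityCurve,
    control: TimeIntensityCurve,
    t_end: float = 240.0,
) -> tuple[float, float]:
    """Signal at the sample nearest ``t_end`` and percent loss vs control.

    When the schedule contains ``t_end`` the exact sample is used. Percent
    signal loss is 100 * (1 - S_r(t_end) / S_0(t_end)), in (-inf, 100] for
    non-negative signals. Raises when the control signal at the endpoint is
    not positive (the percentage is undefined).
    """
    if len(curve.times) != len(control.times) or np.any(curve.times != control.times):
        raise ValueError("treated and control curves must share the same schedule")
    i = int(np.argmin(np.abs(curve.times - t_end)))
    s = float(curve.mean[i])
    s0 = float(control.mean[i])
    if s0 <= 0:
        raise ValueError(
            f"control signal at t={curve.times[i]} min is {s0}; percent loss undefined"
        )
    return s, 100.0 * (1.0 - s / s0)


def fit_linearity(cells_per_well, total_flux) -> tuple[float, float, float]:
    """OLS fit of total flux on plated cell number; returns
    (slope, intercept, adjusted R^2) with adj R^2 = 1 - (1-R^2)(n-1)/(n-2).
    """
    x = np.asarray(cells_per_well, dtype=float)
    y = np.asarray(total_flux, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.any(x <= 0):
        raise ValueError("cell numbers must be positive")
    if np.ptp(x) == 0:
        raise ValueError("cell numbers have zero variance; slope undefined")
    fit = stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(fit.slope), float(fit.intercept), float(adj)


def summarize_conditions(
    curves: dict[float, TimeIntensityCurve],
    sustain: int = 2,
    t_end: float = 240.0,
) -> list[KineticSummary]:
    """KineticSummary per treated condition, using the r=0 curve as control."""
    if 0.0 not in curves:
        raise ValueError("no control (r=0) curve available")
    control = curves[0.0]
    out = []
    for r in sorted(curves):
        if r == 0.0:
            continue
        c = curves[r]
        pk, tpk = peak(c)
        tint, censored = intersection_time(c, control, sustain=sustain)
        sig, loss = endpoint(c, control, t_end=t_end)
        out.append(KineticSummary(r, pk, tpk, tint, censored, sig, loss))
    return out


def _trend_flag(values: np.ndarray) -> str:
    diffs = np.diff(values)
    if len(diffs) == 0 or np.all(diffs == 0):
        return "tie"
    if np.all(diffs > 0):
        return "strictly_increasing"
    if np.all(diffs < 0):
        return "strictly_decreasing"
    if np.all(diffs >= 0):
        return "non_decreasing"
    if np.all(diffs <= 0):
        return "non_increasing"
    return "mixed"


def dose_response(
    summaries: list[KineticSummary],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Order summaries by E:T ratio and describe the dose-response trends.

    Returns the sorted table (columns r, peak_intensity, time_to_peak,
    t_int, t_int_censored, endpoint_signal, pct_signal_loss) and descriptive
    monotonicity flags for peak, endpoint and T_int. The flags describe the
    data — exceptions at single doses are reported, not asserted away.
    """
    if len(summaries) < 2:
        raise ValueError("need summaries for at least two E:T ratios")
    rs = [s.r for s in summaries]
    if len(set(rs)) != len(rs):
        raise ValueError(f"duplicate E:T ratios: {sorted(rs)}")
    ordered = sorted(summaries, key=lambda s: s.r)
    table = pd.DataFrame(
        {
            "r": [s.r for s in ordered],
            "peak_intensity": [s.peak_intensity for s in ordered],
            "time_to_peak": [s.time_to_peak for s in ordered],
            "t_int": [s.t_int for s in ordered],
            "t_int_censored": [s.t_int_censored for s in ordered],
            "endpoint_signal": [s.endpoint_signal for s in ordered],
            "pct_signal_loss": [s.pct_signal_loss for s in ordered],
        }
    )
    flags = {
        "peak": _trend_flag(table["peak_intensity"].to_numpy()),
        "endpoint": _trend_flag(table["endpoint_signal"].to_numpy()),
        "t_int": _trend_flag(table["t_int"].to_numpy()),
    }
    return table, flags
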