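"""Comparator endpoint readouts: chromium release and flow-cytometry gating.

The chromium-release assay reports percent specific lysis,
``(mean experimental cpm - mean spontaneous cpm) /
(mean maximum cpm - mean spontaneous cpm) * 100``; the flow assay reports
the percentage of dead (membrane-permeable, 7-AAD+) target cells among
CFSE+ events under fixed-threshold gates. A three-way comparison against
the bioluminescence percent signal loss aligns the readouts on a shared
E:T grid with rank-concordance summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CRAWellSet",
    "LysisResult",
    "specific_lysis",
    "lysis_by_condition",
    "GateConfig",
    "FlowGateResult",
    "gate_flow",
    "compare_assays",
]


@dataclass
class CRAWellSet:
    """Replicate cpm readings for one condition of a chromium-release assay."""

    experimental: np.ndarray
    spontaneous: np.ndarray
    maximum: np.ndarray
    r: float = float("nan")  # E:T ratio, informational

    def __post_init__(self) -> None:
        for name in ("experimental", "spontaneous", "maximum"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} cpm list must be non-empty")
            if np.any(arr < 0):
                raise ValueError(f"{name} cpm values must be non-negative")
            setattr(self, name, arr)


@dataclass(frozen=True)
class LysisResult:
    """Percent specific lysis; flagged when below spontaneous background."""

    pct_lysis: float
    below_spontaneous: bool


def specific_lysis(w: CRAWellSet) -> LysisResult:
    """Percent specific lysis from replicate cpm wells.

    Replicates are averaged first, then the ratio is formed (the formula's
    mean cpm). The value is not clamped: experimental release below the
    spontaneous background yields a negative percentage with the
    ``below_spontaneous`` flag set, surfacing background problems rather
    than hiding them. Raises when mean maximum <= mean spontaneous (the
    assay is degenerate: no dynamic range).
    """
    exp = float(np.mean(w.experimental))
    spont = float(np.mean(w.spontaneous))
    mx = float(np.mean(w.maximum))
    if mx <= spont:
        raise ValueError(
            f"degenerate chromium-release assay: mean maximum cpm ({mx}) "
            f"<= mean spontaneous cpm ({spont})"
        )
    pct = (exp - spont) / (mx - spont) * 100.0
    return LysisResult(pct, pct < 0.0)


def lysis_by_condition(cpm_table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`specific_lysis` per E:T ratio of a tidy cpm table.

    Expects columns well_id, role, et_ratio, cpm with roles ``treated``
    (experimental), ``spontaneous`` and ``max_release``. Returns a table
    with columns r, pct_lysis, below_spontaneous sorted by r.
    """
    spont = cpm_table.loc[cpm_table["role"] == "spontaneous", "cpm"].to_numpy()
    mx = cpm_table.loc[cpm_table["role"] == "max_release", "cpm"].to_numpy()
    rows = []
    treated = cpm_table[cpm_table["role"] == "treated"]
    if treated.empty:
        raise ValueError("cpm table has no treated (experimental) wells")
    for r, grp in treated.groupby("et_ratio"):
        res = specific_lysis(
            CRAWellSet(grp["cpm"].to_numpy(), spont, mx, r=float(r))
        )
        rows.append(
            {
                "r": float(r),
                "pct_lysis": res.pct_lysis,
                "below_spontaneous": res.below_spontaneous,
            }
        )
    return pd.DataFrame(rows).sort_values("r", ignore_index=True)


@dataclass(frozen=True)
class GateConfig:
    """Fixed channel thresholds for manual-style gating (linear units).

    Targets are CFSE+, effectors CD56+, dead cells 7-AAD+. Events positive
    for both CFSE and CD56 conflict with the target/effector dichotomy and
    are counted separately for audit. Defaults are calibrated to the
    synthetic generator's channel locations, not to any instrument.
    """

    cfse_threshold: float = 10.0**2.5
    cd56_threshold: float = 10.0**2.5
    aad_threshold: float = 10.0**2.2


@dataclass(frozen=True)
class FlowGateResult:
    """Gated percentages plus raw per-gate counts for auditability."""

    pct_dead_targets: float
    pct_dead_effectors: float
    counts: dict = field(default_factory=dict)


def gate_flow(events: pd.DataFrame, g: GateConfig = GateConfig()) -> FlowGateResult:
    """Threshold-gate a flow event table.

    pct_dead_targets = 100 * #(CFSE+ & 7AAD+) / #(CFSE+); dead effectors
    analogously on CD56+. Raises when no event passes the CFSE+ target gate
    (the target percentage is undefined).
    """
    for ch in ("CFSE", "CD56", "7AAD"):
        if ch not in events.columns:
            raise ValueError(f"event table lacks channel {ch!r}")
    cfse = events["CFSE"].to_numpy(dtype=float) > g.cfse_threshold
    cd56 = events["CD56"].to_numpy(dtype=float) > g.cd56_threshold
    dead = events["7AAD"].to_numpy(dtype=float) > g.aad_threshold

    n_targets = int(cfse.sum())
    if n_targets == 0:
        raise ValueError("no CFSE+ target-gated events; percent dead undefined")
    n_effectors = int(cd56.sum())
    n_dead_targets = int((cfse & dead).sum())
    n_dead_effectors = int((cd56 & dead).sum())
    counts = {
        "total_events": int(len(events)),
        "targets": n_targets,
        "effectors": n_effectors,
        "dead_targets": n_dead_targets,
        "dead_effectors": n_dead_effectors,
        "cfse_cd56_conflicts": int((cfse & cd56).sum()),
        "ungated": int((~cfse & ~cd56).sum()),
    }
    pct_dead_eff = (
        100.0 * n_dead_effectors / n_effectors if n_effectors else float("nan")
    )
    return FlowGateResult(100.0 * n_dead_targets / n_targets, pct_dead_eff, counts)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the mid-rank of their run."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mid-rank, 1-based
        i = j + 1
    return ranks


def _rank_concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman-type agreement: Pearson correlation of mid-ranks."""
    ra, rb = _midranks(a), _midranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return float("nan")
    return float((ra * rb).sum() / denom)


def compare_assays(
    cra: pd.DataFrame,
    flow: pd.DataFrame,
    bli: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Align the three cytotoxicity percentages on their shared E:T grid.

    Inputs are tables with a column ``r`` plus ``pct_lysis`` (chromium),
    ``pct_dead`` (flow) and ``pct_signal_loss`` (bioluminescence). Returns
    one row per shared r with the three percentages, plus pairwise
    rank-concordance summaries (mid-ranked Spearman-type agreement).
    Raises when the readouts share no E:T ratio.
    """
    merged = (
        cra[["r", "pct_lysis"]]
        .merge(flow[["r", "pct_dead"]], on="r", how="inner")
        .merge(bli[["r", "pct_signal_loss"]], on="r", how="inner")
        .sort_values("r", ignore_index=True)
    )
    if merged.empty:
        raise ValueError("no overlapping E:T ratios across the three assays")
    cols = {
        "cra": merged["pct_lysis"].to_numpy(),
        "flow": merged["pct_dead"].to_numpy(),
        "bli": merged["pct_signal_loss"].to_numpy(),
    }
    concordance = {
        "cra_vs_flow": _rank_concordance(cols["cra"], cols["flow"]),
        "cra_vs_bli": _rank_concordance(cols["cra"], cols["bli"]),
        "flow_vs_bli": _rank_concordance(cols["flow"], cols["bli"]),
    }
    return merged, concordance
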