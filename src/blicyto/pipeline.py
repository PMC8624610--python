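"""End-to-end pipeline: simulate -> quantify -> analyze -> endpoints -> compare.

A single YAML-serializable configuration drives every stage. One master
seed deterministically derives independent per-stage substream seeds, so a
run is reproducible end to end while stages stay statistically independent.
Stage outputs are plain CSV (tables), TIFF+JSON (the image stack) and a
JSON run log carrying the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assays, io, kinetics, plate, synth
from .params import (
    DEFAULT_ET_RATIOS,
    AcquisitionSchedule,
    CRASimParams,
    FlowSimParams,
    KillingModelParams,
    LuminescenceParams,
    RenderParams,
)

__all__ = [
    "PipelineConfig",
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "run_pipeline",
    "killed_fraction",
    "StageError",
]

_STAGES = ("render", "cra", "flow", "shuffle")


@dataclass
class AnalysisOptions:
    """Curve-analysis knobs: smoothing window (samples; 1 = off), the
    sustained-crossing rule for T_int, the endpoint time and the background
    strategy used at quantification."""

    smoothing: int = 1
    sustain: int = 2
    t_end: float = 240.0
    background: str = "none"

    def validate(self) -> list[str]:
        errors = []
        if self.smoothing < 1:
            errors.append("AnalysisOptions.smoothing must be >= 1")
        if self.sustain < 1:
            errors.append("AnalysisOptions.sustain must be >= 1")
        if self.background not in ("none", "blank-wells", "constant"):
            errors.append(
                f"AnalysisOptions.background must be none|blank-wells|constant, "
                f"got {self.background!r}"
            )
        return errors


@dataclass
class PipelineConfig:
    """Complete, validatable description of one synthetic assay run."""

    seed: int = 0
    et_ratios: tuple[float, ...] = DEFAULT_ET_RATIOS
    replicates: int = 3
    noise_cv: float = 0.05  # per-well kinetic flux noise
    killing: KillingModelParams = field(default_factory=KillingModelParams)
    luminescence: LuminescenceParams = field(default_factory=LuminescenceParams)
    render: RenderParams = field(default_factory=RenderParams)
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    cra: CRASimParams = field(default_factory=CRASimParams)
    flow: FlowSimParams = field(default_factory=FlowSimParams)
    gates: assays.GateConfig = field(default_factory=assays.GateConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def validate(self) -> list[str]:
        """All invariant violations across every block, reported at once."""
        errors: list[str] = []
        if self.replicates < 1:
            errors.append("PipelineConfig.replicates must be >= 1")
        if self.noise_cv < 0:
            errors.append("PipelineConfig.noise_cv must be >= 0")
        if len(set(self.et_ratios)) != len(self.et_ratios):
            errors.append("PipelineConfig.et_ratios contains duplicates")
        if any(r <= 0 for r in self.et_ratios):
            errors.append("PipelineConfig.et_ratios must be positive (0 is implicit)")
        for block in (
            self.killing,
            self.luminescence,
            self.render,
            self.schedule,
            self.cra,
            self.flow,
            self.analysis,
        ):
            errors.extend(block.validate())
        return errors

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["schedule"] = {"times": list(map(float, self.schedule.times))}
        d["et_ratios"] = list(map(float, self.et_ratios))
        for key in ("image_shape", "origin_px"):
            if d["render"].get(key) is not None:
                d["render"][key] = list(d["render"][key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage substream seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def _from_dict(d: dict[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    simple = {"seed", "replicates", "noise_cv"}
    blocks = {
        "killing": KillingModelParams,
        "luminescence": LuminescenceParams,
        "render": RenderParams,
        "cra": CRASimParams,
        "flow": FlowSimParams,
        "gates": assays.GateConfig,
        "analysis": AnalysisOptions,
    }
    for key, value in d.items():
        if key in simple:
            kwargs[key] = value
        elif key == "et_ratios":
            kwargs[key] = tuple(float(r) for r in value)
        elif key == "schedule":
            kwargs[key] = AcquisitionSchedule(np.asarray(value["times"], dtype=float))
        elif key in blocks:
            value = dict(value)
            if key == "render":
                if value.get("image_shape") is not None:
                    value["image_shape"] = tuple(value["image_shape"])
                if value.get("origin_px") is not None:
                    value["origin_px"] = tuple(value["origin_px"])
            kwargs[key] = blocks[key](**value)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML configuration file (no validation; see validate_config)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Load and validate a YAML config; returns (config, all errors).

    Parse failures yield (None, [message]); invariant violations are
    collected across every block rather than stopping at the first.
    """
    try:
        config = load_config(path)
    except (OSError, ValueError, TypeError, yaml.YAMLError) as exc:
        return None, [str(exc)]
    errors = config.validate()
    return (config if not errors else None), errors


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def killed_fraction(config: PipelineConfig, r: float) -> float:
    """Fraction of targets killed by t_end under the killing model; the
    shared ground truth that makes the three simulated readouts coherent."""
    kp = config.killing
    n_end = synth.live_cells(config.analysis.t_end, r, kp)
    return float((kp.n0 - n_end) / kp.n0)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run every stage and leave a report bundle in ``outdir``.

    Writes: layout.csv, stack.tif (+ .json sidecar), time_intensity.csv,
    kinetic_summary.csv, cra_counts.csv, cra_lysis.csv, flow_gating.csv,
    assay_comparison.csv and run_log.json. Deterministic given the seed
    (``seed`` overrides ``config.seed``). Completed stage outputs remain on
    disk when a later stage fails; failures are re-raised as
    :class:`StageError` naming the stage.

    Returns a dict with the key tables and the dose-response/concordance
    summaries.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = config.stage_seeds()
    result: dict[str, Any] = {"config_hash": chash}

    # --- simulate + render ------------------------------------------------
    stage = "simulate"
    try:
        layout = synth.default_plate_layout(
            config.et_ratios, config.replicates, n_cells=config.killing.n0
        )
        render = dataclasses.replace(config.render, seed=seeds["render"])
        stack = synth.render_stack(
            layout,
            config.schedule,
            config.killing,
            config.luminescence,
            render,
            noise_cv=config.noise_cv,
        )
        io.write_layout(layout, outdir / "layout.csv")
        io.write_stack(stack, outdir / "stack.tif")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- quantify ---------------------------------------------------------
    stage = "quantify"
    try:
        grid = plate.build_grid(stack.image_shape, stack.geometry)
        table = plate.quantify_stack(
            stack, grid, background=config.analysis.background, layout=layout
        )
        io.write_table(table, outdir / "time_intensity.csv", chash)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- kinetic analysis -------------------------------------------------
    stage = "analyze"
    try:
        curves = kinetics.build_curves(table, layout, config.analysis.smoothing)
        summaries = kinetics.summarize_conditions(
            curves, sustain=config.analysis.sustain, t_end=config.analysis.t_end
        )
        summary_df, flags = kinetics.dose_response(summaries)
        io.write_table(summary_df, outdir / "kinetic_summary.csv", chash)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- endpoint assays --------------------------------------------------
    stage = "endpoints"
    try:
        killed = {r: killed_fraction(config, r) for r in config.et_ratios}
        cra_table = synth.simulate_cra_counts(killed, config.cra, seeds["cra"])
        io.write_table(cra_table, outdir / "cra_counts.csv", chash)
        cra_lysis = assays.lysis_by_condition(cra_table)
        io.write_table(cra_lysis, outdir / "cra_lysis.csv", chash)

        flow_rows = []
        flow_state = np.random.SeedSequence(seeds["flow"]).generate_state(
            len(config.et_ratios)
        )
        for r, sub in zip(sorted(config.et_ratios), flow_state):
            fp = dataclasses.replace(config.flow, seed=int(sub % 2**31))
            events = synth.simulate_flow_events(killed[r], fp)
            gated = assays.gate_flow(events, config.gates)
            flow_rows.append(
                {"r": r, "pct_dead": gated.pct_dead_targets, **gated.counts}
            )
        flow_df = pd.DataFrame(flow_rows)
        io.write_table(flow_df, outdir / "flow_gating.csv", chash)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- three-way comparison ---------------------------------------------
    stage = "compare"
    try:
        bli = summary_df.rename(columns={"r": "r"})[["r", "pct_signal_loss"]]
        comparison, concordance = assays.compare_assays(cra_lysis, flow_df, bli)
        io.write_table(comparison, outdir / "assay_comparison.csv", chash)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    log = {
        "config_hash": chash,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "dose_response_flags": flags,
        "rank_concordance": concordance,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))

    result.update(
        {
            "layout": layout,
            "time_intensity": table,
            "kinetic_summary": summary_df,
            "dose_response_flags": flags,
            "cra_lysis": cra_lysis,
            "flow_gating": flow_df,
            "comparison": comparison,
            "rank_concordance": concordance,
        }
    )
    return result
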