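#!/usr/bin/env python
"""Simulate the killing-assay plate: layout plus time-lapse image stack.

5e4 luciferase+ target cells per well, NK effectors at E:T ratios 1.25:1 to
40:1 plus a 0:1 control, three replicate wells each and three blank wells;
photon emission imaged every 2 min for 1 h then every 5 min up to 4 h. The
plate layout goes to results/, the (binary) TIFF stack to scratch/.
"""

import argparse
import dataclasses
from pathlib import Path

from blicyto import io, pipeline, synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = pipeline.default_config(seed=args.seed)
    seeds = config.stage_seeds()
    layout = synth.default_plate_layout(
        config.et_ratios, config.replicates, n_cells=config.killing.n0
    )
    render = dataclasses.replace(config.render, seed=seeds["render"])
    stack = synth.render_stack(
        layout, config.schedule, config.killing, config.luminescence,
        render, noise_cv=config.noise_cv,
    )

    io.write_layout(layout, ROOT / "results" / "layout.csv")
    io.write_stack(stack, ROOT / "scratch" / "analysis" / "stack.tif")
    pipeline.save_config(config, ROOT / "scratch" / "analysis" / "config.yaml")

    n_imaged = (layout["role"] != "blank").sum()
    print(f"plate: {len(layout)} annotated wells ({n_imaged} imaged conditions x replicates)")
    print(f"stack: {stack.frames.shape[0]} frames of {stack.image_shape} px, "
          f"{stack.times[0]:.0f}-{stack.times[-1]:.0f} min")
    print(f"wrote {ROOT / 'results' / 'layout.csv'} and scratch/analysis/stack.tif")


if __name__ == "__main__":
    main()
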