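# blicyto

Kinetic analysis of bioluminescence-based cell-mediated cytotoxicity
assays.

When luciferase-expressing tumor target cells (e.g. HepG2-Red-FLuc) are
co-cultured with NK effector cells and given d-luciferin, photon emission
tracks the number of living, metabolically active targets — so killing can
be followed *live*, frame by frame, instead of with the single-time-point
readouts of the radioactive chromium-release assay (CRA) or
flow-cytometry viability staining. `blicyto` implements the full analysis
chain for such experiments, plus a synthetic-data generator that emulates
them, for bench scientists and image analysts who want a tested, scriptable
alternative to point-and-click ROI tools:

1. **simulate** — time-lapse 96-well plate image stacks (wells as Gaussian
   spots whose pixel integral equals the well flux), chromium-release cpm
   tables, and flow event tables (CFSE/CD56/7-AAD/FSC/SSC), all seeded;
2. **quantify** — a fixed 12×8 grid of square ROIs placed from declared
   geometry, applied identically to every frame, yielding a tidy
   well × time table of total flux (photons/s);
3. **analyze** — per-condition time–intensity curves and their kinetic
   features;
4. **endpoints + compare** — percent specific lysis, gated percent dead
   targets, and a three-way rank-concordance comparison at 4 h.

## The statistics at the core

For each effector-to-target ratio *r*, replicate wells are averaged into a
time–intensity curve S_r(t), and:

* **peak intensity** — the maximum reached sampled signal (ties to the
  earliest time). Higher NK dose permeabilizes targets, speeds luciferin
  uptake, and raises the early peak;
* **T_int (intersection time)** — the time at which S_r(t) falls back to
  the no-NK control curve S_0(t): a sustained-crossing rule (2 consecutive
  sub-control samples, linearly interpolated, searched from the treated
  curve's own peak) that decreases with NK dose;
* **4-h endpoint** — S_r(240 min) and the percent signal loss
  100·(1 − S_r/S_0), the one feature directly comparable with CRA percent
  specific lysis, (x̄_exp − x̄_spont)/(x̄_max − x̄_spont)·100, and with the
  flow-gated percentage of CFSE⁺7-AAD⁺ dead targets;
* **linearity** — adjusted R² of the OLS fit of flux versus plated cell
  number over a dilution series, the assay's calibration check.

The generator's signal model is S(t) = N(t)·L(t)·(1+ε): first-order
killing toward a resistant floor with Michaelis-type dose saturation,
times a Bateman (uptake-minus-decay) per-cell emission curve peaking ~8 min
after substrate addition. See `docs/methods.md` for the model, defaults
and their rationale.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (binary image stacks go under `scratch/`, tables under `results/`):

```
python analysis/01_simulate.py --seed 0
python analysis/02_quantify.py
python analysis/03_kinetics.py
python analysis/04_endpoint_assays.py
python analysis/05_compare.py
```

`03_kinetics.py` prints the per-ratio kinetic summary (seed 0, 5% well
noise, three replicates per condition):

```
    r  peak_intensity  time_to_peak  t_int  t_int_censored  endpoint_signal  pct_signal_loss
 1.25        94142.25           6.0   6.45           False          7754.82            14.06
 2.50        96629.31           8.0  20.36           False          8122.89             9.98
 5.00        94334.51           4.0   5.82           False          7091.97            21.41
10.00        96569.88           4.0   5.74           False          5504.71            39.00
20.00        94309.58           2.0   6.03           False          4030.64            55.33
40.00        97766.59           6.0   6.64           False          2835.41            68.58
dose-response trends: {'peak': 'mixed', 'endpoint': 'mixed', 't_int': 'mixed'}
```

Read: all curves peak within the first 10 minutes (time_to_peak 2–8 min);
the 4-h signal collapses with NK dose (14% loss at 1.25:1 → 69% at 40:1);
at this noise level single-seed orderings show exceptions ("mixed" flags —
the r = 2.5 inversion here), while noise-free runs are strictly monotone in
all three features and medians over 200 seeds keep T_int strictly
decreasing in dose (both are test-enforced properties). `05_compare.py`
then aligns the three assays at 4 h:

```
    r  pct_lysis  pct_dead  pct_signal_loss
 1.25      10.04     12.06            14.06
 2.50      13.57     18.05             9.98
 5.00      23.37     28.52            21.41
10.00      45.25     42.15            39.00
20.00      56.52     58.07            55.33
40.00      68.48     70.08            68.58
rank concordance: {'cra_vs_flow': 1.0, 'cra_vs_bli': 0.943, 'flow_vs_bli': 0.943}
```

The same pipeline is available as a CLI (`blicyto run --out outdir`,
plus `simulate` / `quantify` / `analyze` / `lysis` / `gate` / `compare` /
`validate-config` subcommands) driven by a YAML config
(`config/default.yaml`); real experiments enter as multi-page TIFF stacks
with a JSON sidecar (timestamps + plate geometry) and a plate-layout CSV.

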