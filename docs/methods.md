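# Methods

`blicyto` models, quantifies and analyzes a radioactive-free kinetic
cytotoxicity assay: luciferase-expressing tumor target cells are co-cultured
with NK effector cells at graded effector-to-target (E:T) ratios in a
96-well plate, and killing is read out live as the loss of bioluminescent
photon emission after d-luciferin addition. Because no raw plate images or
count tables for such experiments are publicly deposited, the package ships
a synthetic-data generator that reproduces the statistical and kinetic
structure of the assay; every analysis stage is exercised and validated
against that generator's known ground truth.

## Signal model

The total flux of a well at E:T ratio `r` and time `t` (minutes after
effector addition) is the product of a killing curve and a per-cell
emission curve, with multiplicative noise:

    S(t) = N(t) · L(t) · (1 + ε_t)

**Killing.** Live targets decay first-order toward a resistant floor,

    N(t) = n0 · [f_res + (1 − f_res) · exp(−k(r) · t)],
    k(r) = k_max · r / (r + r50),

a minimal model producing the monotone dose–response that endpoint
cytotoxicity assays report: no killing without effectors (k(0) = 0), a
saturating rate at high effector excess, and a dose-independent resistant
fraction. Defaults: `n0 = 5·10⁴` cells/well, `k_max = 0.012`/min,
`r50 = 40`, `f_res = 0.1`. At 4 h these give killed fractions from ~8%
(1.25:1) to ~69% (40:1), spanning the range typical of primary-NK
dose–response panels.

**Per-cell emission.** Luciferin enters the cell at rate `k'_up` and the
available substrate decays at `k_deg`, giving a Bateman
(difference-of-exponentials) curve

    L(t) = amp · k'_up/(k'_up − k_deg) · (exp(−k_deg·t) − exp(−k'_up·t)),

zero at substrate addition, with a single interior peak at
`t* = ln(k'_up/k_deg)/(k'_up − k_deg)`. Effector contact permeabilizes the
target membrane and accelerates uptake,

    k'_up = k_up · (1 + alpha_perm · r / (r + r50)),

which is the mechanism behind the transient early rise being *higher and
earlier* at higher NK dose, before killing pulls the curve below the
control. Defaults `k_up = 0.5`/min and `k_deg = 0.01`/min put the control
peak at `t* = ln(50)/0.49 ≈ 7.98` min — inside the first 10 minutes, as
live-imaging killing assays show. The degenerate case `k'_up = k_deg` is
rejected unless the limiting form `amp·k_deg·t·exp(−k_deg·t)` is explicitly
requested.

**Permeabilization strength.** `alpha_perm = 10` with `r50 = 40` was chosen
so that the peak of the noise-free product curve, *sampled on the default
acquisition schedule*, is strictly increasing across the six E:T ratios
while the 4-h signal is strictly decreasing and T_int strictly decreasing.
This ordering is a structural property of the assay being emulated, and it
constrains the parameters more than is obvious: the killing loss accrued by
the (early) peak time competes against the permeabilization gain, and for
weak permeabilization (alpha_perm ≲ 3 at these rates) the peak ordering
*inverts* — peaks would decrease with dose. The default is the
smallest round value giving the correct ordering with a sampled-peak margin
(≥ 0.6% between adjacent ratios) comfortably above the 2-min sampling
quantization.

**Noise.** ε_t is i.i.d. mean-zero with coefficient of variation
`noise_cv` (default 0.05), implemented as a mean-one log-normal factor —
luminescence noise scales with signal, and the factor is positive by
construction. Pixel-level multiplicative noise at render time is available
separately (`RenderParams.noise_cv`, default 0).

## Plate rendering and ROI quantification

Wells are drawn as isotropic Gaussian spots on a 12×8 grid (default
256×384 px image, 30 px pitch, σ = 3 px, uniform background). Spots are
rendered *exactly* by separable per-pixel Gaussian integrals (differences
of normal CDFs), so the discrete pixel sum of a spot equals the well's
total flux to machine precision; truncation beyond 8σ loses < 1e−14 of the
mass. This makes the quantification contract testable: summing a square
ROI that covers ≥ 6σ of the spot recovers the ground-truth flux within 1%
(in practice within ~0.01%; the 1% bound absorbs float32 frame storage).

Quantification places one square ROI per well from declared geometry
(origin + pitch; no content-based registration), computed once per stack
and reused for every frame. ROI bounds are 0-based, half-open, which makes
area arithmetic and the pairwise-disjointness check exact. The ROI side
defaults to `floor(0.93 · pitch)` so neighbouring squares never touch;
orientation flips are available because plate-on-image orientation is a
convention. Background strategies: `none` (default — subtraction is an
analysis choice, not assumed), `blank-wells` (per-frame mean per-pixel flux
over blank-well ROIs) and `constant`. ROI sums use a per-frame summed-area
table, so a 67-frame default stack quantifies in well under a second.

## Kinetic features

Replicate wells of a condition are averaged pointwise; SE = SD/√n (0 for
n = 1). Optional centered moving-average smoothing is off by default.

* **Peak**: maximum of the sampled means, ties to the earliest time, no
  interpolation — the reported peak is a reached, measured value.
* **T_int**: the time at which the treated curve falls to the control
  curve. The difference D(t) = treated − control is scanned from the
  treated curve's own time-to-peak (the early permeabilization-driven
  excursion above control is not killing and must not trigger a crossing),
  for the first run of `sustain` (default 2) consecutive negative samples;
  the crossing is linearly interpolated between the bracketing samples.
  Two consecutive sub-control samples resist single-frame noise; if no
  sustained crossing occurs by the last acquisition the value is censored
  there (no extrapolation) and flagged.
* **Endpoint**: the signal at the sample nearest 240 min (exact when 240
  is on the schedule, as in the default), plus percent signal loss
  `100·(1 − S_r/S_0)` versus the control — the quantity comparable with
  the endpoint assays. A non-positive control signal makes the percentage
  undefined and raises.
* **Linearity**: ordinary least squares of flux on cell number
  (`scipy.stats.linregress`), reporting adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − 2).
* **Dose–response**: summaries sorted by `r` with *descriptive* trend
  flags (strictly_increasing / non_decreasing / tie / mixed …) — real
  noisy runs do show occasional peak-order exceptions, and the flags
  report rather than assert.

## Endpoint comparators

**Chromium release.** Percent specific lysis
`(mean experimental − mean spontaneous)/(mean maximum − mean spontaneous)·100`,
with replicate means taken before the ratio. The value is deliberately not
clamped: experimental release below the spontaneous background yields a
negative percentage plus a flag, surfacing the high-background failure mode
of the assay instead of hiding it. Mean maximum ≤ mean spontaneous is a
degenerate assay and raises. The simulator draws experimental wells at
`spont + f·(max − spont)`, so at zero count noise the measure/simulate
round trip is the identity `f ↦ 100·f` — a tested contract.

**Flow cytometry.** Events are log10-normal per channel and population:
targets CFSE-high/CD56-low, effectors CD56-high/CFSE-low/7-AAD-low, dead
targets shifted only in 7-AAD; targets sit higher in FSC/SSC (bigger
cells). The 7-AAD+ target fraction is
`baseline + (1 − baseline)·dead_frac` with `baseline = 0.05` representing
dye-toxicity background in unchallenged wells. Gating is fixed-threshold
(the manual-gate style of the bench assay), with CFSE+∧CD56+ conflicts
counted and reported; separability is a parameter contract — with ≥ 2.5 dex
between population locations and 0.15 dex spread, misclassification is
negligible against the binomial sampling band the tests use. Thresholds are
generator-calibrated defaults, not instrument values.

**Comparison.** The three 4-h percentages are aligned on the shared E:T
grid; agreement is summarized by mid-ranked Spearman-type concordance
computed from the explicit rank formula (ties mid-ranked, Pearson on
ranks). On noise-free simulations all three readouts are monotone in dose
and pairwise concordance is exactly 1.

## Pipeline, seeding, problem sizes

`run_pipeline` derives independent per-stage substream seeds from one
master seed via `numpy.random.SeedSequence`, so runs are byte-reproducible
end to end while stages remain statistically independent; every output CSV
carries the configuration hash, and a JSON run log records seeds and
parameters. Completed stage outputs stay on disk when a later stage fails.

The default full run — 96 wells, 67 frames of 256×384 px, three endpoint
conditions per ratio — completes in a few seconds on one CPU. The test
suite exercises reduced geometries (144×208 px, 16 px pitch, coarser
schedules) where image size is irrelevant to the property under test, and
the full default geometry where the contract is about the default run
itself (flux recovery, dose–response monotonicity). The stochastic
T_int property uses 200 seeded replications at the default noise level.

## Known limitations

* The killing and emission models are deliberately minimal: no effector
  exhaustion, no target regrowth, no delay between effector addition and
  first contact, no luciferin rebinding kinetics. They reproduce the
  *shape* families of real time–intensity curves, not any specific donor's
  magnitudes; passing tests certify the pipeline's measurement operations,
  not biological parameter values.
* Rendered plates use ideal Gaussian optics — no vignetting, spot overlap
  at default geometry, PSF tails, or camera offset/dark current; the
  quantification tolerance would need revisiting for real IVIS-class
  images with optical crosstalk.
* Flow simulation has no compensation/spillover, doublets, or debris;
  fixed-threshold gating on such data is easier than on real cytometry.
* T_int censoring is reported, not modelled; survival-style analysis of
  censored intersection times is out of scope.
* Real-image ingestion is limited to multi-page TIFF stacks with a JSON
  sidecar (timestamps + geometry); FCS files and proprietary instrument
  formats are out of scope.
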