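# Methods

## Scope and model

mesoplan models the *endpoint* of a controlled in meso phase (CIMP)
crystallization experiment: a protein droplet on a monoolein-precoated
well, mixed with diluted screening solution, equilibrating through the
vapor phase against undiluted screening solution in the reservoir.  Three
linked sub-models are implemented.

### 1. Vapor-diffusion mass balance (`mesoplan.hydration`)

Water leaves the droplet until its precipitant concentration equals the
reservoir's, so the moles of precipitant dispensed fix the final volume:
`V_f = V_s/d` for screen volume `V_s` and dilution factor `d` (an optional
term adds precipitant carried by the protein buffer; by default the
protein solution is assumed precipitant-free, which is how such
experiments are normally described).  The water mass at the endpoint is
`W = φ·V_f`, and the hydration level of the condensed system is
`w = 100·W/(W+M)` wt%.

φ (µg water per nl of equilibrated droplet, default **0.88**) is the one
non-obvious constant.  It is below 1 because the equilibrated droplet is a
concentrated salt solution, and it absorbs the solute mass fraction.  It
is *not* hard-coded knowledge: `calibrate_phi` recovers it from published
(dilution factor, expected hydration) pairs by minimax fit — with the four
pairs of the standard 132 µg / 450 + 450 nl experiment (75 % at d = 1,
60 % at 2, 43 % at 4, 30 % at 7) the fit returns φ = 0.883 with every
residual below 0.1 percentage point, and φ = 0.88 reproduces all four
printed levels exactly after integer rounding (unrounded: 75.0, 60.0,
42.86, 30.0).  The minimax criterion is used because the inputs are
integer-rounded captions: it bounds the worst caption's disagreement
instead of letting one rounded value bias a least-squares mean.  With a
single observation the closed form `φ = w·M·d/((100−w)·V_s)` is used.

Initial (pre-equilibration) hydration counts the full dispensed volume as
water at density 1.0 µg/nl, giving 87 % for 900 nl on 132 µg.  Reported
hydration levels round half-up to integer percent.

Units everywhere: volumes nl, masses µg, water density 1 µg/nl,
precipitant concentrations mol/l.

### 2. Mesophase classification (`mesoplan.phasemap`)

A `PhaseMap` partitions hydration [0, 100] wt% into mesophase labels at
22 °C.  Defaults: Lc below 4 %, Lα 4–30 %, Ia3d 30–37 %, Pn3m 37–45 %,
Pn3m + excess water above 45 %.  These bounds are read off the published
monoolein/water isotherm and placed so that the hydration levels of the
standard dilution series classify as practitioners describe them: 60–75 %
excess-water, 43 % cubic, 30 % on the cubic/lamellar boundary.  Hydration
values within 1.5 points of an internal boundary carry a boundary tag
(e.g. `cubic/lamellar`), because conditions printed with slash names are
exactly such boundary conditions.  The cubic-phase upper bound sits at
45 % rather than 44 % so that the 43 % cubic condition is a plain Pn3m
call at the default tolerance.  All bounds and the tolerance are config
values, not constants: any real screen (salt, detergent, protein, added
lipids) shifts the true diagram, so the map defines starting points, not
ground truth.

The inverse model `d = φ·V_s·(100−w)/(w·M)` recommends dilutions; phase
requests are targeted at the interval midpoint (boundary requests at the
boundary itself), optionally snapped to the practical pipetting grid
{1, 2, 4, 7}.  Targets above the undiluted maximum (75 % for the standard
format) raise a target-unreachable error carrying the reachable range.

### 3. Nernst partitioning (`mesoplan.partition`)

The protein is assumed monomeric in both phases with constant
`K = C_lip/C_aq`.  Molality basis: `C_lip` per mass of monoolein, `C_aq`
per mass of **total** water — supernatant plus the water inside the
mesophase channels, which exchange freely on the experiment's timescale.
This yields `f = K·M/(K·M + W)`.  The basis is a genuine modelling choice
(per-hydrated-lipid-mass is defensible too) and is isolated in
`fraction_incorporated` so an alternative convention can be swapped
without touching callers.  Because of that convention-dependence, the
qualitative thresholds ("K above ~5 incorporates >90 % below 40 wt%
water; K below ~0.2 incorporates <30 %") are asserted in the tests at the
representative values K = 25 and K = 0.1, where the margin is much larger
than any basis effect; at K = 5 exactly, the convention shift is of the
same order as the 2-point margin.

The depletion assay is modeled as sealed (24 h, no reservoir gradient), so
the aqueous water equals the applied volume.  Estimation:
`f̂ = 1 − C_sup/C_0`, `K̂ = f̂·W/((1−f̂)·M)` per replicate, median
summary, percentile bootstrap CI over replicates.  Degenerate readings are
signalled, not hidden: `C_sup = 0` → K̂ = +inf with an "unbounded" flag;
`C_sup > C_0` → K̂ clamped to 0 with a flag.

`suggest_assay_volume` returns the applied volume giving ~50 % depletion
(`V ≈ K·M`, clipped to 100–900 nl, the volumes a coated well
accommodates).  Matching the volume to the anticipated K is what makes
small constants measurable: at K = 0.1 a 900 nl assay depletes only 1.4 %,
below a 5 % photometric CV, while a 100 nl assay depletes 12 %.

## Synthetic data (`mesoplan.synthetic`)

The generator runs the same forward models with known truth:

- **Partition assays**: `C_sup = (1−f)·C_0 · ε` with ε multiplicative
  lognormal, mean 1, CV configurable (default **5 %**, a typical
  photometric error; mean-one so an undepleted assay reads `C_0` on
  average).  Defaults mirror the standard bench assay: 16 µg/µl sample,
  900 nl applied, 132 µg monoolein, 8 replicates.
- **Calibration observations**: forward hydration pairs, optionally
  integer-rounded the way figure captions print them.
- **Demo bundle**: a full 8×12 phosphate grid plate (pH 4.5–8.5,
  0.5–4.0 M), an additive plate (10 % v/v sodium malonate into ammonium
  sulfate across the dilution grid), and a K = 50 assay.

Seeds are explicit arguments; no global random state.  What the generator
does **not** emulate: kinetics (equilibration takes days–weeks; only the
endpoint exists here), detergent effects on the phase diagram, protein
aggregation, plate-to-plate coating variation, or correlated photometric
drift.  Passing recovery tests therefore demonstrate the estimator is
correct *under the stated noise model*, not that a bench assay with
systematic errors will recover K equally well.

Parameter-recovery conditions used in the tests: K over
{0.1, 1, 5, 25, 50, 125}, CV 5 %, n = 8 replicates, 200 seeds,
depletion-matched assay volumes; the median estimate recovers each K
within 10 %.  These sizes run in seconds and were chosen as the smallest
grid that covers both threshold regimes and both volume-clipping ends.

## Screens, plates, worklists (`mesoplan.screens`)

Plate formats mirror the commercial monoolein-precoated consumables:

| format  | MO/well | droplet        | reservoir |
|---------|---------|----------------|-----------|
| MO132   | 132 µg  | 450 + 450 nl   | 75 µl     |
| MO29    | 29 µg   | 100 + 100 nl   | 75 µl     |
| FOIL100 | 100 µg  | 300 + 300 nl   | 50 µl     |

(The 29 µg reservoir volume is not separately documented for the scaled
format; 75 µl is the default and configurable.)  Wells are SBS A1–H12,
row-major, 1-based.  Grid screens include both axis endpoints; additive
mixing replaces a v/v fraction (default 10 %) of the screen with additive
stock, diluting the base accordingly.  The protocol constants (3 h
swelling, 22 °C, weekly inspection) are stored as metadata, not simulated.

The worklist CSV is deliberately lowest-common-denominator: UTF-8,
comma-separated, integer volumes in nl, three dispensing rows per well in
protocol order (protein → [seal, 3 h] → diluted screen → reservoir).
Solution compositions and layout metadata (including φ) ride along in
extra columns and `#` header lines, making the file self-contained:
import reconstructs the layout and recomputes predictions, so
export → import → export is byte-identical.  A custom phase map is not
serialized into the worklist; layouts with non-default maps round-trip
their dispensing content but re-classify phases with the map passed to
`import_worklist` (the layout JSON, in contrast, carries everything).

## Pipeline and CLI

`run_pipeline(RunConfig)` chains screen construction → plate planning →
per-well hydration/phase prediction → optional K estimation from a
measured assay CSV, and emits a JSON report.  Reports are deterministic
for a given config and seed; a timestamp is only added on request so
reports diff cleanly.  Stage failures surface as `PipelineError` naming
the stage and, for planning, the offending well.  The `mesoplan` CLI is a
thin wrapper (results to stdout as JSON, logs to stderr).

## Numerical choices and edge cases

- Rounding of reported hydration: half-up to integer percent.
- `calibrate_phi` minimax is solved by bounded scalar minimization on
  (0.5, 1.1) with `xatol = 1e-7`; the objective is quasiconvex in φ
  (each residual is monotone in φ), so the bounded method converges; a
  brute-force grid cross-checks it in the tests.
- Degenerate calibration (all observations at one dilution factor) raises
  an under-determined error rather than returning a fit.
- `fraction_incorporated` defines f = 0 for K = 0 with W = 0 (no water and
  no partitioning) to avoid 0/0.
- Dilution snapping picks the nearest grid value; ties resolve to the
  smaller dilution via `min`'s first-wins rule.
- Bootstrap uses `numpy.random.default_rng(seed)`; identical seeds give
  identical intervals.

## Known limitations

- Endpoint-only: no equilibration kinetics, no oil-layer diffusion
  barriers, no swelling-time dependence beyond the stored 3 h constant.
- Single-lipid (monoolein), single-temperature (22 °C) phase map.
- The partitioning molality basis is a stated convention; apparent-K
  values from other bases differ by a bounded factor and should not be
  compared across conventions.
- Protein-solution solutes other than the optional buffer-precipitant term
  are ignored in the mass balance.
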