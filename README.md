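# mesoplan

Planning calculus for **controlled in meso phase (CIMP) crystallization** of
membrane proteins: vapor-diffusion crystallization performed directly on
monoolein-precoated 96-well plates, where the protein passively partitions
into the lipidic mesophase and the screen dilution factor steers the
endpoint hydration — and hence the mesophase — of each well.

It is written for structural biologists and beamline/automation engineers
who set up lipidic cubic phase (LCP) screens: it predicts what each well
will do before any protein is spent, and emits robot-ready worklists.

## The model

A droplet of `V_p` nl protein solution plus `V_s` nl screening solution,
diluted by a factor `d` relative to the reservoir, equilibrates through the
vapor phase until its precipitant concentration matches the reservoir.
Precipitant conservation fixes the endpoint droplet volume and water mass:

```
V_f = V_s / d              W = φ · V_f          (φ ≈ 0.88 µg water / nl)
w   = 100 · W / (W + M)    [wt% water of the water + monoolein system]
```

The hydration level `w` selects the monoolein mesophase on the 22 °C
isotherm (Lc → Lα → Ia3d → Pn3m → Pn3m + excess water), so choosing `d`
targets a phase; the closed-form inverse is
`d = φ·V_s·(100−w) / (w·M)`.  The single constant φ is recoverable from
published expected hydration levels with `calibrate_phi`.

The protein distributes between mesophase and aqueous pool by the Nernst
partition law with constant `K = C_lip/C_aq` (molalities per mass of
monoolein and of total water):

```
f = K·M / (K·M + W)        fraction of protein in the lipidic phase
C_aq/C_0 = (1 − f) · V_p / V_f     ≤ the ideal-dilution (K = 0) value
```

The apparent K of a real protein comes from a sealed 24-h depletion assay:
`f̂ = 1 − C_sup/C_0`, `K̂ = f̂·W / ((1−f̂)·M)` with W the applied volume at
1 µg/nl, summarized as the median over replicates with a bootstrap CI.

## Worked example

```python
import mesoplan as mp

cal = mp.calibrate_phi([(1, 75), (2, 60), (4, 43), (7, 30)], 450, 132).params
print(round(cal.phi, 3))                      # 0.883

for d in (1, 2, 4, 7):
    spec = mp.DropletSpec(protein_volume=450, screen_volume=450, dilution_factor=d)
    r = mp.expected_final_hydration(spec, cal, 132)
    call = mp.classify_phase(r.hydration_pct)
    print(d, r.rounded_hydration_pct, call.label, call.boundary)
# 1 75 Pn3m_excess_water None
# 2 60 Pn3m_excess_water None
# 4 43 Pn3m None
# 7 30 Ia3d cubic/lamellar
```

Undiluted and 1:2 screens leave the mesophase in excess water, a 1:4
dilution lands in the cubic phase (Pn3m) and 1:7 on the cubic/lamellar
boundary — the three regimes a dilution trio screens in one pass.  The same
calculus runs from the shell:

```
$ mesoplan hydration --dilution 4            # JSON EquilibriumResult
$ mesoplan phase --hydration 30              # {"label": "L_alpha", "boundary": "cubic/lamellar", ...}
$ mesoplan simulate --k-true 50 --seed 1 --out assay.csv
$ mesoplan estimate-k assay.csv              # {"k": 48.96, "bootstrap_95ci": [47.8, 51.6], ...}
$ mesoplan plan run.yaml --out-dir out/      # layout.json + worklist.csv + report.json
```

A full campaign config (protein, plate format, grid screen, dilution
scheme) is a small JSON/YAML file validated against the schema printed by
`mesoplan config-schema`; see `tests/test_pipeline_cli.py` for examples.

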