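# lumenflow

Coupled bio-hemodynamics toolkit for stenotic arteries: pulsatile
incompressible flow in lumen geometries represented by an immersed boundary,
wall-shear-stress (WSS) extraction, leukocyte concentration transport with a
shear-thresholded adhesion sink, and the correlation analysis that links a
predicted adhesion profile to baseline → follow-up lumen-area change.
Because clinical pullback imagery is not publicly available, a synthetic
study generator emulates contour-frame series (0.5 mm spacing) with a
localized stenosis, a tortuous centerline, and controlled follow-up change,
so every stage is testable end to end.

## Layout

| module | contents |
| --- | --- |
| `lumenflow.geometry` | contour frames, centerlines, idealized stenoses, frame stacking (rotation-minimizing frames), straightening, inlet/outlet extensions, signed-distance queries |
| `lumenflow.hemodynamics` | staggered-grid fractional-step Navier–Stokes with direct-forcing immersed boundaries, pulsatile parabolic inlet, convective outlet, exact FFT/DCT pressure solve; 2D planar and 3D modes plus an axially periodic driven mode |
| `lumenflow.wall_shear` | wall probes (one-sided second-order normal gradient), time averages `<WSS>`, azimuthal averages `WSSbar` (r dθ / perimeter weighting, arclength variant) |
| `lumenflow.leukocyte` | thresholded rate law k(WSS), positivity-preserving donor-cell scalar transport, tracked vs uniform-concentration adhesion ledgers binned by (s, θ) |
| `lumenflow.clinical_analysis` | lumen-area series, ΔA construction, population-normalized Pearson correlation, summary statistics |
| `lumenflow.synthetic_study` | seeded baseline/follow-up generators |
| `lumenflow.cli_io` | CSV/VTK/JSON/HDF5 I/O, config validation, CLI |

Units: geometry I/O is in millimetres; physics is SI internally.

## CLI

```sh
lumenflow synth --config run.yaml --out-dir study/         # synthetic study
lumenflow simulate --config run.yaml [--dry-run]           # full pipeline
lumenflow analyze --baseline b.csv --followup f.csv --adhesion a.csv
lumenflow compare-centerlines --config run.yaml            # tortuous vs straight
lumenflow compare-followup --config run.yaml --followup-contours f.csv
lumenflow validate                                         # built-in oracles
```

A minimal config:

```yaml
geometry:
  kind: synthetic          # ideal | synthetic | files
  synthetic: {n_frames: 30, stenosis_severity: 0.5, tortuosity_amplitude: 0.6}
fluid: {rho: 1060.0, mu: 0.0035}
waveform: {kind: triphasic, u_mean: 0.384, period: 0.8}
grid: {cells_per_diameter: 16}
solver: {cycles: 3, transient: 1}
species:
  - {name: neutrophil}     # rho_ref 4.34e9/l, threshold 1.2 Pa
seed: 0
```

Every command supports `--dry-run` (config validation + grid-size estimate).
All randomness flows from the single `seed`; identical configs give
identical outputs.

## Notes on defaults

- Fluid defaults are standard Newtonian blood surrogates (ρ = 1060 kg/m³,
  μ = 3.5 mPa·s); the triphasic waveform shape is this package's own,
  rescaled to the configured mean bulk velocity (default 0.384 m/s,
  period 0.8 s).
- Only the neutrophil parameters (reference 4.34×10⁹/l, threshold 1.2 Pa)
  are clinically anchored; monocyte/lymphocyte defaults are provisional
  placeholders and should be configured per run.
- The adhesion rate law is pluggable (`linear` ramp to zero at the
  threshold by default, `step` available); register new laws in
  `lumenflow.leukocyte`.
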