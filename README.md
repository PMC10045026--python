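# hemodyn

A tested, reusable Python pipeline for image-based cardiovascular
hemodynamics at desk scale: CT-slice lumen segmentation into 3D point
clouds, pulsatile inlet/outlet boundary-condition models, wall-shear and
vortex indices, and the scalar verification statistics that accompany a
patient-specific CFD study. Every stage is exercised on synthetic
phantoms and analytic pulsatile flow fields with closed-form oracles —
no external data or 3D flow solver is required.

## Modules

| Module | What it does |
| --- | --- |
| `hemodyn.synthetic` | CT-like lumen phantoms with exact ground truth; Poiseuille / Womersley / rigid-rotation / pure-shear analytic fields with closed-form wall shear and velocity-gradient references; physiologic inlet waveforms (period 0.96 s, peak ~0.5 m/s, mean flow ~6 L/min, diastolic backflow); outlet flow series |
| `hemodyn.segmentation` | histogram equalization, adaptive-threshold smoothing, binarization (Otsu default), Moore-neighbor boundary tracing with Jacob's stopping criterion, contour-to-point-cloud assembly |
| `hemodyn.boundary` | least-squares harmonic waveform fitting and evaluation, 3-element Windkessel (explicit Euler) integration and parameter estimation, k–ε turbulence initialization, Reynolds number |
| `hemodyn.wall` | wall shear stress (one-sided no-slip difference), wall shear force, TAWSS, OSI, y+ |
| `hemodyn.vortex` | velocity-gradient tensors on structured lattices, Q-criterion and vortex-region counting, turbulence intensity, axial backflow diagnostics |
| `hemodyn.metrics` | cycle-to-cycle convergence error, mesh-sensitivity metric for wall shear force, per-outlet volume-flow shares and relative perfusion changes, cycle-averaged pressure drops (mmHg) |
| `hemodyn.vtkio` | minimal legacy-ASCII VTK point-set I/O, PLY/XYZ cloud writers |

A per-geometry outlet-share reference table ships with the package
(`hemodyn/data/flow_shares.csv`).

## CLI

```bash
# generate a phantom stack and segment it
hemodyn phantom --out stack/ --size 128 --slices 4 --noise-sd 5
hemodyn segment --stack stack/ --roi 32,96,16,112 --threshold otsu --out cloud.ply

# fit an 8-mode harmonic series to a sampled inlet waveform
hemodyn waveform fit --csv wave.csv --modes 8 --out series.json

# Windkessel: estimate constants for a 90 mmHg mean, then simulate
hemodyn wk3 estimate --pressure-mmhg 90 --flow q.csv --out wk.json
hemodyn wk3 simulate --params wk.json --flow q.csv --cycles 4 --out p.csv

# wall indices from a snapshot series + wall patch
hemodyn indices --fields 'fields_*.vtk' --wall wall.json --period 0.96 --out indices.vtk

# reporting statistics
hemodyn report flow --dist shares.csv --geometry FPA
hemodyn report convergence --pressure pi.csv --period 0.96
hemodyn report meshsens --ref wsf_fine.csv --other wsf_coarse.csv
```

## Conventions

- Coordinates: row-major pixels, 0-based; x = col × pixel spacing,
  y = row × pixel spacing, z = slice × slice thickness (mm).
- Fluid defaults: ρ = 1060 kg/m³, μ = 3.71×10⁻³ Pa·s.
- Pressure I/O accepts mmHg (1 mmHg = 133.322 Pa); internal unit is Pa.
- Cycle integrals use periodic trapezoidal quadrature on uniform grids.
- All generators take an integer seed (default 0) and are bit-exact
  reproducible.
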