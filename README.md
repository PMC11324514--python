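# prewetbelt

Tight junctions seal epithelial tissues with a continuous belt of the
scaffold protein ZO-1 running around the apical cell perimeter. The belt
does not assemble all at once: ZO-1 condensates nucleate at cell–cell
contacts and then *elongate* along the apical–lateral membrane interface
at constant speed, a behaviour explained by a **prewetting transition** —
the formation of a condensed surface layer below the bulk saturation
concentration, driven by preferential binding to the interface.

`prewetbelt` is a library for scientists studying this process. It
provides three things:

1. **The surface-condensation model.** A dimensionless composition field
   φ(x, y) ∈ (0, 1) on a membrane patch, with regular-solution free
   energy density

   f(φ) = φ ln φ + (1 − φ) ln(1 − φ) + χ φ(1 − φ),

   position-dependent binding affinity ε(x, y) (baseline ε₀ on the
   apical and lateral domains, ε_int on the interface stripe, ε_nuc
   extra inside nucleation discs), and reservoir-exchange dynamics

   ∂φ/∂t = −Γ (μ − μ_bulk),  μ = f′(φ) − ε − κ∇²φ,

   where μ_bulk < 0 is the chemical potential of the sub-saturated
   cytoplasmic pool. The control parameter is the relative binding
   affinity Δε̄ = ε_int + μ_bulk (in kT). The dynamics is a gradient
   flow of the grand potential G[φ] = ∫ [f − (ε + μ_bulk)φ + (κ/2)|∇φ|²],
   which decreases monotonically along every trajectory. On a stripe of
   finite width the condensate is *pinned* (velocity 0) below a critical
   Δε̄ and elongates at constant velocity above it, with extension
   E(t) ∝ t and mass I(t) ∝ t. A 1D travelling-front solver serves as an
   independent velocity oracle.

2. **Quantification.** The measurement procedures used on junction
   movies and images: condensate segmentation and tracking (with
   fusion/fission flagging), moment-based eccentricity, skeleton belt
   length and perimeter coverage, extension-rate fits, the
   bleaching-invariant junction/cytoplasm enrichment ratio, Hill-model
   recruitment half-times, signed apical offsets of clusters from a
   strand, cyst tracer permeability, condensate partition coefficients
   and TEER normalization.

3. **Synthetic data with ground truth.** Generators for tissue movies
   (Voronoi cells, condensates nucleating on edges and elongating at
   drawn velocities under PSF blur, Poisson noise and photobleaching),
   Hill kinetics traces, strand/cluster geometries and cyst
   cross-sections — each returning a `GroundTruth` record so every
   estimator can be validated by parameter recovery.

## Worked example

```python
from prewetbelt import GridGeometry, ModelParams, build_affinity_landscape, evolve
from prewetbelt.model import fit_linear_rate

geometry = GridGeometry(n_across=96, n_along=256)
params = ModelParams()          # chi=3.5, kappa=4, Gamma=1, mu_bulk=-3, dt=0.012
affinity = build_affinity_landscape(
    geometry, eps0=2.4, eps_int=0.43 - params.mu_bulk, eps_nuc=0.6,
    sites=[(geometry.center_row, geometry.n_along // 2, 6)],
)
traj = evolve(None, affinity, params, n_steps=12000, snapshot_stride=200,
              seed_discs=True)
fit = fit_linear_rate(traj.times, traj.E_series, saturation=0.9 * 256)
print(fit.slope, fit.r_squared)
```

This is `examples/simulate_condensate.py`; it prints

```
extension rate      dE/dt = 1.500 length/time  (R^2 = 0.9999)
mass uptake rate    dI/dt = 10.444 mass/time    (R^2 = 1.0000)
grand potential     monotone decreasing: True
```

i.e. at Δε̄ = 0.43 the nucleated condensate elongates at a constant
1.50 grid lengths per unit time (0.75 per front) while taking up
material linearly, and the grand potential never increases. Running
`examples/affinity_scan.py` shows the other regime: at Δε̄ = 0.19–0.25
the fitted velocity is exactly 0 (the condensate stays pinned at its
nucleation disc), with the threshold bracketed between 0.25 and 0.31 on
the small scan grid.

The other example scripts cover tracking and rate recovery on a
synthetic movie, recruitment-kinetics Hill fits, and the offset/assay
estimators; each prints the numbers it computes and a line on what they
mean.

## Command line

```bash
prewetbelt simulate --config run.yaml --out outdir     # E/I/G series + snapshots
prewetbelt scan --config run.yaml --eps 0.19,0.43 --out outdir
prewetbelt synth tissue --seed 1 --out data/
prewetbelt quantify belt --in belt.tif --pixel-size 0.1 --n-cells 18 --out metrics.csv
prewetbelt simulate --dump-config                      # print packaged defaults
```

Every run writes its resolved configuration (with a provenance stamp)
next to its outputs; identical config and seed reproduce outputs
bit-exactly.

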