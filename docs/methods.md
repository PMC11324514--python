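# Methods

## The surface-condensation model

The membrane patch is a rectangular grid; axis 0 runs across the
apical–lateral interface (row 0 apical), axis 1 along it. Boundary
conditions are periodic along the interface (the belt closes on itself
around the cell perimeter) and zero-flux across. The state is the
dimensionless composition φ ∈ (0, 1), related to the ZO-1 surface
density ρ by φ = ρa² with molecular area a (a = 1 throughout; kT = 1).

The local free-energy density is the regular-solution form
f(φ) = φ ln φ + (1 − φ) ln(1 − φ) + χ φ(1 − φ), a symmetric double well
for χ > 2 whose wells are the dilute and condensed surface states.
Membrane binding enters linearly: the tilted density
ω(φ) = f(φ) − (ε + μ_bulk) φ decides which state is favoured locally.
The affinity map ε(x, y) carries three levels: ε₀ on the apical and
lateral domains, ε_int ≥ ε₀ on an interface stripe of half-width w
(half-open row band of exactly 2w rows, centred at row n_across/2), and
an additive ε_nuc inside circular nucleation discs on the stripe.

The layer exchanges material with the cytoplasmic reservoir at chemical
potential μ_bulk < 0 (sub-saturated bulk — no bulk phase separation):

∂φ/∂t = −Γ (μ − μ_bulk),  μ = f′(φ) − ε − κ∇²φ.

There is no conserved lateral flux by default: growth proceeds by
recruiting molecules from the bulk at the condensate edge, which is what
produces linear extension *and* linear mass increase. (A conserved
surface-diffusion term can be added by evolving a composite model, but
none of the packaged analyses use one.)

### Lyapunov structure

The dynamics is a gradient flow of the grand potential
G[φ] = Σ [f − (ε + μ_bulk)φ + (κ/2)|∇φ|²] h². Discretely, G uses
forward-difference gradients and the Laplacian uses the finite-volume
(face-mirror) ghost convention at the zero-flux rows; under exactly
these conventions μ − μ_bulk is the exact discrete gradient of G, so G
decreases monotonically in continuous time and, at the packaged time
step, at every recorded snapshot. The suite asserts this on every test
trajectory. φ leaving (0, 1) or turning non-finite aborts the run with
a diagnostic; it is never clamped.

### Default calibration and why

| parameter | default | units | rationale |
|---|---|---|---|
| χ | 3.5 | kT | deep enough quench that the dilute branch on the stripe stays metastable up to Δε̄ ≈ 0.73, so the whole studied affinity range (up to 0.46) shows nucleated front growth rather than spontaneous stripe condensation; χ only slightly above 2 leaves too narrow a metastable window |
| κ | 4.0 | kT·length² | interface width ≈ 4–5 grid points |
| Γ | 1.0 | 1/(kT·time) | sets the time unit |
| μ_bulk | −3.0 | kT | any negative value; only sums ε + μ_bulk matter |
| ε₀ | 2.4 | kT | off-stripe tilt ε₀ + μ_bulk = −0.6 kT: dilute favoured on apical/lateral domains |
| stripe half-width w | 4 | px | narrow stripe; confinement creates the pinning threshold |
| ε_nuc | 0.6 | kT | mild disc boost; large boosts push the local dense fixed point so close to φ = 1 that the explicit scheme would need a far smaller dt |
| disc radius | 6 | px | supercritical nucleus at the affinities studied |
| dt | 0.012 | time | explicit-Euler heuristic dt ≤ 0.2 h²/(4Γκ) = 0.0125 |

With these values the measured 2D pinning threshold lies between
Δε̄ = 0.28 and 0.31: fitted velocity is exactly 0 for Δε̄ ≤ 0.28 and
increases monotonically above ≈ 0.31; at Δε̄ = 0.43 extension and mass
grow linearly with R² > 0.999. Because f is symmetric, the equal-depth
(Maxwell) tilt is exactly 0, which gives a clean stationary-wall case
for the 1D oracle.

Scans and acceptance runs use the *seeded* initialization: φ starts at
the local dense fixed point inside nucleation discs (representing a
completed nucleation event) and at the dilute fixed point for ε₀
everywhere else. This decouples the front-propagation question from the
stochastic barrier-crossing time and keeps the affinity contrast inside
the stability budget of the explicit scheme.

### Observables and velocity convention

Extension E = spacing × number of along-stripe columns whose maximum φ
within the stripe exceeds the midpoint of the two wells at ε_int; excess
mass I = Σ max(φ − φ_dilute(ε₀), 0) h². Velocities are ordinary
least-squares slopes of E(t) with the first 25% of samples (nucleation
transient) and any saturated tail (condensate filling the periodic
stripe) discarded; fitted slopes below 10⁻³ report v = 0. E counts both
fronts of a single condensate, so comparisons with the 1D single-front
oracle use dE/dt / 2; on a stripe wider than ~5 interface widths the
two agree within 5%.

### Problem sizes

The packaged analyses use 128×512 for single-condensate runs, 96×256
for affinity scans and 1,500 points for the 1D oracle — sizes at which
the threshold location, monotonicity and oracle agreement are already
converged (doubling the grid moves fitted velocities by < 2%).

## Quantification conventions

**Eccentricity** comes from the second central moments of the region:
with covariance eigenvalues λ₁ ≥ λ₂, e = √(1 − λ₂/λ₁) — 0 for a circle,
1 for a line segment. By default no pixel-area term is added, so a
one-pixel-wide straight segment reports exactly 1 (the degenerate-case
definition); the 1/12 unit-square-pixel convention of some
region-property implementations is available as `pixel_correction=True`
(a 64-px segment then gives 0.999878). Float masks are treated as
per-pixel weights, which lets anti-aliased rasterizations of few-pixel
shapes approach their continuum moments (the rasterized 5×3 ellipse
measures 0.798 against the analytic 0.8).

**Skeleton length** thins the mask to a one-pixel centerline and
supports three length conventions: `pixel` (count × pixel size; the
sum-of-the-skeleton-image formula; underestimates oblique paths),
`sqrt2` (diagonal steps weigh √2; overestimates by ~5% on average over
orientations), and `calibrated` (chain-code weights 0.948/1.340, the
standard low-bias estimator; ~1–2% error on digitized straight
segments). Belt length per cell divides by the cell count; perimeter
coverage is belt/perimeter × 100 with values over 100% flagged.

**Tracking** links per-frame label masks by maximal pixel overlap,
counting an overlap only when it covers ≥ 30% of the smaller footprint
(grazing contact between neighbours must not re-wire identities).
Merges flag fusion on all traces involved; splits flag fission, the
largest fragment keeping the trace. Per-frame condensate length is the
longest geodesic path through the skeleton of the footprint
(8-connected, √2 diagonals; double-Dijkstra diameter — exact on trees,
which skeletons of elongated condensates effectively are), an open-curve
length like a filament tracker reports. Extension rates are OLS slopes
of the longest segment free of flags and of frame-to-frame jumps larger
than 3× the median |ΔE|.

**Enrichment ratio** = mean junctional / mean cytoplasmic intensity per
frame. Any global per-frame multiplicative factor cancels exactly, so
the series is invariant under spatially homogeneous photobleaching; a
spatially graded bleach (available in the generator as a negative
control) breaks the assumption. **Hill fits** use
y = base + amp·tⁿ/(t_halfⁿ + tⁿ) with base = min(y), amp = range,
t_half = half-range crossing, n = 1 as starting point and bounded
least squares; non-saturating or decreasing series return a flagged
failure. The arrival-time difference of two proteins is the difference
of their fitted half-times.

**Offsets**: each cluster centroid gets the distance to the nearest
point of the strand polyline, signed positive on the apical side of the
supplied direction; histogram bins are centred on multiples of the
20-nm default bin width and the mode is the centre of the fullest bin,
ties broken apically.

**Scalar assays**: cyst permeability = mean lumen / mean outside
intensity (0 sealed, 1 fully leaky); partition coefficient =
(inside − background)/(outside − background); TEER =
(measured − blank) × filter area, subtracting the series blank before
area normalization.

**Segmentation** (for synthetic data and simple real images) is
rolling-ball background subtraction, a global threshold and 8-connected
labelling with small-object removal. The default threshold rule is
Yen's, which suits the strongly skewed histograms of sparse bright
puncta; Otsu tends to split the background noise when the foreground
fraction is tiny.

## What the synthetic data emulate — and what they do not

The tissue generator lays out cells as a box-bounded Voronoi
tessellation (jittered-grid seeds, so cells are comparably sized),
nucleates condensates on cell–cell edges at Poisson times within the
first 60% of the movie (junction assembly nucleates early after a
calcium switch) and elongates each symmetrically along its edge at a
velocity drawn from its genotype class — wild-type-like
N(0.53, 0.14²) µm/min or mutant-like N(0.02, 0.07²) µm/min, truncated
at zero — clipped at edge vertices. Rendering: line photon sources
(fixed photons per µm), isotropic Gaussian PSF (σ = 0.15 µm), global
exponential bleach (0.01/min), Poisson shot noise, Gaussian read noise;
64 µm box at 0.1 µm/px, one frame per minute for 40 min, 18 cells.
Ground truth records per-condensate nucleation time, edge, drawn
velocity, true length per frame and intensity slope.

Not emulated: cell motion and shape change, genuine condensate
coalescence dynamics, intensity maturation, depth effects, uneven
illumination, camera artifacts beyond read noise. Passing recovery
tests therefore show that the estimators are unbiased under the stated
imaging physics at realistic noise, not that they are robust to every
failure mode of real microscopy. All noise sources can be set to zero,
giving every estimator an exact-recovery regime, and every generator is
bit-reproducible per seed.

The strand/cluster fixture draws signed offsets from a two-sided
exponential peaked at the programmed mode (35% of the mass decaying
apically with a 15-nm scale, the rest decaying lateral-ward with a
60-nm scale — a pronounced peak with an exponential-like lateral tail);
the cyst fixture is an annulus of tracer-excluding cells with outside
intensity 1 and lumen intensity equal to the programmed leakiness.

## Numerical choices and degenerate inputs

Explicit Euler at fixed dt in double precision; dt validated against
0.2 h²/(4Γκ) before every run. Well-finding uses bracketed root solves
on the two stable branches of f′, with the spinodal compositions as
brackets. Degenerate cases are defined rather than special-cased where
possible: empty masks have zero skeleton length but no eccentricity
(error); a constant extension series fits slope 0 with R² = 1; a
one-pixel skeleton has length one pixel; ties in the offset-histogram
mode break toward apical. Estimators that can fail on legitimate data
(Hill fits, extension-rate fits) return flagged result objects instead
of raising.

## Known limitations

- The model is two-dimensional and purely relaxational: no bulk
  diffusion gradients, no hydrodynamics, no active stresses, no coupling
  to actin or claudin polymerization, and no mapping of model units to
  µm/min (so simulated and measured velocities are compared only
  qualitatively — two regimes, monotonicity, linear growth).
- The explicit integrator restricts affinity contrasts; very strong
  nucleation boosts require smaller time steps than the packaged
  default.
- The pinning threshold depends on stripe width, κ and the off-stripe
  tilt; the packaged bracket (0.28–0.31) is a property of the default
  calibration, not a universal number.
- Tracking assumes condensates move slowly relative to the frame
  interval (overlap linking) and that masks are reasonably accurate;
  heavily merged objects are measured as one.
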