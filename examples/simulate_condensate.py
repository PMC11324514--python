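"""Elongation of a single nucleated surface condensate.

Builds the default polarized affinity landscape (apical/lateral domains,
interface stripe, one nucleation disc), runs the reservoir-exchange
dynamics above the prewetting threshold, and fits the condensate
extension E(t) and excess mass I(t).
"""

import numpy as np

from prewetbelt import GridGeometry, ModelParams, build_affinity_landscape, evolve
from prewetbelt.model import fit_linear_rate

geometry = GridGeometry(n_across=96, n_along=256)
params = ModelParams()  # chi=3.5, kappa=4, Gamma=1, mu_bulk=-3, dt=0.012
delta_eps_bar = 0.43  # relative binding affinity eps_int + mu_bulk, in kT

affinity = build_affinity_landscape(
    geometry,
    eps0=2.4,                                # off-stripe tilt: 2.4 - 3 = -0.6 kT
    eps_int=delta_eps_bar - params.mu_bulk,  # stripe tilt: +0.43 kT
    eps_nuc=0.6,
    sites=[(geometry.center_row, geometry.n_along // 2, 6)],
)
traj = evolve(None, affinity, params, n_steps=12000, snapshot_stride=200,
              seed_discs=True, store_snapshots=False)

fit_E = fit_linear_rate(traj.times, traj.E_series, saturation=0.9 * 256)
fit_I = fit_linear_rate(traj.times, traj.I_series)
print(f"relative affinity   delta_eps_bar = {delta_eps_bar}")
print(f"extension rate      dE/dt = {fit_E.slope:.3f} length/time  (R^2 = {fit_E.r_squared:.4f})")
print(f"mass uptake rate    dI/dt = {fit_I.slope:.3f} mass/time    (R^2 = {fit_I.r_squared:.4f})")
print(f"grand potential     monotone decreasing: {bool(np.all(np.diff(traj.G_series) <= 1e-10))}")
print()
print("Above the threshold the condensate elongates along the interface at")
print("constant speed while recruiting material from the reservoir, so both")
print("E(t) and I(t) are linear; the grand potential decreases throughout.")
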