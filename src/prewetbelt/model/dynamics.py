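"""Reservoir-exchange dynamics of the surface composition field.

The adsorbed layer exchanges material with the cytoplasmic reservoir at
chemical potential mu_bulk (< 0, sub-saturated):

    d phi / dt = -Gamma (mu - mu_bulk),

with mu the local chemical potential of the layer. There is no conserved
lateral flux by default: condensate growth proceeds by recruiting
molecules from the bulk at the condensate edge, which produces the
linear-in-time extension and mass increase characteristic of prewetting
fronts. Integration is explicit Euler at fixed dt in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AffinityField, GridGeometry
from .thermo import (
    chemical_potential_field,  # noqa: F401  (re-exported convenience)
    equilibrium_wells,
    grand_potential,
    laplacian,
)

__all__ = ["ModelParams", "SurfaceField", "Trajectory", "evolve", "initial_field"]


@dataclass(frozen=True)
class ModelParams:
    """Free-energy and kinetic parameters (kT = 1, molecular area a = 1).

    Attributes
    ----------
    chi : float
        Interaction strength in kT; chi > 2 gives the double well.
    kappa : float
        Gradient-penalty coefficient (kT * length^2); sets the interface
        width, about 4 px at the default calibration.
    gamma : float
        Exchange mobility with the bulk, 1/(kT * time).
    mu_bulk : float
        Cytoplasmic chemical potential in kT; must be negative
        (the bulk is below saturation).
    dt : float
        Euler time step. Must satisfy the explicit-stability heuristic
        dt <= 0.2 h^2 / (4 Gamma kappa).
    a : float
        Molecular area linking phi = rho a^2. Documentation only.
    """

    chi: float = 3.5
    kappa: float = 4.0
    gamma: float = 1.0
    mu_bulk: float = -3.0
    dt: float = 0.012
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.chi <= 2:
            raise ValueError("chi must exceed 2 (double-well regime)")
        if self.kappa <= 0 or self.gamma <= 0 or self.dt <= 0:
            raise ValueError("kappa, gamma and dt must be positive")
        if self.mu_bulk >= 0:
            raise ValueError("mu_bulk must be negative (sub-saturated bulk)")

    def delta_eps(self, eps_int: float) -> float:
        """Relative binding affinity delta_eps = eps_int + mu_bulk (kT)."""
        return eps_int + self.mu_bulk

    def stability_dt(self, spacing: float = 1.0) -> float:
        """Explicit-Euler step-size heuristic 0.2 h^2 / (4 Gamma kappa)."""
        return 0.2 * spacing**2 / (4.0 * self.gamma * self.kappa)


@dataclass
class SurfaceField:
    """Composition field phi on the grid; strictly inside (0, 1)."""

    geometry: GridGeometry
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != self.geometry.shape:
            raise ValueError("phi shape does not match geometry")
        if not np.all((self.phi > 0) & (self.phi < 1)):
            raise ValueError("phi must lie strictly in (0, 1)")


@dataclass
class Trajectory:
    """Time series recorded during a run.

    ``E_series`` is the condensate extension along the stripe,
    ``I_series`` the excess adsorbed mass over the dilute baseline, and
    ``G_series`` the grand potential (the Lyapunov function); all are
    sampled every ``snapshot_stride`` steps, together with (possibly
    strided) snapshots of phi.
    """

    times: np.ndarray
    E_series: np.ndarray
    I_series: np.ndarray
    G_series: np.ndarray
    snapshots: list[np.ndarray] = field(default_factory=list)
    snapshot_times: np.ndarray | None = None
    phi_cut: float = 0.5
    baseline: float = 0.0

    def final(self) -> np.ndarray:
        return self.snapshots[-1]


class IntegrationError(RuntimeError):
    """Raised when phi leaves (0,1) or turns non-finite during a run."""


def initial_field(
    geometry: GridGeometry,
    affinity: AffinityField,
    params: ModelParams,
    seed_discs: bool = False,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SurfaceField:
    """Dilute fixed point for eps0, optionally dense-seeded inside discs.

    The baseline is the homogeneous dilute solution of
    f'(phi) = eps0 + mu_bulk. With ``seed_discs`` the pixels inside
    nucleation discs start at the local dense fixed point (if the
    condensed branch exists there), which stands in for a completed
    nucleation event when the eps_nuc-driven barrier crossing would be
    slow.
    """
    tilt0 = affinity.eps0 + params.mu_bulk
    wells = equilibrium_wells(params.chi, tilt0)
    phi = np.full(geometry.shape, wells[0][0])
    if seed_discs and affinity.nucleation_sites:
        disc = affinity.disc_mask()
        tilt_disc = float(np.max(affinity.values[disc])) + params.mu_bulk
        w = equilibrium_wells(params.chi, tilt_disc)
        dense = w[-1][0] if len(w) > 1 else max(p for p, _ in w)
        phi[disc] = dense
    if noise > 0.0:
        rng = rng or np.random.default_rng()
        phi = np.clip(phi + rng.normal(0.0, noise, geometry.shape), 1e-6, 1 - 1e-6)
    return SurfaceField(geometry=geometry, phi=phi)


def evolve(
    field_or_none: SurfaceField | None,
    affinity: AffinityField,
    params: ModelParams,
    n_steps: int,
    snapshot_stride: int = 200,
    seed: int | None = None,
    seed_discs: bool = False,
    init_noise: float = 0.0,
    store_snapshots: bool = True,
) -> Trajectory:
    """Integrate d phi/dt = -Gamma (mu - mu_bulk) for ``n_steps`` steps.

    Deterministic for fixed inputs; ``seed`` only perturbs the optional
    initial noise. Every ``snapshot_stride`` steps the trajectory records
    time, extension E, excess mass I and grand potential G (and a phi
    snapshot unless ``store_snapshots`` is off).

    Raises
    ------
    IntegrationError
        If phi leaves (0, 1) or becomes non-finite; the run is aborted
        with a diagnostic rather than silently clamped.
    """
    from .observables import measure_excess_mass, measure_extension

    geometry = affinity.geometry
    if params.dt > params.stability_dt(geometry.spacing) * (1 + 1e-9):
        raise ValueError(
            f"dt={params.dt} exceeds the stability bound "
            f"{params.stability_dt(geometry.spacing):.3g}"
        )
    if field_or_none is None:
        rng = np.random.default_rng(seed) if seed is not None else None
        field = initial_field(
            geometry, affinity, params, seed_discs=seed_discs,
            noise=init_noise, rng=rng,
        )
    else:
        field = field_or_none

    phi = field.phi.astype(float, copy=True)
    eps = affinity.values
    chi, kappa, gamma, mu_b, dt = (
        params.chi, params.kappa, params.gamma, params.mu_bulk, params.dt,
    )
    h = geometry.spacing

    # measurement conventions for this run
    tilt_int = params.delta_eps(affinity.eps_int)
    wells_int = equilibrium_wells(chi, tilt_int)
    if len(wells_int) == 2:
        phi_cut = 0.5 * (wells_int[0][0] + wells_int[1][0])
    else:
        phi_cut = 0.5
    baseline = equilibrium_wells(chi, affinity.eps0 + params.mu_bulk)[0][0]

    times, E_s, I_s, G_s = [], [], [], []
    snaps: list[np.ndarray] = []
    snap_t = []

    def record(step: int) -> None:
        t = step * dt
        times.append(t)
        E_s.append(measure_extension(phi, geometry, phi_cut))
        I_s.append(measure_excess_mass(phi, geometry, baseline))
        G_s.append(grand_potential(phi, eps, chi, kappa, mu_b, h))
        if store_snapshots:
            snaps.append(phi.copy())
            snap_t.append(t)

    record(0)
    # inner loop duplicates chemical_potential_field without its domain
    # check: a bound violation shows up as NaN and is caught at the next
    # stride, where it aborts the run (never clamped)
    for step in range(1, n_steps + 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = (
                np.log(phi / (1 - phi))
                + chi * (1 - 2 * phi)
                - eps
                - kappa * laplacian(phi, h)
            )
            phi -= dt * gamma * (mu - mu_b)
        if step % snapshot_stride == 0 or step == n_steps:
            if not np.isfinite(phi).all():
                raise IntegrationError(
                    f"non-finite phi at step {step} (t={step * dt:.4g}); "
                    "reduce dt or the affinity contrast"
                )
            if phi.min() <= 0.0 or phi.max() >= 1.0:
                raise IntegrationError(
                    f"phi left (0,1) at step {step}: min={phi.min():.4g}, "
                    f"max={phi.max():.4g}"
                )
            record(step)

    return Trajectory(
        times=np.asarray(times),
        E_series=np.asarray(E_s),
        I_series=np.asarray(I_s),
        G_series=np.asarray(G_s),
        snapshots=snaps,
        snapshot_times=np.asarray(snap_t) if snap_t else None,
        phi_cut=phi_cut,
        baseline=baseline,
    )
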