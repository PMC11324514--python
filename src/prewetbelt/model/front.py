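"""Traveling-front velocity: 1D oracle and 2D affinity scans.

Above the prewetting threshold a condensed domain on the interface
stripe elongates at constant speed. The 1D restriction of the same
dynamics (no confinement across the stripe) provides an independent
velocity oracle: its front moves for any tilt beyond the Maxwell
(equal-well) point, whereas the finite-width 2D stripe pins the front
until the tilt also pays for the two lateral interfaces -- the 2D
threshold therefore exceeds the 1D one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import IntegrationError, ModelParams, evolve
from .geometry import GridGeometry, build_affinity_landscape
from .observables import LinearFit, fit_linear_rate
from .thermo import equilibrium_wells

__all__ = [
    "FrontVelocity1D",
    "front_velocity_1d",
    "VelocityScan",
    "scan_velocity_vs_affinity",
]

#: fitted slopes below this magnitude (model length / model time) are
#: reported as zero velocity
VELOCITY_FLOOR = 1e-3


@dataclass(frozen=True)
class FrontVelocity1D:
    """Single-front speed of the 1D traveling wave."""

    velocity: float
    slope: float
    r_squared: float
    flag: str = ""


def front_velocity_1d(
    params: ModelParams,
    eps_int: float,
    n_points: int = 1500,
    spacing: float = 1.0,
    t_total: float = 200.0,
    sample_stride: int = 100,
) -> FrontVelocity1D:
    """Speed of the 1D front of d phi/dt = -Gamma (mu - mu_bulk).

    A dense domain occupying the left quarter of a fine 1D grid invades
    (or retreats from) the dilute phase; the front position, measured as
    spacing x (count of phi above the well midpoint), is fitted linearly
    over the last 75% of the run. At the Maxwell tilt the wall is
    stationary and the speed is zero. If no condensed well exists at
    ``eps_int`` the function returns 0 with flag ``"no condensed
    phase"``.
    """
    tilt = params.delta_eps(eps_int)
    wells = equilibrium_wells(params.chi, tilt)
    if len(wells) < 2:
        if wells and wells[0][0] > 0.5:
            pass  # condensed phase is the only phase: front undefined but moving
        else:
            return FrontVelocity1D(0.0, 0.0, 1.0, flag="no condensed phase")
    phi_dil = wells[0][0]
    phi_den = wells[-1][0]
    cut = 0.5 * (phi_dil + phi_den)

    h = spacing
    dt = min(params.dt, params.stability_dt(h))
    phi = np.full(n_points, phi_dil)
    phi[: n_points // 4] = phi_den
    chi, kappa, gamma = params.chi, params.kappa, params.gamma
    n_steps = int(t_total / dt)
    ts, pos = [], []
    lap = np.empty_like(phi)
    for i in range(n_steps + 1):
        if i % sample_stride == 0:
            if not np.isfinite(phi).all():
                raise IntegrationError(f"non-finite 1D front at step {i}")
            ts.append(i * dt)
            pos.append((phi > cut).sum() * h)
        lap[1:-1] = phi[2:] + phi[:-2] - 2 * phi[1:-1]
        lap[0] = phi[1] - phi[0]
        lap[-1] = phi[-2] - phi[-1]
        mu_ex = (
            np.log(phi / (1 - phi))
            + chi * (1 - 2 * phi)
            - kappa * lap / (h * h)
            - tilt
        )
        phi -= dt * gamma * mu_ex

    fit = fit_linear_rate(
        np.asarray(ts), np.asarray(pos), saturation=0.9 * n_points * h
    )
    slope = fit.slope
    v = 0.0 if abs(slope) < VELOCITY_FLOOR else max(slope, 0.0)
    return FrontVelocity1D(v, slope, fit.r_squared)


@dataclass
class VelocityScan:
    """Fitted elongation velocity v(delta_eps) across a 2D scan.

    ``velocities[i]`` is dE/dt (both fronts) at ``delta_eps_bars[i]``;
    ``critical_estimate`` brackets the pinning threshold between the
    last zero-velocity and the first positive-velocity affinity.
    """

    delta_eps_bars: np.ndarray
    velocities: np.ndarray
    r_squared: np.ndarray
    failed: list[str]
    critical_estimate: tuple[float, float] | None

    def rows(self):
        return list(zip(self.delta_eps_bars, self.velocities, self.r_squared))


def _fit_velocity(traj, geometry: GridGeometry) -> LinearFit:
    return fit_linear_rate(
        traj.times,
        traj.E_series,
        saturation=0.9 * geometry.n_along * geometry.spacing,
    )


def fitted_velocity(traj, geometry: GridGeometry) -> tuple[float, float]:
    """(v, R^2) from a trajectory's extension series; v floored to 0."""
    fit = _fit_velocity(traj, geometry)
    if abs(fit.slope) < VELOCITY_FLOOR:
        return 0.0, fit.r_squared
    return max(fit.slope, 0.0), fit.r_squared


def scan_velocity_vs_affinity(
    params: ModelParams,
    delta_eps_bars: list[float],
    geometry: GridGeometry | None = None,
    eps0_tilt: float = -0.6,
    eps_nuc: float = 0.6,
    disc_radius: int = 6,
    n_steps: int = 25000,
    snapshot_stride: int = 200,
    seed_discs: bool = True,
) -> VelocityScan:
    """One seeded 2D run per relative affinity; fit v = dE/dt for each.

    ``delta_eps_bars`` must be sorted ascending. A single nucleation
    disc sits at the stripe centre; ``eps0_tilt`` fixes the off-stripe
    tilt eps0 + mu_bulk (negative: dilute favoured). Failures of single
    runs are recorded and the scan continues.
    """
    if list(delta_eps_bars) != sorted(delta_eps_bars):
        raise ValueError("delta_eps_bars must be sorted ascending")
    geometry = geometry or GridGeometry(n_across=96, n_along=256)
    eps0 = eps0_tilt - params.mu_bulk
    vs, r2s, failed = [], [], []
    for deps in delta_eps_bars:
        eps_int = deps - params.mu_bulk
        affinity = build_affinity_landscape(
            geometry,
            eps0=eps0,
            eps_int=eps_int,
            eps_nuc=eps_nuc,
            sites=[(geometry.center_row, geometry.n_along // 2, disc_radius)],
        )
        try:
            traj = evolve(
                None,
                affinity,
                params,
                n_steps=n_steps,
                snapshot_stride=snapshot_stride,
                seed_discs=seed_discs,
                store_snapshots=False,
            )
        except IntegrationError as exc:
            failed.append(f"delta_eps={deps}: {exc}")
            vs.append(np.nan)
            r2s.append(np.nan)
            continue
        v, r2 = fitted_velocity(traj, geometry)
        vs.append(v)
        r2s.append(r2)

    vs_arr = np.asarray(vs)
    critical = None
    finite = np.isfinite(vs_arr)
    zero_idx = [i for i in range(len(vs)) if finite[i] and vs_arr[i] == 0.0]
    pos_idx = [i for i in range(len(vs)) if finite[i] and vs_arr[i] > 0.0]
    if zero_idx and pos_idx and min(pos_idx) > max(zero_idx):
        critical = (
            float(delta_eps_bars[max(zero_idx)]),
            float(delta_eps_bars[min(pos_idx)]),
        )
    return VelocityScan(
        delta_eps_bars=np.asarray(delta_eps_bars, float),
        velocities=vs_arr,
        r_squared=np.asarray(r2s),
        failed=failed,
        critical_estimate=critical,
    )
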