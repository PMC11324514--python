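"""Regular-solution thermodynamics of the adsorbed ZO-1 layer.

The composition field phi in (0, 1) is the dimensionless ZO-1 surface
density (phi = rho * a^2 with molecular area a). The local free-energy
density per unit area (kT = 1, a = 1) is

    f(phi) = phi ln phi + (1 - phi) ln(1 - phi) + chi phi (1 - phi),

a symmetric double well for chi > 2. Membrane binding enters linearly:
the tilted density omega(phi) = f(phi) - (eps + mu_bulk) phi decides
which surface state -- dilute or condensed -- is favoured locally. On
the apical and lateral domains the tilt eps0 + mu_bulk is negative
(dilute favoured); on the interface stripe the tilt
delta_eps = eps_int + mu_bulk can favour the condensed layer, which is
the prewetting situation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "local_free_energy",
    "f_prime",
    "equilibrium_wells",
    "spinodal_tilts",
    "chemical_potential_field",
    "laplacian",
    "grand_potential",
]


def _check_phi(phi: np.ndarray | float) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if not np.all((phi > 0.0) & (phi < 1.0)):
        raise ValueError("composition phi must lie strictly in (0, 1)")
    return phi


def local_free_energy(phi, chi: float):
    """Free-energy density f(phi) in kT per unit area.

    Symmetric about phi = 1/2: f(phi) == f(1 - phi).
    """
    phi = _check_phi(phi)
    return phi * np.log(phi) + (1 - phi) * np.log(1 - phi) + chi * phi * (1 - phi)


def f_prime(phi, chi: float):
    """Exchange chemical potential f'(phi) of the homogeneous layer."""
    phi = _check_phi(phi)
    return np.log(phi / (1 - phi)) + chi * (1 - 2 * phi)


def spinodal_tilts(chi: float) -> tuple[float, float] | None:
    """Tilt values at which the dilute / dense branches lose metastability.

    Returns ``(tilt_dilute_limit, tilt_dense_limit)`` = f' at the two
    spinodal compositions, or None for chi <= 2 (no double well).
    """
    if chi <= 2:
        return None
    d = np.sqrt(1 - 2 / chi)
    s1, s2 = 0.5 * (1 - d), 0.5 * (1 + d)
    return (float(f_prime(s1, chi)), float(f_prime(s2, chi)))


def equilibrium_wells(chi: float, tilt: float) -> list[tuple[float, float]]:
    """Local minima of omega(phi) = f(phi) - tilt*phi.

    Solves f'(phi) = tilt on the outer (stable) branches. Returns one or
    two ``(phi, omega(phi))`` pairs, dilute first. For chi <= 2 (single
    well) the unique solution is returned.
    """
    if chi <= 0 and chi != 0:
        pass  # any chi is admissible; double well only for chi > 2
    eps = 1e-14

    def g(p):
        return np.log(p / (1 - p)) + chi * (1 - 2 * p) - tilt

    def omega(p):
        return float(local_free_energy(p, chi) - tilt * p)

    out: list[tuple[float, float]] = []
    sp = spinodal_tilts(chi)
    if sp is None:
        # f' monotone increasing: single root
        p = brentq(g, eps, 1 - eps)
        return [(float(p), omega(p))]
    d = np.sqrt(1 - 2 / chi)
    s1, s2 = 0.5 * (1 - d), 0.5 * (1 + d)
    if g(eps) < 0 < g(s1):
        p = brentq(g, eps, s1)
        out.append((float(p), omega(p)))
    if g(s2) < 0 < g(1 - eps):
        p = brentq(g, s2, 1 - eps)
        out.append((float(p), omega(p)))
    return out


def laplacian(phi: np.ndarray, spacing: float) -> np.ndarray:
    """5-point Laplacian: periodic along axis 1, zero-flux across axis 0.

    The zero-flux rows use the finite-volume (face-mirror) ghost
    convention, under which this stencil is the exact discrete gradient
    of the forward-difference gradient energy -- the property that makes
    the grand potential an exact Lyapunov function of the dynamics.
    """
    out = np.roll(phi, 1, axis=1) + np.roll(phi, -1, axis=1) - 4.0 * phi
    out[1:-1] += phi[2:] + phi[:-2]
    out[0] += phi[1] + phi[0]
    out[-1] += phi[-2] + phi[-1]
    out /= spacing * spacing
    return out


def chemical_potential_field(
    phi: np.ndarray,
    affinity_values: np.ndarray,
    chi: float,
    kappa: float,
    spacing: float = 1.0,
) -> np.ndarray:
    """Per-pixel chemical potential of the adsorbed layer (kT).

        mu = ln(phi/(1-phi)) + chi (1 - 2 phi) - eps - kappa lap(phi)

    This is the discrete functional derivative of the total free energy
    (with forward-difference gradient energy), so reservoir-exchange
    dynamics driven by mu - mu_bulk monotonically lowers the grand
    potential.
    """
    phi = _check_phi(phi)
    affinity_values = np.asarray(affinity_values, dtype=float)
    if affinity_values.shape != phi.shape:
        raise ValueError(
            f"affinity shape {affinity_values.shape} != field shape {phi.shape}"
        )
    return (
        np.log(phi / (1 - phi))
        + chi * (1 - 2 * phi)
        - affinity_values
        - kappa * laplacian(phi, spacing)
    )


def grand_potential(
    phi: np.ndarray,
    affinity_values: np.ndarray,
    chi: float,
    kappa: float,
    mu_bulk: float,
    spacing: float = 1.0,
) -> float:
    """Grand potential G[phi] of the layer coupled to the bulk reservoir.

        G = sum_pixels [ f(phi) - (eps + mu_bulk) phi
                         + (kappa/2) |grad phi|^2 ] h^2

    The gradient energy uses forward differences with the run's boundary
    conditions, the convention under which `chemical_potential_field` is
    the exact discrete gradient of G; G is then a Lyapunov function of
    the dynamics.
    """
    phi = _check_phi(phi)
    h = spacing
    f = local_free_energy(phi, chi)
    bulk = f - (affinity_values + mu_bulk) * phi
    # forward differences; axis 1 periodic, axis 0 no wrap (zero-flux)
    gx = (np.roll(phi, -1, axis=1) - phi) / h
    gy = (phi[1:] - phi[:-1]) / h
    grad2 = (gx**2).sum() + (gy**2).sum()
    return float(bulk.sum() * h * h + 0.5 * kappa * grad2 * h * h)
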