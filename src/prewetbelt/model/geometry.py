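"""Grid geometry and the position-dependent binding-affinity landscape.

The membrane is modelled as a rectangular patch: axis 0 runs across the
apical--lateral interface (apical side at row 0), axis 1 runs along it.
Boundary conditions are zero-flux across (axis 0) and periodic along
(axis 1), reflecting that the junctional belt closes on itself around the
cell perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "AffinityField", "build_affinity_landscape"]


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular grid with an interface stripe through the middle.

    Parameters
    ----------
    n_across : int
        Grid points across the interface (axis 0). Must be >= 8.
    n_along : int
        Grid points along the interface (axis 1, periodic). Must be >= 8.
    spacing : float
        Grid spacing ``h`` in model length units.
    stripe_halfwidth : int
        Half-width ``w`` of the interface stripe in grid points. The
        stripe occupies the half-open row band
        ``[n_across//2 - w, n_across//2 + w)``, i.e. exactly ``2*w`` rows.
    """

    n_across: int = 128
    n_along: int = 512
    spacing: float = 1.0
    stripe_halfwidth: int = 4

    def __post_init__(self) -> None:
        if self.n_across < 8 or self.n_along < 8:
            raise ValueError("grid must be at least 8x8 points")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        w = self.stripe_halfwidth
        if w < 1 or 2 * w >= self.n_across:
            raise ValueError("stripe_halfwidth out of range for this grid")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_across, self.n_along)

    @property
    def center_row(self) -> int:
        return self.n_across // 2

    @property
    def stripe_rows(self) -> slice:
        c, w = self.center_row, self.stripe_halfwidth
        return slice(c - w, c + w)

    def stripe_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.stripe_rows] = True
        return m

    def apical_mask(self) -> np.ndarray:
        """Rows apical of the stripe (above it; row 0 is the apical edge)."""
        m = np.zeros(self.shape, dtype=bool)
        m[: self.center_row - self.stripe_halfwidth] = True
        return m

    def lateral_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.center_row + self.stripe_halfwidth:] = True
        return m


@dataclass(frozen=True)
class AffinityField:
    """Per-pixel binding affinity eps(x, y) in kT per molecule.

    ``values`` equals ``eps0`` on the apical and lateral domains,
    ``eps_int`` on the interface stripe, with ``eps_nuc`` added inside
    nucleation discs.
    """

    geometry: GridGeometry
    eps0: float
    eps_int: float
    eps_nuc: float
    nucleation_sites: tuple[tuple[int, int, int], ...]
    values: np.ndarray = field(repr=False)

    def disc_mask(self) -> np.ndarray:
        """Boolean mask of all nucleation-disc pixels."""
        rr, cc = np.indices(self.geometry.shape)
        m = np.zeros(self.geometry.shape, dtype=bool)
        for r0, c0, rad in self.nucleation_sites:
            m |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        return m


def build_affinity_landscape(
    geometry: GridGeometry,
    eps0: float,
    eps_int: float,
    eps_nuc: float = 0.0,
    sites: list[tuple[int, int, int]] | None = None,
) -> AffinityField:
    """Build the affinity map: baseline domains, interface stripe, discs.

    Parameters
    ----------
    sites : list of (row, col, radius)
        Nucleation discs; centres must lie on the interface stripe and
        radii must be >= 1 grid point. ``eps_nuc`` is added inside each
        disc (on top of whatever value the pixel already carries).

    Raises
    ------
    ValueError
        If ``eps_int < eps0`` or a disc centre lies off the stripe.
    """
    if eps_int < eps0:
        raise ValueError(f"eps_int ({eps_int}) must be >= eps0 ({eps0})")
    sites = list(sites or [])
    stripe = geometry.stripe_rows
    for r0, c0, rad in sites:
        if not (stripe.start <= r0 < stripe.stop):
            raise ValueError(f"nucleation site row {r0} is off the stripe {stripe}")
        if not (0 <= c0 < geometry.n_along):
            raise ValueError(f"nucleation site col {c0} outside the grid")
        if rad < 1:
            raise ValueError("nucleation disc radius must be >= 1 grid point")

    values = np.full(geometry.shape, float(eps0))
    values[stripe] = eps_int
    if sites and eps_nuc != 0.0:
        rr, cc = np.indices(geometry.shape)
        for r0, c0, rad in sites:
            values[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] += eps_nuc
    return AffinityField(
        geometry=geometry,
        eps0=float(eps0),
        eps_int=float(eps_int),
        eps_nuc=float(eps_nuc),
        nucleation_sites=tuple((int(r), int(c), int(a)) for r, c, a in sites),
        values=values,
    )
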