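"""Derived observables: condensate extension, excess mass, velocity fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import GridGeometry

__all__ = [
    "measure_extension",
    "measure_excess_mass",
    "fit_linear_rate",
    "LinearFit",
]


def measure_extension(
    phi: np.ndarray, geometry: GridGeometry, phi_cut: float
) -> float:
    """Extension E of the condensed region along the interface stripe.

    E = spacing x (number of along-stripe columns whose maximum phi
    within the stripe exceeds ``phi_cut``). ``phi_cut`` is normally the
    midpoint of the two wells at eps_int.
    """
    if not (0.0 < phi_cut < 1.0):
        raise ValueError("phi_cut must lie in (0, 1)")
    colmax = phi[geometry.stripe_rows].max(axis=0)
    return float((colmax > phi_cut).sum() * geometry.spacing)


def measure_excess_mass(
    phi: np.ndarray, geometry: GridGeometry, baseline: float
) -> float:
    """Excess adsorbed amount I = sum max(phi - baseline, 0) h^2 >= 0."""
    h = geometry.spacing
    return float(np.maximum(phi - baseline, 0.0).sum() * h * h)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int


def fit_linear_rate(
    times: np.ndarray,
    values: np.ndarray,
    discard_fraction: float = 0.25,
    saturation: float | None = None,
) -> LinearFit:
    """Ordinary least squares on the post-transient part of a series.

    The first ``discard_fraction`` of the samples is dropped (nucleation
    transient); samples at or above ``saturation`` (e.g. a condensate
    that has filled the periodic stripe) are excluded from the fit.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if saturation is not None:
        keep = y < saturation
        t, y = t[keep], y[keep]
    k = int(len(t) * discard_fraction)
    t, y = t[k:], y[k:]
    if len(t) < 3:
        return LinearFit(np.nan, np.nan, np.nan, np.nan, len(t))
    if np.ptp(y) == 0.0:
        # exactly constant series: zero slope, perfect fit
        return LinearFit(0.0, float(y[0]), 1.0, 0.0, len(t))
    res = stats.linregress(t, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n=len(t),
    )
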