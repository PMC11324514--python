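"""Junctional-belt metrics: skeleton length, length per cell, coverage."""

from __future__ import annotations

import warnings

import numpy as np
from skimage import morphology

__all__ = [
    "skeleton_length",
    "belt_length_per_cell",
    "perimeter_coverage",
]

_SQRT2 = float(np.sqrt(2.0))


def _step_counts(skel: np.ndarray) -> tuple[int, int]:
    # unique 8-neighbour adjacencies: diagonals that shortcut an existing
    # orthogonal corner are dropped to avoid double counting
    s = skel.astype(bool)
    right = s[:, :-1] & s[:, 1:]
    down = s[:-1, :] & s[1:, :]
    diag1 = s[:-1, :-1] & s[1:, 1:]
    diag2 = s[:-1, 1:] & s[1:, :-1]
    # corner shortcut: diagonal (r,c)-(r+1,c+1) redundant if (r,c+1) or (r+1,c) set
    corner1 = s[:-1, 1:] | s[1:, :-1]
    corner2 = s[:-1, :-1] | s[1:, 1:]
    n_orth = int(right.sum() + down.sum())
    n_diag = int((diag1 & ~corner1).sum()) + int((diag2 & ~corner2).sum())
    return n_orth, n_diag


def skeleton_length(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    weighting: str = "pixel",
    skeletonize: bool = True,
) -> float:
    """Length of the 1-px centerline of a binary mask, in length units.

    The mask is morphologically thinned to a one-pixel skeleton and its
    length estimated from the chain of skeleton pixels:

    - ``"pixel"`` (default): skeleton pixel count x ``pixel_size``, the
      sum-of-the-skeleton-image convention. Underestimates oblique paths
      (up to a factor 1/sqrt(2) at 45 degrees).
    - ``"sqrt2"``: orthogonal steps weigh 1, diagonal steps sqrt(2).
      Overestimates shallow oblique paths by up to ~8% (mean ~5% over
      uniformly distributed angles).
    - ``"calibrated"``: chain-code weights 0.948 / 1.340 per orthogonal /
      diagonal step, the standard low-bias estimator for digitized
      straight segments (error ~1-2% for random orientations).

    Empty masks report 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return 0.0
    skel = morphology.skeletonize(mask) if skeletonize else mask
    if weighting == "pixel":
        return float(skel.sum() * pixel_size)
    n_orth, n_diag = _step_counts(skel)
    if weighting == "sqrt2":
        return (n_orth + _SQRT2 * n_diag) * pixel_size
    if weighting == "calibrated":
        return (0.948 * n_orth + 1.340 * n_diag) * pixel_size
    raise ValueError(f"unknown weighting {weighting!r}")


def belt_length_per_cell(
    mask: np.ndarray,
    n_cells: int,
    pixel_size: float = 1.0,
    weighting: str = "pixel",
) -> float:
    """Belt length per cell: skeleton length divided by the cell count."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return skeleton_length(mask, pixel_size, weighting=weighting) / n_cells


def perimeter_coverage(belt_length: float, cell_perimeter: float) -> float:
    """Percent of the cell perimeter covered by the junctional belt.

    (belt length / perimeter) x 100. Values above 100 (skeletonization
    artifacts) are reported as-is with a warning.
    """
    if cell_perimeter <= 0:
        raise ValueError("cell perimeter must be positive")
    cov = 100.0 * belt_length / cell_perimeter
    if cov > 100.0:
        warnings.warn(
            f"perimeter coverage {cov:.1f}% exceeds 100% "
            "(likely a skeletonization artifact)",
            stacklevel=2,
        )
    return cov
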