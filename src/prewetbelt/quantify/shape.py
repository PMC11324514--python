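"""Moment-based shape descriptors for segmented condensates."""

from __future__ import annotations

import numpy as np

__all__ = ["eccentricity"]


def eccentricity(mask: np.ndarray, pixel_correction: bool = False) -> float:
    """Eccentricity of the moment-equivalent ellipse of a binary region.

    The covariance matrix of the pixel coordinates is diagonalized; with
    eigenvalues lam1 >= lam2 the eccentricity is

        e = sqrt(1 - lam2 / lam1),

    the focus-distance-to-major-axis ratio of the equivalent ellipse:
    0 for a circle, 1 for a line segment.

    Parameters
    ----------
    mask : ndarray of bool or float
        Region mask with at least one pixel. A float array is treated as
        per-pixel weights (e.g. the coverage fractions of an
        anti-aliased rasterization), which reduces discretization error
        for small regions.
    pixel_correction : bool
        Add the 1/12 pixel-area term to both eigenvalues (the unit-square
        pixel convention used by some region-property implementations).
        Off by default, so that a one-pixel-wide straight segment reports
        exactly 1.
    """
    mask = np.asarray(mask)
    w_img = mask.astype(float)
    ys, xs = np.nonzero(w_img)
    if ys.size == 0:
        raise ValueError("empty mask has no eccentricity")
    if ys.size == 1:
        return 0.0
    w = w_img[ys, xs]
    wsum = w.sum()
    y = ys - (w * ys).sum() / wsum
    x = xs - (w * xs).sum() / wsum
    uyy = (w * y * y).sum() / wsum
    uxx = (w * x * x).sum() / wsum
    uxy = (w * x * y).sum() / wsum
    if pixel_correction:
        uyy += 1.0 / 12.0
        uxx += 1.0 / 12.0
    # eigenvalues of [[uxx, uxy], [uxy, uyy]]
    tr = uxx + uyy
    det = uxx * uyy - uxy * uxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    if lam1 <= 0.0:
        return 0.0
    return float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))
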