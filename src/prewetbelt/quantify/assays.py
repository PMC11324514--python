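"""Scalar assay read-outs: permeability, partitioning, TEER."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["permeability_ratio", "partition_coefficient", "teer_normalize"]


def permeability_ratio(
    image: np.ndarray, lumen_mask: np.ndarray, outside_mask: np.ndarray
) -> float:
    """Tracer exclusion of a cyst: mean lumen / mean outside intensity.

    0 for a perfectly sealed lumen, 1 for a fully leaky one. The two
    masks must be disjoint and non-empty.
    """
    image = np.asarray(image, dtype=float)
    lumen = np.asarray(lumen_mask).astype(bool)
    outside = np.asarray(outside_mask).astype(bool)
    if not lumen.any() or not outside.any():
        raise ValueError("lumen and outside masks must be non-empty")
    if (lumen & outside).any():
        raise ValueError("lumen and outside masks must be disjoint")
    return float(image[lumen].mean() / image[outside].mean())


def partition_coefficient(
    inside: float, outside: float, background: float = 0.0
) -> float:
    """Client partition coefficient (inside - bg) / (outside - bg).

    ``inside``/``outside`` are client intensities inside and outside the
    scaffold condensate (cytoplasm); ``background`` is the extracellular
    signal, subtracted from both.
    """
    denom = outside - background
    if denom <= 0:
        raise ValueError("outside intensity must exceed background")
    return float((inside - background) / denom)


def teer_normalize(
    measured_ohm: float, blank_ohm: float, filter_area_cm2: float = 1.12
) -> float:
    """Blank-corrected, area-normalized transepithelial resistance.

    (measured - blank) x area, in Ohm cm^2: the blank (medium-only
    filter) resistance is in series with the epithelium and is
    subtracted before area normalization. Negative results are reported
    as-is with a warning.
    """
    if filter_area_cm2 <= 0:
        raise ValueError("filter area must be positive")
    out = (measured_ohm - blank_ohm) * filter_area_cm2
    if out < 0:
        warnings.warn(
            f"negative TEER ({out:.3g} Ohm cm^2): measured below blank",
            stacklevel=2,
        )
    return float(out)
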