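"""Recruitment kinetics: enrichment ratio, Hill fits, correlation.

The junction-to-cytoplasm intensity ratio is the bleaching-robust
readout of client recruitment: a spatially homogeneous bleach multiplies
both compartments by the same factor per frame, which cancels in the
ratio. Arrival kinetics are summarized by the half-time t_1/2 of a Hill
fit; the arrival-time difference of two proteins is the difference of
their t_1/2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["HillFit", "enrichment_ratio_series", "fit_hill", "correlate"]


def enrichment_ratio_series(
    movie,
    junction_masks: np.ndarray | list[np.ndarray],
    cytoplasm_masks: np.ndarray | list[np.ndarray],
) -> np.ndarray:
    """Mean junctional / mean cytoplasmic intensity, per frame.

    Masks may be a single 2D mask (applied to every frame) or one mask
    per frame, and must be disjoint. A frame with an empty mask yields
    NaN with a warning.
    """
    stack = np.asarray(movie.stack, dtype=float)
    T = stack.shape[0]

    def per_frame(masks):
        m = np.asarray(masks) if not isinstance(masks, list) else masks
        if isinstance(m, np.ndarray) and m.ndim == 2:
            return [m.astype(bool)] * T
        out = [np.asarray(x).astype(bool) for x in m]
        if len(out) != T:
            raise ValueError("need one mask per frame (or a single 2D mask)")
        return out

    jm = per_frame(junction_masks)
    cm = per_frame(cytoplasm_masks)
    ratios = np.empty(T)
    for t in range(T):
        if (jm[t] & cm[t]).any():
            raise ValueError(f"junction and cytoplasm masks overlap in frame {t}")
        if not jm[t].any() or not cm[t].any():
            warnings.warn(f"empty mask in frame {t}; ratio set to NaN", stacklevel=2)
            ratios[t] = np.nan
            continue
        ratios[t] = stack[t][jm[t]].mean() / stack[t][cm[t]].mean()
    return ratios


@dataclass(frozen=True)
class HillFit:
    """Parameters of y = base + amplitude * t^n / (t_half^n + t^n)."""

    base: float
    amplitude: float
    n: float
    t_half: float
    r_squared: float
    ok: bool
    reason: str = ""

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.base + self.amplitude * t**self.n / (self.t_half**self.n + t**self.n)


def _hill(t, base, amplitude, n, t_half):
    return base + amplitude * t**n / (t_half**n + t**n)


def fit_hill(t: np.ndarray, y: np.ndarray) -> HillFit:
    """Least-squares Hill fit of a saturating recruitment curve.

    Initialization: base = min(y), amplitude = range, t_half = time of
    the half-range crossing, n = 1; bounded so that amplitude and
    t_half stay positive. A non-convergent or degenerate fit (e.g. a
    strictly decreasing series) is returned flagged rather than raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 6:
        return HillFit(*(np.nan,) * 5, ok=False, reason="need at least 6 points")
    if np.any(t < 0):
        return HillFit(*(np.nan,) * 5, ok=False, reason="negative times")
    rng_y = np.ptp(y)
    if rng_y == 0:
        return HillFit(*(np.nan,) * 5, ok=False, reason="constant series")
    base0 = float(y.min())
    amp0 = float(rng_y)
    half = base0 + 0.5 * amp0
    above = np.nonzero(y >= half)[0]
    t_half0 = float(t[above[0]]) if above.size else float(np.median(t))
    t_half0 = max(t_half0, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _hill,
                t,
                y,
                p0=[base0, amp0, 1.0, t_half0],
                bounds=(
                    [-np.inf, 1e-12, 0.05, 1e-9],
                    [np.inf, np.inf, 20.0, max(t.max() * 100, 1.0)],
                ),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        return HillFit(*(np.nan,) * 5, ok=False, reason=f"fit failed: {exc}")
    pred = _hill(t, *popt)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    fit = HillFit(
        base=float(popt[0]),
        amplitude=float(popt[1]),
        n=float(popt[2]),
        t_half=float(popt[3]),
        r_squared=r2,
        ok=True,
    )
    # an increasing Hill curve cannot describe a decreasing series
    if fit.amplitude <= 0 or r2 < 0.2 or fit.t_half > t.max() * 50:
        return HillFit(
            fit.base, fit.amplitude, fit.n, fit.t_half, r2,
            ok=False, reason="degenerate fit (non-saturating or decreasing data)",
        )
    return fit


def correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient R in [-1, 1].

    Raises on unequal lengths, fewer than 3 points, non-finite values or
    zero variance (undefined R).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("correlate needs two equal-length 1D series, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
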