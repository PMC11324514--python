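"""Small synthetic fixtures: kinetics traces, strand/cluster geometry,
cyst cross-sections and analytic shape masks."""

from __future__ import annotations

import numpy as np
from skimage.draw import disk as draw_disk

from ..containers import GroundTruth

__all__ = [
    "generate_kinetics",
    "generate_sted_fixture",
    "generate_cyst_image",
    "generate_shape_fixtures",
]


def _hill(t, base, amplitude, n, t_half):
    return base + amplitude * t**n / (t_half**n + t**n)


def generate_kinetics(
    t_half_list: list[float],
    n_points: int = 60,
    noise_sd: float = 0.05,
    seed: int | None = None,
    duration: float = 60.0,
    base: float = 1.0,
    amplitude: float = 2.0,
    hill_n: float = 2.0,
) -> tuple[np.ndarray, list[np.ndarray], GroundTruth]:
    """Hill-shaped enrichment traces with Gaussian noise.

    One trace per requested half-time, emulating the staggered arrival
    of clients at the junction (fast, intermediate, late). Times are in
    minutes; noise_sd = 0 reproduces the Hill formula exactly.
    """
    for th in t_half_list:
        if th <= 0:
            raise ValueError("t_half values must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    traces = []
    records = []
    for th in t_half_list:
        y = _hill(t, base, amplitude, hill_n, th)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, y.shape)
        traces.append(y)
        records.append(
            {
                "t_half": float(th),
                "base": base,
                "amplitude": amplitude,
                "hill_n": hill_n,
            }
        )
    truth = GroundTruth(
        kind="kinetics",
        seed=seed,
        params={"noise_sd": noise_sd, "n_points": n_points, "duration": duration},
        records=records,
    )
    return t, traces, truth


def generate_sted_fixture(
    n_clusters: int = 979,
    offset_mode: float = 40.0,
    decay_apical: float = 15.0,
    decay_lateral: float = 60.0,
    apical_fraction: float = 0.35,
    strand_length: float = 3000.0,
    strand_amplitude: float = 100.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Strand polyline plus clusters at known signed apical offsets (nm).

    The strand is a gently curved polyline; cluster offsets are drawn
    from an asymmetric two-sided exponential peaked at ``offset_mode``:
    a fraction ``apical_fraction`` of the mass decays quickly on the
    apical side (scale ``decay_apical``), the rest forms the long
    exponential-like tail towards the lateral membrane (scale
    ``decay_lateral``). The density steps up at the mode, so the modal
    histogram bin is well defined. Offsets are applied along the local
    strand normal, with the apical direction +y. A zero-width
    distribution (decay_apical = decay_lateral = 0) places every
    cluster exactly at ``offset_mode``.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    xs = np.linspace(0.0, strand_length, 200)
    ys = strand_amplitude * np.sin(2 * np.pi * xs / strand_length)
    strand = np.column_stack([xs, ys])

    # two-sided exponential around the mode with fixed apical mass
    u = rng.uniform(size=n_clusters)
    offsets = np.full(n_clusters, float(offset_mode))
    if decay_apical > 0 or decay_lateral > 0:
        apical_side = u < apical_fraction
        offsets = np.where(
            apical_side,
            offset_mode + rng.exponential(max(decay_apical, 1e-12), n_clusters),
            offset_mode - rng.exponential(max(decay_lateral, 1e-12), n_clusters),
        )

    # place clusters along local normals (apical = +y for this strand)
    t_par = rng.uniform(0.0, 1.0, n_clusters)
    seg = np.minimum(
        (t_par * (len(xs) - 1)).astype(int), len(xs) - 2
    )
    frac = t_par * (len(xs) - 1) - seg
    p0 = strand[seg]
    p1 = strand[seg + 1]
    base_pts = p0 + frac[:, None] * (p1 - p0)
    tang = p1 - p0
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    flip = normal[:, 1] < 0  # orient normals apically (+y)
    normal[flip] *= -1
    clusters = base_pts + offsets[:, None] * normal

    truth = GroundTruth(
        kind="sted",
        seed=seed,
        params={
            "offset_mode": float(offset_mode),
            "decay_apical": float(decay_apical),
            "decay_lateral": float(decay_lateral),
            "n_clusters": n_clusters,
            "apical_direction": [0.0, 1.0],
        },
        records=[{"offsets": offsets.tolist()}],
    )
    return strand, clusters, truth


def generate_cyst_image(
    leakiness: float,
    image_size: int = 256,
    lumen_radius: float = 50.0,
    cell_ring_width: float = 30.0,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Cross-section of a cyst in a tracer bath: annulus of cells.

    Outside intensity is 1, the lumen carries ``leakiness`` in [0, 1]
    (0 = sealed, 1 = fully leaky), the cell ring is dark. Returns the
    image plus lumen and outside masks (eroded away from the ring by a
    safety margin).
    """
    if not 0.0 <= leakiness <= 1.0:
        raise ValueError("leakiness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    c = image_size / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - c, xx - c)
    r_out = lumen_radius + cell_ring_width
    img = np.ones((image_size, image_size))
    img[r < r_out] = 0.05  # cells exclude the tracer
    img[r < lumen_radius] = leakiness
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    margin = 5.0
    lumen_mask = r < lumen_radius - margin
    outside_mask = r > r_out + margin
    truth = GroundTruth(
        kind="cyst",
        seed=seed,
        params={"leakiness": float(leakiness), "noise_sd": noise_sd},
    )
    return img, lumen_mask, outside_mask, truth


def generate_shape_fixtures(shapes: list) -> list[tuple[np.ndarray, float]]:
    """Rasterized masks with closed-form eccentricities.

    ``shapes`` entries: ``("segment", length)``, ``("disc", radius)`` or
    ``("ellipse", a, b)`` with semi-axes a >= b in pixels. Returns
    (mask, analytic eccentricity) pairs: a segment is the degenerate
    ellipse with e = 1, a disc has e = 0, an ellipse(a, b) has
    e = sqrt(1 - (b/a)^2).
    """
    out = []
    for spec_item in shapes:
        kind = spec_item[0]
        if kind == "segment":
            length = int(spec_item[1])
            mask = np.zeros((3, length + 2), dtype=bool)
            mask[1, 1 : 1 + length] = True
            out.append((mask, 1.0))
        elif kind == "disc":
            radius = int(spec_item[1])
            size = 2 * radius + 5
            mask = np.zeros((size, size), dtype=bool)
            rr, cc = draw_disk((size // 2, size // 2), radius, shape=mask.shape)
            mask[rr, cc] = True
            out.append((mask, 0.0))
        elif kind == "ellipse":
            a, b = float(spec_item[1]), float(spec_item[2])
            if b > a:
                a, b = b, a
            # anti-aliased rasterization: per-pixel coverage fractions,
            # so moment estimates approach the continuum values even for
            # few-pixel shapes
            size = 2 * int(np.ceil(a)) + 5
            ss = 8
            c = size / 2.0
            coords = (np.arange(size * ss) + 0.5) / ss - 0.5
            yy, xx = np.meshgrid(coords, coords, indexing="ij")
            inside = ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
            cover = inside.reshape(size, ss, size, ss).mean(axis=(1, 3))
            out.append((cover, float(np.sqrt(1.0 - (b / a) ** 2))))
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
    return out
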