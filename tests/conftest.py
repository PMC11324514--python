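import numpy as np
import pytest

from prewetbelt import (
    GridGeometry,
    ModelParams,
    build_affinity_landscape,
    evolve,
)

DELTA_EPS_GROWING = 0.43  # relative affinity well above the pinning threshold


@pytest.fixture(scope="session")
def small_geometry():
    return GridGeometry(n_across=48, n_along=96, stripe_halfwidth=4)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def growing_trajectory(small_geometry, default_params):
    """A short seeded run above threshold, shared across tests."""
    affinity = build_affinity_landscape(
        small_geometry,
        eps0=2.4,
        eps_int=DELTA_EPS_GROWING - default_params.mu_bulk,
        eps_nuc=0.6,
        sites=[(small_geometry.center_row, small_geometry.n_along // 2, 6)],
    )
    return evolve(
        None,
        affinity,
        default_params,
        n_steps=3000,
        snapshot_stride=200,
        seed_discs=True,
    )
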