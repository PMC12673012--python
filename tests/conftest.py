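"""Shared fixtures: optics, small dipole grids, and the session-scoped
Mueller-matrix library used by the population and mixture tests."""

from __future__ import annotations

import numpy as np
import pytest

from rbcsim.dda import OpticalParams
from rbcsim.geometry import Sphere, discretize
from rbcsim.populations import LibraryConfig, build_library


@pytest.fixture(scope="session")
def optics() -> OpticalParams:
    return OpticalParams()


@pytest.fixture(scope="session")
def small_sphere_grid(optics):
    """Voxelized 0.3 um sphere at the default spacing (about 1.3k dipoles)."""
    return discretize(Sphere(radius=0.15), optics.spacing(), supersample=4)


@pytest.fixture(scope="session")
def mm_library():
    """Default cached DDA library (built once per session; a few minutes)."""
    return build_library(LibraryConfig())


def rng_orientations(n, seed):
    from rbcsim.orientation import EulerOrientation

    rng = np.random.default_rng(seed)
    return [
        EulerOrientation(
            alpha=float(rng.uniform(0, 360)),
            beta=float(rng.uniform(0, 180)),
            gamma=float(rng.uniform(0, 360)),
        )
        for _ in range(n)
    ]
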