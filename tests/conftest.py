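"""Shared fixtures: small phantom grids, bundles and noiseless DWI series."""

import numpy as np
import pytest

from tractaging import Geometry
from tractaging.phantom import (
    CurveBundleSpec,
    default_scheme,
    eigenvalues_for_fa,
    rasterize_tensor_field,
    simulate_dwi,
)

TRACE = 2.1e-3


@pytest.fixture(scope="session")
def small_grid():
    return Geometry((30, 16, 12), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def straight_spec():
    return CurveBundleSpec(
        centerline=np.array([[8.0, 16.0, 12.0], [52.0, 16.0, 12.0]]),
        radius=4.0, n_streamlines=20, seed_label=10, target_label=1010,
        name="straight",
    )


@pytest.fixture(scope="session")
def arc_grid():
    return Geometry((48, 80, 16), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def arc_spec():
    """Quarter-circle arc of radius 24 mm in the x-y plane (1 mm voxels)."""
    theta = np.linspace(0.0, np.pi / 2, 400)
    pts = np.stack(
        [12.0 + 24.0 * np.sin(theta), 64.0 - 24.0 * np.cos(theta),
         8.0 + 0.0 * theta],
        axis=1,
    )
    return CurveBundleSpec(centerline=pts, radius=4.0, n_streamlines=20,
                           seed_label=11, target_label=1011, name="arc")


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def straight_phantom(small_grid, straight_spec):
    """Noiseless straight-bundle phantom at FA 0.45: (tensors, labels, dwi)."""
    evals = eigenvalues_for_fa(0.45, TRACE)
    tensors, labels = rasterize_tensor_field(straight_spec, small_grid, evals)
    dwi = simulate_dwi(tensors, default_scheme(), s0=1000.0, snr=None)
    return tensors, labels, dwi


@pytest.fixture(scope="session")
def straight_fitted(straight_phantom):
    """(fa, evals, evecs) from the noiseless straight phantom."""
    from tractaging import fit_fa

    _, _, dwi = straight_phantom
    return fit_fa(dwi)
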