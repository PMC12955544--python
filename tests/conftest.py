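import warnings

import pytest

import nemaiq as nq
from nemaiq.phantom import GeometryWarning


@pytest.fixture(scope="session")
def warm_fill():
    # the 99mTc warm fill: 236 / 23.7 kBq/mL
    return nq.PhantomFill("99mTc", 236.0, 23.7)


@pytest.fixture(scope="session")
def cold_fill():
    return nq.PhantomFill("99mTc", 236.0, 0.0)


@pytest.fixture(scope="session")
def warm_spec(warm_fill):
    return nq.default_nema_spec(warm_fill)


@pytest.fixture(scope="session")
def cold_spec(cold_fill):
    return nq.default_nema_spec(cold_fill)


@pytest.fixture(scope="session")
def sim_grid():
    """Simulation grid for projection-domain tests: 4.8-mm voxels,
    in-plane field wide enough that nothing rotates out of view."""
    return nq.VoxelGrid((32, 80, 80), (4.8, 4.8, 4.8))


@pytest.fixture(scope="session")
def tiny_grid():
    """Coarse grid for fast end-to-end runs (10-mm sphere is below the
    2-voxel sampling limit, hence the suppressed warning)."""
    return nq.VoxelGrid((16, 48, 48), (4.8, 6.4, 6.4))


@pytest.fixture(scope="session")
def fine_grid():
    """1-mm grid covering the sphere plane, for analytic-oracle tests."""
    return nq.VoxelGrid((56, 212, 212), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def fine_cold_truth(cold_spec, fine_grid):
    return nq.voxelize(cold_spec, fine_grid, supersample=4)


@pytest.fixture(scope="session")
def fine_warm_truth(warm_spec, fine_grid):
    return nq.voxelize(warm_spec, fine_grid, supersample=4)


@pytest.fixture(scope="session")
def spect_protocol():
    return nq.ScanProtocol()


@pytest.fixture(scope="session")
def noise_free_sweep(warm_spec, spect_protocol, sim_grid):
    """One noise-free iteration sweep (1..32, 4 subsets) shared by the
    convergence-behaviour tests."""
    return nq.iteration_sweep(warm_spec, spect_protocol, sim_grid, seed=None)


@pytest.fixture()
def suppress_geometry_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GeometryWarning)
        yield
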