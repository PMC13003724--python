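import numpy as np
import pytest

from aawss.mesh import cylinder_profile, make_vessel_mesh
from aawss.metrics import WssSeries


@pytest.fixture(scope="session")
def tiny_mesh():
    """Small open tube used as a carrier for analytic signal tests."""
    return make_vessel_mesh(cylinder_profile(0.01), 0.1, n_circ=8, n_axial=8)


@pytest.fixture(scope="session")
def cyl_mesh():
    return make_vessel_mesh(cylinder_profile(0.01), 0.1, n_circ=32, n_axial=32)


def series_from_signal(mesh, times, fx, fy=None, fz=None):
    """Broadcast scalar component signals to every node of a mesh."""
    times = np.asarray(times, dtype=float)
    n = mesh.n_nodes
    tau = np.zeros((len(times), n, 3))
    tau[:, :, 0] = np.asarray(fx, dtype=float)[:, None]
    if fy is not None:
        tau[:, :, 1] = np.asarray(fy, dtype=float)[:, None]
    if fz is not None:
        tau[:, :, 2] = np.asarray(fz, dtype=float)[:, None]
    return WssSeries(mesh=mesh, times=times, tau=tau)


@pytest.fixture(scope="session")
def closed_cycle_times():
    """One cardiac cycle sampled at 0.01 s including both endpoints."""
    return np.linspace(0.0, 1.0, 101)
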