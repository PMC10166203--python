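import numpy as np
import pytest

from retortsim import (
    CanGeometry,
    SolverConfig,
    build_mesh,
    chestnut_puree,
    constant_properties,
    default_can,
)


@pytest.fixture(scope="session")
def puree():
    return chestnut_puree()


@pytest.fixture(scope="session")
def can():
    return default_can()


@pytest.fixture
def coarse_mesh(can):
    return build_mesh(can, nr=12, nz=24)


@pytest.fixture
def coarse_config(coarse_mesh, puree):
    return SolverConfig(mesh=coarse_mesh, properties=puree,
                        mode="convection", dt=2.0)


def conduction_config(nr=12, nz=24, dt=5.0, **kw):
    """Helper: a conduction-mode config on the default can."""
    mesh = build_mesh(default_can(), nr=nr, nz=nz)
    return SolverConfig(mesh=mesh, properties=chestnut_puree(),
                        mode="conduction", dt=dt, **kw)
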