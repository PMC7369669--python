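"""Shared fixtures: default physical parameters, inverse-Hill table, and a
coarse perforated mesh reused across test modules (all generated in-process;
no data files)."""

import numpy as np
import pytest

from oxytrans import transport
from oxytrans.geometry import build_domain, triangulate
from oxytrans.kinetics import ModelParameters, build_inverse_hill


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def table(params):
    return build_inverse_hill(params)


@pytest.fixture(scope="session")
def coarse_mesh():
    """A reduced perforated domain: 0.9 mm square, 8+8 holes, 24 edge
    segments — same structure as the full experiment at ~1/10 the cost."""
    return triangulate(build_domain(side=0.9, n_inlets=8, n_outlets=8), 24, 8)


@pytest.fixture(scope="session")
def unit_square_mesh():
    return triangulate(build_domain(1.0, 0, 0), 8, 8)


@pytest.fixture()
def closed_bc():
    """No-flux Robin data (gamma = delta = 0): the closed configuration."""
    zero = {c: 0.0 for c in transport.CLASSES}
    return transport.BoundaryData(gamma=dict(zero), delta=dict(zero),
                                  phi_b=dict(zero))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
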