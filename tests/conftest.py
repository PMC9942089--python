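"""Shared fixtures: small grids, fixture molecules, a reusable force field."""

import numpy as np
import pytest

from afmsim.dataset import fixture_molecules
from afmsim.elements import default_element_table
from afmsim.geometry import Atom, Molecule, center_in_cell
from afmsim.grids import GridSpec
from afmsim.pipeline import build_force_field


@pytest.fixture(scope="session")
def table():
    return default_element_table()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_molecules(seed=7)


@pytest.fixture(scope="session")
def positives(fixtures):
    return [m for m in fixtures if not (m.name or "").startswith("reject-")]


@pytest.fixture(scope="session")
def halo_ring(fixtures):
    return next(m for m in fixtures if m.name == "halo-aza-ring")


@pytest.fixture(scope="session")
def coarse_spec():
    """64x64x53 grid over the standard 24 A cell: fast but resolved."""
    return GridSpec(spacing=0.375)


@pytest.fixture(scope="session")
def halo_ff(halo_ring, coarse_spec):
    """Force field of the halogenated ring on the coarse grid (reused)."""
    return build_force_field(halo_ring, spec=coarse_spec)


@pytest.fixture
def benzene_like():
    ring = []
    for i in range(6):
        a = 2 * np.pi * i / 6
        ring.append(Atom("C", 1.39 * np.cos(a), 1.39 * np.sin(a), 0.0))
        ring.append(Atom("H", 2.48 * np.cos(a), 2.48 * np.sin(a), 0.0))
    return Molecule(id=241, atoms=tuple(ring), name="benzene")
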