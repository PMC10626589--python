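"""Shared fixtures: analytic toy clusters and small RHF water clusters.

Expensive objects (grids, SCF solutions, fields) are session-scoped; every
fixture is generated programmatically and deterministically.
"""

from __future__ import annotations

import numpy as np
import pytest

from dbmbe.backend import BackendRequest, RhfBackend
from dbmbe.fixtures import (
    GaussianToySpec,
    WaterClusterSpec,
    make_gaussian_toy,
    make_water_cluster,
)
from dbmbe.grid import build_supermolecular_grid
from dbmbe.mbe import InteractionLedger, enumerate_subsystems
from dbmbe.system import subsystem_geometry


@pytest.fixture(scope="session")
def toy3():
    """Gaussian toy trimer with a 3-body energy term + default-level grid."""
    cluster, mock = make_gaussian_toy(
        GaussianToySpec(positions=((0.0, 0.0, 0.0), (4.0, 0.0, 0.0), (1.5, 3.5, 0.0)),
                        charges=(2, 2, 2), c3=0.001)
    )
    grid = build_supermolecular_grid(cluster, 3)
    return cluster, mock, grid


@pytest.fixture(scope="session")
def toy3_fields(toy3):
    cluster, mock, grid = toy3
    fields = {k: mock.density_for(k, grid)
              for k in enumerate_subsystems(cluster.n_fragments, cluster.n_fragments)}
    ledger = InteractionLedger()
    for k in fields:
        ledger.set_total(k, mock.total_energy(k))
    return fields, ledger


@pytest.fixture(scope="session")
def toy5():
    """Five-fragment Gaussian toy on a lighter grid (coefficient identities)."""
    rng = np.random.default_rng(5)
    pos = rng.uniform(-4, 4, size=(5, 3))
    cluster, mock = make_gaussian_toy(
        GaussianToySpec(positions=tuple(map(tuple, pos)), charges=(2, 2, 2, 2, 2),
                        exponents=(1.0, 0.8, 1.2, 0.9, 1.1), c3=0.0005)
    )
    grid = build_supermolecular_grid(cluster, 2)
    fields = {k: mock.density_for(k, grid)
              for k in enumerate_subsystems(5, 5)}
    return cluster, mock, grid, fields


@pytest.fixture(scope="session")
def water1_hf():
    """Single water, built-in RHF in the minimal basis, light grid."""
    cluster = make_water_cluster(WaterClusterSpec(n_waters=1, seed=3))
    backend = RhfBackend()
    grid = build_supermolecular_grid(cluster, 2)
    req = BackendRequest(geometry=subsystem_geometry(cluster, (0,)), basis="sto-3g")
    res = backend._solve(req)
    field = backend.density_on_grid(req, grid, (0,))
    return cluster, grid, res, field


@pytest.fixture(scope="session")
def water3_hf():
    """Water trimer, HF/minimal basis: complete order-3 ledger and fields."""
    cluster = make_water_cluster(WaterClusterSpec(n_waters=3, seed=7))
    backend = RhfBackend()
    grid = build_supermolecular_grid(cluster, 1)
    ledger = InteractionLedger()
    fields = {}
    for key in enumerate_subsystems(3, 3):
        req = BackendRequest(geometry=subsystem_geometry(cluster, key), basis="sto-3g")
        ledger.set_total(key, backend.compute_energy(req))
        fields[key] = backend.density_on_grid(req, grid, key)
    return cluster, grid, backend, ledger, fields


@pytest.fixture(scope="session")
def water4_hf():
    """Four hydrogen-bonded waters, HF/6-31G, order-2 ledger and fields plus
    the supermolecular reference — the reduced-scale headline comparison."""
    cluster = make_water_cluster(WaterClusterSpec(n_waters=4, seed=11))
    backend = RhfBackend()
    grid = build_supermolecular_grid(cluster, 2)
    ledger = InteractionLedger()
    fields = {}
    for key in enumerate_subsystems(4, 2):
        req = BackendRequest(geometry=subsystem_geometry(cluster, key), basis="6-31g")
        ledger.set_total(key, backend.compute_energy(req))
        fields[key] = backend.density_on_grid(req, grid, key)
    sup = backend.compute_energy(
        BackendRequest(geometry=subsystem_geometry(cluster, (0, 1, 2, 3)), basis="6-31g")
    )
    return cluster, grid, backend, ledger, fields, sup
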