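"""Density-based correction: telescoping exactness, term identities, oracles."""

import numpy as np
import pytest

from dbmbe.dbcorr import db_correction, db_mbe_total, mbe_of_functional_term
from dbmbe.fields import ExpandedField, coulomb_energy, nuclear_attraction_energy
from dbmbe.fixtures import GaussianToySpec, make_gaussian_toy
from dbmbe.functionals import FunctionalSpec, functional_energy
from dbmbe.grid import build_supermolecular_grid, integrate
from dbmbe.mbe import (
    InteractionLedger,
    enumerate_subsystems,
    expansion_coefficients,
)


def test_full_order_correction_vanishes(toy3, toy3_fields):
    """At n = N the expanded density equals the supermolecular density and
    every MBE telescopes: all five terms and the total are numerically zero."""
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    c = db_correction(fields, cluster, 3, grid)
    assert abs(c.v_nuc_term) < 1e-8
    assert abs(c.coulomb_term) < 1e-8
    assert c.nn_term == 0.0
    assert abs(c.ts_nonadd) < 1e-8
    assert abs(c.xc_nonadd) < 1e-8
    assert abs(c.total) < 1e-8


def test_single_fragment_correction_is_zero():
    cluster, mock = make_gaussian_toy(GaussianToySpec(positions=((0.0, 0.0, 0.0),)))
    grid = build_supermolecular_grid(cluster, 1)
    fields = {(0,): mock.density_for((0,), grid)}
    c = db_correction(fields, cluster, 1, grid)
    assert abs(c.total) < 1e-10


def test_nn_correction_only_at_first_order(toy3, toy3_fields):
    """E_NN is pairwise additive: its MBE is exact for n >= 2, so the nn term
    survives only at n = 1 (where it is generally nonzero)."""
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    c1 = db_correction(fields, cluster, 1, grid)
    assert c1.nn_term != 0.0
    for n in (2, 3):
        assert db_correction(fields, cluster, n, grid).nn_term == 0.0
    # explicit telescoping of the MBE of E_NN at n = 2
    e_nn_mbe2 = mbe_of_functional_term(fields, cluster, 2, "e_nn", grid)
    assert e_nn_mbe2 == pytest.approx(cluster.nuclear_repulsion(), abs=1e-12)


def test_term_mbe_telescopes_at_full_order(toy3, toy3_fields):
    """At n = N the MBE of each functional term equals the term evaluated on
    the supermolecular density with the full nuclei."""
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    full = fields[(0, 1, 2)]
    spec = FunctionalSpec()
    pairs = [
        ("v_nuc", nuclear_attraction_energy(grid, full, cluster.atoms)),
        ("coulomb", coulomb_energy(grid, full)),
        ("kinetic", functional_energy(grid, full, spec, "kinetic")),
        ("xc", functional_energy(grid, full, spec, "xc")),
        ("e_nn", cluster.nuclear_repulsion()),
    ]
    for term, direct in pairs:
        mbe = mbe_of_functional_term(fields, cluster, 3, term, grid, spec)
        assert mbe == pytest.approx(direct, abs=1e-10), term


def test_coulomb_term_mbe_matches_analytic_pairwise_sum(toy3, toy3_fields):
    """Order-2 MBE of J against an independent evaluation assembled purely
    from the Gaussian closed-form Coulomb integrals."""
    cluster, mock, grid = toy3
    fields, _ledger = toy3_fields
    mbe = mbe_of_functional_term(fields, cluster, 2, "coulomb", grid)
    co = expansion_coefficients(3, 2)
    analytic = sum(c * mock.analytic_coulomb(k) for k, c in co.items())
    assert mbe == pytest.approx(analytic, abs=5e-6)


def test_correction_total_matches_direct_assembly(toy3, toy3_fields):
    """db correction at n=2 equals E_tot[rho^(2)] - MBE_2(E_tot) assembled
    directly (non-recursively) from scratch."""
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    spec = FunctionalSpec()
    co = expansion_coefficients(3, 2)
    ex = ExpandedField([(float(c), fields[k]) for k, c in co.items()])
    e_on_expanded = (
        nuclear_attraction_energy(grid, ex, cluster.atoms)
        + coulomb_energy(grid, ex)
        + functional_energy(grid, ex, spec, "kinetic")
        + functional_energy(grid, ex, spec, "xc")
        + cluster.nuclear_repulsion()
    )
    e_mbe = 0.0
    for key, c in co.items():
        nuclei = [a for i in key for a in cluster.fragments[i].atoms]
        e_mbe += c * (
            nuclear_attraction_energy(grid, fields[key], nuclei)
            + coulomb_energy(grid, fields[key])
            + functional_energy(grid, fields[key], spec, "kinetic")
            + functional_energy(grid, fields[key], spec, "xc")
            + cluster.nuclear_repulsion(keys=key)
        )
    direct = e_on_expanded - e_mbe
    c2 = db_correction(fields, cluster, 2, grid, spec)
    assert c2.total == pytest.approx(direct, abs=1e-10)
    # and the five stored terms sum to the total exactly
    s = c2.v_nuc_term + c2.coulomb_term + c2.nn_term + c2.ts_nonadd + c2.xc_nonadd
    assert c2.total == pytest.approx(s, abs=1e-14)


def test_recursive_and_flattened_routes_agree(toy3, toy3_fields):
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    for n in (1, 2, 3):
        a = db_correction(fields, cluster, n, grid, route="recursive")
        b = db_correction(fields, cluster, n, grid, route="flattened")
        assert a.total == pytest.approx(b.total, abs=1e-10)
        assert a.coulomb_term == pytest.approx(b.coulomb_term, abs=1e-10)


def test_db_total_at_full_order_equals_supermolecular(toy3, toy3_fields):
    cluster, mock, grid = toy3
    fields, ledger = toy3_fields
    sup = mock.total_energy((0, 1, 2))
    res = db_mbe_total(ledger, fields, cluster, 3, grid, supermolecular=sup)
    assert res.eb_energy == pytest.approx(sup, abs=1e-12)
    assert res.db_energy == pytest.approx(sup, abs=1e-8)
    assert [k for k, _eb, _db in res.per_order] == [1, 2, 3]


def test_db_equals_eb_plus_correction(toy3, toy3_fields):
    cluster, _mock, grid = toy3
    fields, ledger = toy3_fields
    res = db_mbe_total(ledger, fields, cluster, 2, grid)
    assert res.db_energy == res.eb_energy + res.correction.total


def test_missing_field_is_named(toy3, toy3_fields):
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    partial = {k: v for k, v in fields.items() if k != (1, 2)}
    with pytest.raises(KeyError, match=r"\(1, 2\)"):
        db_correction(partial, cluster, 2, grid)
    with pytest.raises(ValueError, match="order"):
        db_correction(fields, cluster, 4, grid)


def test_electron_count_conservation_all_orders(toy5):
    """int rho^(n) equals the total electron count for every 1 <= n <= N:
    the coefficient identity carried through quadrature."""
    cluster, _mock, grid, fields = toy5
    total = cluster.total_electrons
    for n in range(1, 6):
        co = expansion_coefficients(5, n)
        ex = ExpandedField([(float(c), fields[k]) for k, c in co.items()])
        assert integrate(grid, ex.density) == pytest.approx(total, abs=5e-4)
        assert ex.electron_count == pytest.approx(total, abs=1e-10)
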