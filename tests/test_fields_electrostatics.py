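"""Electrostatic energy terms on the grid against erf-form closed expressions."""

import numpy as np
import pytest
from scipy.special import erf

from dbmbe.fields import (
    ExpandedField,
    FieldOnGrid,
    coulomb_energy,
    coulomb_energy_pairwise,
    nuclear_attraction_energy,
)
from dbmbe.fixtures import GaussianToySpec, make_gaussian_toy
from dbmbe.grid import build_supermolecular_grid, integrate
from dbmbe.mbe import enumerate_subsystems, expansion_coefficients
from dbmbe.system import Atom

GRID_TOL = 1e-6  # electrostatics accuracy target at the default grid level


def test_unit_gaussian_nuclear_attraction(toy3):
    """For a unit Gaussian (alpha=1) on a Z=1-like center the self term is
    -Z q 2 sqrt(alpha/pi); cross terms follow erf(sqrt(alpha) R)/R."""
    cluster, mock, grid = toy3
    f0 = mock.density_for((0,), grid)
    own = nuclear_attraction_energy(grid, f0, cluster.fragments[0].atoms)
    assert own == pytest.approx(mock.analytic_nuclear_attraction((0,), (0,)), abs=GRID_TOL)
    # full-cluster nuclei minus own nuclei isolates the cross attraction
    full = nuclear_attraction_energy(grid, f0, cluster.atoms)
    cross = full - own
    expected = mock.analytic_nuclear_attraction((0,), (1, 2))
    assert cross == pytest.approx(expected, abs=GRID_TOL)
    # erf closed form spelled out for one pair
    q0 = mock.charges_e[0]
    Z1 = cluster.fragments[1].nuclear_charge
    R = np.linalg.norm(cluster.fragments[1].atoms[0].position
                       - cluster.fragments[0].atoms[0].position)
    assert mock.analytic_nuclear_attraction((0,), (1,)) == pytest.approx(
        -Z1 * q0 * erf(np.sqrt(mock.alphas[0]) * R) / R, abs=1e-14
    )


def test_zero_density_gives_zero(toy3):
    cluster, _mock, grid = toy3
    z = FieldOnGrid(subsystem=(0,), density=np.zeros(grid.size),
                    gradient=np.zeros((grid.size, 3)),
                    coulomb_potential=np.zeros(grid.size), electron_count=0.0)
    assert nuclear_attraction_energy(grid, z, cluster.atoms) == 0.0
    assert coulomb_energy(grid, z) == 0.0


def test_gaussian_coulomb_self_and_cross(toy3):
    cluster, mock, grid = toy3
    f01 = mock.density_for((0, 1), grid)
    assert coulomb_energy(grid, f01) == pytest.approx(mock.analytic_coulomb((0, 1)),
                                                      abs=GRID_TOL)
    # cross term alone: J(dimer) - J(mono) - J(mono) = q^2 erf(sqrt(a/2) R)/R
    cross = (mock.analytic_coulomb((0, 1)) - mock.analytic_coulomb((0,))
             - mock.analytic_coulomb((1,)))
    a, q = mock.alphas[0], mock.charges_e[0]
    R = np.linalg.norm(cluster.fragments[1].atoms[0].position
                       - cluster.fragments[0].atoms[0].position)
    assert cross == pytest.approx(q * q * erf(np.sqrt(a / 2.0) * R) / R, abs=1e-14)
    f0 = mock.density_for((0,), grid)
    f1 = mock.density_for((1,), grid)
    grid_cross = (coulomb_energy(grid, f01) - coulomb_energy(grid, f0)
                  - coulomb_energy(grid, f1))
    assert grid_cross == pytest.approx(cross, abs=GRID_TOL)


def test_single_term_expanded_field_is_identity(toy3):
    cluster, mock, grid = toy3
    f = mock.density_for((0, 1), grid)
    ex = ExpandedField([(1.0, f)])
    assert coulomb_energy(grid, ex) == coulomb_energy(grid, f)
    assert nuclear_attraction_energy(grid, ex, cluster.atoms) == pytest.approx(
        nuclear_attraction_energy(grid, f, cluster.atoms), rel=1e-15
    )


def test_linear_functional_accumulation_exactness(toy3, toy3_fields):
    """V_nuc and the electron count on an ExpandedField equal the
    coefficient-weighted sums of per-term evaluations to 1e-12 relative."""
    cluster, mock, grid = toy3
    fields, _ledger = toy3_fields
    co = expansion_coefficients(3, 2)
    ex = ExpandedField([(float(c), fields[k]) for k, c in co.items()])
    v_acc = nuclear_attraction_energy(grid, ex, cluster.atoms)
    v_sum = sum(c * nuclear_attraction_energy(grid, fields[k], cluster.atoms)
                for k, c in co.items())
    assert v_acc == pytest.approx(v_sum, rel=1e-12)
    n_acc = integrate(grid, ex.density)
    n_sum = sum(c * integrate(grid, fields[k].density) for k, c in co.items())
    assert n_acc == pytest.approx(n_sum, rel=1e-12)


def test_coulomb_accumulated_vs_pairwise(toy3, toy3_fields):
    """The accumulated-potential J equals the pairwise double-sum J."""
    cluster, _mock, grid = toy3
    fields, _ledger = toy3_fields
    for order in (1, 2, 3):
        co = expansion_coefficients(3, order)
        ex = ExpandedField([(float(c), fields[k]) for k, c in co.items()])
        assert coulomb_energy(grid, ex) == pytest.approx(
            coulomb_energy_pairwise(grid, ex), abs=1e-10
        )


def test_potential_density_symmetry(toy3):
    """int rho_a v_b = int rho_b v_a on a shared fine grid (the residual is
    pure quadrature error, so it vanishes with grid refinement)."""
    cluster, mock, _grid = toy3
    grid = build_supermolecular_grid(cluster, 5)
    fa = mock.density_for((0,), grid)
    fb = mock.density_for((1, 2), grid)
    ab = integrate(grid, fa.density * fb.coulomb_potential)
    ba = integrate(grid, fb.density * fa.coulomb_potential)
    assert ab == pytest.approx(ba, abs=1e-8)


def test_missing_potential_is_reported(toy3):
    _cluster, mock, grid = toy3
    f = mock.density_for((0,), grid)
    bare = FieldOnGrid(subsystem=(1,), density=f.density, gradient=f.gradient,
                       coulomb_potential=None, electron_count=2.0)
    ex = ExpandedField([(1.0, f), (-1.0, bare)])
    with pytest.raises(ValueError, match="Coulomb potential"):
        _ = ex.coulomb_potential
    with pytest.raises(ValueError, match="Coulomb potential"):
        coulomb_energy_pairwise(grid, ex)


def test_nuclear_cusp_exclusion_never_nan():
    """A degenerate grid point sitting exactly on a nucleus is excluded from
    that nucleus' -Z/r term instead of producing NaN/inf."""
    from dbmbe.grid import IntegrationGrid
    from dbmbe.fields import nuclear_potential_values

    pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    grid = IntegrationGrid(points=pts, weights=np.array([1.0, 1.0]), level=0)
    v = nuclear_potential_values(grid, [Atom("O", np.zeros(3))])
    assert np.all(np.isfinite(v))
    assert v[0] == 0.0 and v[1] == pytest.approx(-8.0)
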