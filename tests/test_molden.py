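"""Molden ingestion: round-trips, dialects, and the d-shell normalization fix."""

import numpy as np
import pytest

from dbmbe.backend import field_from_wavefunction
from dbmbe.gaussian.basis import BasisShell, MoleculeBasis
from dbmbe.gaussian.molden import read_molden, write_molden
from dbmbe.gaussian.scf import rhf
from dbmbe.grid import build_supermolecular_grid, integrate
from dbmbe.fixtures import WaterClusterSpec, make_water_cluster


def density_at(basis, mo_coeff, mo_occ, points):
    ao = basis.ao_values(points)
    C = basis.cart_from_func.T @ mo_coeff[:, mo_occ > 0]
    psi = ao @ C
    return np.einsum("i,mi,mi->m", mo_occ[mo_occ > 0], psi, psi)


@pytest.fixture(scope="module")
def water_wfn():
    cluster = make_water_cluster(WaterClusterSpec(n_waters=1, seed=9))
    atoms = [(a.element, a.nuclear_charge, a.position) for a in cluster.atoms]
    return rhf(atoms, "6-31g")


def test_roundtrip_density_identity(tmp_path, water_wfn):
    """Write standard Molden, re-read: identical density at 100 random points
    to 1e-12."""
    res = water_wfn
    path = tmp_path / "w.molden"
    shell_atom = []
    for si, sh in enumerate(res.basis.shells):
        for ai, (_el, _z, pos) in enumerate(res.atoms):
            if np.allclose(sh.center, pos):
                shell_atom.append(ai)
                break
    write_molden(path, res.atoms, res.basis.shells, shell_atom,
                 res.mo_coeff, res.mo_occ, res.mo_energy)
    data = read_molden(path)
    rng = np.random.default_rng(0)
    pts = rng.uniform(-3, 3, size=(100, 3))
    rho_orig = density_at(res.basis, res.mo_coeff, res.mo_occ, pts)
    rho_back = density_at(data.molecule_basis(), data.mo_coeff, data.mo_occ, pts)
    assert np.max(np.abs(rho_orig - rho_back)) < 1e-12
    assert data.electron_count == pytest.approx(10.0)


def test_reimported_field_matches_direct_backend(tmp_path, water_wfn):
    """The full field pipeline is source-agnostic: Molden re-import yields
    the same density/potential as the direct engine route (1e-10)."""
    res = water_wfn
    path = tmp_path / "w.molden"
    shell_atom = [0] * 5 + [1] * 2 + [2] * 2  # O: 5 shells, H: 2 each (6-31G)
    write_molden(path, res.atoms, res.basis.shells, shell_atom,
                 res.mo_coeff, res.mo_occ, res.mo_energy)
    data = read_molden(path)
    from dbmbe.system import Atom
    grid = build_supermolecular_grid([Atom(el, pos) for el, _z, pos in res.atoms], 1)
    f_direct = field_from_wavefunction(res.basis, res.mo_coeff, res.mo_occ, grid)
    f_molden = field_from_wavefunction(data.molecule_basis(), data.mo_coeff,
                                       data.mo_occ, grid)
    assert np.max(np.abs(f_direct.density - f_molden.density)) < 1e-10
    assert np.max(np.abs(f_direct.coulomb_potential - f_molden.coulomb_potential)) < 1e-8


def _d_shell_wavefunction():
    """Synthetic one-orbital wavefunction with an s and a spherical d shell."""
    center = np.zeros(3)
    shells = [
        BasisShell(0, center, np.array([0.9, 0.3]), np.array([0.4, 0.7])),
        BasisShell(2, center, np.array([0.8]), np.array([1.0]), spherical=True),
    ]
    basis = MoleculeBasis(shells)
    C = np.zeros((basis.nao, 1))
    C[0] = 0.6   # s
    C[1] = 0.5   # d m=0
    C[3] = 0.4   # d m=-1
    # normalize against the overlap so occupations integrate cleanly
    from dbmbe.gaussian.integrals import IntegralEngine

    S_cart = IntegralEngine(basis).overlap_kinetic()[0]
    T = basis.cart_from_func
    S = T @ S_cart @ T.T
    C /= np.sqrt((C.T @ S @ C).item())
    occ = np.array([2.0])
    atoms = [("He", 2, center)]
    return atoms, basis, C, occ


def test_orca_dialect_fix_roundtrip(tmp_path):
    """The same wavefunction exported in standard vs Orca dialect reads back
    to the identical density when the documented d-coefficient rescaling is
    applied — and to a measurably different one when it is not."""
    atoms, basis, C, occ = _d_shell_wavefunction()
    std = tmp_path / "std.molden"
    orca = tmp_path / "orca.molden"
    write_molden(std, atoms, basis.shells, [0, 0], C, occ, dialect="standard")
    write_molden(orca, atoms, basis.shells, [0, 0], C, occ, dialect="orca")
    d_std = read_molden(std, dialect="standard")
    d_fix = read_molden(orca, dialect="orca")
    rng = np.random.default_rng(1)
    pts = rng.uniform(-2, 2, size=(100, 3))
    rho_std = density_at(d_std.molecule_basis(), d_std.mo_coeff, d_std.mo_occ, pts)
    rho_fix = density_at(d_fix.molecule_basis(), d_fix.mo_coeff, d_fix.mo_occ, pts)
    assert np.max(np.abs(rho_std - rho_fix)) < 1e-12
    # regression guard: reading the orca file as standard diverges
    d_raw = read_molden(orca, dialect="standard", validate=False)
    rho_raw = density_at(d_raw.molecule_basis(), d_raw.mo_coeff, d_raw.mo_occ, pts)
    assert np.max(np.abs(rho_std - rho_raw)) > 1e-4
    # ... and the electron-count validation catches it
    with pytest.raises(ValueError, match="dialect"):
        read_molden(orca, dialect="standard")


def test_molden_error_cases(tmp_path, water_wfn):
    res = water_wfn
    path = tmp_path / "w.molden"
    shell_atom = [0] * 5 + [1] * 2 + [2] * 2
    write_molden(path, res.atoms, res.basis.shells, shell_atom,
                 res.mo_coeff, res.mo_occ)
    text = path.read_text()
    bad = tmp_path / "bad.molden"
    bad.write_text(text.replace(" s ", " h ", 1))
    with pytest.raises(ValueError, match="unknown shell label"):
        read_molden(bad)
    with pytest.raises(ValueError, match="dialect"):
        read_molden(path, dialect="gaussian")
    bad2 = tmp_path / "noatoms.molden"
    bad2.write_text("[Molden Format]\n[GTO]\n")
    with pytest.raises(ValueError, match="Atoms"):
        read_molden(bad2)
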