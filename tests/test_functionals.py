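"""Semilocal functionals: exact limits, scaling, and an independent
arbitrary-precision implementation as cross-check oracle."""

import mpmath as mp
import numpy as np
import pytest

from dbmbe.fields import FieldOnGrid
from dbmbe.functionals import (
    C_TF,
    FunctionalSpec,
    functional_energy,
    kinetic_energy_density,
    xc_energy_density,
)
from dbmbe.grid import build_supermolecular_grid, integrate
from dbmbe.system import Atom, ClusterSystem, Fragment

mp.mp.dps = 30


# --- independent scalar implementations (mpmath, coded from the published
#     parameterizations, structurally unrelated to the vectorized path) ---

def pw91k_mp(rho, sigma):
    rho, sigma = mp.mpf(rho), mp.mpf(sigma)
    ctf = mp.mpf(3) / 10 * (3 * mp.pi**2) ** (mp.mpf(2) / 3)
    s = mp.sqrt(sigma) / (2 * (3 * mp.pi**2) ** (mp.mpf(1) / 3) * rho ** (mp.mpf(4) / 3))
    a, b = mp.mpf("0.093907"), mp.mpf("76.320")
    c, d = mp.mpf("0.26608"), mp.mpf("0.0809615")
    e, f = mp.mpf(100), mp.mpf("0.57767e-4")
    x = a * s * mp.asinh(b * s)
    F = (1 + x + (c - d * mp.e ** (-e * s**2)) * s**2) / (1 + x + f * s**4)
    return ctf * rho ** (mp.mpf(5) / 3) * F


def pbe_xc_mp(rho, sigma):
    rho, sigma = mp.mpf(rho), mp.mpf(sigma)
    third = mp.mpf(1) / 3
    kf = (3 * mp.pi**2 * rho) ** third
    # exchange
    eps_x = -mp.mpf(3) / 4 * (3 / mp.pi) ** third * rho**third
    s = mp.sqrt(sigma) / (2 * kf * rho)
    kappa, mu = mp.mpf("0.804"), mp.mpf("0.2195149727645171")
    fx = 1 + kappa - kappa / (1 + mu * s**2 / kappa)
    # PW92 correlation, unpolarized
    rs = (3 / (4 * mp.pi * rho)) ** third
    A0, a1 = mp.mpf("0.031091"), mp.mpf("0.21370")
    b1, b2, b3, b4 = (mp.mpf(x) for x in ("7.5957", "3.5876", "1.6382", "0.49294"))
    q = 2 * A0 * (b1 * mp.sqrt(rs) + b2 * rs + b3 * rs ** mp.mpf("1.5") + b4 * rs**2)
    eps_c = -2 * A0 * (1 + a1 * rs) * mp.log(1 + 1 / q)
    # PBE gradient correction H
    gamma = (1 - mp.log(2)) / mp.pi**2
    beta = mp.mpf("0.06672455060314922")
    ks = mp.sqrt(4 * kf / mp.pi)
    t2 = (mp.sqrt(sigma) / (2 * ks * rho)) ** 2
    Ac = beta / gamma / (mp.e ** (-eps_c / gamma) - 1)
    H = gamma * mp.log(1 + beta / gamma * t2 * (1 + Ac * t2) / (1 + Ac * t2 + (Ac * t2) ** 2))
    return rho * (eps_x * fx + eps_c + H)


def test_thomas_fermi_recovery_at_zero_gradient():
    """F(s) -> 1 as s -> 0: at rho=1 the PW91k energy density is C_TF."""
    val = kinetic_energy_density(np.array([1.0]), np.array([0.0]))[0]
    assert val == pytest.approx(C_TF, rel=1e-14)
    assert C_TF == pytest.approx(2.8712340001881918, rel=1e-12)
    # s = 1e-8 regime
    tiny_sigma = (1e-8 * 2 * (3 * np.pi**2) ** (1 / 3)) ** 2
    val = kinetic_energy_density(np.array([1.0]), np.array([tiny_sigma]))[0]
    assert val == pytest.approx(C_TF, rel=1e-16 + 1e-12)


def test_vanishing_density_gives_zero():
    assert kinetic_energy_density(np.array([0.0]), np.array([0.0]))[0] == 0.0
    assert xc_energy_density(np.array([0.0]), np.array([0.0]))[0] == 0.0
    # below clamp threshold too
    assert kinetic_energy_density(np.array([1e-12]), np.array([1.0]))[0] == 0.0
    assert xc_energy_density(np.array([1e-12]), np.array([1.0]))[0] == 0.0


def test_pbe_reduces_to_lda_at_zero_gradient():
    rho = np.array([0.3, 1.0, 2.5])
    zero = np.zeros(3)
    pbe = xc_energy_density(rho, zero, FunctionalSpec(xc_name="PBE"))
    lda = xc_energy_density(rho, zero, FunctionalSpec(xc_name="LDA"))
    assert pbe == pytest.approx(lda, rel=1e-14)
    # Slater exchange anchor at rho=1 (correlation subtracted via oracle)
    ex_only = -0.75 * (3.0 / np.pi) ** (1.0 / 3.0)
    corr = float(pbe_xc_mp(1.0, 0.0)) - ex_only
    assert lda[1] == pytest.approx(ex_only + corr, rel=1e-12)


def test_cross_implementation_agreement_1000_points():
    """Vectorized production path vs independent mpmath implementation at
    1000 random (rho, sigma) points, 1e-10 relative."""
    rng = np.random.default_rng(2024)
    rho = 10.0 ** rng.uniform(-6, 1, size=1000)
    s_red = rng.uniform(0.0, 5.0, size=1000)
    sigma = (s_red * 2.0 * (3 * np.pi**2) ** (1 / 3) * rho ** (4 / 3)) ** 2
    ts = kinetic_energy_density(rho, sigma)
    xc = xc_energy_density(rho, sigma)
    for i in range(1000):
        ref_t = float(pw91k_mp(rho[i], sigma[i]))
        ref_x = float(pbe_xc_mp(rho[i], sigma[i]))
        assert ts[i] == pytest.approx(ref_t, rel=1e-10)
        assert xc[i] == pytest.approx(ref_x, rel=1e-10)


def test_kinetic_scaling_lambda_squared():
    """Under rho -> l^3 rho(l r), T_s scales as l^2 (within quadrature error)."""
    sys1 = ClusterSystem(fragments=[Fragment(0, [Atom("He", np.zeros(3))])])
    grid = build_supermolecular_grid(sys1, 3)

    def gaussian_field(alpha):
        d = grid.points
        r2 = np.einsum("ij,ij->i", d, d)
        rho = 2.0 * (alpha / np.pi) ** 1.5 * np.exp(-alpha * r2)
        grad = -2.0 * alpha * rho[:, None] * d
        return FieldOnGrid(subsystem=(0,), density=rho, gradient=grad,
                           coulomb_potential=None, electron_count=2.0)

    lam = 1.3
    t1 = functional_energy(grid, gaussian_field(1.0), which="kinetic")
    t2 = functional_energy(grid, gaussian_field(lam**2), which="kinetic")
    assert t2 / t1 == pytest.approx(lam**2, rel=1e-6)


def test_gga_kinetic_tracks_orbital_kinetic_on_water(water1_hf):
    """PW91k approximates the exact orbital kinetic energy of a water HF
    density to within the known ~10% GGA accuracy scale."""
    from dbmbe.gaussian.integrals import IntegralEngine

    _cluster, grid, res, field = water1_hf
    eng = IntegralEngine(res.basis)
    _S, T = eng.overlap_kinetic()
    t_exact = float(np.einsum("pq,pq->", res.density_matrix, T))
    t_gga = functional_energy(grid, field, which="kinetic")
    assert abs(t_gga - t_exact) / t_exact < 0.10


def test_functional_energy_contract(toy3):
    _cluster, mock, grid = toy3
    f = mock.density_for((0,), grid)
    zero = FieldOnGrid(subsystem=(0,), density=np.zeros(grid.size),
                       gradient=np.zeros((grid.size, 3)),
                       coulomb_potential=None, electron_count=0.0)
    assert functional_energy(grid, zero, which="kinetic") == 0.0
    from dbmbe.fields import ExpandedField

    ex = ExpandedField([(1.0, f)])
    assert functional_energy(grid, ex, which="xc") == pytest.approx(
        functional_energy(grid, f, which="xc"), rel=1e-14
    )
    with pytest.raises(ValueError, match="unknown functional term"):
        functional_energy(grid, f, which="banana")
    with pytest.raises(ValueError):
        FunctionalSpec(kinetic_name="nope")
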