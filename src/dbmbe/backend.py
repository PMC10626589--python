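"""Backends supplying subsystem energies and densities.

Three interchangeable sources implement the same contract:

* :class:`RhfBackend` — the built-in restricted Hartree-Fock engine
  (energies, densities, gradients, analytic Coulomb potentials).
* :class:`MoldenBackend` — wavefunctions imported from Molden files written
  by any quantum-chemistry program (single-determinant densities per
  rho(r) = 2 sum_i |phi_i(r)|^2); energies are supplied alongside, so an
  expansion can pair e.g. coupled-cluster energies with HF densities.
* :class:`GaussianMockBackend` — an analytic toy: each fragment is one
  normalized s-Gaussian charge cloud and the total energy is a declared
  pairwise (+ optional triple-dipole-like) potential, so every expansion
  quantity has a closed form.  Makes the whole pipeline testable with no
  engine at all.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .fields import FieldOnGrid
from .gaussian.molden import MoldenData, read_molden
from .gaussian.scf import RhfResult, rhf
from .gaussian.integrals import IntegralEngine
from .grid import IntegrationGrid
from .mbe import SubsystemKey
from .system import ClusterSystem, Fragment

__all__ = [
    "BackendRequest",
    "RhfBackend",
    "GaussianMockBackend",
    "MoldenBackend",
    "field_from_wavefunction",
]


@dataclass(frozen=True)
class BackendRequest:
    """What to compute for one subsystem."""

    geometry: Fragment
    method: str = "HF"
    basis: str = "6-31g"
    want_density: bool = False
    density_method: str | None = None  # defaults to ``method``

    @property
    def charge(self) -> int:
        return self.geometry.charge

    @property
    def multiplicity(self) -> int:
        return self.geometry.spin_multiplicity


def _geometry_key(frag: Fragment, method: str, basis: str) -> str:
    h = hashlib.sha256()
    for a in frag.atoms:
        h.update(a.element.encode())
        h.update(np.ascontiguousarray(a.position).tobytes())
    h.update(f"{frag.charge}|{method}|{basis}".encode())
    return h.hexdigest()[:24]


def field_from_wavefunction(
    basis,
    mo_coeff: np.ndarray,
    mo_occ: np.ndarray,
    grid: IntegrationGrid,
    subsystem: SubsystemKey = (),
    engine: IntegralEngine | None = None,
    with_potential: bool = True,
) -> FieldOnGrid:
    """Sample rho, grad rho and v_Coul of a single-determinant wavefunction.

    The density comes from the occupied orbitals, the Coulomb potential from
    analytic integrals of the Coulomb operator over the basis.
    """
    occ_mask = mo_occ > 0
    C_func = mo_coeff[:, occ_mask]
    occ = mo_occ[occ_mask]
    C_cart = basis.cart_from_func.T @ C_func
    ao, ao_grad = basis.ao_values(grid.points, deriv=True)
    psi = ao @ C_cart
    rho = np.einsum("i,mi,mi->m", occ, psi, psi)
    grad = np.stack(
        [2.0 * np.einsum("i,mi,mi->m", occ, ao_grad[ax] @ C_cart, psi) for ax in range(3)],
        axis=1,
    )
    v = None
    if with_potential:
        if engine is None:
            engine = IntegralEngine(basis)
        dm_func = (mo_coeff * mo_occ) @ mo_coeff.T
        dm_cart = basis.density_matrix_cart(dm_func)
        v = engine.coulomb_potential(dm_cart, grid.points)
    return FieldOnGrid(
        subsystem=subsystem,
        density=rho,
        gradient=grad,
        coulomb_potential=v,
        electron_count=float(occ.sum()),
    )


class RhfBackend:
    """Built-in RHF engine behind the backend contract."""

    name = "rhf"

    def __init__(self, conv_tol: float = 1e-10):
        self.conv_tol = conv_tol
        self._cache: dict[str, RhfResult] = {}
        self.calls = 0  # actual SCF solves (cache misses)

    def _solve(self, request: BackendRequest) -> RhfResult:
        if request.method.upper() not in ("HF", "RHF"):
            raise ValueError(
                f"built-in engine only provides HF, requested {request.method!r}"
            )
        key = _geometry_key(request.geometry, "HF", request.basis)
        if key not in self._cache:
            atoms = [(a.element, a.nuclear_charge, a.position) for a in request.geometry.atoms]
            self._cache[key] = rhf(
                atoms, request.basis, charge=request.charge, conv_tol=self.conv_tol
            )
            self.calls += 1
        return self._cache[key]

    def compute_energy(self, request: BackendRequest) -> float:
        return self._solve(request).energy

    def density_on_grid(
        self, request: BackendRequest, grid: IntegrationGrid, subsystem: SubsystemKey = ()
    ) -> FieldOnGrid:
        res = self._solve(request)
        eng = IntegralEngine(res.basis)
        return field_from_wavefunction(
            res.basis, res.mo_coeff, res.mo_occ, grid, subsystem, engine=eng
        )


class MoldenBackend:
    """Subsystem wavefunctions from Molden files plus a total-energy table.

    ``sources`` maps subsystem keys to ``(molden_path, total_energy)``;
    ``dialect`` selects the standard or Orca flavor of the format.
    """

    name = "molden"

    def __init__(self, sources: dict[SubsystemKey, tuple[str, float]], dialect: str = "standard"):
        self.sources = dict(sources)
        self.dialect = dialect
        self._cache: dict[SubsystemKey, MoldenData] = {}

    def compute_energy_for(self, key: SubsystemKey) -> float:
        if key not in self.sources:
            raise KeyError(f"no Molden source registered for subsystem {key}")
        return self.sources[key][1]

    def density_for(self, key: SubsystemKey, grid: IntegrationGrid) -> FieldOnGrid:
        if key not in self.sources:
            raise KeyError(f"no Molden source registered for subsystem {key}")
        if key not in self._cache:
            self._cache[key] = read_molden(self.sources[key][0], dialect=self.dialect)
        data = self._cache[key]
        basis = data.molecule_basis()
        return field_from_wavefunction(
            basis, data.mo_coeff, data.mo_occ, grid, subsystem=key
        )


@dataclass
class GaussianMockBackend:
    """Analytic toy backend over single-Gaussian fragments.

    Fragment I is a normalized s-Gaussian density of ``q_I`` electrons with
    exponent ``alpha_I`` centered on its (single) nucleus.  The declared
    total energy of a subsystem S is

        E_S = sum_{I in S} e_I + sum_{I<J} A exp(-B R_IJ) + sum_{I<J<K} c3 / (R_IJ R_JK R_IK)

    so interaction energies, truncated expansions and all electrostatic
    quantities (erf closed forms) are exactly computable.
    """

    cluster: ClusterSystem
    alphas: np.ndarray          # per fragment
    charges_e: np.ndarray       # electrons q_I per fragment
    e_mono: np.ndarray          # declared monomer energies e_I
    pair_A: float = -0.01
    pair_B: float = 0.5
    c3: float = 0.0

    name = "gaussian-mock"

    def __post_init__(self):
        n = self.cluster.n_fragments
        for arr in ("alphas", "charges_e", "e_mono"):
            v = np.asarray(getattr(self, arr), dtype=float)
            if len(v) != n:
                raise ValueError(f"{arr} must have one entry per fragment")
            setattr(self, arr, v)

    def _center(self, i: int) -> np.ndarray:
        return self.cluster.fragments[i].atoms[0].position

    def total_energy(self, key: SubsystemKey) -> float:
        e = float(sum(self.e_mono[i] for i in key))
        for ii, i in enumerate(key):
            for j in key[ii + 1:]:
                r = np.linalg.norm(self._center(i) - self._center(j))
                e += self.pair_A * np.exp(-self.pair_B * r)
        if self.c3 != 0.0:
            for ii, i in enumerate(key):
                for jj in range(ii + 1, len(key)):
                    j = key[jj]
                    for k in key[jj + 1:]:
                        rij = np.linalg.norm(self._center(i) - self._center(j))
                        rjk = np.linalg.norm(self._center(j) - self._center(k))
                        rik = np.linalg.norm(self._center(i) - self._center(k))
                        e += self.c3 / (rij * rjk * rik)
        return e

    # --- closed-form fields ---

    def density_for(self, key: SubsystemKey, grid: IntegrationGrid) -> FieldOnGrid:
        pts = grid.points
        rho = np.zeros(grid.size)
        grad = np.zeros((grid.size, 3))
        v = np.zeros(grid.size)
        for i in key:
            a, q = self.alphas[i], self.charges_e[i]
            d = pts - self._center(i)
            r2 = np.einsum("ij,ij->i", d, d)
            g = q * (a / np.pi) ** 1.5 * np.exp(-a * r2)
            rho += g
            grad += -2.0 * a * g[:, None] * d
            r = np.sqrt(r2)
            small = r < 1e-12
            rs = np.where(small, 1.0, r)
            vi = q * erf(np.sqrt(a) * rs) / rs
            vi[small] = q * 2.0 * np.sqrt(a / np.pi)
            v += vi
        return FieldOnGrid(
            subsystem=key, density=rho, gradient=grad, coulomb_potential=v,
            electron_count=float(sum(self.charges_e[i] for i in key)),
        )

    # --- analytic oracles used by the tests ---

    def analytic_coulomb(self, key: SubsystemKey) -> float:
        """J[rho_S] in closed form (Gaussian self + cross terms)."""
        J = 0.0
        for ii, i in enumerate(key):
            a, q = self.alphas[i], self.charges_e[i]
            J += 0.5 * q * q * np.sqrt(2.0 * a / np.pi)
            for j in key[ii + 1:]:
                b, qj = self.alphas[j], self.charges_e[j]
                r = np.linalg.norm(self._center(i) - self._center(j))
                mu = a * b / (a + b)
                J += q * qj * erf(np.sqrt(mu) * r) / r
        return float(J)

    def analytic_nuclear_attraction(self, key: SubsystemKey, nuclei_key: SubsystemKey) -> float:
        """V_nuc of the density of ``key`` in the field of ``nuclei_key``'s nuclei."""
        V = 0.0
        for i in key:
            a, q = self.alphas[i], self.charges_e[i]
            for j in nuclei_key:
                Z = self.cluster.fragments[j].nuclear_charge
                r = np.linalg.norm(self._center(i) - self._center(j))
                if r < 1e-12:
                    V -= Z * q * 2.0 * np.sqrt(a / np.pi)
                else:
                    V -= Z * q * erf(np.sqrt(a) * r) / r
        return float(V)
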