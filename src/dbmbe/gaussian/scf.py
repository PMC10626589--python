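"""Restricted Hartree-Fock for closed-shell molecules (built-in engine).

A deliberately compact RHF: core-Hamiltonian guess, DIIS-accelerated SCF,
full in-memory two-electron tensor.  Intended for the small fragment
calculations of a many-body expansion (tens of basis functions), not for
production electronic structure.  One-electron systems (H atom, H2+) are
solved exactly by diagonalizing the core Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import MoleculeBasis, build_basis
from .integrals import IntegralEngine

__all__ = ["RhfResult", "rhf"]


@dataclass
class RhfResult:
    energy: float            # total energy incl. nuclear repulsion, Hartree
    energy_electronic: float
    e_nn: float
    mo_coeff: np.ndarray     # (nao, nao), columns are MOs (function space)
    mo_energy: np.ndarray
    mo_occ: np.ndarray
    basis: MoleculeBasis
    atoms: list              # [(element, Z, position-Bohr), ...]
    converged: bool
    n_iter: int

    @property
    def density_matrix(self) -> np.ndarray:
        C = self.mo_coeff
        return (C * self.mo_occ) @ C.T


def _nuclear_repulsion(atoms) -> float:
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            r = np.linalg.norm(atoms[i][2] - atoms[j][2])
            e += atoms[i][1] * atoms[j][1] / r
    return e


def rhf(
    atoms: list[tuple[str, int, np.ndarray]],
    basis_name: str = "6-31g",
    charge: int = 0,
    conv_tol: float = 1e-10,
    max_iter: int = 150,
) -> RhfResult:
    """Solve restricted Hartree-Fock.

    Parameters
    ----------
    atoms:
        ``[(element, Z, position-in-Bohr), ...]``.
    conv_tol:
        Convergence threshold on the energy change and on the DIIS error
        norm ("very tight" by default).
    """
    nelec = sum(a[1] for a in atoms) - charge
    if nelec <= 0:
        raise ValueError("system has no electrons")
    basis = build_basis([(a[0], np.asarray(a[2], float)) for a in atoms], basis_name)
    eng = IntegralEngine(basis)
    S, T = eng.overlap_kinetic()
    V = eng.nuclear_attraction(
        np.array([a[2] for a in atoms], dtype=float),
        np.array([a[1] for a in atoms], dtype=float),
    )
    H = T + V
    e_nn = _nuclear_repulsion(atoms)

    # symmetric orthogonalization
    sval, svec = np.linalg.eigh(S)
    if sval.min() < 1e-9:
        raise RuntimeError("near-linear-dependent basis (smallest S eigenvalue "
                           f"{sval.min():.2e})")
    X = svec @ np.diag(sval ** -0.5) @ svec.T

    if nelec == 1:
        Hp = X.T @ H @ X
        e, c = np.linalg.eigh(Hp)
        C = X @ c
        occ = np.zeros(basis.nao_cart)
        occ[0] = 1.0
        return RhfResult(
            energy=e[0] + e_nn, energy_electronic=e[0], e_nn=e_nn,
            mo_coeff=C, mo_energy=e, mo_occ=occ, basis=basis,
            atoms=list(atoms), converged=True, n_iter=1,
        )

    if nelec % 2 != 0:
        raise NotImplementedError(
            "open-shell systems are not supported by the built-in RHF engine; "
            "supply densities via Molden import instead"
        )
    nocc = nelec // 2
    eri = eng.eri()

    def fock(D):
        J = np.einsum("pqrs,rs->pq", eri, D)
        K = np.einsum("prqs,rs->pq", eri, D)
        return H + J - 0.5 * K

    def density(F):
        Fp = X.T @ F @ X
        e, c = np.linalg.eigh(Fp)
        C = X @ c
        Cocc = C[:, :nocc]
        return 2.0 * Cocc @ Cocc.T, C, e

    D, C, mo_e = density(H)
    e_old = 0.0
    diis_F, diis_err = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        err = X.T @ err @ X
        diis_F.append(F.copy())
        diis_err.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = diis_err[a] @ diis_err[b]
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        D_new, C, mo_e = density(F)
        e_elec = 0.5 * np.einsum("pq,pq->", D_new, H + fock(D_new))
        if abs(e_elec - e_old) < conv_tol and np.linalg.norm(err) < np.sqrt(conv_tol):
            D = D_new
            converged = True
            e_old = e_elec
            break
        e_old = e_elec
        D = D_new
    if not converged:
        raise RuntimeError(
            f"SCF failed to converge in {max_iter} iterations "
            f"(last dE={abs(e_elec - e_old):.2e})"
        )
    occ = np.zeros(basis.nao_cart)
    occ[:nocc] = 2.0
    return RhfResult(
        energy=e_old + e_nn, energy_electronic=e_old, e_nn=e_nn,
        mo_coeff=C, mo_energy=mo_e, mo_occ=occ, basis=basis,
        atoms=list(atoms), converged=True, n_iter=it,
    )
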