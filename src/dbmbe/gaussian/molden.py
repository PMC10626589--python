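"""Molden file reading/writing (standard and Orca dialects).

The Molden [GTO] section lists, per atom, contracted shells whose
coefficients refer to normalized primitives.  Orca's Molden export uses an
inconsistent normalization convention for shells with l >= 2: the published
correction rescales d / f / g contraction coefficients by sqrt(3) /
sqrt(15) / sqrt(105) before use.  The reader applies that rescaling when
``dialect="orca"`` and otherwise takes the file at face value; an
electron-count validation (Tr[D S] vs the occupation sum) catches files
read with the wrong dialect.

Only s, p and d shells are supported (spherical [5D] or Cartesian d); this
covers the double-zeta-class bases the built-in engine provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from pathlib import Path

import numpy as np

from ..constants import ELEMENT_Z, ANGSTROM_TO_BOHR
from .basis import BasisShell, MoleculeBasis, _primitive_norm
from .integrals import IntegralEngine

__all__ = ["MoldenData", "read_molden", "write_molden"]

_ORCA_SCALE = {0: 1.0, 1: 1.0, 2: sqrt(3.0), 3: sqrt(15.0), 4: sqrt(105.0)}
_L_LABEL = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}


@dataclass
class MoldenData:
    """Parsed wavefunction: geometry, basis shells, MOs, occupations."""

    atoms: list  # [(element, Z, position-Bohr), ...]
    shells: list[BasisShell]
    shell_atom: list[int]
    mo_coeff: np.ndarray  # (nao, nmo), function space, Molden AO order
    mo_occ: np.ndarray
    mo_energy: np.ndarray

    def molecule_basis(self) -> MoleculeBasis:
        return MoleculeBasis(self.shells)

    def density_matrix(self) -> np.ndarray:
        C = self.mo_coeff
        return (C * self.mo_occ) @ C.T

    @property
    def electron_count(self) -> float:
        return float(self.mo_occ.sum())


def _molden_coefficients(shell: BasisShell) -> np.ndarray:
    """Coefficients to print so that re-reading reproduces the shell exactly."""
    c_eff = shell.normalized_coefficients()
    prim_norms = np.array([_primitive_norm(shell.l, a) for a in shell.exponents])
    return c_eff / prim_norms


def write_molden(
    path: str | Path,
    atoms: list,
    shells: list[BasisShell],
    shell_atom: list[int],
    mo_coeff: np.ndarray,
    mo_occ: np.ndarray,
    mo_energy: np.ndarray | None = None,
    dialect: str = "standard",
) -> None:
    """Write a Molden file.

    ``dialect="orca"`` emulates Orca's inconsistent l >= 2 normalization by
    dividing the printed d coefficients by sqrt(3) (the inverse of the
    documented read-side fix); useful as a regression fixture.
    """
    if dialect not in ("standard", "orca"):
        raise ValueError(f"unknown Molden dialect {dialect!r}")
    lines = ["[Molden Format]", "[Atoms] AU"]
    for i, (el, z, pos) in enumerate(atoms):
        lines.append(
            f"{el:<3s} {i + 1:4d} {z:4d} {pos[0]:20.12f} {pos[1]:20.12f} {pos[2]:20.12f}"
        )
    lines.append("[GTO]")
    lab = {0: "s", 1: "p", 2: "d"}
    for ai in range(len(atoms)):
        lines.append(f"{ai + 1:4d} 0")
        for sh, sa in zip(shells, shell_atom):
            if sa != ai:
                continue
            coefs = _molden_coefficients(sh)
            if dialect == "orca":
                coefs = coefs / _ORCA_SCALE[sh.l]
            lines.append(f" {lab[sh.l]} {len(sh.exponents):3d} 1.00")
            for a, c in zip(sh.exponents, coefs):
                lines.append(f"  {a:24.16e} {c:24.16e}")
        lines.append("")
    if any(sh.spherical and sh.l == 2 for sh in shells):
        lines.append("[5D]")
    lines.append("[MO]")
    nmo = mo_coeff.shape[1]
    if mo_energy is None:
        mo_energy = np.zeros(nmo)
    for m in range(nmo):
        lines.append(" Sym= A")
        lines.append(f" Ene= {mo_energy[m]:.10f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {mo_occ[m]:.8f}")
        for a in range(mo_coeff.shape[0]):
            lines.append(f" {a + 1:4d} {mo_coeff[a, m]:24.16e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_molden(path: str | Path, dialect: str = "standard", validate: bool = True) -> MoldenData:
    """Parse a Molden file.

    Parameters
    ----------
    dialect:
        ``"standard"`` or ``"orca"`` (applies the documented d/f/g
        coefficient rescaling before use).
    validate:
        Check Tr[D S] against the occupation sum (tolerance 1e-6 electrons);
        a mismatch usually means the wrong dialect was requested.
    """
    if dialect not in ("standard", "orca"):
        raise ValueError(f"unknown Molden dialect {dialect!r}")
    text = Path(path).read_text().splitlines()
    sections: dict[str, list[str]] = {}
    current = None
    flags = set()
    for raw in text:
        line = raw.strip()
        if not line:
            if current is not None:
                sections[current].append("")
            continue
        if line.startswith("["):
            tag = line.split("]")[0][1:].strip().lower()
            rest = line.split("]", 1)[1].strip()
            if tag in ("5d", "7f", "5d7f", "9g", "5d10f"):
                flags.add(tag)
                current = None
                continue
            current = tag
            sections[current] = [rest] if rest else []
            continue
        if current is not None:
            sections[current].append(raw)

    if "atoms" not in sections:
        raise ValueError(f"{path}: no [Atoms] section")
    unit_line = sections["atoms"][0].strip().lower() if sections["atoms"] else ""
    body = sections["atoms"]
    scale = 1.0
    if unit_line in ("au", "angs", "(au)", "(angs)"):
        body = body[1:]
        if unit_line.strip("()") == "angs":
            scale = ANGSTROM_TO_BOHR
    atoms = []
    for line in body:
        if not line.strip():
            continue
        parts = line.split()
        el, _idx, z = parts[0].capitalize(), int(parts[1]), int(parts[2])
        if el not in ELEMENT_Z:
            raise ValueError(f"{path}: unknown element {parts[0]!r} in [Atoms]")
        pos = np.array([float(p) for p in parts[3:6]]) * scale
        atoms.append((el, z, pos))

    if "gto" not in sections:
        raise ValueError(f"{path}: no [GTO] section")
    spherical_d = any(f in flags for f in ("5d", "5d7f", "5d10f"))
    shells: list[BasisShell] = []
    shell_atom: list[int] = []
    lines = [l for l in sections["gto"]]
    i = 0
    cur_atom = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            cur_atom = None
            continue
        parts = line.split()
        if cur_atom is None:
            cur_atom = int(parts[0]) - 1
            if not 0 <= cur_atom < len(atoms):
                raise ValueError(f"{path}: [GTO] atom index {parts[0]} out of range")
            continue
        label = parts[0].lower()
        if label not in _L_LABEL:
            raise ValueError(f"{path}: unknown shell label {parts[0]!r} in [GTO]")
        l = _L_LABEL[label]
        if l > 2:
            raise NotImplementedError(
                f"{path}: shells with l={l} ({label}) are not supported (s, p, d only)"
            )
        nprim = int(parts[1])
        exps, coefs = [], []
        for _ in range(nprim):
            pl = lines[i].replace("D", "e").replace("d", "e").split()
            i += 1
            exps.append(float(pl[0]))
            coefs.append(float(pl[1]))
        coefs = np.array(coefs) * _ORCA_SCALE[l] if dialect == "orca" else np.array(coefs)
        # primitive norms folded in, but no contracted renormalization:
        # the dialect correction must stay observable in the density
        shells.append(BasisShell(l, atoms[cur_atom][2], np.array(exps), coefs,
                                 spherical=(spherical_d and l == 2),
                                 renormalize=False))
        shell_atom.append(cur_atom)

    if "mo" not in sections:
        raise ValueError(f"{path}: no [MO] section")
    nao = sum(sh.n_func for sh in shells)
    coeffs, occs, enes = [], [], []
    cur = None
    for line in sections["mo"] + ["Sym= end"]:
        s = line.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("sym="):
            if cur is not None:
                coeffs.append(cur)
            cur = np.zeros(nao)
            continue
        if low.startswith("ene="):
            enes.append(float(s.split("=")[1]))
            continue
        if low.startswith("spin="):
            if "alpha" not in low:
                raise NotImplementedError(f"{path}: only closed-shell (Alpha) MOs supported")
            continue
        if low.startswith("occup="):
            occs.append(float(s.split("=")[1]))
            continue
        parts = s.split()
        if cur is None:
            cur = np.zeros(nao)
        idx = int(parts[0]) - 1
        if not 0 <= idx < nao:
            raise ValueError(f"{path}: MO coefficient index {parts[0]} exceeds {nao} basis functions")
        cur[idx] = float(parts[1])
    if len(coeffs) != len(occs):
        raise ValueError(f"{path}: MO occupation/coefficient count mismatch")
    mo_coeff = np.array(coeffs).T if coeffs else np.zeros((nao, 0))
    data = MoldenData(
        atoms=atoms, shells=shells, shell_atom=shell_atom,
        mo_coeff=mo_coeff, mo_occ=np.array(occs),
        mo_energy=np.array(enes) if len(enes) == len(occs) else np.zeros(len(occs)),
    )
    if validate:
        basis = data.molecule_basis()
        eng = IntegralEngine(basis)
        S, _ = eng.overlap_kinetic()
        T = basis.cart_from_func
        dm_cart = T.T @ data.density_matrix() @ T
        n = float(np.einsum("ij,ij->", dm_cart, S))
        if abs(n - data.electron_count) > 1e-6:
            raise ValueError(
                f"{path}: Tr[DS] = {n:.8f} but occupations sum to "
                f"{data.electron_count:.8f}; wrong Molden dialect?"
            )
    return data
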