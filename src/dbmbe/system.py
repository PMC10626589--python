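"""Molecular clusters partitioned into fragments.

A :class:`ClusterSystem` is the universe of a many-body expansion: a list of
:class:`Fragment` objects (whole molecules — a water, a hydronium ion, ...),
each holding :class:`Atom` records.  Coordinates are stored in Bohr
internally; XYZ files are read and written in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    BOHR_IN_ANGSTROM,
    COVALENT_RADIUS,
    ELEMENT_Z,
)

__all__ = [
    "Atom",
    "Fragment",
    "ClusterSystem",
    "read_xyz",
    "write_xyz",
    "subsystem_geometry",
]


@dataclass(frozen=True)
class Atom:
    """A nucleus: element symbol, nuclear charge Z, position in Bohr."""

    element: str
    position: np.ndarray  # shape (3,), Bohr

    def __post_init__(self):
        if self.element not in ELEMENT_Z:
            raise ValueError(f"unknown element symbol {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def nuclear_charge(self) -> int:
        return ELEMENT_Z[self.element]


@dataclass
class Fragment:
    """One molecule of the cluster, with its charge and spin bookkeeping."""

    index: int
    atoms: list[Atom]
    charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("fragment must contain at least one atom")
        if self.electron_count < 0:
            raise ValueError(
                f"fragment {self.index} has negative electron count "
                f"(charge {self.charge} exceeds total nuclear charge)"
            )

    @property
    def nuclear_charge(self) -> int:
        return sum(a.nuclear_charge for a in self.atoms)

    @property
    def electron_count(self) -> int:
        return self.nuclear_charge - self.charge

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class ClusterSystem:
    """A cluster of fragments; the expanded system of the MBE."""

    fragments: list[Fragment]
    name: str = "cluster"

    def __post_init__(self):
        indices = [f.index for f in self.fragments]
        if len(set(indices)) != len(indices):
            raise ValueError("fragment indices must be unique")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def atoms(self) -> list[Atom]:
        return [a for f in self.fragments for a in f.atoms]

    @property
    def total_charge(self) -> int:
        return sum(f.charge for f in self.fragments)

    @property
    def total_electrons(self) -> int:
        return sum(f.electron_count for f in self.fragments)

    def nuclear_repulsion(self, keys: Sequence[int] | None = None) -> float:
        """E_NN of the selected fragments (all by default), in Hartree."""
        frags = self.fragments if keys is None else [self.fragments[i] for i in keys]
        atoms = [a for f in frags for a in f.atoms]
        e = 0.0
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                r = np.linalg.norm(atoms[i].position - atoms[j].position)
                e += atoms[i].nuclear_charge * atoms[j].nuclear_charge / r
        return e


def subsystem_geometry(cluster: ClusterSystem, key: Sequence[int]) -> Fragment:
    """Concatenated geometry of the fragments selected by ``key``.

    The result is returned as a single :class:`Fragment` whose charge is the
    sum of the member charges; spin defaults to the closed-shell singlet
    unless an odd electron count forces a doublet.
    """
    key = tuple(key)
    if len(set(key)) != len(key):
        raise ValueError(f"duplicate fragment indices in key {key}")
    if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
        raise ValueError(f"subsystem key must be strictly increasing, got {key}")
    if not key or key[0] < 0 or key[-1] >= cluster.n_fragments:
        raise ValueError(f"subsystem key {key} out of range for N={cluster.n_fragments}")
    atoms = []
    charge = 0
    for i in key:
        frag = cluster.fragments[i]
        atoms.extend(frag.atoms)
        charge += frag.charge
    nelec = sum(a.nuclear_charge for a in atoms) - charge
    mult = 1 if nelec % 2 == 0 else 2
    return Fragment(index=0, atoms=atoms, charge=charge, spin_multiplicity=mult)


# ---------------------------------------------------------------------------
# XYZ I/O


def _parse_xyz(path: Path) -> tuple[list[str], np.ndarray, str]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}, line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise ValueError(f"{path}: header announces {natoms} atoms but file has fewer lines")
    comment = lines[1]
    symbols, coords = [], []
    for ln in range(2, 2 + natoms):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}, line {ln + 1}: expected 'element x y z', got {lines[ln]!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENT_Z:
            raise ValueError(f"{path}, line {ln + 1}: unknown element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"{path}, line {ln + 1}: non-numeric coordinate") from exc
        symbols.append(sym)
        coords.append(xyz)
    return symbols, np.array(coords), comment


def _auto_fragment_labels(symbols: list[str], coords_ang: np.ndarray) -> list[int]:
    """Connected components of the covalent-radius bond graph.

    Two atoms are bonded when their distance is below 1.2x the sum of their
    covalent radii — robust for whole-molecule clusters (water, hydronium,
    hydroxide) without ever splitting a covalent bond.
    """
    n = len(symbols)
    radii = np.array([COVALENT_RADIUS[s] for s in symbols])
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords_ang[i] - coords_ang[j])
            if d < 1.2 * (radii[i] + radii[j]):
                parent[find(i)] = find(j)

    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels.append(roots[r])
    # renumber in order of first appearance (already guaranteed above)
    return labels


def read_xyz(
    path: str | Path,
    fragment_spec: str | Sequence[int] = "auto",
    charges: Mapping[int, int] | None = None,
    multiplicities: Mapping[int, int] | None = None,
    name: str | None = None,
) -> ClusterSystem:
    """Read an XYZ file (Angstrom) into a :class:`ClusterSystem` (Bohr).

    Parameters
    ----------
    fragment_spec:
        ``"auto"`` assigns fragments as connected components of the
        covalent-radius bond graph; otherwise a per-atom sequence of integer
        fragment labels (0-based, in order of first appearance).
    charges, multiplicities:
        Optional maps fragment-index -> charge / spin multiplicity.  Auto
        mode defaults every fragment to a neutral singlet; ionic fragments
        (hydronium, hydroxide) must be declared explicitly.
    """
    path = Path(path)
    symbols, coords_ang, _comment = _parse_xyz(path)

    if isinstance(fragment_spec, str):
        if fragment_spec != "auto":
            raise ValueError(f"fragment_spec must be 'auto' or per-atom labels, got {fragment_spec!r}")
        labels = _auto_fragment_labels(symbols, coords_ang)
    else:
        labels = [int(x) for x in fragment_spec]
        if len(labels) != len(symbols):
            raise ValueError(
                f"fragment_spec has {len(labels)} labels for {len(symbols)} atoms"
            )

    charges = dict(charges or {})
    multiplicities = dict(multiplicities or {})
    nfrag = max(labels) + 1
    fragments = []
    for fi in range(nfrag):
        atoms = [
            Atom(symbols[i], coords_ang[i] * ANGSTROM_TO_BOHR)
            for i in range(len(symbols))
            if labels[i] == fi
        ]
        if not atoms:
            raise ValueError(f"fragment label {fi} has no atoms")
        frag = Fragment(
            index=fi,
            atoms=atoms,
            charge=charges.get(fi, 0),
            spin_multiplicity=multiplicities.get(fi, 1),
        )
        if frag.electron_count == 0:
            raise ValueError(f"fragment {fi} has zero electrons; check fragment assignment")
        fragments.append(frag)
    return ClusterSystem(fragments=fragments, name=name or path.stem)


def write_xyz(
    cluster: ClusterSystem,
    path: str | Path,
    fragment_sidecar: str | Path | None = None,
    comment: str | None = None,
) -> None:
    """Write a cluster as XYZ (Angstrom) plus an optional fragment sidecar.

    The sidecar holds one integer fragment label per atom line, in the same
    atom order as the XYZ file.
    """
    path = Path(path)
    atoms = cluster.atoms
    lines = [str(len(atoms)), comment if comment is not None else cluster.name]
    labels = []
    for frag in cluster.fragments:
        for a in frag.atoms:
            x, y, z = a.position * BOHR_IN_ANGSTROM
            lines.append(f"{a.element:<2s} {x:20.12f} {y:20.12f} {z:20.12f}")
            labels.append(frag.index)
    path.write_text("\n".join(lines) + "\n")
    if fragment_sidecar is not None:
        Path(fragment_sidecar).write_text("\n".join(str(l) for l in labels) + "\n")


def read_fragment_sidecar(path: str | Path) -> list[int]:
    """Read a fragment sidecar: one integer label per line."""
    return [int(line.split()[0]) for line in Path(path).read_text().split("\n") if line.strip()]
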