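"""Deterministic synthetic inputs: water clusters and Gaussian toy clusters.

Two families of fixtures drive the test suite and the examples:

* rigid-monomer water clusters (r_OH = 0.9572 A, HOH angle 104.52 deg)
  placed either as a hydrogen-bonded ring (each water donating one H to its
  neighbor, O-O near 2.8 A — the geometry regime of low-lying water-cluster
  isomers) or randomly on a shell, with seeded orientations;
* single-Gaussian toy clusters whose every expansion quantity has a closed
  form, backed by :class:`~dbmbe.backend.GaussianMockBackend`.

Everything is reproducible from (spec, seed) and generated in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import GaussianMockBackend
from .constants import ANGSTROM_TO_BOHR, Z_ELEMENT
from .system import Atom, ClusterSystem, Fragment

__all__ = [
    "WaterClusterSpec",
    "GaussianToySpec",
    "make_water_cluster",
    "make_gaussian_toy",
]

R_OH = 0.9572 * ANGSTROM_TO_BOHR
HOH_ANGLE = np.deg2rad(104.52)
MIN_CONTACT = 1.5  # Bohr; steric floor across fragments


@dataclass(frozen=True)
class WaterClusterSpec:
    """Placement recipe for an n-water cluster (distances in Bohr)."""

    n_waters: int
    placement: str = "ring"          # "ring" (H-bonded) or "shell" (random)
    min_oo: float = 2.7 * ANGSTROM_TO_BOHR
    max_oo: float = 3.2 * ANGSTROM_TO_BOHR
    seed: int = 0


@dataclass(frozen=True)
class GaussianToySpec:
    """Fully analytic toy cluster: one s-Gaussian fragment per site."""

    positions: tuple        # n x 3, Bohr
    exponents: tuple = ()   # default 1.0 each
    charges: tuple = ()     # electrons per fragment, default 2 each
    pair_a: float = -0.02
    pair_b: float = 0.4
    c3: float = 0.0
    seed: int = 0


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _water_atoms(origin: np.ndarray, donate: np.ndarray, rng) -> list[Atom]:
    """Rigid water at ``origin`` with one O-H bond along ``donate``."""
    u = donate / np.linalg.norm(donate)
    # second O-H direction at the HOH angle, azimuth seeded
    w = _random_unit(rng)
    w = w - (w @ u) * u
    n = np.linalg.norm(w)
    while n < 1e-8:
        w = _random_unit(rng)
        w = w - (w @ u) * u
        n = np.linalg.norm(w)
    w /= n
    v = np.cos(HOH_ANGLE) * u + np.sin(HOH_ANGLE) * w
    return [
        Atom("O", origin),
        Atom("H", origin + R_OH * u),
        Atom("H", origin + R_OH * v),
    ]


def _check_contacts(fragments: list[Fragment]) -> bool:
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            pi = fragments[i].positions
            pj = fragments[j].positions
            d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
            if d.min() < MIN_CONTACT:
                return False
    return True


def make_water_cluster(spec: WaterClusterSpec) -> ClusterSystem:
    """Build a reproducible rigid-monomer water cluster.

    ``ring`` placement puts the oxygens on a regular polygon with the O-O
    side drawn from [min_oo, max_oo] and orients each water to donate a
    hydrogen toward the next oxygen (a hydrogen-bonded ring; a dimer
    degenerates to a donor-acceptor pair, a single water is random).
    ``shell`` placement scatters oxygens with rejection sampling so every
    nearest-neighbor O-O distance falls in [min_oo, max_oo].
    """
    if spec.n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    if spec.placement not in ("ring", "shell"):
        raise ValueError(f"unknown placement {spec.placement!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_waters

    for _attempt in range(50):
        if spec.placement == "ring" and n >= 2:
            d = rng.uniform(spec.min_oo, spec.max_oo)
            if n == 2:
                oxygens = [np.zeros(3), np.array([d, 0.0, 0.0])]
            else:
                radius = d / (2.0 * np.sin(np.pi / n))
                oxygens = [
                    radius * np.array([np.cos(2 * np.pi * i / n),
                                       np.sin(2 * np.pi * i / n), 0.0])
                    for i in range(n)
                ]
            fragments = []
            for i, o in enumerate(oxygens):
                target = oxygens[(i + 1) % n] if n > 2 else oxygens[1 - i]
                donate = target - o
                if n == 2 and i == 1:
                    donate = _random_unit(rng)  # acceptor water: free orientation
                fragments.append(Fragment(index=i, atoms=_water_atoms(o, donate, rng)))
        elif spec.placement == "shell" and n >= 2:
            oxygens = [np.zeros(3)]
            ok = True
            for _i in range(1, n):
                for _try in range(400):
                    base = oxygens[rng.integers(len(oxygens))]
                    cand = base + rng.uniform(spec.min_oo, spec.max_oo) * _random_unit(rng)
                    dists = [np.linalg.norm(cand - o) for o in oxygens]
                    if min(dists) >= spec.min_oo:
                        oxygens.append(cand)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            fragments = [
                Fragment(index=i, atoms=_water_atoms(o, _random_unit(rng), rng))
                for i, o in enumerate(oxygens)
            ]
        else:  # single water
            fragments = [Fragment(index=0, atoms=_water_atoms(np.zeros(3), _random_unit(rng), rng))]
        if _check_contacts(fragments):
            return ClusterSystem(fragments=fragments, name=f"water{n}-{spec.placement}-s{spec.seed}")
    raise RuntimeError(f"could not pack {n} waters without steric clashes (spec {spec})")


def make_gaussian_toy(spec: GaussianToySpec) -> tuple[ClusterSystem, GaussianMockBackend]:
    """Build an analytic toy cluster plus its mock backend.

    Each fragment is a single neutral atom of Z = q_I electrons whose
    density is one normalized s-Gaussian; energies follow the declared
    pair (+ optional triple) potential.
    """
    positions = np.asarray(spec.positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an n x 3 array")
    nfrag = len(positions)
    for i in range(nfrag):
        for j in range(i + 1, nfrag):
            if np.linalg.norm(positions[i] - positions[j]) < 1e-6:
                raise ValueError(f"duplicate fragment positions {i} and {j}")
    exponents = np.asarray(spec.exponents if spec.exponents else [1.0] * nfrag, float)
    charges = np.asarray(spec.charges if spec.charges else [2.0] * nfrag, float)
    if len(exponents) != nfrag or len(charges) != nfrag:
        raise ValueError("exponents/charges must have one entry per fragment")
    fragments = []
    for i, pos in enumerate(positions):
        z = int(round(charges[i]))
        if z not in Z_ELEMENT:
            raise ValueError(f"no element with Z={z} for fragment {i}")
        fragments.append(Fragment(index=i, atoms=[Atom(Z_ELEMENT[z], pos)]))
    cluster = ClusterSystem(fragments=fragments, name=f"gauss-toy-{nfrag}")
    backend = GaussianMockBackend(
        cluster=cluster,
        alphas=exponents,
        charges_e=charges,
        e_mono=-charges,  # declared monomer energies
        pair_A=spec.pair_a,
        pair_B=spec.pair_b,
        c3=spec.c3,
    )
    return cluster, backend
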