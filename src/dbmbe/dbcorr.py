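"""Assembly of the density-based correction and the db-MBE total energy.

The orbital-free-DFT total-energy functional

    E_tot[rho] = T_s[rho] + V_nuc[rho] + J[rho] + E_xc[rho] + E_NN

is evaluated once on the many-body-expanded density rho^(n) (with the full
cluster's nuclei) and once as its own truncated many-body expansion over
subsystem densities (each with its subsystem's nuclei).  The difference is
the density-based correction: it vanishes order by order as n approaches
the fragment count, and added to the energy-based expansion it yields the
db-MBE(n) total energy

    E_db-MBE(n) = E_eb-MBE(n) + E_db-corr(n).

T_s and E_xc are approximated semilocally (PW91k, PBE by default), so only
their nonadditive parts — differences of the same functional on both sides
— carry functional error.  V_nuc and J are linear/bilinear in the density
and are treated exactly on the shared grid; E_NN is pairwise additive, so
its correction survives only at first order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fields import (
    ExpandedField,
    FieldOnGrid,
    coulomb_energy,
    nuclear_attraction_energy,
)
from .functionals import FunctionalSpec, functional_energy
from .grid import IntegrationGrid
from .mbe import (
    InteractionLedger,
    SubsystemKey,
    eb_mbe_total,
    enumerate_subsystems,
    expansion_coefficients,
    mbe_truncated_sum,
    mbe_truncated_sum_recursive,
)
from .system import ClusterSystem

__all__ = [
    "CorrectionBreakdown",
    "DbMbeResult",
    "mbe_of_functional_term",
    "db_correction",
    "db_mbe_total",
]

_TERMS = ("v_nuc", "coulomb", "e_nn", "kinetic", "xc")


@dataclass(frozen=True)
class CorrectionBreakdown:
    """The five terms of the density-based correction at one order (Hartree)."""

    order: int
    v_nuc_term: float
    coulomb_term: float
    nn_term: float
    ts_nonadd: float
    xc_nonadd: float

    @property
    def total(self) -> float:
        return (self.v_nuc_term + self.coulomb_term + self.nn_term
                + self.ts_nonadd + self.xc_nonadd)


@dataclass
class DbMbeResult:
    """Energy-based and density-based expansion totals with per-order trace."""

    order: int
    eb_energy: float
    correction: CorrectionBreakdown
    per_order: list  # [(k, eb_k, db_k), ...] for k = 1..order
    supermolecular: float | None = None

    @property
    def db_energy(self) -> float:
        return self.eb_energy + self.correction.total

    def error_eb(self) -> float:
        if self.supermolecular is None:
            raise ValueError("no supermolecular reference stored")
        return self.eb_energy - self.supermolecular

    def error_db(self) -> float:
        if self.supermolecular is None:
            raise ValueError("no supermolecular reference stored")
        return self.db_energy - self.supermolecular


def _subsystem_term_value(
    term: str,
    key: SubsystemKey,
    fld: FieldOnGrid,
    cluster: ClusterSystem,
    grid: IntegrationGrid,
    spec: FunctionalSpec,
) -> float:
    """One term of E_tot evaluated for one subsystem (its own nuclei)."""
    if term == "v_nuc":
        nuclei = [a for i in key for a in cluster.fragments[i].atoms]
        return nuclear_attraction_energy(grid, fld, nuclei)
    if term == "coulomb":
        return coulomb_energy(grid, fld)
    if term == "e_nn":
        return cluster.nuclear_repulsion(keys=key)
    if term == "kinetic":
        return functional_energy(grid, fld, spec, "kinetic")
    if term == "xc":
        return functional_energy(grid, fld, spec, "xc")
    raise ValueError(f"unknown term {term!r}; expected one of {_TERMS}")


def mbe_of_functional_term(
    fields: dict[SubsystemKey, FieldOnGrid],
    cluster: ClusterSystem,
    order: int,
    term: str,
    grid: IntegrationGrid,
    spec: FunctionalSpec = FunctionalSpec(),
    route: str = "recursive",
) -> float:
    """Truncated MBE of one E_tot term over subsystem densities.

    ``route="recursive"`` accumulates Moebius increments order by order;
    ``route="flattened"`` applies the closed-form signed coefficients.  The
    two are algebraically identical and both are exposed so either can
    cross-check the other.
    """
    values: dict[SubsystemKey, float] = {}
    for key in enumerate_subsystems(cluster.n_fragments, order):
        if term != "e_nn" and key not in fields:
            raise KeyError(f"missing field for subsystem {key}")
        fld = fields.get(key)
        values[key] = _subsystem_term_value(term, key, fld, cluster, grid, spec)
    if route == "recursive":
        return mbe_truncated_sum_recursive(values, cluster.n_fragments, order)
    if route == "flattened":
        return mbe_truncated_sum(values, cluster.n_fragments, order)
    raise ValueError(f"unknown route {route!r}")


def db_correction(
    fields: dict[SubsystemKey, FieldOnGrid],
    cluster: ClusterSystem,
    order: int,
    grid: IntegrationGrid,
    spec: FunctionalSpec = FunctionalSpec(),
    route: str = "recursive",
) -> CorrectionBreakdown:
    """The density-based correction at truncation ``order``.

    Each term is E_tot-term[rho^(n), full nuclei] minus the truncated MBE of
    the same term over subsystem densities (subsystem nuclei).  The nuclear
    repulsion is pairwise additive, so its correction is identically zero
    for order >= 2 and is evaluated analytically only at order 1.
    """
    N = cluster.n_fragments
    if not 1 <= order <= N:
        raise ValueError(f"order must satisfy 1 <= n <= N={N}, got {order}")
    coeffs = expansion_coefficients(N, order)
    missing = [k for k in enumerate_subsystems(N, order) if k not in fields]
    if missing:
        raise KeyError(f"missing fields for subsystems {missing}")
    expanded = ExpandedField([(float(c), fields[k]) for k, c in coeffs.items()])

    v_full = nuclear_attraction_energy(grid, expanded, cluster.atoms)
    v_mbe = mbe_of_functional_term(fields, cluster, order, "v_nuc", grid, spec, route)
    j_full = coulomb_energy(grid, expanded)
    j_mbe = mbe_of_functional_term(fields, cluster, order, "coulomb", grid, spec, route)
    ts_full = functional_energy(grid, expanded, spec, "kinetic")
    ts_mbe = mbe_of_functional_term(fields, cluster, order, "kinetic", grid, spec, route)
    xc_full = functional_energy(grid, expanded, spec, "xc")
    xc_mbe = mbe_of_functional_term(fields, cluster, order, "xc", grid, spec, route)
    if order >= 2:
        nn_term = 0.0  # exact pairwise additivity of E_NN
    else:
        nn_term = cluster.nuclear_repulsion() - mbe_of_functional_term(
            fields, cluster, order, "e_nn", grid, spec, route
        )
    return CorrectionBreakdown(
        order=order,
        v_nuc_term=v_full - v_mbe,
        coulomb_term=j_full - j_mbe,
        nn_term=nn_term,
        ts_nonadd=ts_full - ts_mbe,
        xc_nonadd=xc_full - xc_mbe,
    )


def db_mbe_total(
    ledger: InteractionLedger,
    fields: dict[SubsystemKey, FieldOnGrid],
    cluster: ClusterSystem,
    order: int,
    grid: IntegrationGrid,
    spec: FunctionalSpec = FunctionalSpec(),
    supermolecular: float | None = None,
    route: str = "recursive",
) -> DbMbeResult:
    """db-MBE(n) = eb-MBE(n) + density-based correction, with per-order trace."""
    N = cluster.n_fragments
    per_order = []
    correction = None
    for k in range(1, order + 1):
        eb_k = eb_mbe_total(ledger, N, k)
        correction = db_correction(fields, cluster, k, grid, spec, route)
        per_order.append((k, eb_k, eb_k + correction.total))
    eb = per_order[-1][1]
    return DbMbeResult(
        order=order,
        eb_energy=eb,
        correction=correction,
        per_order=per_order,
        supermolecular=supermolecular,
    )
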