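"""Many-body expansion bookkeeping.

The total energy of an N-fragment cluster is expanded as

    E = sum_I E_I^(1) + sum_{I<J} dE_IJ^(2) + sum_{I<J<K} dE_IJK^(3) + ...

where each k-mer interaction energy dE_S is the k-mer total energy minus the
interaction energies of all proper subsets of S (equivalently, the Moebius /
inclusion-exclusion sum over subsets).  Truncating the outer sum at order n
gives eb-MBE(n).  The same truncation applied to any per-subsystem quantity
Q_S (the electron density, a functional term evaluated on rho_S, ...) can be
flattened into a single signed sum

    Q^(n) = sum_{k=1..n} c_k(N, n) * sum_{|S|=k} Q_S,

with closed-form coefficients c_k = (-1)^(n-k) * C(N-k-1, n-k); this module
owns both routes and checks they agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Callable, Iterable, Mapping

__all__ = [
    "SubsystemKey",
    "InteractionLedger",
    "enumerate_subsystems",
    "interaction_energy",
    "eb_mbe_total",
    "expansion_coefficients",
    "ExpansionCoefficients",
    "mbe_truncated_sum",
]

# A subsystem key is a strictly increasing tuple of fragment indices.
SubsystemKey = tuple[int, ...]


def validate_key(key: Iterable[int]) -> SubsystemKey:
    key = tuple(int(i) for i in key)
    if not key:
        raise ValueError("subsystem key must be non-empty")
    if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
        raise ValueError(f"subsystem key must be strictly increasing, got {key}")
    return key


def enumerate_subsystems(n_fragments: int, order: int) -> list[SubsystemKey]:
    """All subsystem keys of order <= ``order``, lexicographically sorted.

    The count is sum_{k=1..order} C(N, k) — the number of quantum-chemical
    calculations a truncated expansion requires.
    """
    if not 1 <= order <= n_fragments:
        raise ValueError(f"truncation order must satisfy 1 <= n <= N, got n={order}, N={n_fragments}")
    keys: list[SubsystemKey] = []
    for k in range(1, order + 1):
        keys.extend(combinations(range(n_fragments), k))
    return keys


@dataclass
class InteractionLedger:
    """Per-subsystem total energies and memoized interaction energies (Hartree)."""

    total_energies: dict[SubsystemKey, float] = field(default_factory=dict)
    _interactions: dict[SubsystemKey, float] = field(default_factory=dict)

    def set_total(self, key: Iterable[int], energy: float) -> None:
        self.total_energies[validate_key(key)] = float(energy)
        self._interactions.clear()

    def total(self, key: Iterable[int]) -> float:
        key = validate_key(key)
        try:
            return self.total_energies[key]
        except KeyError:
            raise KeyError(f"no total energy stored for subsystem {key}") from None

    def interaction(self, key: Iterable[int]) -> float:
        return interaction_energy(validate_key(key), self)

    def max_order(self) -> int:
        return max((len(k) for k in self.total_energies), default=0)


def interaction_energy(key: SubsystemKey, ledger: InteractionLedger) -> float:
    """k-mer interaction energy dE_S = E_S - sum over proper subsets of dE_T.

    Evaluated bottom-up with memoization; identical to the Moebius form
    sum_{T subseteq S} (-1)^(|S|-|T|) E_T.
    """
    key = validate_key(key)
    cached = ledger._interactions.get(key)
    if cached is not None:
        return cached
    # bottom-up over orders so recursion depth stays 1
    for k in range(1, len(key) + 1):
        for sub in combinations(key, k):
            if sub in ledger._interactions:
                continue
            e_total = ledger.total(sub)
            lower = sum(
                ledger._interactions[t]
                for j in range(1, k)
                for t in combinations(sub, j)
            )
            ledger._interactions[sub] = e_total - lower
    return ledger._interactions[key]


def eb_mbe_total(ledger: InteractionLedger, n_fragments: int, order: int) -> float:
    """Energy-based MBE truncated at ``order``: sum of all dE_S with |S| <= order."""
    total = 0.0
    for key in enumerate_subsystems(n_fragments, order):
        total += interaction_energy(key, ledger)
    return total


@dataclass(frozen=True)
class ExpansionCoefficients:
    """Signed weights flattening a truncated MBE into a single sum over subsystems."""

    n_fragments: int
    order: int
    by_order: tuple[int, ...]  # c_k for k = 1..order (exact integers)

    def coefficient(self, key: SubsystemKey) -> int:
        k = len(key)
        if not 1 <= k <= self.order:
            raise ValueError(f"key order {k} outside truncation order {self.order}")
        return self.by_order[k - 1]

    def items(self) -> list[tuple[SubsystemKey, int]]:
        return [
            (key, self.by_order[len(key) - 1])
            for key in enumerate_subsystems(self.n_fragments, self.order)
        ]


def expansion_coefficients(n_fragments: int, order: int) -> ExpansionCoefficients:
    """Closed-form weights c_k = (-1)^(n-k) C(N-k-1, n-k) for k = 1..n.

    With these weights, sum_S c_|S| Q_S equals the truncated MBE of Q for any
    per-subsystem quantity Q_S; in particular sum_S c_|S| rho_S is the
    order-n many-body expanded density, and the weighted electron counts sum
    exactly to the total electron count.
    """
    if not 1 <= order <= n_fragments:
        raise ValueError(
            f"truncation order must satisfy 1 <= n <= N, got n={order}, N={n_fragments}"
        )
    N, n = n_fragments, order
    if n == N:
        by_order = tuple(0 for _ in range(N - 1)) + (1,)
    else:
        by_order = tuple(
            (-1) ** (n - k) * comb(N - k - 1, n - k) for k in range(1, n + 1)
        )
    return ExpansionCoefficients(n_fragments=N, order=n, by_order=by_order)


def mbe_truncated_sum(
    values: Mapping[SubsystemKey, float] | Callable[[SubsystemKey], float],
    n_fragments: int,
    order: int,
) -> float:
    """Truncated MBE of an arbitrary per-subsystem quantity.

    ``values`` maps every subsystem key of order <= n to Q_S.  Evaluated via
    the flattened coefficient form; the recursive order-by-order route is
    algebraically identical (see tests, which assert this on random inputs).
    """
    get = values if callable(values) else values.__getitem__
    coeffs = expansion_coefficients(n_fragments, order)
    total = 0.0
    for key in enumerate_subsystems(n_fragments, order):
        try:
            q = get(key)
        except KeyError:
            raise KeyError(f"missing subsystem value for {key}") from None
        total += coeffs.coefficient(key) * q
    return total


def mbe_truncated_sum_recursive(
    values: Mapping[SubsystemKey, float],
    n_fragments: int,
    order: int,
) -> float:
    """Order-by-order route: sum of Moebius increments dQ_S for |S| <= n."""
    ledger = InteractionLedger(total_energies={validate_key(k): float(v) for k, v in values.items()})
    return eb_mbe_total(ledger, n_fragments, order)
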