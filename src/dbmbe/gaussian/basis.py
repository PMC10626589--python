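"""Gaussian basis shells and per-molecule basis layout.

Shells carry contracted primitives with angular momentum l <= 2 (s, p, d).
Internally every integral is evaluated over individually normalized
Cartesian components (Molden component order); spherical (5d) shells carry
a per-shell solid-harmonic transformation applied to coefficients and
density matrices, never to the integral kernels.

Built-in basis sets (STO-3G, 6-31G for H, He, C, N, O, F) use the standard
published exponents/contraction coefficients; contracted functions are
renormalized after construction so small rounding in tabulated coefficients
cannot leak into electron counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np

__all__ = ["BasisShell", "MoleculeBasis", "build_basis", "CART_COMPONENTS"]

# Cartesian component exponents per l, Molden ordering.
CART_COMPONENTS: dict[int, list[tuple[int, int, int]]] = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}

_DOUBLE_FACT = {0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0}


def _primitive_norm(l: int, alpha: float) -> float:
    """Norm of the (l,0,0) Cartesian primitive x^l e^{-a r^2}."""
    return (2.0 * alpha / pi) ** 0.75 * sqrt(
        (4.0 * alpha) ** l / _DOUBLE_FACT[2 * l]
    )


def component_norm_factors(l: int) -> np.ndarray:
    """Per-component factor relative to the (l,0,0) normalization."""
    out = []
    for lx, ly, lz in CART_COMPONENTS[l]:
        out.append(
            sqrt(
                _DOUBLE_FACT[2 * l]
                / (_DOUBLE_FACT[2 * lx] * _DOUBLE_FACT[2 * ly] * _DOUBLE_FACT[2 * lz])
            )
        )
    return np.array(out)


# Real solid-harmonic d functions (order m = 0, +1, -1, +2, -2) in terms of
# normalized Cartesian components (xx, yy, zz, xy, xz, yz).
C2S_D = np.array(
    [
        [-0.5, -0.5, 1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
        [sqrt(3.0) / 2.0, -sqrt(3.0) / 2.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
    ]
)


@dataclass
class BasisShell:
    """One contracted shell on one center."""

    l: int
    center: np.ndarray  # (3,), Bohr
    exponents: np.ndarray
    coefficients: np.ndarray  # contraction coefficients (pre-normalization)
    spherical: bool = False  # only meaningful for l >= 2
    renormalize: bool = True  # rescale to unit self-overlap (False: trust file)

    def __post_init__(self):
        if self.l not in CART_COMPONENTS:
            raise ValueError(f"unsupported angular momentum l={self.l} (s, p, d only)")
        self.center = np.asarray(self.center, dtype=float)
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.exponents.shape != self.coefficients.shape:
            raise ValueError("exponent/coefficient length mismatch")

    @property
    def n_cart(self) -> int:
        return len(CART_COMPONENTS[self.l])

    @property
    def n_func(self) -> int:
        if self.spherical and self.l == 2:
            return 5
        return self.n_cart

    def normalized_coefficients(self) -> np.ndarray:
        """Coefficients x primitive norms, rescaled to unit self-overlap."""
        a = self.exponents
        c = self.coefficients * np.array([_primitive_norm(self.l, ai) for ai in a])
        if not self.renormalize:
            return c
        # self-overlap of the contracted (l,0,0) component
        aij = a[:, None] + a[None, :]
        s = (2.0 * np.sqrt(np.outer(a, a)) / aij) ** (self.l + 1.5)
        norm = float(c @ s @ c)
        return c / sqrt(norm)


class MoleculeBasis:
    """Flattened per-molecule basis: shells plus numba-ready arrays.

    ``nao`` counts the functions as the electronic-structure layer sees them
    (spherical for 5d shells); ``nao_cart`` counts Cartesian components used
    by the integral kernels.  ``cart_from_func`` maps function-space
    coefficient vectors to Cartesian component space.
    """

    def __init__(self, shells: list[BasisShell]):
        if not shells:
            raise ValueError("empty basis")
        self.shells = shells
        self.shell_l = np.array([sh.l for sh in shells], dtype=np.int64)
        self.shell_center = np.array([sh.center for sh in shells])
        nprim = [len(sh.exponents) for sh in shells]
        self.shell_pstart = np.concatenate([[0], np.cumsum(nprim)])[:-1].astype(np.int64)
        self.shell_nprim = np.array(nprim, dtype=np.int64)
        self.prim_exp = np.concatenate([sh.exponents for sh in shells])
        self.prim_coef = np.concatenate([sh.normalized_coefficients() for sh in shells])
        self.shell_cart_start = np.concatenate(
            [[0], np.cumsum([sh.n_cart for sh in shells])]
        )[:-1].astype(np.int64)
        self.nao_cart = int(sum(sh.n_cart for sh in shells))
        self.nao = int(sum(sh.n_func for sh in shells))
        self.comp_norms = [component_norm_factors(sh.l) for sh in shells]
        self._build_transform()

    def _build_transform(self):
        """(nao x nao_cart) map from function space to normalized Cartesian space."""
        T = np.zeros((self.nao, self.nao_cart))
        row = 0
        for si, sh in enumerate(self.shells):
            col = self.shell_cart_start[si]
            if sh.spherical and sh.l == 2:
                T[row : row + 5, col : col + 6] = C2S_D
                row += 5
            else:
                n = sh.n_cart
                T[row : row + n, col : col + n] = np.eye(n)
                row += n
        self.cart_from_func = T

    def density_matrix_cart(self, dm_func: np.ndarray) -> np.ndarray:
        """Transform a function-space density matrix to Cartesian components."""
        T = self.cart_from_func
        return T.T @ dm_func @ T

    # --- AO values on points (numpy; used for rho and grad-rho on grids) ---

    def ao_values(self, points: np.ndarray, deriv: bool = False):
        """Cartesian AO values (and gradients) at ``points`` (M x 3, Bohr).

        Returns ``ao`` (M x nao_cart) and, with ``deriv``, ``ao_grad``
        (3 x M x nao_cart).
        """
        M = len(points)
        ao = np.zeros((M, self.nao_cart))
        grad = np.zeros((3, M, self.nao_cart)) if deriv else None
        for si, sh in enumerate(self.shells):
            d = points - sh.center  # (M,3)
            r2 = np.einsum("ij,ij->i", d, d)
            coefs = sh.normalized_coefficients()
            rad = np.zeros(M)
            drad = np.zeros(M) if deriv else None  # radial part of d/dr2
            for a, c in zip(sh.exponents, coefs):
                e = c * np.exp(-a * r2)
                rad += e
                if deriv:
                    drad -= a * e
            fac = self.comp_norms[si]
            col = self.shell_cart_start[si]
            for ci, (lx, ly, lz) in enumerate(CART_COMPONENTS[sh.l]):
                poly = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
                ao[:, col + ci] = fac[ci] * poly * rad
                if deriv:
                    for ax, lax in enumerate((lx, ly, lz)):
                        g = 2.0 * d[:, ax] * poly * drad
                        if lax > 0:
                            lred = [lx, ly, lz]
                            lred[ax] -= 1
                            g = g + lax * (
                                d[:, 0] ** lred[0]
                                * d[:, 1] ** lred[1]
                                * d[:, 2] ** lred[2]
                            ) * rad
                        grad[ax, :, col + ci] = fac[ci] * g
        if deriv:
            return ao, grad
        return ao


# ---------------------------------------------------------------------------
# Built-in basis-set library (exponents / contraction coefficients)

# fmt: off
_BASIS_LIBRARY: dict[str, dict[str, list[tuple[str, list[float], list[list[float]]]]]] = {
    "sto-3g": {
        "H": [("s", [3.42525091, 0.62391373, 0.16885540],
               [[0.15432897, 0.53532814, 0.44463454]])],
        "He": [("s", [6.36242139, 1.15892300, 0.31364979],
                [[0.15432897, 0.53532814, 0.44463454]])],
        "C": [("s", [71.6168370, 13.0450960, 3.5305122],
               [[0.15432897, 0.53532814, 0.44463454]]),
              ("sp", [2.9412494, 0.6834831, 0.2222899],
               [[-0.09996723, 0.39951283, 0.70011547],
                [0.15591627, 0.60768372, 0.39195739]])],
        "N": [("s", [99.1061690, 18.0523120, 4.8856602],
               [[0.15432897, 0.53532814, 0.44463454]]),
              ("sp", [3.7804559, 0.8784966, 0.2857144],
               [[-0.09996723, 0.39951283, 0.70011547],
                [0.15591627, 0.60768372, 0.39195739]])],
        "O": [("s", [130.7093200, 23.8088610, 6.4436083],
               [[0.15432897, 0.53532814, 0.44463454]]),
              ("sp", [5.0331513, 1.1695961, 0.3803890],
               [[-0.09996723, 0.39951283, 0.70011547],
                [0.15591627, 0.60768372, 0.39195739]])],
        "F": [("s", [166.6791300, 30.3608120, 8.2168207],
               [[0.15432897, 0.53532814, 0.44463454]]),
              ("sp", [6.4648032, 1.5022812, 0.4885885],
               [[-0.09996723, 0.39951283, 0.70011547],
                [0.15591627, 0.60768372, 0.39195739]])],
    },
    "6-31g": {
        "H": [("s", [18.7311370, 2.8253937, 0.6401217],
               [[0.03349460, 0.23472695, 0.81375733]]),
              ("s", [0.1612778], [[1.0]])],
        "O": [("s", [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570, 5.7996353],
               [[0.0018311, 0.0139501, 0.0684451, 0.2327143, 0.4701930, 0.3585209]]),
              ("sp", [15.539616, 3.5999336, 1.0137618],
               [[-0.1107775, -0.1480263, 1.1307670],
                [0.0708743, 0.3397528, 0.7271586]]),
              ("sp", [0.2700058], [[1.0], [1.0]])],
        "N": [("s", [4173.5110, 627.45790, 142.90210, 40.234330, 12.820210, 4.3904370],
               [[0.0018348, 0.0139950, 0.0685870, 0.2322410, 0.4690700, 0.3604550]]),
              ("sp", [11.626358, 2.7162800, 0.7722180],
               [[-0.1149610, -0.1691180, 1.1458520],
                [0.0675800, 0.3239070, 0.7408950]]),
              ("sp", [0.2120313], [[1.0], [1.0]])],
    },
}
# fmt: on


def available_basis_sets() -> list[str]:
    return sorted(_BASIS_LIBRARY)


def build_basis(atoms: list[tuple[str, np.ndarray]], basis_name: str) -> MoleculeBasis:
    """Assemble the molecular basis for ``atoms`` [(element, position-Bohr), ...]."""
    key = basis_name.lower()
    if key not in _BASIS_LIBRARY:
        raise ValueError(
            f"unknown basis {basis_name!r}; built-in sets: {available_basis_sets()}"
        )
    lib = _BASIS_LIBRARY[key]
    shells: list[BasisShell] = []
    for element, pos in atoms:
        if element not in lib:
            raise ValueError(f"basis {basis_name!r} has no data for element {element}")
        for ltype, exps, coefsets in lib[element]:
            if ltype == "s":
                shells.append(BasisShell(0, pos, exps, coefsets[0]))
            elif ltype == "p":
                shells.append(BasisShell(1, pos, exps, coefsets[0]))
            elif ltype == "sp":
                shells.append(BasisShell(0, pos, exps, coefsets[0]))
                shells.append(BasisShell(1, pos, exps, coefsets[1]))
            else:
                raise ValueError(f"unsupported shell type {ltype!r}")
    return MoleculeBasis(shells)
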