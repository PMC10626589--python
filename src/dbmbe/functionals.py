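"""Semilocal (GGA) kinetic and exchange-correlation energy densities.

The density-based correction needs a noninteracting kinetic energy and an
exchange-correlation energy evaluated from the density and its gradient
alone.  The defaults follow the standard orbital-free-DFT choice for
hydrogen-bonded clusters: the PW91k (LC94) gradient-corrected kinetic
functional and the PBE exchange-correlation functional, both closed-shell.

All routines are vectorized over grid points and operate on (rho, sigma)
with sigma = |grad rho|^2.  Densities below a clamping threshold are
treated as vacuum: signed many-body-expanded densities can be slightly
negative in exponential tails, where semilocal functionals are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import IntegrationGrid, integrate

__all__ = [
    "FunctionalSpec",
    "kinetic_energy_density",
    "xc_energy_density",
    "functional_energy",
    "C_TF",
]

C_TF = 0.3 * (3.0 * np.pi**2) ** (2.0 / 3.0)  # Thomas-Fermi constant
_KF_FAC = (3.0 * np.pi**2) ** (1.0 / 3.0)

# LC94 / PW91k enhancement-factor parameters
_LC94 = dict(a=0.093907, b=76.320, c=0.26608, d=0.0809615, e=100.0, f=0.57767e-4)

# PBE exchange
_PBE_KAPPA = 0.804
_PBE_MU = 0.2195149727645171

# PW92 uniform-gas correlation (unpolarized set) and PBE correlation
_PW92 = dict(A=0.031091, a1=0.21370, b1=7.5957, b2=3.5876, b3=1.6382, b4=0.49294)
_PBE_GAMMA = (1.0 - np.log(2.0)) / np.pi**2
_PBE_BETA = 0.06672455060314922

DEFAULT_CLAMP = 1e-10


@dataclass(frozen=True)
class FunctionalSpec:
    """Named functional choices plus the vacuum clamping threshold."""

    kinetic_name: str = "PW91k"
    xc_name: str = "PBE"
    clamp: float = DEFAULT_CLAMP

    def __post_init__(self):
        if self.kinetic_name.lower() not in ("pw91k", "lc94", "tf", "thomas-fermi"):
            raise ValueError(f"unknown kinetic functional {self.kinetic_name!r}")
        if self.xc_name.lower() not in ("pbe", "lda"):
            raise ValueError(f"unknown xc functional {self.xc_name!r}")


def _clamped(rho, sigma, clamp):
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    live = rho > clamp
    r = np.where(live, rho, 1.0)  # placeholder value; masked out below
    s = np.where(live, np.maximum(sigma, 0.0), 0.0)
    return r, s, live


def _pw91k_enhancement(s):
    p = _LC94
    x = p["a"] * s * np.arcsinh(p["b"] * s)
    num = 1.0 + x + (p["c"] - p["d"] * np.exp(-p["e"] * s**2)) * s**2
    den = 1.0 + x + p["f"] * s**4
    return num / den


def kinetic_energy_density(rho, sigma, spec: FunctionalSpec = FunctionalSpec()):
    """tau(r) = C_TF rho^{5/3} F(s) with the PW91k enhancement factor.

    ``spec.kinetic_name = "TF"`` gives the bare Thomas-Fermi limit F = 1.
    """
    r, s2, live = _clamped(rho, sigma, spec.clamp)
    tau = C_TF * r ** (5.0 / 3.0)
    if spec.kinetic_name.lower() in ("pw91k", "lc94"):
        s = np.sqrt(s2) / (2.0 * _KF_FAC * r ** (4.0 / 3.0))
        tau = tau * _pw91k_enhancement(s)
    return np.where(live, tau, 0.0)


def _pw92_eps_c(rs):
    p = _PW92
    q = 2.0 * p["A"] * (p["b1"] * np.sqrt(rs) + p["b2"] * rs
                        + p["b3"] * rs**1.5 + p["b4"] * rs**2)
    return -2.0 * p["A"] * (1.0 + p["a1"] * rs) * np.log1p(1.0 / q)


def xc_energy_density(rho, sigma, spec: FunctionalSpec = FunctionalSpec()):
    """PBE exchange-correlation energy density rho * eps_xc(rho, sigma).

    ``spec.xc_name = "LDA"`` drops both gradient corrections (Slater
    exchange + PW92 correlation).
    """
    r, s2, live = _clamped(rho, sigma, spec.clamp)
    grad = np.sqrt(s2)
    # exchange
    eps_x = -0.75 * (3.0 / np.pi) ** (1.0 / 3.0) * r ** (1.0 / 3.0)
    if spec.xc_name.lower() == "pbe":
        s = grad / (2.0 * _KF_FAC * r ** (4.0 / 3.0))
        fx = 1.0 + _PBE_KAPPA - _PBE_KAPPA / (1.0 + _PBE_MU * s**2 / _PBE_KAPPA)
        eps_x = eps_x * fx
    # correlation
    rs = (3.0 / (4.0 * np.pi * r)) ** (1.0 / 3.0)
    eps_c = _pw92_eps_c(rs)
    if spec.xc_name.lower() == "pbe":
        kf = _KF_FAC * r ** (1.0 / 3.0)
        ks = np.sqrt(4.0 * kf / np.pi)
        t2 = (grad / (2.0 * ks * r)) ** 2
        g, b = _PBE_GAMMA, _PBE_BETA
        # A -> infinity as eps_c -> 0-; guard the exponential
        expo = np.exp(np.minimum(-eps_c / g, 500.0)) - 1.0
        A = b / g / np.maximum(expo, 1e-300)
        num = 1.0 + A * t2
        den = 1.0 + A * t2 + (A * t2) ** 2
        H = g * np.log1p(b / g * t2 * num / den)
        eps_c = eps_c + H
    return np.where(live, r * (eps_x + eps_c), 0.0)


def functional_energy(
    grid: IntegrationGrid,
    fld,
    spec: FunctionalSpec = FunctionalSpec(),
    which: str = "kinetic",
) -> float:
    """Quadrature integral of the selected semilocal energy density.

    ``fld`` is a FieldOnGrid or ExpandedField; the (possibly signed)
    accumulated density is clamped at ``spec.clamp`` before evaluation.
    """
    rho = fld.density
    gradient = fld.gradient
    if gradient is None:
        raise ValueError("field carries no density gradient")
    sigma = np.einsum("ij,ij->i", gradient, gradient)
    if which == "kinetic":
        ed = kinetic_energy_density(rho, sigma, spec)
    elif which == "xc":
        ed = xc_energy_density(rho, sigma, spec)
    else:
        raise ValueError(f"unknown functional term {which!r}")
    return integrate(grid, ed)
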