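# Methods

This note records the model, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Expansions

For a cluster of N whole-molecule fragments, the interaction energy of a
subsystem S is defined recursively, ΔE_S = E_S − Σ_{T⊊S} ΔE_T, which equals
the Möbius / inclusion–exclusion sum Σ_{T⊆S} (−1)^{|S|−|T|} E_T. The
energy-based expansion eb-MBE(n) sums ΔE_S over all |S| ≤ n; at n = N it
telescopes to the supermolecular energy exactly, which the ledger code
guarantees to round-off. Both an order-by-order (recursive) evaluation and a
flattened form with closed-form coefficients c_k = (−1)^{n−k} C(N−k−1, n−k)
are implemented; they are algebraically identical, the recursive path is the
default and the flattened path serves as cross-check. The same coefficients
define the expanded density ρ⁽ⁿ⁾ = Σ_S c_S ρ_S and conserve the electron
count exactly (an integer identity tested for all 1 ≤ n ≤ N ≤ 8).

## The density-based correction

The correction is the difference between the orbital-free total-energy
functional evaluated on ρ⁽ⁿ⁾ (with all nuclei) and the truncated MBE of the
same functional over subsystem densities (each with its own nuclei). Term
choices and their rationale:

- **V_nuc, J** — linear/bilinear in ρ, evaluated exactly on the shared grid;
  v_Coul is computed analytically from the basis (never by solving Poisson on
  the grid), so J needs only one quadrature. The accumulated-potential form
  (cost linear in the number of subsystems) is the default; the pairwise
  double-sum form is retained as an oracle and must agree to 1e-10 Hartree.
- **E_NN** — pairwise additive, hence its truncated MBE is exact for every
  n ≥ 2; the implementation returns an analytic zero there rather than a
  rounded difference of ~10³ Hartree quantities, and evaluates the genuine
  first-order term at n = 1.
- **T̃_s, Ẽ_xc** — semilocal functionals (below); only their nonadditive
  parts survive the difference, which is what makes a semilocal
  approximation tolerable here.

Because every subsystem field lives on one shared supermolecular grid, the
signed combinations cancel *in quadrature*, not merely in the limit: at
n = N all five terms vanish to round-off regardless of grid quality.

## Functionals

Kinetic: Thomas–Fermi times the PW91k (LC94) enhancement factor
F(s) = (1 + a·s·asinh(b·s) + (c − d·e^{−100 s²}) s²) / (1 + a·s·asinh(b·s) + f·s⁴)
with a = 0.093907, b = 76.320, c = 0.26608, d = 0.0809615, f = 5.7767e-5,
s = |∇ρ| / (2 (3π²)^{1/3} ρ^{4/3}). Exchange–correlation: PBE
(κ = 0.804, μ = 0.2195149727645171, β = 0.06672455060314922,
γ = (1 − ln 2)/π²) on top of PW92 correlation, closed-shell throughout. The
implementations are validated against exact limits (Thomas–Fermi at s = 0,
the uniform-gas limit of PBE, λ² scaling of T under density dilation) and
against an independently coded arbitrary-precision (mpmath) implementation
of the same published parameterizations at 1000 random (ρ, σ) points to
1e-10 relative. A pure-TF and an LDA option exist for diagnostics.

Signed expanded densities can be slightly negative in exponential tails;
values below a clamp threshold (default 1e-10 a.u., configurable) are
treated as vacuum before functional evaluation, since semilocal functionals
are undefined for ρ < 0. The clamp affects T̃_s/Ẽ_xc only through regions
that contribute below quadrature accuracy.

## Quadrature

Atom-centered Becke-partitioned grids: Gauss–Chebyshev (second kind) radial
quadrature under Becke's rational map r = R(1+x)/(1−x) with Bragg–Slater
radii, a Gauss–Legendre × uniform-φ spherical product rule, Becke's
three-fold-iterated smoothing polynomial with atomic-size adjustment, and a
pruned (halved) angular set for radial shells inside 0.4 R_Bragg. Grid
levels 1–5 span (25, 8) to (110, 26) radial × θ points; the default level 3
= (70, 16) integrates a water-monomer HF density to 10 electrons within
1e-6 and reproduces erf-form Gaussian electrostatics to better than 1e-6
Hartree. Water-cluster production runs in the examples and the acceptance
script use level 2, where the electron count is good to ~1e-5 and the
*differences* assembled in the correction benefit from systematic
cancellation on the shared grid. Points landing within 1e-10 Bohr of a
nucleus (possible only for degenerate, hand-built grids) have that nucleus'
−Z/r term excluded rather than producing infinities.

## Backends

- **Built-in RHF**: McMurchie–Davidson integrals over contracted Cartesian
  Gaussians (s, p, d), Boys function via an erf closed form with stable
  upward recursion for T > 13 and a convergent series with downward
  recursion below, DIIS-accelerated SCF converged to 1e-10 Hartree, STO-3G
  and 6-31G built in for the water-cluster elements. One-electron systems
  are solved by core-Hamiltonian diagonalization. The engine is validated
  against published minimal-basis anchors (He, H₂, H) and by rotation/
  translation invariance at 1e-10.
- **Molden import**: standard and Orca dialects; the Orca d/f/g contraction
  coefficients are rescaled by √3/√15/√105 before use, and a Tr[DS] vs
  occupation-sum validation catches files read with the wrong dialect.
  Shells up to d are supported (spherical 5d or Cartesian), which covers
  double-zeta-class imports; f/g shells are rejected with a clear error —
  a known limitation for triple-zeta production imports.
- **Gaussian mock**: one normalized s-Gaussian per fragment plus a declared
  pair (+ optional triple) potential; every pipeline quantity has an
  erf-form closed expression, making the full stack testable analytically.

Densities from any single determinant use ρ = Σ_i n_i |φ_i|², with ∇ρ from
analytic orbital gradients and v_Coul from analytic Coulomb integrals
contracted with the density matrix in Hermite space (cost per grid point
linear in primitive pairs).

## Fixtures and what they show

The water generator builds rigid monomers (r_OH = 0.9572 Å, ∠HOH = 104.52°)
in two placements: a hydrogen-bonded ring (oxygens on a regular polygon,
O–O drawn from [2.7, 3.2] Å, each water donating one H to its neighbor) and
a random shell packing; orientations are seeded and reproducible. The ring
reproduces the physics the method targets — cooperative hydrogen-bond
polarization that a two-body truncation misses — and on it the density-based
two-body expansion cuts the error of the energy-based one by an order of
magnitude into the chemical-accuracy regime. The fixtures are *not* the
low-lying isomers of the literature (no external geometries are bundled),
the built-in engine is HF in a double-zeta basis rather than CCSD(T) in
aug-cc-pVTZ, and basis-set and correlation effects on the correction are
therefore not probed; what passing tests establish is the correctness of
the expansion algebra, the quadrature, the functionals and the import
machinery, plus the qualitative superiority of db-MBE(2) over eb-MBE(2) for
hydrogen-bonded clusters at reduced scale.

## Workflow

Runs are described by a YAML config (geometry, fragment spec and charges,
order, energy/density method and basis — the two may differ, grid level,
clamp, units). Subsystem energies and fields are cached in HDF5 keyed by
(subsystem, method, basis) and, for fields, a SHA-based grid signature, so
a changed grid can never be silently paired with stale fields; a warm rerun
performs zero backend calls and a killed run restarts with exactly the
remaining subsystems. Execution is sequential, ordered monomers → dimers →
trimers; parallel dispatch is a straightforward extension point. Energies
are Hartree internally; reports convert with 1 Hartree = 2625.4996394799
kJ/mol (CODATA 2018), and geometry I/O converts with 1 Å = 1/0.529177210903
Bohr.

## Known limitations

Closed-shell densities only (open-shell fragments must come through a
future import path); no embedding potentials in fragment calculations; no
counterpoise correction; Molden import capped at d shells; the built-in
engine is not intended beyond ~60 basis functions. Ionic fragments
(hydronium, hydroxide) are supported by the bookkeeping (explicit charge
maps) and by geometry I/O, and their densities import cleanly, but the
built-in engine computes them like any other closed-shell species — the
stronger many-body effects of charged clusters are not characterized here.
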