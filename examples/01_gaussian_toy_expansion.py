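"""Many-body expansions on a fully analytic Gaussian toy trimer.

Three single-Gaussian fragments with a declared pair + three-body potential:
every quantity has a closed form, so this is the fastest way to see the
machinery.  The energy-based expansion misses the three-body term at order
2 and becomes exact at order 3; the density-based correction vanishes
identically at full order.
"""

import numpy as np

from dbmbe import (
    GaussianToySpec,
    InteractionLedger,
    build_supermolecular_grid,
    db_mbe_total,
    enumerate_subsystems,
    make_gaussian_toy,
)

cluster, mock = make_gaussian_toy(
    GaussianToySpec(
        positions=((0.0, 0.0, 0.0), (4.0, 0.0, 0.0), (1.5, 3.5, 0.0)),
        charges=(2, 2, 2),
        c3=0.001,  # three-body term: makes the two-body truncation inexact
    )
)
grid = build_supermolecular_grid(cluster, level=3)
print(f"toy trimer, shared grid: {grid.size} points")

ledger = InteractionLedger()
fields = {}
for key in enumerate_subsystems(3, 3):
    ledger.set_total(key, mock.total_energy(key))
    fields[key] = mock.density_for(key, grid)

supermolecular = mock.total_energy((0, 1, 2))
print(f"supermolecular energy: {supermolecular:+.8f} Ha\n")
print(f"{'n':>2} {'eb-MBE(n)':>14} {'db-MBE(n)':>14} {'eb err':>10} {'db err':>10}")
for n in (1, 2, 3):
    res = db_mbe_total(ledger, fields, cluster, n, grid, supermolecular=supermolecular)
    print(f"{n:>2} {res.eb_energy:>14.8f} {res.db_energy:>14.8f} "
          f"{res.error_eb():>10.2e} {res.error_db():>10.2e}")

print(
    "\nAt n=3 both expansions reproduce the supermolecular energy exactly: the\n"
    "energy sum telescopes and the density correction cancels term by term on\n"
    "the shared grid.  At n=2 the residual eb error is the declared 3-body\n"
    "potential term that the pairwise truncation cannot see."
)
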