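"""The headline comparison on real electronic structure: four waters at HF.

Builds a hydrogen-bonded water-tetramer fixture, computes all monomer and
dimer energies and densities with the built-in RHF engine (6-31G), and
compares the two-body energy-based and density-based expansions against the
supermolecular HF energy.  Takes a couple of minutes on one core.
"""

import time

from dbmbe import (
    BackendRequest,
    HARTREE_TO_KJMOL,
    InteractionLedger,
    RhfBackend,
    WaterClusterSpec,
    build_supermolecular_grid,
    db_mbe_total,
    enumerate_subsystems,
    make_water_cluster,
    subsystem_geometry,
)

t0 = time.time()
cluster = make_water_cluster(WaterClusterSpec(n_waters=4, seed=11))
backend = RhfBackend()
grid = build_supermolecular_grid(cluster, level=2)
print(f"4 waters (hydrogen-bonded ring), shared grid: {grid.size} points")

ledger = InteractionLedger()
fields = {}
for key in enumerate_subsystems(4, 2):
    req = BackendRequest(geometry=subsystem_geometry(cluster, key), basis="6-31g")
    ledger.set_total(key, backend.compute_energy(req))
    fields[key] = backend.density_on_grid(req, grid, key)
print(f"{backend.calls} subsystem calculations (4 monomers + 6 dimers)")

sup = backend.compute_energy(
    BackendRequest(geometry=subsystem_geometry(cluster, (0, 1, 2, 3)), basis="6-31g")
)
res = db_mbe_total(ledger, fields, cluster, 2, grid, supermolecular=sup)

kj = HARTREE_TO_KJMOL
print(f"\nsupermolecular HF/6-31G : {sup:+.8f} Ha")
print(f"eb-MBE(2)               : {res.eb_energy:+.8f} Ha  "
      f"(error {res.error_eb() * kj:+8.3f} kJ/mol)")
print(f"db-MBE(2)               : {res.db_energy:+.8f} Ha  "
      f"(error {res.error_db() * kj:+8.3f} kJ/mol)")
c = res.correction
print("\ncorrection breakdown (kJ/mol):")
for label, v in [("electron-nuclei", c.v_nuc_term), ("Coulomb", c.coulomb_term),
                 ("nuclear repulsion", c.nn_term), ("nonadditive T_s", c.ts_nonadd),
                 ("nonadditive E_xc", c.xc_nonadd), ("total", c.total)]:
    print(f"  {label:<18} {v * kj:+10.3f}")
print(
    f"\nThe two-body energy expansion misses the cooperative (3- and 4-body)\n"
    f"polarization of the hydrogen-bonded ring; the orbital-free correction,\n"
    f"evaluated on the expanded density, recovers most of it.  "
    f"({time.time() - t0:.0f} s)"
)
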