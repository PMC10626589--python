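"""End-to-end orchestration: configuration, caching, execution, reporting.

A run takes a cluster geometry plus a :class:`RunConfig`, computes or loads
every subsystem energy and density field through the truncation order,
assembles eb-MBE(k) and db-MBE(k) for k = 1..n, and writes a plain-text and
a JSON report.  Energies and fields are cached in an HDF5 store keyed by
(subsystem, method, basis) and — for fields — by a hash of the quadrature
grid, because fields are grid-bound and a silent grid mismatch would poison
the signed-combination arithmetic.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import yaml

from .backend import BackendRequest, GaussianMockBackend, RhfBackend
from .constants import HARTREE_TO_KJMOL
from .dbcorr import DbMbeResult, db_mbe_total
from .fields import FieldOnGrid
from .functionals import FunctionalSpec
from .grid import DEFAULT_LEVEL, IntegrationGrid, build_supermolecular_grid
from .mbe import InteractionLedger, SubsystemKey, enumerate_subsystems
from .system import ClusterSystem, read_fragment_sidecar, read_xyz, subsystem_geometry

__all__ = ["RunConfig", "RunCache", "run", "report_text", "report_json"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    geometry: str                      # XYZ path
    order: int = 2
    fragment_spec: str = "auto"        # "auto" or path to a sidecar label file
    charges: dict = dc_field(default_factory=dict)   # fragment index -> charge
    energy_method: str = "HF"
    energy_basis: str = "6-31g"
    density_method: str | None = None  # defaults to energy_method
    density_basis: str | None = None   # defaults to energy_basis
    kinetic_functional: str = "PW91k"
    xc_functional: str = "PBE"
    grid_level: int = DEFAULT_LEVEL
    clamp: float = 1e-10
    cache: str | None = None           # HDF5 path
    backend: str = "rhf"               # "rhf" or "mock"
    supermolecular_reference: bool = False
    units: str = "kjmol"               # report units: "kjmol" or "hartree"

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.density_method is None:
            self.density_method = self.energy_method
        if self.density_basis is None:
            self.density_basis = self.energy_basis
        self.charges = {int(k): int(v) for k, v in (self.charges or {}).items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def functional_spec(self) -> FunctionalSpec:
        return FunctionalSpec(
            kinetic_name=self.kinetic_functional,
            xc_name=self.xc_functional,
            clamp=self.clamp,
        )


def _key_str(key: SubsystemKey) -> str:
    return "-".join(str(i) for i in key)


class RunCache:
    """HDF5-backed store of subsystem energies and grid fields."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    # energies -------------------------------------------------------------

    def get_energy(self, key, method, basis):
        with h5py.File(self.path, "a") as f:
            name = f"energies/{method}/{basis}/{_key_str(key)}"
            if name in f:
                return float(f[name][()])
        return None

    def set_energy(self, key, method, basis, value):
        with h5py.File(self.path, "a") as f:
            name = f"energies/{method}/{basis}/{_key_str(key)}"
            if name in f:
                del f[name]
            f[name] = float(value)

    # fields ---------------------------------------------------------------

    def get_field(self, key, method, basis, grid_sig):
        with h5py.File(self.path, "a") as f:
            name = f"fields/{method}/{basis}/{grid_sig}/{_key_str(key)}"
            if name not in f:
                return None
            g = f[name]
            return FieldOnGrid(
                subsystem=key,
                density=g["rho"][()],
                gradient=g["grad"][()],
                coulomb_potential=g["vcoul"][()] if "vcoul" in g else None,
                electron_count=float(g.attrs["electron_count"]),
            )

    def set_field(self, key, method, basis, grid_sig, fld: FieldOnGrid):
        with h5py.File(self.path, "a") as f:
            name = f"fields/{method}/{basis}/{grid_sig}/{_key_str(key)}"
            if name in f:
                del f[name]
            g = f.create_group(name)
            g["rho"] = fld.density
            g["grad"] = fld.gradient
            if fld.coulomb_potential is not None:
                g["vcoul"] = fld.coulomb_potential
            g.attrs["electron_count"] = fld.electron_count


def load_cluster(config: RunConfig) -> ClusterSystem:
    spec = config.fragment_spec
    if spec not in (None, "auto") and Path(spec).exists():
        spec = read_fragment_sidecar(spec)
    return read_xyz(config.geometry, fragment_spec=spec or "auto", charges=config.charges)


def _make_backend(config: RunConfig):
    if config.backend == "rhf":
        return RhfBackend()
    raise ValueError(
        f"unknown backend {config.backend!r}; the mock backend is constructed "
        "programmatically via dbmbe.fixtures.make_gaussian_toy"
    )


@dataclass
class RunOutput:
    result: DbMbeResult
    cluster: ClusterSystem
    grid: IntegrationGrid
    config: RunConfig
    backend_calls: int
    log: list


def run(config: RunConfig, backend=None, cluster: ClusterSystem | None = None,
        grid: IntegrationGrid | None = None) -> RunOutput:
    """Execute a full eb-/db-MBE run.

    ``backend`` may be a ready-made backend object (e.g. a
    :class:`GaussianMockBackend`); by default it is built from the config.
    On a warm cache a rerun performs zero backend calculations.  Any failed
    subsystem aborts the run with a manifest of completed/failed subsystems
    (the cache keeps completed work, so the run is restartable).
    """
    t_start = time.time()
    if cluster is None:
        cluster = load_cluster(config)
    if backend is None:
        backend = _make_backend(config)
    if grid is None:
        grid = build_supermolecular_grid(cluster, config.grid_level)
    cache = RunCache(config.cache) if config.cache else None
    sig = grid.signature()
    N = cluster.n_fragments
    keys = enumerate_subsystems(N, config.order)
    is_mock = isinstance(backend, GaussianMockBackend)

    log = []
    ledger = InteractionLedger()
    fields: dict[SubsystemKey, FieldOnGrid] = {}
    calls = 0
    done = []
    try:
        for key in keys:
            e = cache.get_energy(key, config.energy_method, config.energy_basis) if cache else None
            if e is None:
                if is_mock:
                    e = backend.total_energy(key)
                else:
                    req = BackendRequest(
                        geometry=subsystem_geometry(cluster, key),
                        method=config.energy_method, basis=config.energy_basis,
                    )
                    e = backend.compute_energy(req)
                calls += 1
                if cache:
                    cache.set_energy(key, config.energy_method, config.energy_basis, e)
                log.append(f"energy {_key_str(key)} computed ({config.energy_method}/{config.energy_basis})")
            else:
                log.append(f"energy {_key_str(key)} cache hit")
            ledger.set_total(key, e)

            fld = cache.get_field(key, config.density_method, config.density_basis, sig) if cache else None
            if fld is None:
                if is_mock:
                    fld = backend.density_for(key, grid)
                else:
                    req = BackendRequest(
                        geometry=subsystem_geometry(cluster, key),
                        method=config.density_method, basis=config.density_basis,
                        want_density=True,
                    )
                    fld = backend.density_on_grid(req, grid, key)
                calls += 1
                if cache:
                    cache.set_field(key, config.density_method, config.density_basis, sig, fld)
                log.append(f"field {_key_str(key)} computed ({config.density_method}/{config.density_basis})")
            else:
                log.append(f"field {_key_str(key)} cache hit")
            fields[key] = fld
            done.append(key)
    except Exception as exc:
        failed = keys[len(done)] if len(done) < len(keys) else None
        manifest = {
            "completed": [_key_str(k) for k in done],
            "failed": _key_str(failed) if failed else None,
            "remaining": [_key_str(k) for k in keys[len(done) + 1:]],
            "error": str(exc),
        }
        raise RuntimeError(
            f"subsystem calculation failed for {failed}: {exc}\n"
            f"manifest: {json.dumps(manifest)}"
        ) from exc

    sup = None
    if config.supermolecular_reference:
        full = tuple(range(N))
        if full in ledger.total_energies:
            sup = ledger.total(full)
        else:
            sup = cache.get_energy(full, config.energy_method, config.energy_basis) if cache else None
            if sup is None:
                if is_mock:
                    sup = backend.total_energy(full)
                else:
                    sup = backend.compute_energy(BackendRequest(
                        geometry=subsystem_geometry(cluster, full),
                        method=config.energy_method, basis=config.energy_basis,
                    ))
                calls += 1
                if cache:
                    cache.set_energy(full, config.energy_method, config.energy_basis, sup)

    result = db_mbe_total(
        ledger, fields, cluster, config.order, grid,
        spec=config.functional_spec(), supermolecular=sup,
    )
    log.append(f"run finished in {time.time() - t_start:.1f} s, {calls} backend calculations")
    return RunOutput(result=result, cluster=cluster, grid=grid, config=config,
                     backend_calls=calls, log=log)


# ---------------------------------------------------------------------------
# reporting


def _conv(units: str) -> tuple[float, str]:
    if units.lower() in ("kjmol", "kj/mol"):
        return HARTREE_TO_KJMOL, "kJ/mol"
    if units.lower() in ("hartree", "ha", "a.u.", "au"):
        return 1.0, "Hartree"
    raise ValueError(f"unknown unit system {units!r}")


def report_json(output: RunOutput) -> dict:
    """Machine-readable report (energies in Hartree; errors also in kJ/mol)."""
    r = output.result
    c = r.correction
    data = {
        "cluster": output.cluster.name,
        "n_fragments": output.cluster.n_fragments,
        "order": r.order,
        "eb_energy_hartree": r.eb_energy,
        "db_energy_hartree": r.db_energy,
        "correction_hartree": {
            "v_nuc": c.v_nuc_term, "coulomb": c.coulomb_term, "e_nn": c.nn_term,
            "ts_nonadd": c.ts_nonadd, "xc_nonadd": c.xc_nonadd, "total": c.total,
        },
        "per_order": [
            {"order": k, "eb_hartree": eb, "db_hartree": db} for k, eb, db in r.per_order
        ],
        "backend_calculations": output.backend_calls,
    }
    if r.supermolecular is not None:
        data["supermolecular_hartree"] = r.supermolecular
        data["eb_error_kjmol"] = r.error_eb() * HARTREE_TO_KJMOL
        data["db_error_kjmol"] = r.error_db() * HARTREE_TO_KJMOL
    return data


def report_text(output: RunOutput) -> str:
    r = output.result
    c = r.correction
    fac, unit = _conv(output.config.units)
    lines = [
        f"cluster {output.cluster.name}: {output.cluster.n_fragments} fragments, "
        f"truncation order {r.order}",
        f"backend calculations this run: {output.backend_calls}",
        "",
        f"{'order':>5} {'eb-MBE':>18} {'db-MBE':>18}   [{unit}]",
    ]
    for k, eb, db in r.per_order:
        lines.append(f"{k:>5} {eb * fac:>18.8f} {db * fac:>18.8f}")
    lines += [
        "",
        f"density-based correction at order {r.order} [{unit}]:",
        f"  electron-nuclei   {c.v_nuc_term * fac:>16.8f}",
        f"  Coulomb           {c.coulomb_term * fac:>16.8f}",
        f"  nuclear repulsion {c.nn_term * fac:>16.8f}",
        f"  nonadditive T_s   {c.ts_nonadd * fac:>16.8f}",
        f"  nonadditive E_xc  {c.xc_nonadd * fac:>16.8f}",
        f"  total             {c.total * fac:>16.8f}",
    ]
    if r.supermolecular is not None:
        lines += [
            "",
            f"supermolecular reference: {r.supermolecular * fac:.8f} {unit}",
            f"eb-MBE({r.order}) error: {r.error_eb() * fac:+.6f} {unit}",
            f"db-MBE({r.order}) error: {r.error_db() * fac:+.6f} {unit}",
        ]
    return "\n".join(lines) + "\n"


def write_reports(output: RunOutput, stem) -> tuple[Path, Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    txt = stem.with_suffix(".txt")
    js = stem.with_suffix(".json")
    txt.write_text(report_text(output))
    js.write_text(json.dumps(report_json(output), indent=2))
    return txt, js
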