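"""Orchestration: configuration, caching, restartability, reports, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from dbmbe.cli import main as cli_main
from dbmbe.constants import HARTREE_TO_KJMOL
from dbmbe.fixtures import GaussianToySpec, WaterClusterSpec, make_gaussian_toy, make_water_cluster
from dbmbe.grid import build_supermolecular_grid
from dbmbe.system import write_xyz
from dbmbe.workflow import (
    RunCache,
    RunConfig,
    load_cluster,
    report_json,
    report_text,
    run,
    write_reports,
)


@pytest.fixture()
def toy_setup(tmp_path):
    cluster, mock = make_gaussian_toy(
        GaussianToySpec(positions=((0.0, 0.0, 0.0), (4.0, 0.0, 0.0), (1.5, 3.5, 0.0)),
                        charges=(2, 2, 2), c3=0.001)
    )
    xyz = tmp_path / "toy.xyz"
    write_xyz(cluster, xyz)
    config = RunConfig(
        geometry=str(xyz), order=3, backend="mock", grid_level=1,
        cache=str(tmp_path / "cache.h5"), supermolecular_reference=True,
    )
    grid = build_supermolecular_grid(cluster, 1)
    return cluster, mock, config, grid


def test_full_order_run_reaches_supermolecular(toy_setup):
    cluster, mock, config, grid = toy_setup
    out = run(config, backend=mock, cluster=cluster, grid=grid)
    assert out.result.db_energy == pytest.approx(mock.total_energy((0, 1, 2)), abs=1e-8)
    # 7 energies + 7 fields; the supermolecular reference reuses the ledger
    assert out.backend_calls == 2 * 7


def test_warm_cache_rerun_makes_zero_backend_calls(toy_setup):
    cluster, mock, config, grid = toy_setup
    config.supermolecular_reference = False
    first = run(config, backend=mock, cluster=cluster, grid=grid)
    assert first.backend_calls == 14
    second = run(config, backend=mock, cluster=cluster, grid=grid)
    assert second.backend_calls == 0
    assert second.result.db_energy == first.result.db_energy  # bit-identical cache


def test_restartability_after_partial_cache(toy_setup):
    """Pre-seeding m subsystems leaves exactly (total - m) calculations."""
    cluster, mock, config, grid = toy_setup
    config.supermolecular_reference = False
    cache = RunCache(config.cache)
    sig = grid.signature()
    pre = [(0,), (1,), (0, 1)]
    for key in pre:
        cache.set_energy(key, config.energy_method, config.energy_basis,
                         mock.total_energy(key))
        cache.set_field(key, config.density_method, config.density_basis, sig,
                        mock.density_for(key, grid))
    out = run(config, backend=mock, cluster=cluster, grid=grid)
    assert out.backend_calls == 2 * (7 - len(pre))


def test_grid_signature_mismatch_forces_recompute(toy_setup):
    cluster, mock, config, grid = toy_setup
    config.supermolecular_reference = False
    run(config, backend=mock, cluster=cluster, grid=grid)
    other_grid = build_supermolecular_grid(cluster, 2)
    out = run(config, backend=mock, cluster=cluster, grid=other_grid)
    assert out.backend_calls == 7  # fields recomputed, energies still cached


def test_subsystem_count_matches_binomial_sum(tmp_path):
    """A cold-cache order-2 run on 4 fragments performs 10 calculations."""
    cluster, mock = make_gaussian_toy(
        GaussianToySpec(positions=tuple((3.5 * i, 0.0, 0.0) for i in range(4)))
    )
    config = RunConfig(geometry="unused.xyz", order=2, backend="mock", grid_level=1)
    grid = build_supermolecular_grid(cluster, 1)
    out = run(config, backend=mock, cluster=cluster, grid=grid)
    assert out.backend_calls == 2 * 10  # 4 monomers + 6 dimers, energy + field


def test_failed_subsystem_aborts_with_manifest(toy_setup):
    cluster, mock, config, grid = toy_setup
    config.supermolecular_reference = False
    boom = (0, 2)
    orig_fn = mock.total_energy

    def failing(key):
        if key == boom:
            raise RuntimeError("engine blew up")
        return orig_fn(key)

    mock.total_energy = failing  # instance-level override; fixture is per-test
    with pytest.raises(RuntimeError, match="manifest") as exc:
        run(config, backend=mock, cluster=cluster, grid=grid)
    msg = str(exc.value)
    assert "completed" in msg and "0-2" in msg


def test_reports_roundtrip_and_units(toy_setup, tmp_path):
    cluster, mock, config, grid = toy_setup
    out = run(config, backend=mock, cluster=cluster, grid=grid)
    data = report_json(out)
    assert data["db_energy_hartree"] == pytest.approx(
        data["eb_energy_hartree"] + data["correction_hartree"]["total"], abs=1e-14
    )
    txt, js = write_reports(out, tmp_path / "report")
    back = json.loads(js.read_text())
    assert back["eb_energy_hartree"] == data["eb_energy_hartree"]
    # kJ/mol conversion uses the declared constant
    assert "supermolecular reference" in txt.read_text()
    config.units = "hartree"
    t2 = report_text(out)
    assert "Hartree" in t2
    # no reference -> error lines omitted, not zero-filled
    out.result.supermolecular = None
    t3 = report_text(out)
    assert "error" not in t3
    with pytest.raises(ValueError):
        config.units = "calories"
        report_text(out)


def test_config_yaml_roundtrip(tmp_path):
    cfg = RunConfig(geometry="g.xyz", order=2, charges={0: 1}, grid_level=2)
    path = tmp_path / "c.yaml"
    cfg.to_yaml(path)
    back = RunConfig.from_yaml(path)
    assert back.__dict__ == cfg.__dict__
    assert back.density_method == "HF"  # defaulted from energy method


def test_cli_fixture_generation_and_cluster_load(tmp_path):
    runner = CliRunner()
    out_xyz = tmp_path / "w4.xyz"
    result = runner.invoke(
        cli_main,
        ["fixtures", "make-water", "--n", "4", "--seed", "7", "--out", str(out_xyz)],
    )
    assert result.exit_code == 0, result.output
    assert out_xyz.exists() and out_xyz.with_suffix(".frag").exists()
    # determinism: same seed -> identical file
    out2 = tmp_path / "w4b.xyz"
    runner.invoke(cli_main, ["fixtures", "make-water", "--n", "4", "--seed", "7",
                             "--out", str(out2)])
    assert out2.read_text() == out_xyz.read_text()
    cfg = RunConfig(geometry=str(out_xyz), fragment_spec=str(out_xyz.with_suffix(".frag")))
    cluster = load_cluster(cfg)
    assert cluster.n_fragments == 4
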