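"""Orchestration: initialization, stepping, determinism, I/O, analysis."""

import dataclasses

import numpy as np
import pytest

from biofilmsim import io as bio_io
from biofilmsim.driver import (Simulation, analyze, frames_to_table,
                               initialize, run_replicates)
from biofilmsim.interactions import total_forces
from biofilmsim.nutrient_field import NutrientGrid
from biofilmsim.params import ModelParams


@pytest.fixture
def fast_params(params):
    # tiny colony target keeps driver tests to seconds
    return dataclasses.replace(params, Ks_star=1e-9, max_biomass=12.0,
                               seed=3)


class TestInitialize:
    def test_wall_force_equilibrium(self, params, rng):
        colony, _ = initialize(params, rng)
        (ft,) = total_forces(colony.to_cells(), params)
        assert abs(ft.F[2]) < 1e-6

    def test_uniform_bulk_field(self, params, rng):
        _, grid = initialize(params, rng)
        assert grid.C.min() == grid.C.max() == params.C0

    def test_single_horizontal_cell(self, params, rng):
        colony, _ = initialize(params, rng)
        assert colony.n == 1
        assert colony.Lstar[0] == params.L0_star
        assert colony.ori[0, 2] == 0.0

    def test_seed_determines_azimuth(self, params):
        c1, _ = initialize(params, np.random.default_rng(5))
        c2, _ = initialize(params, np.random.default_rng(5))
        c3, _ = initialize(params, np.random.default_rng(6))
        np.testing.assert_array_equal(c1.ori, c2.ori)
        assert not np.array_equal(c1.ori, c3.ori)

    def test_margin_from_dirichlet_faces(self, params, rng):
        colony, grid = initialize(params, rng)
        idx = np.floor((colony.pos[0] - grid.origin) / grid.h).astype(int)
        shape = np.array(grid.shape)
        assert np.all(idx[:2] >= 3) and np.all(idx[:2] <= shape[:2] - 4)
        assert idx[2] <= shape[2] - 4


class TestStepContracts:
    def test_zero_nutrient_freezes_biomass(self, params):
        sim = Simulation(dataclasses.replace(params, seed=1))
        sim.grid.C[:] = 0.0
        sim.grid.C0 = 0.0
        m0 = sim.colony.biomass
        for _ in range(300):
            sim.step()
        assert sim.colony.biomass == m0
        assert np.all(sim.colony.growth == 0.0)

    def test_same_seed_bit_identical_state(self, params):
        def run(seed, n=2000):
            sim = Simulation(dataclasses.replace(params, seed=seed))
            for _ in range(n):
                sim.step()
            return sim

        a = run(9)
        b = run(9)
        np.testing.assert_array_equal(a.colony.pos, b.colony.pos)
        np.testing.assert_array_equal(a.colony.ori, b.colony.ori)
        np.testing.assert_array_equal(a.colony.Lstar, b.colony.Lstar)
        np.testing.assert_array_equal(a.grid.C, b.grid.C)

    def test_time_advances_by_dt(self, params):
        sim = Simulation(params)
        for _ in range(10):
            sim.step()
        assert sim.t == pytest.approx(10 * params.dt)


class TestGridExpansion:
    def test_expansion_preserves_existing_values(self, params, rng):
        sim = Simulation(dataclasses.replace(params, seed=2))
        g = sim.grid
        g.C = rng.uniform(0.5, 1.0, g.shape)
        C_old = g.C.copy()
        origin_old = g.origin.copy()
        shape_old = g.shape
        # push the cell towards the +x Dirichlet face
        sim.colony.pos[0, 0] = g.origin[0] + (shape_old[0] - 1.5) * g.h
        sim._ensure_margin()
        assert sim.grid.shape[0] > shape_old[0]
        shift = np.round((origin_old - sim.grid.origin) / g.h).astype(int)
        sl = tuple(slice(shift[ax], shift[ax] + shape_old[ax])
                   for ax in range(3))
        np.testing.assert_array_equal(sim.grid.C[sl], C_old)
        # new shells filled with bulk concentration
        assert sim.grid.C.sum() == pytest.approx(
            C_old.sum() + (sim.grid.C.size - C_old.size) * params.C0)

    def test_no_expansion_when_colony_is_central(self, params):
        sim = Simulation(params)
        shape_before = sim.grid.shape
        sim._ensure_margin()
        assert sim.grid.shape == shape_before


class TestSnapshotIO:
    def test_snapshot_round_trip_lossless(self, tmp_path, params, rng):
        sim = Simulation(dataclasses.replace(params, seed=4))
        for _ in range(500):
            sim.step()
        path = tmp_path / "snap.tsv"
        bio_io.write_snapshot(path, sim.t, sim.colony)
        t, colony = bio_io.read_snapshot(path)
        assert t == sim.t
        np.testing.assert_array_equal(colony.pos, sim.colony.pos)
        np.testing.assert_array_equal(colony.ori, sim.colony.ori)
        np.testing.assert_array_equal(colony.Lstar, sim.colony.Lstar)
        np.testing.assert_array_equal(colony.ids, sim.colony.ids)

    def test_grid_round_trip_lossless(self, tmp_path, params, rng):
        grid = NutrientGrid.uniform((5, 4, 3), params.grid_h)
        grid.C = rng.uniform(0, 1, grid.shape)
        bio_io.write_grid(tmp_path / "grid.tsv", grid, t=1.25)
        t, back = bio_io.read_grid(tmp_path / "grid.tsv")
        assert t == 1.25
        np.testing.assert_array_equal(back.C, grid.C)
        np.testing.assert_array_equal(back.origin, grid.origin)
        assert back.h == grid.h


class TestRunAndAnalyze:
    def test_stop_contract_on_biomass(self, tmp_path, fast_params):
        sim = Simulation(fast_params, out_dir=tmp_path / "run")
        frames = sim.run()
        assert frames[-1].m >= fast_params.max_biomass
        assert frames[-2].m < fast_params.max_biomass
        ms = [f.m for f in frames]
        assert ms == sorted(ms)

    def test_analysis_reproduces_in_run_frames(self, tmp_path, fast_params):
        out = tmp_path / "run"
        sim = Simulation(fast_params, out_dir=out)
        frames = sim.run()
        result = analyze(out, biomass_checkpoints=(6.0,))
        table = result["observables"]
        in_run = frames_to_table(frames)
        for col in ("m", "N", "a", "b", "c", "Tp", "Bp", "S2", "rho"):
            np.testing.assert_allclose(table[col].to_numpy(),
                                       in_run[col].to_numpy(),
                                       atol=1e-10, equal_nan=True)
        assert "g2" in result and "profiles" in result

    def test_replicates_average_with_standard_errors(self, tmp_path,
                                                     fast_params):
        p = dataclasses.replace(fast_params, max_biomass=7.0)
        table = run_replicates(p, 2, out_dir=tmp_path / "reps")
        assert "m_sem" in table.columns
        assert len(table) >= 2
        assert (tmp_path / "reps" / "rep_000" / "observables.tsv").exists()
        assert (tmp_path / "reps" / "observables_mean.tsv").exists()

    def test_config_file_round_trip(self, tmp_path, params):
        p = dataclasses.replace(params, Ks_star=0.7, seed=17)
        path = tmp_path / "params.cfg"
        p.to_file(path)
        back = ModelParams.from_file(path)
        assert back == p

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("not_a_parameter = 1\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelParams.from_file(path)


def test_cli_run_and_analyze(tmp_path):
    from click.testing import CliRunner
    from biofilmsim.cli import main

    cfg = tmp_path / "params.cfg"
    ModelParams(Ks_star=1e-9, max_biomass=8.0, seed=5).to_file(cfg)
    runner = CliRunner()
    out = tmp_path / "out"
    res = runner.invoke(main, ["run", "--config", str(cfg),
                               "--seed", "5", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "observables.tsv").exists()
    res2 = runner.invoke(main, ["analyze", "--in", str(out),
                                "--out", str(tmp_path / "tables"),
                                "--checkpoint", "6"])
    assert res2.exit_code == 0, res2.output
    assert (tmp_path / "tables" / "observables.tsv").exists()
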