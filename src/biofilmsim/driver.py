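"""Simulation orchestration: initialization, stepping, runs and analysis.

One timestep couples all the pieces in a fixed order: (1) forces and
torques, (2) Brownian-dynamics move, (3) per-cell Monod uptake from the
local compartment concentration (with availability scaling) and the derived
elongation rates, (4) elongation and binary fission, (5) the explicit
nutrient-diffusion update.  A run starts from a single cell resting on the
substrate at its wall-force equilibrium height in a uniform nutrient bath,
and stops at a biomass (default) or time criterion, recording observable
frames and plain-text snapshots on a logarithmic-in-biomass schedule.  The
nutrient grid auto-expands with new bulk-concentration shells whenever the
colony approaches within three compartments of a Dirichlet face.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as bio_io
from .dynamics import bd_step_arrays
from .geometry import Colony
from .growth_division import divide_colony, elongate_colony
from .interactions import total_forces_arrays
from .nutrient_field import (GridBoundsError, NutrientGrid, compute_uptake,
                             diffusion_step)
from .observables import (ObservableFrame, biomass, density, ellipsoid_fit,
                          geometry_metrics, nematic_order,
                          orientational_correlation, radial_profiles,
                          shape_params)
from .params import ModelParams

__all__ = ["Simulation", "initialize", "equilibrium_height", "compute_frame",
           "run_replicates", "analyze", "frames_to_table"]

logger = logging.getLogger(__name__)

#: Minimum number of compartments between the colony and any Dirichlet face.
GRID_MARGIN = 3
#: Compartments added per side when the margin is violated.
GRID_EXPAND = 2
#: Steps between log summaries.
LOG_STRIDE = 50_000
#: Steps between grid-margin checks (cells move << h between checks).
MARGIN_CHECK_STRIDE = 50


def equilibrium_height(params: ModelParams) -> float:
    """Centre height of a horizontal cell where the net wall force is zero.

    Balances the substrate repulsion against the adhesion spring for a
    single horizontal cell of aspect ratio L0* (for which d_iw = r_z).
    """
    def net(rz: float) -> float:
        u = params.sigma_w / rz
        rep = (params.eps_rep / rz) * (1.2 * u ** 10 - 3.0 * u ** 4)
        return rep - params.eps_att * params.L0_star * rz

    lo, hi = 0.2 * params.d_rep, params.d_rep * (1 - 1e-12)
    return float(brentq(net, lo, hi, xtol=1e-12))


def initialize(params: ModelParams,
               rng: np.random.Generator) -> tuple[Colony, NutrientGrid]:
    """Single founder cell on the substrate in a uniform nutrient bath.

    The cell lies horizontally (random azimuth) at the wall-force
    equilibrium height; the grid is sized so the colony starts well clear
    of every Dirichlet face and the field is uniform at C0.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    e = np.array([np.cos(phi), np.sin(phi), 0.0])
    r = np.array([0.0, 0.0, equilibrium_height(params)])
    colony = Colony(ids=[0], pos=r[None, :], ori=e[None, :],
                    Lstar=[params.L0_star], next_id=1)
    n_lat = 2 * (GRID_MARGIN + 1) + 3   # colony compartment + margins + walls
    nz = GRID_MARGIN + 4
    grid = NutrientGrid.uniform((n_lat, n_lat, nz), params.grid_h,
                                C0=params.C0)
    return colony, grid


def compute_frame(colony: Colony, grid: NutrientGrid, params: ModelParams,
                  t: float, frame_index: int,
                  with_profiles: bool = False,
                  with_g2: bool = False) -> ObservableFrame:
    """All observables for one snapshot.

    The axis-point sampling RNG is derived deterministically from the run
    seed and the frame index, so re-analysis of a stored snapshot
    reproduces the in-run frame exactly.
    """
    rng = np.random.default_rng([int(params.seed), 7, int(frame_index)])
    m = biomass(colony)
    frame = ObservableFrame(t=t, m=m, N=colony.n, fit=None)
    if colony.n >= 1:
        frame.S2 = nematic_order(colony)
    if colony.n >= 2:
        fit = ellipsoid_fit(colony, rng)
        frame.fit = fit
        frame.Ve, frame.Ae, frame.Az = geometry_metrics(fit)
        frame.c = fit.c
        frame.rho = density(m, frame.Ve)
        frame.Tp, frame.Bp = shape_params(fit)
        if with_g2:
            frame.gr2 = orientational_correlation(
                colony, r_max=30.0, bin_width=1.0)
        if with_profiles:
            frame.profiles = radial_profiles(colony, grid)
    return frame


def frames_to_table(frames: list[ObservableFrame]) -> pd.DataFrame:
    df = pd.DataFrame([f.to_row() for f in frames])
    df.insert(0, "frame", np.arange(len(frames)))
    return df


class Simulation:
    """One replicate of the biofilm growth model.

    Parameters
    ----------
    params
        Model constants; ``params.seed`` seeds the dynamics RNG.
    out_dir
        Optional output directory; when given, snapshots, grid dumps, the
        observable table and a log are written there.
    """

    def __init__(self, params: ModelParams, out_dir: str | Path | None = None):
        self.params = params
        self.out_dir = Path(out_dir) if out_dir is not None else None
        self.rng = np.random.default_rng(params.seed)
        self.colony, self.grid = initialize(params, self.rng)
        self.t = 0.0
        self.step_index = 0
        self.frames: list[ObservableFrame] = []
        self._sink_accum = np.zeros(self.grid.shape)
        self._stride_count = 0
        self._next_measure_m = self.colony.biomass * params.snapshot_factor
        self._n_capped_total = 0
        if self.out_dir is not None:
            (self.out_dir / "snapshots").mkdir(parents=True, exist_ok=True)
            (self.out_dir / "grids").mkdir(parents=True, exist_ok=True)
            params.to_file(self.out_dir / "params.cfg")
            self._log_fh = open(self.out_dir / "log.txt", "w")
        else:
            self._log_fh = None

    # ---- grid management ---------------------------------------------------

    def _ensure_margin(self) -> None:
        """Expand the grid if the colony is near a Dirichlet face.

        New shells are filled with the bulk concentration; pre-existing
        compartment values are preserved exactly.
        """
        g = self.grid
        lo = np.floor((self.colony.pos.min(axis=0) - g.origin) / g.h)
        hi = np.floor((self.colony.pos.max(axis=0) - g.origin) / g.h)
        shape = np.array(g.shape)
        pad_lo = np.zeros(3, dtype=int)
        pad_hi = np.zeros(3, dtype=int)
        for ax in range(3):
            if ax < 2 and lo[ax] < GRID_MARGIN:
                pad_lo[ax] = GRID_EXPAND + max(0, GRID_MARGIN - int(lo[ax]))
            if hi[ax] > shape[ax] - 1 - GRID_MARGIN:
                pad_hi[ax] = GRID_EXPAND + max(
                    0, int(hi[ax]) - (shape[ax] - 1 - GRID_MARGIN))
        if pad_lo.any() or pad_hi.any():
            new_shape = shape + pad_lo + pad_hi
            C_new = np.full(tuple(new_shape), g.C0)
            sl = tuple(slice(pad_lo[ax], pad_lo[ax] + shape[ax])
                       for ax in range(3))
            C_new[sl] = g.C
            g.C = C_new
            g.origin = g.origin - pad_lo * g.h
            sink_new = np.zeros(tuple(new_shape))
            sink_new[sl] = self._sink_accum
            self._sink_accum = sink_new
            logger.info("grid expanded to %s at t = %.3f", tuple(new_shape),
                        self.t)

    # ---- core loop ---------------------------------------------------------

    def step(self) -> None:
        """Advance the full model by one timestep dt."""
        p = self.params
        col = self.colony
        F, T, n_capped = total_forces_arrays(
            col.pos, col.ori, col.half_lengths, col.Lstar, p)
        self._n_capped_total += n_capped
        noise = self.rng.standard_normal((col.n, 5))
        bd_step_arrays(col.pos, col.ori, F, T, col.Lstar, p.D0,
                       p.dt, p.kBT, noise)
        # the margin check is strided: cells move far less than one
        # compartment edge between checks
        if self.step_index % MARGIN_CHECK_STRIDE == 0:
            self._ensure_margin()
        try:
            mu, v, sinks = compute_uptake(col, self.grid, p, p.dt)
        except GridBoundsError:
            self._ensure_margin()
            mu, v, sinks = compute_uptake(col, self.grid, p, p.dt)
        col.uptake = mu
        col.growth = v
        mask = elongate_colony(col, v, p.dt, p)
        if mask.any():
            divide_colony(col, mask)
        self._sink_accum += sinks
        self._stride_count += 1
        if self._stride_count >= p.nutrient_stride:
            diffusion_step(self.grid,
                           self._sink_accum / self._stride_count,
                           p.dt * self._stride_count, p.DN)
            self._sink_accum[:] = 0.0
            self._stride_count = 0
        self.t += p.dt
        self.step_index += 1

    def _measure(self) -> None:
        k = len(self.frames)
        frame = compute_frame(self.colony, self.grid, self.params,
                              self.t, k)
        self.frames.append(frame)
        if self.out_dir is not None:
            bio_io.write_snapshot(
                self.out_dir / "snapshots" / f"snap_{k:05d}.tsv",
                self.t, self.colony)
            bio_io.write_grid(
                self.out_dir / "grids" / f"grid_{k:05d}.tsv",
                self.grid, self.t)

    def _log_summary(self) -> None:
        if self._log_fh is not None:
            col = self.colony
            self._log_fh.write(
                f"step={self.step_index} t={self.t:.4f} N={col.n} "
                f"m={col.biomass:.3f} Cmin={self.grid.C.min():.4f} "
                f"capped={self._n_capped_total}\n")
            self._log_fh.flush()

    def run(self) -> list[ObservableFrame]:
        """Run to the stop criterion, recording frames along the way.

        Measurement points are logarithmically spaced in biomass
        (successive snapshot biomasses differ by ``snapshot_factor``); a
        frame is always recorded at the start and at the stop point.
        """
        p = self.params
        self._measure()
        try:
            while (self.colony.biomass < p.max_biomass
                   and self.t < p.max_time):
                self.step()
                if self.colony.biomass >= self._next_measure_m:
                    self._measure()
                    self._next_measure_m = (self.colony.biomass
                                            * p.snapshot_factor)
                if self.step_index % LOG_STRIDE == 0:
                    self._log_summary()
        except FloatingPointError:
            if self.out_dir is not None:
                bio_io.write_snapshot(self.out_dir / "checkpoint_error.tsv",
                                      self.t, self.colony)
            raise
        self._measure()
        self._log_summary()
        if self.out_dir is not None:
            bio_io.write_frames(self.out_dir / "observables.tsv",
                                frames_to_table(self.frames))
            self._log_fh.close()
            self._log_fh = None
        return self.frames


def run_replicates(params: ModelParams, n: int,
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run ``n`` independent replicates and average their observables.

    Replicate ``i`` uses a seed derived from ``(params.seed, i)``.  Frames
    are aligned by snapshot index (the schedule is biomass-indexed, so index
    k corresponds to the same biomass target in every replicate) and the
    mean and standard error of every observable are returned.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    tables = []
    for i in range(n):
        seed_i = int(np.random.SeedSequence([params.seed, i])
                     .generate_state(1)[0] % (2 ** 31))
        params_i = dataclasses.replace(params, seed=seed_i)
        rep_dir = out_dir / f"rep_{i:03d}" if out_dir is not None else None
        sim = Simulation(params_i, out_dir=rep_dir)
        frames = sim.run()
        tables.append(frames_to_table(frames))
    combined = pd.concat(tables, keys=range(n), names=["replicate"])
    grouped = combined.groupby("frame")
    mean = grouped.mean()
    sem = grouped.sem()
    out = mean.join(sem, lsuffix="", rsuffix="_sem").reset_index()
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        bio_io.write_frames(out_dir / "observables_mean.tsv", out)
    return out


def analyze(in_dirs, out_dir: str | Path | None = None,
            biomass_checkpoints=(1e3,)) -> dict[str, pd.DataFrame]:
    """Recompute observables from stored snapshots, decoupled from the run.

    ``in_dirs`` is one run directory or a list of replicate directories.
    For each directory the per-snapshot frames are recomputed from the
    snapshot and grid files (bit-identical to the in-run frames thanks to
    the deterministic per-frame sampling seed), then averaged across
    replicates.  At each biomass checkpoint (first snapshot with
    m >= target) the orientational correlation g2(r) and the radial
    concentration/growth-rate profiles are emitted as long-format tables.
    """
    if isinstance(in_dirs, (str, Path)):
        in_dirs = [in_dirs]
    in_dirs = [Path(d) for d in in_dirs]
    out_dir = Path(out_dir) if out_dir is not None else None

    tables = []
    checkpoint_tables: list[pd.DataFrame] = []
    for rep, d in enumerate(in_dirs):
        params = ModelParams.from_file(d / "params.cfg")
        snaps = sorted((d / "snapshots").glob("snap_*.tsv"))
        frames = []
        for snap in snaps:
            k = int(snap.stem.split("_")[1])
            try:
                t, colony = bio_io.read_snapshot(snap)
            except (ValueError, KeyError) as exc:
                logger.warning("skipping corrupt snapshot %s: %s", snap, exc)
                continue
            gpath = d / "grids" / f"grid_{k:05d}.tsv"
            _, grid = bio_io.read_grid(gpath)
            frames.append(compute_frame(colony, grid, params, t, k))
        table = frames_to_table(frames)
        tables.append(table)

        for target in biomass_checkpoints:
            hit = table[table["m"] >= target]
            if hit.empty:
                continue
            k = int(hit.iloc[0]["frame"])
            t, colony = bio_io.read_snapshot(
                d / "snapshots" / f"snap_{k:05d}.tsv")
            _, grid = bio_io.read_grid(d / "grids" / f"grid_{k:05d}.tsv")
            g2 = orientational_correlation(colony, r_max=30.0, bin_width=1.0)
            g2.insert(0, "m_target", target)
            g2.insert(0, "replicate", rep)
            C_prof, v_prof = radial_profiles(colony, grid)
            C_prof = C_prof.assign(kind="concentration", m_target=target,
                                   replicate=rep)
            v_prof = v_prof.assign(kind="growth_rate", m_target=target,
                                   replicate=rep)
            checkpoint_tables.append(("g2", g2))
            checkpoint_tables.append(("profiles", C_prof))
            checkpoint_tables.append(("profiles", v_prof))

    combined = pd.concat(tables, keys=range(len(tables)),
                         names=["replicate"])
    grouped = combined.groupby("frame")
    mean = grouped.mean().join(grouped.sem(), rsuffix="_sem").reset_index()

    result: dict[str, pd.DataFrame] = {"observables": mean}
    for name in ("g2", "profiles"):
        parts = [df for tag, df in checkpoint_tables if tag == name]
        if parts:
            result[name] = pd.concat(parts, ignore_index=True)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in result.items():
            bio_io.write_frames(out_dir / f"{name}.tsv", df)
    return result
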