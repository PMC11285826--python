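"""Plain-text artifact formats: snapshots, grid dumps, observable tables.

Everything is tab-separated text with ``# key = value`` header lines, so
runs are diff-able and language-agnostic.  Floating-point values are
written with 17 significant digits and round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Colony
from .nutrient_field import NutrientGrid

__all__ = [
    "write_snapshot", "read_snapshot",
    "write_grid", "read_grid",
    "write_frames", "read_frames",
]

_SNAP_COLUMNS = ["id", "x", "y", "z", "ex", "ey", "ez",
                 "Lstar", "uptake", "growth_rate"]


def _read_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_snapshot(path: str | Path, t: float, colony: Colony) -> None:
    """Write one per-cell snapshot table with its time stamp."""
    path = Path(path)
    df = pd.DataFrame({
        "id": colony.ids,
        "x": colony.pos[:, 0], "y": colony.pos[:, 1], "z": colony.pos[:, 2],
        "ex": colony.ori[:, 0], "ey": colony.ori[:, 1],
        "ez": colony.ori[:, 2],
        "Lstar": colony.Lstar,
        "uptake": colony.uptake,
        "growth_rate": colony.growth,
    })
    with open(path, "w") as fh:
        fh.write(f"# time = {float(t)!r}\n")
        fh.write(f"# next_id = {colony.next_id}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_snapshot(path: str | Path) -> tuple[float, Colony]:
    """Read a snapshot written by :func:`write_snapshot`."""
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    if list(df.columns) != _SNAP_COLUMNS:
        raise ValueError(f"unexpected snapshot columns in {path}")
    colony = Colony(
        ids=df["id"].to_numpy(np.int64),
        pos=df[["x", "y", "z"]].to_numpy(float),
        ori=df[["ex", "ey", "ez"]].to_numpy(float),
        Lstar=df["Lstar"].to_numpy(float),
        uptake=df["uptake"].to_numpy(float),
        growth=df["growth_rate"].to_numpy(float),
        next_id=int(meta.get("next_id", 0)) or None,
    )
    return float(meta["time"]), colony


def write_grid(path: str | Path, grid: NutrientGrid, t: float = 0.0) -> None:
    """Write a nutrient-grid dump as an indexed long table."""
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    df = pd.DataFrame({"i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
                       "C": grid.C.ravel()})
    with open(path, "w") as fh:
        fh.write(f"# time = {float(t)!r}\n")
        fh.write(f"# origin = {float(grid.origin[0])!r} "
                 f"{float(grid.origin[1])!r} {float(grid.origin[2])!r}\n")
        fh.write(f"# h = {float(grid.h)!r}\n")
        fh.write(f"# shape = {nx} {ny} {nz}\n")
        fh.write(f"# C0 = {float(grid.C0)!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_grid(path: str | Path) -> tuple[float, NutrientGrid]:
    """Read a grid dump written by :func:`write_grid`."""
    path = Path(path)
    meta = _read_header(path)
    shape = tuple(int(s) for s in meta["shape"].split())
    origin = np.array([float(s) for s in meta["origin"].split()])
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    C = np.empty(shape)
    C[df["i"].to_numpy(), df["j"].to_numpy(), df["k"].to_numpy()] = \
        df["C"].to_numpy(float)
    grid = NutrientGrid(origin=origin, h=float(meta["h"]), C=C,
                        C0=float(meta.get("C0", 1.0)))
    return float(meta["time"]), grid


def write_frames(path: str | Path, frames_df: pd.DataFrame) -> None:
    """Write an observable table (one row per snapshot)."""
    with open(path, "w") as fh:
        frames_df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_frames(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
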