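"""Spherocylinder geometry: cell state, distances, axis sampling.

A bacterial cell is a spherocylinder: a cylinder of length ``(L* - 1) sigma``
capped by hemispheres of diameter ``sigma``, so the end-to-end extent is
``L* sigma``.  The cell is fully described by its centre ``r``, its unit
orientation ``e`` and the dimensionless aspect ratio ``L* = L/sigma + 1``.
All distance computations reduce to the central axis segment of half-length
``(L* - 1)/2`` (in sigma units; sigma = 1 throughout the code).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels

__all__ = [
    "CellState",
    "Colony",
    "min_distance",
    "wall_distance",
    "sample_axis_points",
    "half_length",
]

_UNIT_TOL = 1e-9


def half_length(Lstar: float) -> float:
    """Half-length of the cylindrical core segment, (L* - 1)/2 [sigma]."""
    return 0.5 * (Lstar - 1.0)


@dataclasses.dataclass
class CellState:
    """One spherocylindrical cell.

    Attributes
    ----------
    id
        Unique integer identity, preserved across snapshots.
    r
        Position of the geometric centre [sigma].
    e
        Unit orientation of the long axis.
    Lstar
        Aspect ratio ``L* = L/sigma + 1``.
    uptake
        Last computed nutrient uptake mu_i [C0 sigma^3 / tau].
    growth_rate
        Last computed elongation rate v_i [1/tau].
    """

    id: int
    r: np.ndarray
    e: np.ndarray
    Lstar: float
    uptake: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.e = np.asarray(self.e, dtype=float)

    @property
    def half_length(self) -> float:
        return half_length(self.Lstar)

    def validate(self) -> None:
        """Raise ``ValueError`` if the orientation is not a unit vector
        or the aspect ratio is below the spherical limit."""
        if self.r.shape != (3,) or self.e.shape != (3,):
            raise ValueError("r and e must be 3-vectors")
        norm = float(np.linalg.norm(self.e))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"orientation is not unit length: |e| = {norm}")
        if self.Lstar < 1.0:
            raise ValueError(f"aspect ratio below 1: {self.Lstar}")


class Colony:
    """Structure-of-arrays container for a collection of cells.

    The driver operates on these flat arrays (positions ``pos`` (N, 3),
    orientations ``ori`` (N, 3), aspect ratios ``Lstar`` (N), cached
    ``uptake`` and ``growth`` (N)); :class:`CellState` objects are views
    created on demand for the per-cell API.
    """

    __slots__ = ("ids", "pos", "ori", "Lstar", "uptake", "growth", "next_id")

    def __init__(self, ids, pos, ori, Lstar, uptake=None, growth=None,
                 next_id=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.pos = np.ascontiguousarray(pos, dtype=float)
        self.ori = np.ascontiguousarray(ori, dtype=float)
        self.Lstar = np.asarray(Lstar, dtype=float)
        n = len(self.ids)
        self.uptake = (np.zeros(n) if uptake is None
                       else np.asarray(uptake, dtype=float))
        self.growth = (np.zeros(n) if growth is None
                       else np.asarray(growth, dtype=float))
        self.next_id = (int(self.ids.max()) + 1 if next_id is None and n
                        else int(next_id or 0))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def half_lengths(self) -> np.ndarray:
        return 0.5 * (self.Lstar - 1.0)

    @property
    def biomass(self) -> float:
        return float(self.Lstar.sum())

    @classmethod
    def from_cells(cls, cells: list[CellState]) -> "Colony":
        return cls(
            ids=[c.id for c in cells],
            pos=np.array([c.r for c in cells], dtype=float).reshape(-1, 3),
            ori=np.array([c.e for c in cells], dtype=float).reshape(-1, 3),
            Lstar=[c.Lstar for c in cells],
            uptake=[c.uptake for c in cells],
            growth=[c.growth_rate for c in cells],
        )

    def to_cells(self) -> list[CellState]:
        return [
            CellState(int(self.ids[i]), self.pos[i].copy(), self.ori[i].copy(),
                      float(self.Lstar[i]), float(self.uptake[i]),
                      float(self.growth[i]))
            for i in range(self.n)
        ]

    def cell(self, i: int) -> CellState:
        """The i-th cell (by array index, not id) as a :class:`CellState`."""
        return CellState(int(self.ids[i]), self.pos[i].copy(),
                         self.ori[i].copy(), float(self.Lstar[i]),
                         float(self.uptake[i]), float(self.growth[i]))

    def copy(self) -> "Colony":
        return Colony(self.ids.copy(), self.pos.copy(), self.ori.copy(),
                      self.Lstar.copy(), self.uptake.copy(),
                      self.growth.copy(), next_id=self.next_id)


def min_distance(cell_i: CellState, cell_j: CellState):
    """Minimum distance between the axis segments of two spherocylinders.

    Returns ``(dm, p_i, p_j)``: the distance and the closest points on each
    cell's central segment.  Symmetric in its arguments; for exactly
    parallel overlapping segments the midpoint of the overlap interval is
    used, which preserves the symmetry.
    """
    cell_i.validate()
    cell_j.validate()
    dm, s, t = _kernels.segment_distance(
        cell_i.r, cell_i.e, cell_i.half_length,
        cell_j.r, cell_j.e, cell_j.half_length)
    return float(dm), cell_i.r + s * cell_i.e, cell_j.r + t * cell_j.e


def wall_distance(cell: CellState) -> float:
    """Distance from the cell's axis segment to the substrate plane z = 0.

    ``d_iw = r_z - ((L* - 1)/2) |e_z|``; may be negative during transient
    overlap (the force routines decide how to respond).
    """
    cell.validate()
    return float(cell.r[2] - cell.half_length * abs(cell.e[2]))


def sample_axis_points(cell: CellState, density: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Random points uniformly distributed on the cell's axis segment.

    ``round(density * L*)`` points are drawn (density 20 reproduces the
    20 L* points-per-cell convention used for colony morphometrics).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    n = int(round(density * cell.Lstar))
    s = (rng.random(n) - 0.5) * (cell.Lstar - 1.0)
    return cell.r[None, :] + s[:, None] * cell.e[None, :]


def sample_colony_axis_points(colony: Colony, density: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Vectorized axis-point sampling over a whole colony."""
    counts = np.round(density * colony.Lstar).astype(np.int64)
    total = int(counts.sum())
    rep = np.repeat(np.arange(colony.n), counts)
    s = (rng.random(total) - 0.5) * (colony.Lstar[rep] - 1.0)
    return colony.pos[rep] + s[:, None] * colony.ori[rep]
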