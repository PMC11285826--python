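"""Cell-cell and cell-substrate forces and torques.

Cells interact sterically through a truncated-and-shifted Kihara potential:
a 12-6 Lennard-Jones form evaluated on the minimum distance ``dm`` between
the two cylinder axes rather than the centre separation,

    U(dm) = 4 eps_BB [ (sigma/dm)^12 - (sigma/dm)^6 + 0.0154 ],  dm <= 2 sigma,

and zero beyond the cutoff.  The shift 0.0154 = (1/2)^6 - (1/2)^12 (to three
significant figures) makes U vanish continuously at the cutoff.  The force
acts along the minimum-distance vector and is applied at the closest axis
points, which also yields the torques.

The substrate (the plane z = 0) repels cells whose axis comes closer than
``d_rep = (2/5)^(1/6) sigma_w`` with a 10-4-type force and, within the
adhesion range ``d_c``, attracts them with a length-proportional spring that
models uniformly distributed surface adhesion factors.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import _kernels
from .geometry import CellState, Colony, min_distance, wall_distance
from .params import ModelParams

__all__ = [
    "ForceTorque",
    "kihara_potential",
    "pair_force_torque",
    "wall_repulsion",
    "wall_adhesion",
    "total_forces",
    "total_forces_arrays",
]

logger = logging.getLogger(__name__)

KIHARA_SHIFT = 0.0154
KIHARA_CUTOFF = 2.0


@dataclasses.dataclass
class ForceTorque:
    """Accumulated force [eps/sigma] and torque [eps] on one cell."""

    F: np.ndarray
    T: np.ndarray

    @classmethod
    def zero(cls) -> "ForceTorque":
        return cls(np.zeros(3), np.zeros(3))

    def __add__(self, other: "ForceTorque") -> "ForceTorque":
        return ForceTorque(self.F + other.F, self.T + other.T)


def kihara_potential(dm, eps_BB: float):
    """Truncated-and-shifted Kihara pair energy at minimum distance ``dm``.

    Accepts scalars or arrays; ``dm <= 0`` is a domain error (overlapping
    cores are prevented upstream by the timestep and the force cap).
    """
    dm_arr = np.asarray(dm, dtype=float)
    if np.any(dm_arr <= 0.0):
        raise ValueError("dm must be positive")
    inv6 = (1.0 / dm_arr) ** 6
    u = 4.0 * eps_BB * (inv6 * inv6 - inv6 + KIHARA_SHIFT)
    u = np.where(dm_arr > KIHARA_CUTOFF, 0.0, u)
    return float(u) if np.isscalar(dm) else u


def pair_force_torque(cell_i: CellState, cell_j: CellState,
                      params: ModelParams):
    """Kihara force/torque pair between two cells.

    Newton's third law holds by construction: the same force vector, applied
    at the closest point of each cell's axis with opposite signs.
    """
    dm, p_i, p_j = min_distance(cell_i, cell_j)
    fi, fj = ForceTorque.zero(), ForceTorque.zero()
    if dm > KIHARA_CUTOFF:
        return fi, fj
    if dm > 1e-9:
        mag = float(_kernels.kihara_force_mag(dm, params.eps_BB))
        mag = float(np.clip(mag, -params.force_cap, params.force_cap))
        u = (p_i - p_j) / dm
    else:
        # numerically coincident closest points: capped push along the
        # centre separation
        logger.warning("coincident closest points between cells %d and %d",
                       cell_i.id, cell_j.id)
        mag = params.force_cap
        dr = cell_i.r - cell_j.r
        nrm = np.linalg.norm(dr)
        u = dr / nrm if nrm > 1e-12 else np.array([1.0, 0.0, 0.0])
    fi.F[:] = mag * u
    fj.F[:] = -fi.F
    fi.T[:] = np.cross(p_i - cell_i.r, fi.F)
    fj.T[:] = np.cross(p_j - cell_j.r, fj.F)
    return fi, fj


def wall_repulsion(cell: CellState, params: ModelParams) -> ForceTorque:
    """Steric substrate repulsion, active for ``d_iw < d_rep``.

    Magnitude ``(eps_rep/d_iw) [ (6/5)(sigma_w/d_iw)^10 - 3 (sigma_w/d_iw)^4 ]``
    along +z, applied at the axis point closest to the substrate.  The
    bracket vanishes analytically at ``d_iw = d_rep``.
    """
    out = ForceTorque.zero()
    diw = wall_distance(cell)
    if diw >= params.d_rep:
        return out
    if diw <= 1e-12:
        logger.warning("cell %d penetrated the substrate (d_iw = %g)",
                       cell.id, diw)
        mag = params.force_cap
    else:
        u = params.sigma_w / diw
        mag = min((params.eps_rep / diw) * (1.2 * u ** 10 - 3.0 * u ** 4),
                  params.force_cap)
    out.F[2] = mag
    ez = cell.e[2]
    if abs(ez) > 1e-12:
        s = -cell.half_length if ez > 0 else cell.half_length
        out.T[:] = np.cross(s * cell.e, out.F)
    return out


def wall_adhesion(cell: CellState, params: ModelParams) -> ForceTorque:
    """Adhesion to the substrate, active for ``d_iw < d_c``.

    Force ``-eps_att L* r_z`` along z (spring-like in the centre height
    r_z), applied at the offset ``(L*^2 / (12 r_z)) (e.k) e`` from the cell
    centre; for a horizontal cell the offset vanishes and the torque is zero.
    """
    out = ForceTorque.zero()
    rz = float(cell.r[2])
    if rz <= 0.0:
        raise ValueError("wall adhesion requires a centre above the substrate")
    if wall_distance(cell) >= params.d_c:
        return out
    out.F[2] = -params.eps_att * cell.Lstar * rz
    offset = (cell.Lstar ** 2 / (12.0 * rz)) * cell.e[2] * cell.e
    out.T[:] = np.cross(offset, out.F)
    return out


def total_forces_arrays(pos, ori, hl, Lstar, params: ModelParams):
    """Assembled per-cell forces/torques on flat arrays (driver fast path).

    Returns ``(F, T, n_capped)`` where ``n_capped`` counts magnitude-capped
    contributions.
    """
    F, T, n_capped = _kernels.total_forces_kernel(
        pos, ori, hl, Lstar,
        params.eps_BB, params.eps_rep, params.eps_att,
        params.sigma_w, params.d_rep, params.d_c, params.force_cap)
    return F, T, n_capped


def total_forces(cells, params: ModelParams, method: str = "cell_list"):
    """Total force and torque on every cell (pair + substrate terms).

    ``cells`` may be a list of :class:`CellState` or a :class:`Colony`.
    ``method='cell_list'`` uses the linked-cell kernel; ``method='brute'``
    is the reference O(N^2) double loop built from the per-pair operations
    (used as the oracle in tests).
    """
    colony = cells if isinstance(cells, Colony) else Colony.from_cells(cells)
    if method == "cell_list":
        F, T, n_capped = total_forces_arrays(
            colony.pos, colony.ori, colony.half_lengths, colony.Lstar, params)
        if n_capped:
            logger.warning("%d force contributions were magnitude-capped",
                           n_capped)
    elif method == "brute":
        cell_objs = colony.to_cells()
        n = len(cell_objs)
        F = np.zeros((n, 3))
        T = np.zeros((n, 3))
        for i, ci in enumerate(cell_objs):
            w = wall_repulsion(ci, params) + wall_adhesion(ci, params)
            F[i] += w.F
            T[i] += w.T
            for j in range(i + 1, n):
                fi, fj = pair_force_torque(ci, cell_objs[j], params)
                F[i] += fi.F
                T[i] += fi.T
                F[j] += fj.F
                T[j] += fj.T
    else:
        raise ValueError(f"unknown method {method!r}")
    if isinstance(cells, Colony):
        return F, T
    return [ForceTorque(F[i].copy(), T[i].copy()) for i in range(len(F))]
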