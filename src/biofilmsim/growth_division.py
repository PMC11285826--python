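"""Cell elongation and binary fission.

Cells elongate at the nutrient-set rate ``v_i = dL*/dt`` and divide when
they reach twice the initial aspect ratio.  The two daughters inherit the
parent's orientation and exactly tile the parent's end-to-end extent: a
parent of aspect ratio ``L_p`` (extent ``L_p sigma``) yields daughters of
aspect ratio ``L_p/2`` centred at ``r +/- (L_p/4) sigma e``, so total
biomass (the sum of aspect ratios) is continuous across every division.
"""

from __future__ import annotations

import numpy as np

from .geometry import CellState, Colony
from .params import ModelParams

__all__ = ["elongate", "divide", "elongate_colony", "divide_colony"]

#: Tolerance on the division threshold (one elongation step's worth).
DIVISION_TOL = 1e-9


def elongate(cell: CellState, vi: float, dt: float,
             params: ModelParams) -> tuple[CellState, bool]:
    """Grow one cell by ``vi * dt``, capping at the division length.

    Returns the updated cell and a flag marking it ready for division.
    Excess growth beyond ``2 L0*`` in the triggering step is discarded
    (sub-timestep correction is negligible at the default timestep).
    """
    if vi < 0:
        raise ValueError("growth rate must be non-negative")
    new_L = cell.Lstar + vi * dt
    flagged = new_L >= params.max_Lstar
    cell.Lstar = min(new_L, params.max_Lstar)
    return cell, flagged


def divide(cell: CellState, id_source,
           params: ModelParams | None = None) -> tuple[CellState, CellState]:
    """Binary fission of a predivisional cell.

    ``id_source`` is an iterator of fresh unique ids.  Daughters keep the
    parent's orientation, halve its aspect ratio, tile its extent, and start
    with cleared uptake/growth caches.  When ``params`` is given, calling
    below the division threshold ``2 L0*`` raises ``ValueError``.
    """
    if params is not None:
        check_divide(cell, params)
    half = 0.5 * cell.Lstar
    offset = 0.25 * cell.Lstar * cell.e
    d1 = CellState(next(id_source), cell.r + offset, cell.e.copy(), half)
    d2 = CellState(next(id_source), cell.r - offset, cell.e.copy(), half)
    return d1, d2


def check_divide(cell: CellState, params: ModelParams) -> None:
    """Raise if ``cell`` is below the division threshold."""
    if cell.Lstar < params.max_Lstar - DIVISION_TOL:
        raise ValueError(
            f"cell {cell.id} below division threshold: "
            f"L* = {cell.Lstar} < {params.max_Lstar}")


def elongate_colony(colony: Colony, v: np.ndarray, dt: float,
                    params: ModelParams) -> np.ndarray:
    """Vectorized elongation; returns the boolean division mask."""
    colony.Lstar += v * dt
    mask = colony.Lstar >= params.max_Lstar
    if mask.any():
        colony.Lstar[mask] = params.max_Lstar
    return mask


def divide_colony(colony: Colony, mask: np.ndarray) -> Colony:
    """Replace every flagged cell by its two daughters.

    The first daughter overwrites the parent's row; the second is appended,
    so unflagged rows keep their array positions.
    """
    if not mask.any():
        return colony
    idx = np.flatnonzero(mask)
    k = len(idx)
    new_ids = colony.next_id + np.arange(2 * k, dtype=np.int64)
    colony.next_id += 2 * k

    half = 0.5 * colony.Lstar[idx]
    offset = (0.25 * colony.Lstar[idx])[:, None] * colony.ori[idx]

    second_pos = colony.pos[idx] - offset
    second_ori = colony.ori[idx].copy()

    colony.ids[idx] = new_ids[:k]
    colony.pos[idx] += offset
    colony.Lstar[idx] = half
    colony.uptake[idx] = 0.0
    colony.growth[idx] = 0.0

    colony.ids = np.concatenate([colony.ids, new_ids[k:]])
    colony.pos = np.ascontiguousarray(
        np.concatenate([colony.pos, second_pos]))
    colony.ori = np.ascontiguousarray(
        np.concatenate([colony.ori, second_ori]))
    colony.Lstar = np.concatenate([colony.Lstar, half])
    colony.uptake = np.concatenate([colony.uptake, np.zeros(k)])
    colony.growth = np.concatenate([colony.growth, np.zeros(k)])
    return colony
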