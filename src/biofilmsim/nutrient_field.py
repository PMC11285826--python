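"""Nutrient concentration field, Monod uptake and reaction-diffusion step.

The simulation box is discretized into cubic compartments of edge
``h = 10.85 sigma``; the concentration is uniform inside each compartment.
Nutrient evolves by

    dC/dt = DN lap(C) - sum_i mu_i / h^3,

solved with an explicit forward-in-time, centred-in-space (FTCS) scheme.
The outermost lateral and top compartment layers are Dirichlet boundaries
held at the bulk concentration ``C0`` ("far away" condition); the substrate
plane z = 0 is zero-flux.  Each cell consumes nutrient at the Monod rate

    mu_i = mu_max L* C / (Ks + C),

proportional to its length, so ``Ks`` is the concentration at which uptake
is half of the saturating value ``mu_max L*``.  All cells sharing a
compartment see the same local concentration and hence the same specific
growth rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from .geometry import Colony
from .params import ModelParams

__all__ = [
    "NutrientGrid",
    "monod_uptake",
    "growth_rate",
    "assign_compartments",
    "diffusion_step",
    "compute_uptake",
]


class GridBoundsError(ValueError):
    """A cell lies outside the interior of the nutrient grid."""


@dataclasses.dataclass
class NutrientGrid:
    """Cubic-compartment concentration field with boundary metadata.

    ``C[i, j, k]`` is the concentration (in C0 units) of the compartment
    spanning ``origin + (i, j, k) h`` to ``origin + (i+1, j+1, k+1) h``.
    The grid origin sits on the substrate plane: ``origin[2] = 0``.
    """

    origin: np.ndarray
    h: float
    C: np.ndarray
    C0: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.C = np.ascontiguousarray(self.C, dtype=float)
        if self.C.ndim != 3:
            raise ValueError("C must be a 3-d array")
        if self.h <= 0:
            raise ValueError("compartment edge h must be positive")

    @classmethod
    def uniform(cls, shape, h: float, C0: float = 1.0,
                origin=None) -> "NutrientGrid":
        """A grid filled with the bulk concentration C0."""
        nx, ny, nz = shape
        if origin is None:
            origin = np.array([-0.5 * nx * h, -0.5 * ny * h, 0.0])
        return cls(origin=origin, h=h, C=np.full((nx, ny, nz), float(C0)),
                   C0=C0)

    @property
    def shape(self):
        return self.C.shape

    def compartment_centres(self) -> np.ndarray:
        """Centre coordinates of every compartment, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.C.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        out = np.stack([ii, jj, kk], axis=-1) + 0.5
        return self.origin + out * self.h

    def stability_limit(self, DN: float) -> float:
        """Largest stable FTCS timestep, h^2 / (6 DN)."""
        return self.h ** 2 / (6.0 * DN)


def monod_uptake(C_local, Lstar, params: ModelParams):
    """Monod nutrient uptake mu_i = mu_max L* C / (Ks + C).

    Monotonically increasing in the local concentration and bounded by the
    saturating value ``mu_max L*``; exactly half-saturated at C = Ks.
    """
    C = np.asarray(C_local, dtype=float)
    if np.any(C < 0.0):
        raise ValueError("negative nutrient concentration")
    mu = params.mu_max * np.asarray(Lstar, dtype=float) * C / (params.Ks + C)
    return float(mu) if np.isscalar(C_local) and np.isscalar(Lstar) else mu


def growth_rate(mu_i, Lstar, params: ModelParams):
    """Elongation rate v_i = veff mu_i / L* [dL*/dt].

    At saturating concentration this is ``veff mu_max`` independent of the
    cell length: cells elongate at a constant speed and divide at fixed
    intervals.
    """
    v = params.veff * np.asarray(mu_i, dtype=float) / np.asarray(Lstar,
                                                                 dtype=float)
    return float(v) if np.isscalar(mu_i) and np.isscalar(Lstar) else v


def assign_compartments(cells, grid: NutrientGrid) -> np.ndarray:
    """Map each cell centre to its compartment index (half-open convention).

    Accepts a :class:`Colony`, a list of cells, or an (N, 3) position array;
    returns an (N, 3) integer index array.  Uses the floor convention
    ``idx = floor((r - origin)/h)`` (half-open compartments), so a centre
    sitting exactly on a shared face belongs to the compartment whose lower
    face it touches.  Raises
    :class:`GridBoundsError` for centres outside the grid (the driver reacts
    by expanding the grid).
    """
    if isinstance(cells, Colony):
        pos = cells.pos
    elif hasattr(cells, "ndim"):
        pos = np.asarray(cells, dtype=float)
    else:
        pos = np.array([c.r for c in cells], dtype=float).reshape(-1, 3)
    rel = (pos - grid.origin) / grid.h
    idx = np.floor(rel).astype(np.int64)
    # a centre exactly on the upper face of the last compartment still counts
    on_top = (rel == np.array(grid.shape, dtype=float))
    idx[on_top] -= 1
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise GridBoundsError("cell centre outside the nutrient grid")
    return idx


def diffusion_step(grid: NutrientGrid, sinks: np.ndarray, dt: float,
                   DN: float) -> np.ndarray:
    """Advance the field one FTCS step with per-compartment sinks.

    ``sinks`` holds the total uptake rate of each compartment in amount
    units [C0 sigma^3 / tau]; it is converted to a concentration rate by
    dividing by the compartment volume h^3.  Dirichlet layers (lateral and
    top) are re-imposed at C0, the substrate is treated as a mirror, and
    concentrations are clamped at zero.  Returns the actually-delivered
    uptake per compartment over the step [C0 sigma^3] so growth bookkeeping
    can use nutrients actually consumed.
    """
    if np.any(sinks < 0):
        raise ValueError("sinks must be non-negative")
    if dt > grid.stability_limit(DN) * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt} violates the FTCS stability limit "
            f"{grid.stability_limit(DN):g}; sub-cycle the diffusion update")
    h3 = grid.h ** 3
    sink_rate = np.ascontiguousarray(sinks, dtype=float) / h3
    C_new, delivered_rate = _kernels.ftcs_kernel(grid.C, sink_rate, grid.h,
                                                 dt, DN)
    # Dirichlet layers are untouched by the kernel; re-impose defensively.
    C_new[0, :, :] = grid.C0
    C_new[-1, :, :] = grid.C0
    C_new[:, 0, :] = grid.C0
    C_new[:, -1, :] = grid.C0
    C_new[:, :, -1] = grid.C0
    grid.C = C_new
    return delivered_rate * h3 * dt


def compute_uptake(colony: Colony, grid: NutrientGrid, params: ModelParams,
                   dt: float):
    """Per-cell uptake and growth rate with nutrient-availability scaling.

    All cells in one compartment share the local concentration.  If the
    total requested uptake of a compartment over ``dt`` exceeds its nutrient
    content, every resident cell's uptake is scaled down proportionally
    (preserving the equal-growth-within-compartment rule and keeping the
    field non-negative).  Returns ``(mu, v, sinks)`` where ``sinks`` is the
    per-compartment total uptake rate [C0 sigma^3/tau], shaped like the grid.
    """
    nx, ny, nz = grid.shape
    mu = np.empty(colony.n)
    v = np.empty(colony.n)
    sinks = np.zeros(nx * ny * nz)
    status = _kernels.uptake_kernel(
        colony.pos, colony.Lstar, grid.origin, grid.h, grid.C.reshape(-1),
        nx, ny, nz, params.mu_max, params.Ks, params.veff, dt, mu, v, sinks)
    if status:
        raise GridBoundsError("cell centre outside the nutrient grid")
    return mu, v, sinks.reshape(grid.shape)
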