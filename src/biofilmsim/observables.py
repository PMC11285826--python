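"""Colony morphometrics and order parameters.

The colony is characterized by its biomass ``m = sum_i L*_i``, a
half-ellipsoid fit of the cell distribution (semi-axes ``a >= b`` in the
substrate plane, ``c`` vertical), the derived volume/surface/base-area
metrics, the density ``rho = m / Ve``, the triaxial and biaxial shape
parameters

    Tp = (a^2 - b^2) / (a^2 - c^2),    Bp = (a^2 - b^2) / (a^2 + b^2),

the nematic order parameter ``S2`` (largest eigenvalue of the traceless
orientation tensor) and the distance-resolved orientational correlation
``g2(r) = <P2(e_i . e_j)>``.

The ellipsoid fit samples ``20 L*`` random points along each cell axis,
mirrors them through the substrate plane (the colony is modelled as half of
an ellipsoid symmetric about z = 0, which also forces the xz/yz inertia
components to zero), forms the inertia tensor about the in-plane centre of
mass and maps its eigenvalues to semi-axes with the uniform-solid-ellipsoid
moment relations ``I_aa = (b^2 + c^2)/5`` etc.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .geometry import Colony, sample_colony_axis_points
from .nutrient_field import NutrientGrid

__all__ = [
    "EllipsoidFit",
    "ObservableFrame",
    "biomass",
    "ellipsoid_fit",
    "geometry_metrics",
    "density",
    "shape_params",
    "nematic_order",
    "orientational_correlation",
    "radial_profiles",
    "growth_rate_extrema",
    "colony_centre_of_mass",
]

#: Axis points per unit aspect ratio used by the ellipsoid fit.
POINT_DENSITY = 20.0
#: Exponent of the Thomsen-type approximate ellipsoid surface formula.
THOMSEN_P = 1.6075
#: Floor on the vertical semi-axis for degenerate (coplanar) colonies.
C_FLOOR = 0.5


def _as_colony(cells) -> Colony:
    return cells if isinstance(cells, Colony) else Colony.from_cells(cells)


@dataclasses.dataclass
class EllipsoidFit:
    """Fitted semi-axes of the colony half-ellipsoid.

    ``a >= b`` are in the substrate plane, ``c`` is vertical; ``axes`` holds
    the two in-plane principal directions as columns (a-axis first).
    """

    a: float
    b: float
    c: float
    axes: np.ndarray

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0 and self.c > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0, c > 0")


@dataclasses.dataclass
class ObservableFrame:
    """All per-snapshot colony observables."""

    t: float
    m: float
    N: int
    fit: EllipsoidFit | None
    Ve: float = np.nan
    Ae: float = np.nan
    Az: float = np.nan
    c: float = np.nan
    rho: float = np.nan
    Tp: float = np.nan
    Bp: float = np.nan
    S2: float = np.nan
    gr2: pd.DataFrame | None = None
    profiles: tuple[pd.DataFrame, pd.DataFrame] | None = None

    def to_row(self) -> dict:
        fit = self.fit
        return {
            "t": self.t, "m": self.m, "N": self.N,
            "a": fit.a if fit else np.nan,
            "b": fit.b if fit else np.nan,
            "c": fit.c if fit else np.nan,
            "Ve": self.Ve, "Ae": self.Ae, "Az": self.Az,
            "rho": self.rho, "Tp": self.Tp, "Bp": self.Bp, "S2": self.S2,
        }


def biomass(cells) -> float:
    """Total biomass m = sum of aspect ratios."""
    colony = _as_colony(cells)
    return float(colony.Lstar.sum()) if len(colony) else 0.0


def colony_centre_of_mass(colony: Colony) -> np.ndarray:
    """Biomass-weighted centre of the colony (cells weighted by L*)."""
    w = colony.Lstar / colony.Lstar.sum()
    return w @ colony.pos


def ellipsoid_fit(cells, rng: np.random.Generator,
                  density: float = POINT_DENSITY) -> EllipsoidFit:
    """Half-ellipsoid fit of the colony via the inertia tensor.

    See the module docstring for the procedure.  For colonies that are
    effectively coplanar with the substrate the vertical semi-axis is
    floored at sigma/2 (half a cell diameter).
    """
    colony = _as_colony(cells)
    if colony.n < 2:
        raise ValueError("ellipsoid fit requires at least 2 cells")
    pts = sample_colony_axis_points(colony, density, rng)
    mirrored = np.concatenate([pts, pts * np.array([1.0, 1.0, -1.0])])
    com_xy = mirrored[:, :2].mean(axis=0)
    x = mirrored[:, 0] - com_xy[0]
    y = mirrored[:, 1] - com_xy[1]
    z = mirrored[:, 2]
    Ixx = np.mean(y * y + z * z)
    Iyy = np.mean(x * x + z * z)
    Izz = np.mean(x * x + y * y)
    Ixy = -np.mean(x * y)
    # xz / yz components forced to zero by the z-mirror symmetry
    evals, evecs = np.linalg.eigh(np.array([[Ixx, Ixy], [Ixy, Iyy]]))
    lam1, lam2 = evals  # ascending: lam1 is the moment about the long axis
    a2 = 2.5 * (lam2 + Izz - lam1)
    b2 = 2.5 * (lam1 + Izz - lam2)
    c2 = 2.5 * (lam1 + lam2 - Izz)
    a = float(np.sqrt(max(a2, C_FLOOR ** 2)))
    b = float(np.sqrt(max(b2, C_FLOOR ** 2)))
    c = float(np.sqrt(max(c2, C_FLOOR ** 2)))
    # eigh sorts ascending, so column 0 (smallest moment) is the a-direction
    return EllipsoidFit(a=a, b=b, c=c, axes=evecs)


def geometry_metrics(fit: EllipsoidFit,
                     az_convention: str = "as-printed"):
    """Colony volume, external surface and base area from the fitted axes.

    Ve = (2/3) pi a b c (half-ellipsoid volume).  Ae is half of the
    Thomsen approximate ellipsoid surface
    ``4 pi [((ab)^p + (ac)^p + (bc)^p)/3]^(1/p)`` with p = 1.6075 (exact in
    the sphere limit, ~1% worst-case error).  Az follows the configured
    convention: ``"as-printed"`` gives (pi/4) a b, ``"consistent"`` gives
    the full ellipse area pi a b.
    """
    a, b, c = fit.a, fit.b, fit.c
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    Ve = (2.0 / 3.0) * np.pi * a * b * c
    p = THOMSEN_P
    Ae = 2.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p)
                        / 3.0) ** (1.0 / p)
    if az_convention == "as-printed":
        Az = 0.25 * np.pi * a * b
    elif az_convention == "consistent":
        Az = np.pi * a * b
    else:
        raise ValueError(f"unknown Az convention {az_convention!r}")
    return float(Ve), float(Ae), float(Az)


def density(m: float, Ve: float) -> float:
    """Colony density rho = m / Ve [1/sigma^3]."""
    if Ve <= 0:
        raise ValueError("Ve must be positive")
    return m / Ve


def shape_params(fit: EllipsoidFit) -> tuple[float, float]:
    """Triaxial and biaxial shape parameters (Tp, Bp).

    Tp = (a^2 - b^2)/(a^2 - c^2): 1 when b = c, 0 when a = b, signed
    infinity when a = c with a != b (the degenerate biaxial case); values in
    (0, 1) correspond to flat triaxial colonies with a >= b >= c.
    Bp = (a^2 - b^2)/(a^2 + b^2) in [0, 1) measures how far the base ellipse
    is from a circle.
    """
    a2, b2, c2 = fit.a ** 2, fit.b ** 2, fit.c ** 2
    Bp = (a2 - b2) / (a2 + b2)
    num = a2 - b2
    den = a2 - c2
    if den == 0.0:
        Tp = 1.0 if num == 0.0 else np.inf
    else:
        Tp = num / den
    return float(Tp), float(Bp)


def nematic_order(cells) -> float:
    """Nematic order parameter S2 in [0, 1].

    Largest eigenvalue of the traceless orientation tensor
    ``Q = (1/N) sum (3 e e^T - I)/2``; 1 for perfectly aligned cells, of
    order N^(-1/2) for an isotropic ensemble.
    """
    colony = _as_colony(cells)
    if colony.n < 1:
        raise ValueError("need at least one cell")
    e = colony.ori
    Q = 1.5 * (e.T @ e) / colony.n - 0.5 * np.eye(3)
    s2 = float(np.linalg.eigvalsh(Q)[-1])
    return float(np.clip(s2, 0.0, 1.0))


def orientational_correlation(cells, r_max: float,
                              bin_width: float) -> pd.DataFrame:
    """Distance-resolved orientational correlation g2(r) = <P2(e_i . e_j)>.

    Every unordered pair contributes the second Legendre polynomial of its
    orientation dot product to the bin of its centre-to-centre distance.
    Returns a table with columns ``r_lo, r_hi, r_mid, g2, n_pairs``; empty
    bins carry NaN.
    """
    colony = _as_colony(cells)
    if colony.n < 2:
        raise ValueError("need at least two cells")
    from scipy.spatial.distance import pdist
    r = pdist(colony.pos)
    # pairwise orientation dot products via the Gram matrix
    G = colony.ori @ colony.ori.T
    iu = np.triu_indices(colony.n, k=1)
    cosang = G[iu]
    p2 = 0.5 * (3.0 * cosang ** 2 - 1.0)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    which = np.digitize(r, edges) - 1
    nb = len(edges) - 1
    ok = (which >= 0) & (which < nb)
    sums = np.bincount(which[ok], weights=p2[ok], minlength=nb)
    counts = np.bincount(which[ok], minlength=nb)
    with np.errstate(invalid="ignore"):
        g2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "r_lo": edges[:-1], "r_hi": edges[1:],
        "r_mid": 0.5 * (edges[:-1] + edges[1:]),
        "g2": g2, "n_pairs": counts,
    })


def radial_profiles(cells, grid: NutrientGrid, com=None,
                    layer_height: float | None = None,
                    bin_width: float | None = None):
    """Radial concentration and growth-rate profiles near the substrate.

    Restricts to the first compartment layer above z = 0 (``layer_height``
    defaults to the compartment edge h) and bins compartment centres (for
    the concentration) and cells (for the growth rate) by lateral distance
    from the colony centre of mass.  Returns ``(C_table, v_table)``; with no
    cells the growth table is empty but the concentration table is still
    defined (centred on the provided ``com`` or the grid centre).
    """
    colony = _as_colony(cells)
    h = grid.h
    layer_height = h if layer_height is None else layer_height
    bin_width = h if bin_width is None else bin_width
    if com is None:
        if colony.n:
            com = colony_centre_of_mass(colony)
        else:
            nx, ny, _ = grid.shape
            com = grid.origin + 0.5 * np.array([nx * h, ny * h, 0.0])
    com_xy = np.asarray(com, dtype=float)[:2]

    centres = grid.compartment_centres()
    layer = centres[..., 2] < layer_height
    cxy = centres[layer][:, :2]
    cvals = grid.C[layer]
    r_comp = np.linalg.norm(cxy - com_xy, axis=1)

    def _binned(r, vals):
        if len(r) == 0:
            return pd.DataFrame(columns=["r_lo", "r_hi", "r_mid",
                                         "mean", "n"])
        edges = np.arange(0.0, r.max() + bin_width, bin_width)
        which = np.digitize(r, edges) - 1
        nb = len(edges) - 1
        sums = np.bincount(which, weights=vals, minlength=nb)
        counts = np.bincount(which, minlength=nb)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return pd.DataFrame({
            "r_lo": edges[:-1], "r_hi": edges[1:],
            "r_mid": 0.5 * (edges[:-1] + edges[1:]),
            "mean": mean, "n": counts,
        })

    C_table = _binned(r_comp, cvals)
    if colony.n:
        in_layer = colony.pos[:, 2] < layer_height
        r_cell = np.linalg.norm(colony.pos[in_layer, :2] - com_xy, axis=1)
        v_table = _binned(r_cell, colony.growth[in_layer])
    else:
        v_table = _binned(np.array([]), np.array([]))
    return C_table, v_table


def growth_rate_extrema(cells) -> tuple[float, float, float]:
    """(max, mean, min) of the cached per-cell growth rates."""
    colony = _as_colony(cells)
    if colony.n < 1:
        raise ValueError("need at least one cell")
    v = colony.growth
    return float(v.max()), float(v.mean()), float(v.min())
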