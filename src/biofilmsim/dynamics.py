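"""Overdamped Brownian dynamics of spherocylindrical cells.

Each cell moves by anisotropic translational diffusion (parallel and
perpendicular to its axis) and rotational diffusion, with deterministic
drift ``(D/kBT) F dt`` and Gaussian noise of variance ``2 D dt`` per
component.  The length-dependent diffusion coefficients come from
hydrodynamic fits for rods,

    D_par /D0 = -0.0198 ln L* + 0.0777 + 0.0437/L* - 0.0158/L*^2
    D_perp/D0 = -0.0119 ln L* + 0.0452 + 0.0796022/L* - 0.0190/L*^2
    D_rot sigma^2/D0 = -0.0002 ln L* + 0.0012 - 0.0243/L* + 0.3232/L*^2
                       + 0.2597/L*^3 - 0.0483/L*^4 - 0.1931/L*^5,

with the reciprocal powers matching the decrease of all three coefficients
for longer rods.  Orientations are advanced with a first-order Euler update
and renormalized to unit length each step.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import Colony
from .interactions import ForceTorque
from .params import ModelParams

__all__ = ["DiffusionCoeffs", "diffusion_coeffs", "bd_step",
           "bd_step_arrays", "perpendicular_frame"]


@dataclasses.dataclass
class DiffusionCoeffs:
    """Short-time diffusion coefficients of a rod of aspect ratio L*."""

    D_par: float    # translational, along the axis   [sigma^2/tau]
    D_perp: float   # translational, perpendicular    [sigma^2/tau]
    D_rot: float    # rotational                      [1/tau]


def _dpar_reduced(L):
    return -0.0198 * np.log(L) + 0.0777 + 0.0437 / L - 0.0158 / L ** 2


def _dperp_reduced(L):
    return -0.0119 * np.log(L) + 0.0452 + 0.0796022 / L - 0.0190 / L ** 2


def _drot_reduced(L):
    return (-0.0002 * np.log(L) + 0.0012 - 0.0243 / L + 0.3232 / L ** 2
            + 0.2597 / L ** 3 - 0.0483 / L ** 4 - 0.1931 / L ** 5)


def diffusion_coeffs(Lstar, D0: float):
    """Evaluate the three diffusion coefficients for aspect ratio ``Lstar``.

    Scalar input returns a :class:`DiffusionCoeffs`; array input returns a
    tuple of arrays ``(D_par, D_perp, D_rot)``.  All scale linearly with
    ``D0``; the rotational coefficient carries the extra 1/sigma^2 (= 1 in
    reduced units).
    """
    L = np.asarray(Lstar, dtype=float)
    if np.any(L < 1.0):
        raise ValueError("aspect ratio must be >= 1")
    dpar = _dpar_reduced(L) * D0
    dperp = _dperp_reduced(L) * D0
    drot = _drot_reduced(L) * D0
    if np.isscalar(Lstar):
        return DiffusionCoeffs(float(dpar), float(dperp), float(drot))
    return dpar, dperp, drot


def perpendicular_frame(ori: np.ndarray):
    """Two unit vectors perpendicular to each orientation in ``ori`` (N, 3).

    Built deterministically by Gram-Schmidt against the coordinate axis
    least aligned with each orientation; the Gaussian noise distribution is
    invariant to this frame choice.
    """
    axis = np.argmin(np.abs(ori), axis=1)
    a = np.zeros_like(ori)
    a[np.arange(len(ori)), axis] = 1.0
    v1 = a - (np.sum(a * ori, axis=1, keepdims=True)) * ori
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.cross(ori, v1)
    return v1, v2


def bd_step_arrays(pos, ori, F, T, Lstar, D0, dt, kBT, noise):
    """In-place Brownian-dynamics update on flat arrays (compiled path).

    ``noise`` is an (N, 5) array of standard Gaussians: one parallel and two
    perpendicular translational components, then two orientational
    components.  Passing zeros disables thermal motion (deterministic
    drift-only limit).  The length-dependent diffusion coefficients are
    evaluated inline per cell.
    """
    from . import _kernels
    status = _kernels.bd_kernel(pos, ori, F, T, Lstar, D0, dt, kBT, noise)
    if status:
        raise FloatingPointError("non-finite force or torque in BD step")


def _bd_step_numpy(pos, ori, F, T, D_par, D_perp, D_rot, dt, kBT, noise):
    """Plain-numpy reference of the BD update (oracle for the compiled path)."""
    e = ori
    fpar = np.sum(F * e, axis=1, keepdims=True)
    Fpar = fpar * e
    Fperp = F - Fpar
    v1, v2 = perpendicular_frame(e)
    dpar = D_par[:, None]
    dperp = D_perp[:, None]
    drot = D_rot[:, None]
    pos += (dpar / kBT) * Fpar * dt + np.sqrt(2.0 * dpar * dt) * noise[:, 0:1] * e
    pos += ((dperp / kBT) * Fperp * dt
            + np.sqrt(2.0 * dperp * dt) * (noise[:, 1:2] * v1 + noise[:, 2:3] * v2))
    e_new = (e + (drot / kBT) * np.cross(T, e) * dt
             + np.sqrt(2.0 * drot * dt) * (noise[:, 3:4] * v1 + noise[:, 4:5] * v2))
    e_new /= np.linalg.norm(e_new, axis=1, keepdims=True)
    ori[:] = e_new


def bd_step(cells, forces, params: ModelParams, rng: np.random.Generator,
            with_noise: bool = True):
    """One Brownian-dynamics step for a list of cells (or a Colony).

    ``forces`` is a matching list of :class:`ForceTorque` (or an ``(F, T)``
    array pair for a Colony).  Returns the updated cells in the same form;
    the test hook ``with_noise=False`` reduces the update to the
    deterministic drift.
    """
    is_colony = isinstance(cells, Colony)
    colony = cells if is_colony else Colony.from_cells(cells)
    if is_colony:
        F, T = forces
    else:
        if len(forces) != len(cells):
            raise ValueError("one ForceTorque per cell required")
        F = np.array([ft.F for ft in forces], dtype=float).reshape(-1, 3)
        T = np.array([ft.T for ft in forces], dtype=float).reshape(-1, 3)
    noise = (rng.standard_normal((colony.n, 5)) if with_noise
             else np.zeros((colony.n, 5)))
    bd_step_arrays(colony.pos, colony.ori, np.ascontiguousarray(F),
                   np.ascontiguousarray(T), colony.Lstar, params.D0,
                   params.dt, params.kBT, noise)
    return colony if is_colony else colony.to_cells()
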