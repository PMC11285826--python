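"""Numba-compiled numerical kernels.

These are the hot inner loops of the simulation: segment-segment closest
points, the assembled force/torque evaluation with a linked-cell neighbour
list, and the explicit (FTCS) update of the nutrient grid.  Everything here
works on plain float64 arrays in reduced units (sigma = 1); the public
modules wrap these kernels with validated, documented interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PARALLEL_TOL = 1e-9


@njit(cache=True)
def segment_params(r1, e1, h1, r2, e2, h2):
    """Closest-approach parameters (s, t) of two segments.

    Segment i is {r_i + u * e_i : |u| <= h_i} with unit e_i.  Exactly
    parallel overlapping segments resolve to the midpoint of the overlap
    interval.  Returns the axis coordinates of the closest points.
    """
    dx = r1[0] - r2[0]
    dy = r1[1] - r2[1]
    dz = r1[2] - r2[2]
    b = e1[0] * e2[0] + e1[1] * e2[1] + e1[2] * e2[2]
    d1 = e1[0] * dx + e1[1] * dy + e1[2] * dz
    d2 = e2[0] * dx + e2[1] * dy + e2[2] * dz
    denom = 1.0 - b * b

    if denom > _PARALLEL_TOL:
        s = (b * d2 - d1) / denom
    else:
        # Parallel: the set of s with unclamped partner inside segment 2 is
        # s in [lo, hi]; take the midpoint of its overlap with [-h1, h1].
        if b > 0.0:
            lo = (-h2 - d2) / b
            hi = (h2 - d2) / b
        else:
            lo = (h2 - d2) / b
            hi = (-h2 - d2) / b
        o_lo = max(lo, -h1)
        o_hi = min(hi, h1)
        if o_lo <= o_hi:
            s = 0.5 * (o_lo + o_hi)
        elif lo > h1:
            s = h1
        else:
            s = -h1

    if s < -h1:
        s = -h1
    elif s > h1:
        s = h1
    t = d2 + s * b
    if t < -h2:
        t = -h2
        s = t * b - d1
        if s < -h1:
            s = -h1
        elif s > h1:
            s = h1
    elif t > h2:
        t = h2
        s = t * b - d1
        if s < -h1:
            s = -h1
        elif s > h1:
            s = h1
    return s, t


@njit(cache=True)
def segment_distance(r1, e1, h1, r2, e2, h2):
    """Minimum distance between two segments and the closest points."""
    s, t = segment_params(r1, e1, h1, r2, e2, h2)
    wx = r1[0] + s * e1[0] - r2[0] - t * e2[0]
    wy = r1[1] + s * e1[1] - r2[1] - t * e2[1]
    wz = r1[2] + s * e1[2] - r2[2] - t * e2[2]
    dm = np.sqrt(wx * wx + wy * wy + wz * wz)
    return dm, s, t


@njit(cache=True)
def kihara_force_mag(dm, eps_BB):
    """-dU/ddm of the truncated-shifted Kihara potential (sigma = 1)."""
    if dm > 2.0:
        return 0.0
    inv = 1.0 / dm
    inv6 = inv ** 6
    return 4.0 * eps_BB * (12.0 * inv6 * inv6 - 6.0 * inv6) * inv


@njit(cache=True)
def total_forces_kernel(pos, ori, hl, Lstar,
                        eps_BB, eps_rep, eps_att, sigma_w, d_rep, d_c,
                        force_cap):
    """Forces and torques on every cell: pair + substrate contributions.

    Pairs are found with a linked-cell list whose bin edge is the maximum
    interaction range 2 sigma + 2 max(hl).  Each individual contribution is
    magnitude-capped at ``force_cap``; the number of capped contributions is
    returned for diagnostic logging by the caller.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    n_capped = 0

    # ---- substrate forces --------------------------------------------------
    for i in range(n):
        ez = ori[i, 2]
        rz = pos[i, 2]
        diw = rz - hl[i] * abs(ez)
        if diw < d_rep:
            if diw <= 1e-12:
                mag = force_cap
                n_capped += 1
            else:
                u = sigma_w / diw
                u2 = u * u
                u4 = u2 * u2
                u10 = u4 * u4 * u2
                mag = (eps_rep / diw) * (1.2 * u10 - 3.0 * u4)
                if mag > force_cap:
                    mag = force_cap
                    n_capped += 1
            F[i, 2] += mag
            # applied at the axis point closest to the substrate
            if abs(ez) > 1e-12:
                s = -hl[i] if ez > 0.0 else hl[i]
                # torque = (s e) x (mag k) = mag * s * (e_y, -e_x, 0)
                T[i, 0] += mag * s * ori[i, 1]
                T[i, 1] -= mag * s * ori[i, 0]
        if diw < d_c and rz > 0.0:
            fz = -eps_att * Lstar[i] * rz
            if fz < -force_cap:
                fz = -force_cap
                n_capped += 1
            F[i, 2] += fz
            # application point offset (L*^2 / (12 rz)) (e.k) e from centre
            off = Lstar[i] * Lstar[i] / (12.0 * rz) * ez
            T[i, 0] += fz * off * ori[i, 1]
            T[i, 1] -= fz * off * ori[i, 0]

    if n < 2:
        return F, T, n_capped

    # ---- linked-cell neighbour list ---------------------------------------
    hmax = hl[0]
    for i in range(1, n):
        if hl[i] > hmax:
            hmax = hl[i]
    edge = 2.0 + 2.0 * hmax

    xmin, ymin, zmin = pos[0, 0], pos[0, 1], pos[0, 2]
    xmax, ymax, zmax = xmin, ymin, zmin
    for i in range(1, n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        elif pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        elif pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        elif pos[i, 2] > zmax:
            zmax = pos[i, 2]
    nbx = int((xmax - xmin) / edge) + 1
    nby = int((ymax - ymin) / edge) + 1
    nbz = int((zmax - zmin) / edge) + 1

    head = np.full(nbx * nby * nbz, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    binx = np.empty(n, dtype=np.int64)
    biny = np.empty(n, dtype=np.int64)
    binz = np.empty(n, dtype=np.int64)
    for i in range(n):
        bx = int((pos[i, 0] - xmin) / edge)
        by = int((pos[i, 1] - ymin) / edge)
        bz = int((pos[i, 2] - zmin) / edge)
        if bx >= nbx:
            bx = nbx - 1
        if by >= nby:
            by = nby - 1
        if bz >= nbz:
            bz = nbz - 1
        binx[i], biny[i], binz[i] = bx, by, bz
        b = (bx * nby + by) * nbz + bz
        nxt[i] = head[b]
        head[b] = i

    # ---- pair forces -------------------------------------------------------
    for i in range(n):
        ri = pos[i]
        ei = ori[i]
        for dxb in range(-1, 2):
            bx = binx[i] + dxb
            if bx < 0 or bx >= nbx:
                continue
            for dyb in range(-1, 2):
                by = biny[i] + dyb
                if by < 0 or by >= nby:
                    continue
                for dzb in range(-1, 2):
                    bz = binz[i] + dzb
                    if bz < 0 or bz >= nbz:
                        continue
                    j = head[(bx * nby + by) * nbz + bz]
                    while j != -1:
                        if j > i:
                            reach = hl[i] + hl[j] + 2.0
                            cdx = ri[0] - pos[j, 0]
                            cdy = ri[1] - pos[j, 1]
                            cdz = ri[2] - pos[j, 2]
                            if (cdx * cdx + cdy * cdy + cdz * cdz
                                    <= reach * reach):
                                dm, s, t = segment_distance(
                                    ri, ei, hl[i], pos[j], ori[j], hl[j])
                                if dm < 2.0:
                                    if dm > 1e-9:
                                        f = kihara_force_mag(dm, eps_BB)
                                        if f > force_cap:
                                            f = force_cap
                                            n_capped += 1
                                        elif f < -force_cap:
                                            f = -force_cap
                                            n_capped += 1
                                        wx = (ri[0] + s * ei[0]
                                              - pos[j, 0] - t * ori[j, 0])
                                        wy = (ri[1] + s * ei[1]
                                              - pos[j, 1] - t * ori[j, 1])
                                        wz = (ri[2] + s * ei[2]
                                              - pos[j, 2] - t * ori[j, 2])
                                        ux, uy, uz = wx / dm, wy / dm, wz / dm
                                    else:
                                        # coincident closest points: push
                                        # apart along the centre separation
                                        f = force_cap
                                        n_capped += 1
                                        cn = np.sqrt(cdx * cdx + cdy * cdy
                                                     + cdz * cdz)
                                        if cn > 1e-12:
                                            ux, uy, uz = (cdx / cn, cdy / cn,
                                                          cdz / cn)
                                        else:
                                            ux, uy, uz = 1.0, 0.0, 0.0
                                    fx, fy, fz = f * ux, f * uy, f * uz
                                    F[i, 0] += fx
                                    F[i, 1] += fy
                                    F[i, 2] += fz
                                    F[j, 0] -= fx
                                    F[j, 1] -= fy
                                    F[j, 2] -= fz
                                    # torque_i = (s e_i) x F
                                    T[i, 0] += s * (ei[1] * fz - ei[2] * fy)
                                    T[i, 1] += s * (ei[2] * fx - ei[0] * fz)
                                    T[i, 2] += s * (ei[0] * fy - ei[1] * fx)
                                    # torque_j = (t e_j) x (-F)
                                    T[j, 0] -= t * (ori[j, 1] * fz
                                                    - ori[j, 2] * fy)
                                    T[j, 1] -= t * (ori[j, 2] * fx
                                                    - ori[j, 0] * fz)
                                    T[j, 2] -= t * (ori[j, 0] * fy
                                                    - ori[j, 1] * fx)
                        j = nxt[j]
    return F, T, n_capped


@njit(cache=True)
def bd_kernel(pos, ori, F, T, Lstar, D0, dt, kBT, noise):
    """In-place overdamped Brownian-dynamics update.

    Translational drift/noise are decomposed parallel and perpendicular to
    each cell's axis with the length-dependent diffusion coefficients
    evaluated inline; orientations get the torque drift plus rotational
    noise in the two perpendicular frame directions and are renormalized.
    Returns 0, or 1 if a non-finite force/torque was encountered.
    """
    n = pos.shape[0]
    for i in range(n):
        fx, fy, fz = F[i, 0], F[i, 1], F[i, 2]
        tx, ty, tz = T[i, 0], T[i, 1], T[i, 2]
        if not (np.isfinite(fx) and np.isfinite(fy) and np.isfinite(fz)
                and np.isfinite(tx) and np.isfinite(ty) and np.isfinite(tz)):
            return 1
        L = Lstar[i]
        lnL = np.log(L)
        L2 = L * L
        dpar = (-0.0198 * lnL + 0.0777 + 0.0437 / L - 0.0158 / L2) * D0
        dperp = (-0.0119 * lnL + 0.0452 + 0.0796022 / L - 0.0190 / L2) * D0
        L3 = L2 * L
        drot = (-0.0002 * lnL + 0.0012 - 0.0243 / L + 0.3232 / L2
                + 0.2597 / L3 - 0.0483 / (L2 * L2) - 0.1931 / (L3 * L2)) * D0

        ex, ey, ez = ori[i, 0], ori[i, 1], ori[i, 2]
        # frame vector 1: Gram-Schmidt against the least-aligned axis
        axx, axy, axz = abs(ex), abs(ey), abs(ez)
        if axx <= axy and axx <= axz:
            dot = ex
            v1x, v1y, v1z = 1.0 - dot * ex, -dot * ey, -dot * ez
        elif axy <= axz:
            dot = ey
            v1x, v1y, v1z = -dot * ex, 1.0 - dot * ey, -dot * ez
        else:
            dot = ez
            v1x, v1y, v1z = -dot * ex, -dot * ey, 1.0 - dot * ez
        inv = 1.0 / np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        v1x, v1y, v1z = v1x * inv, v1y * inv, v1z * inv
        v2x = ey * v1z - ez * v1y
        v2y = ez * v1x - ex * v1z
        v2z = ex * v1y - ey * v1x

        fpar = fx * ex + fy * ey + fz * ez
        cpar = (dpar / kBT) * dt
        cperp = (dperp / kBT) * dt
        spar = np.sqrt(2.0 * dpar * dt) * noise[i, 0]
        sp1 = np.sqrt(2.0 * dperp * dt) * noise[i, 1]
        sp2 = np.sqrt(2.0 * dperp * dt) * noise[i, 2]
        pos[i, 0] += (cpar * fpar + spar) * ex + cperp * (fx - fpar * ex) \
            + sp1 * v1x + sp2 * v2x
        pos[i, 1] += (cpar * fpar + spar) * ey + cperp * (fy - fpar * ey) \
            + sp1 * v1y + sp2 * v2y
        pos[i, 2] += (cpar * fpar + spar) * ez + cperp * (fz - fpar * ez) \
            + sp1 * v1z + sp2 * v2z

        # torque drift (T x e) and rotational noise
        crot = (drot / kBT) * dt
        sr1 = np.sqrt(2.0 * drot * dt) * noise[i, 3]
        sr2 = np.sqrt(2.0 * drot * dt) * noise[i, 4]
        dex = crot * (ty * ez - tz * ey) + sr1 * v1x + sr2 * v2x
        dey = crot * (tz * ex - tx * ez) + sr1 * v1y + sr2 * v2y
        dez = crot * (tx * ey - ty * ex) + sr1 * v1z + sr2 * v2z
        if dex != 0.0 or dey != 0.0 or dez != 0.0:
            nex, ney, nez = ex + dex, ey + dey, ez + dez
            inv = 1.0 / np.sqrt(nex * nex + ney * ney + nez * nez)
            ori[i, 0] = nex * inv
            ori[i, 1] = ney * inv
            ori[i, 2] = nez * inv
    return 0


@njit(cache=True)
def uptake_kernel(pos, Lstar, origin, h, C_flat, nx, ny, nz,
                  mu_max, Ks, veff, dt, mu_out, v_out, sinks_flat):
    """Monod uptake per cell with per-compartment availability scaling.

    Fills ``mu_out``, ``v_out`` and the per-compartment total uptake rate
    ``sinks_flat`` [amount/tau].  Returns 0, or 1 if any cell centre falls
    outside the grid (the caller then expands the grid and retries).
    """
    n = pos.shape[0]
    flat_idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        rx = (pos[i, 0] - origin[0]) / h
        ry = (pos[i, 1] - origin[1]) / h
        rz = (pos[i, 2] - origin[2]) / h
        if rx < 0.0 or ry < 0.0 or rz < 0.0:
            return 1
        ix, iy, iz = int(rx), int(ry), int(rz)
        if ix >= nx or iy >= ny or iz >= nz:
            return 1
        f = (ix * ny + iy) * nz + iz
        flat_idx[i] = f
        C = C_flat[f]
        mu = mu_max * Lstar[i] * C / (Ks + C)
        mu_out[i] = mu
        sinks_flat[f] += mu
    h3 = h * h * h
    ncomp = nx * ny * nz
    scale = np.ones(ncomp)
    for f in range(ncomp):
        req = sinks_flat[f]
        if req > 0.0:
            s = C_flat[f] * h3 / (req * dt)
            if s < 1.0:
                scale[f] = s
                sinks_flat[f] = req * s
    for i in range(n):
        m = mu_out[i] * scale[flat_idx[i]]
        mu_out[i] = m
        v_out[i] = veff * m / Lstar[i]
    return 0


@njit(cache=True)
def ftcs_kernel(C, sink_rate, h, dt, DN):
    """One FTCS step of dC/dt = DN lap(C) - sink_rate on the compartment grid.

    Boundary conditions: the outermost layers in x, y and the top z layer are
    Dirichlet (left untouched, held at the bulk value by the caller); z = 0 is
    zero-flux (mirror ghost).  Concentrations are clamped at zero; the
    actually-delivered sink rate is returned so growth bookkeeping can use
    nutrients actually consumed.
    """
    nx, ny, nz = C.shape
    Cn = C.copy()
    delivered = sink_rate.copy()
    a = dt * DN / (h * h)
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(0, nz - 1):
                below = C[i, j, k - 1] if k > 0 else C[i, j, k]
                lap = (C[i + 1, j, k] + C[i - 1, j, k]
                       + C[i, j + 1, k] + C[i, j - 1, k]
                       + C[i, j, k + 1] + below - 6.0 * C[i, j, k])
                v = C[i, j, k] + a * lap - dt * sink_rate[i, j, k]
                if v < 0.0:
                    delivered[i, j, k] = sink_rate[i, j, k] + v / dt
                    if delivered[i, j, k] < 0.0:
                        delivered[i, j, k] = 0.0
                    v = 0.0
                Cn[i, j, k] = v
    return Cn, delivered
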