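"""Numba-compiled kernels: cell/Verlet neighbor search, force evaluation and
the NVT/NVE integration loop.

Everything here works on plain float64/int64 arrays so the hot loop never
re-enters Python.  Geometry is selected by two flags: ``periodic`` (cubic
box of edge ``L``, minimum-image convention) and ``sphere`` (smooth
repulsive wall of radius ``R`` centred at the origin).  A particulate wall
is represented by appending frozen wall beads and masking them immobile.

Status codes returned by the integrators:
    0  OK
    1  FENE bond overstretched (r >= R0)
    2  neighbor-list buffer overflow (caller should retry with more room)
    3  monomer escaped the sphere (|r| >= R)
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
FENE_OVERSTRETCH = 1
NEIGHBOR_OVERFLOW = 2
ESCAPED = 3


# ---------------------------------------------------------------------------
# Neighbor search
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos, rlist, periodic, L, R, mobile,
                 pairs_i, pairs_j):
    """Half list of index pairs with separation < rlist.

    Cell edge is >= rlist so only the 27 surrounding cells are scanned.
    Pairs where both particles are immobile (wall beads) are skipped.
    Returns the pair count, or -1 on buffer overflow.
    """
    n = pos.shape[0]
    rlist2 = rlist * rlist
    if periodic:
        lo = 0.0
        extent = L
    else:
        lo = -(R + 2.0)
        extent = 2.0 * (R + 2.0)
    nc = int(extent / rlist)
    if nc < 1:
        nc = 1
    maxp = pairs_i.shape[0]
    if periodic and nc < 3:
        # box too small for a 3^3 stencil: brute-force all pairs
        np_pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                if mobile[i] == 0 and mobile[j] == 0:
                    continue
                ddx = pos[i, 0] - pos[j, 0]
                ddy = pos[i, 1] - pos[j, 1]
                ddz = pos[i, 2] - pos[j, 2]
                ddx -= L * np.rint(ddx / L)
                ddy -= L * np.rint(ddy / L)
                ddz -= L * np.rint(ddz / L)
                if ddx * ddx + ddy * ddy + ddz * ddz < rlist2:
                    if np_pairs >= maxp:
                        return -1
                    pairs_i[np_pairs] = i
                    pairs_j[np_pairs] = j
                    np_pairs += 1
        return np_pairs
    cell = extent / nc

    ncell = nc * nc * nc
    cidx = np.empty(n, np.int64)
    for i in range(n):
        x = pos[i, 0] - lo
        y = pos[i, 1] - lo
        z = pos[i, 2] - lo
        if periodic:
            x -= L * np.floor(x / L)
            y -= L * np.floor(y / L)
            z -= L * np.floor(z / L)
        ix = int(x / cell)
        iy = int(y / cell)
        iz = int(z / cell)
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix >= nc:
            ix = nc - 1
        if iy >= nc:
            iy = nc - 1
        if iz >= nc:
            iz = nc - 1
        cidx[i] = (ix * nc + iy) * nc + iz

    count = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        count[cidx[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count[:ncell].copy()
    for i in range(n):
        c = cidx[i]
        order[fill[c]] = i
        fill[c] += 1

    np_pairs = 0
    for i in range(n):
        c = cidx[i]
        cz = c % nc
        cy = (c // nc) % nc
        cx = c // (nc * nc)
        for dx in range(-1, 2):
            ex = cx + dx
            if periodic:
                ex = (ex + nc) % nc
            elif ex < 0 or ex >= nc:
                continue
            for dy in range(-1, 2):
                ey = cy + dy
                if periodic:
                    ey = (ey + nc) % nc
                elif ey < 0 or ey >= nc:
                    continue
                for dz in range(-1, 2):
                    ez = cz + dz
                    if periodic:
                        ez = (ez + nc) % nc
                    elif ez < 0 or ez >= nc:
                        continue
                    cc = (ex * nc + ey) * nc + ez
                    for k in range(count[cc], count[cc + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        if mobile[i] == 0 and mobile[j] == 0:
                            continue
                        ddx = pos[i, 0] - pos[j, 0]
                        ddy = pos[i, 1] - pos[j, 1]
                        ddz = pos[i, 2] - pos[j, 2]
                        if periodic:
                            ddx -= L * np.rint(ddx / L)
                            ddy -= L * np.rint(ddy / L)
                            ddz -= L * np.rint(ddz / L)
                        d2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2 < rlist2:
                            if np_pairs >= maxp:
                                return -1
                            pairs_i[np_pairs] = i
                            pairs_j[np_pairs] = j
                            np_pairs += 1
    return np_pairs


# ---------------------------------------------------------------------------
# Forces and energies
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _compute_forces(pos, forces, pairs_i, pairs_j, npairs,
                    bonds, angles, angle_k,
                    fene_k, fene_r0, eps, sigma, rc,
                    periodic, L, sphere, R, wall_eps,
                    fcap, energies):
    """Fill ``forces`` with -grad U and ``energies`` with the four terms
    (fene, pair, bending, wall).  ``fcap`` < 0 disables force capping.

    Returns a status code; on FENE overstretch the offending bond index is
    written to energies[4] as a float for diagnostics.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e_fene = 0.0
    e_pair = 0.0
    e_bend = 0.0
    e_wall = 0.0

    rc2 = rc * rc
    sig2 = sigma * sigma
    # WCA pairs (bonded and non-bonded alike)
    for k in range(npairs):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < rc2:
            s2 = sig2 / d2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            e_pair += 4.0 * eps * (s12 - s6 + 0.25)
            fmag = 24.0 * eps * (2.0 * s12 - s6) / d2  # -(dU/dr)/r
            if fcap >= 0.0:
                d1 = np.sqrt(d2)
                if fmag * d1 > fcap:
                    fmag = fcap / d1
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    # FENE bonds
    r02 = fene_r0 * fene_r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if periodic:
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        x = d2 / r02
        if x >= 1.0:
            energies[4] = float(b)
            return FENE_OVERSTRETCH
        e_fene += -0.5 * fene_k * r02 * np.log(1.0 - x)
        g = fene_k / (1.0 - x)  # (dU/dr)/r, attractive along the bond
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # Bending: U = kb * (1 + cos(theta)) with theta the interior angle at
    # the middle monomer (pi when collinear) => U = kb * (1 - u.v) for unit
    # bond vectors u = b1/|b1|, v = b2/|b2|.
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k2 = angles[a, 2]
        kb = angle_k[a]
        if kb == 0.0:
            continue
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k2, 0] - pos[j, 0]
        b2y = pos[k2, 1] - pos[j, 1]
        b2z = pos[k2, 2] - pos[j, 2]
        if periodic:
            b1x -= L * np.rint(b1x / L)
            b1y -= L * np.rint(b1y / L)
            b1z -= L * np.rint(b1z / L)
            b2x -= L * np.rint(b2x / L)
            b2y -= L * np.rint(b2y / L)
            b2z -= L * np.rint(b2z / L)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        ux = b1x / n1
        uy = b1y / n1
        uz = b1z / n1
        vx = b2x / n2
        vy = b2y / n2
        vz = b2z / n2
        c = ux * vx + uy * vy + uz * vz
        e_bend += kb * (1.0 - c)
        # F = kb * dc/dr  (since U = kb(1-c))
        gi_x = -(vx - c * ux) / n1
        gi_y = -(vy - c * uy) / n1
        gi_z = -(vz - c * uz) / n1
        gk_x = (ux - c * vx) / n2
        gk_y = (uy - c * vy) / n2
        gk_z = (uz - c * vz) / n2
        forces[i, 0] += kb * gi_x
        forces[i, 1] += kb * gi_y
        forces[i, 2] += kb * gi_z
        forces[k2, 0] += kb * gk_x
        forces[k2, 1] += kb * gk_y
        forces[k2, 2] += kb * gk_z
        forces[j, 0] -= kb * (gi_x + gk_x)
        forces[j, 1] -= kb * (gi_y + gk_y)
        forces[j, 2] -= kb * (gi_z + gk_z)

    # Smooth wall: WCA on the radial gap d = R - |r|
    if sphere:
        for i in range(n):
            r2 = (pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
                  + pos[i, 2] * pos[i, 2])
            r1 = np.sqrt(r2)
            if r1 >= R:
                energies[4] = float(i)
                return ESCAPED
            gap = R - r1
            if gap < rc and r1 > 0.0:
                s2 = sig2 / (gap * gap)
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                e_wall += 4.0 * wall_eps * (s12 - s6 + 0.25)
                # dU/dgap < 0 (repulsive); F = -dU/dr_vec = dU/dgap * r_hat
                dudg = -24.0 * wall_eps * (2.0 * s12 - s6) / gap
                if fcap >= 0.0 and -dudg > fcap:
                    dudg = -fcap
                forces[i, 0] += dudg * pos[i, 0] / r1
                forces[i, 1] += dudg * pos[i, 1] / r1
                forces[i, 2] += dudg * pos[i, 2] / r1

    energies[0] = e_fene
    energies[1] = e_pair
    energies[2] = e_bend
    energies[3] = e_wall
    return OK


@njit(cache=True)
def evaluate(pos, bonds, angles, angle_k,
             fene_k, fene_r0, eps, sigma, rc,
             periodic, L, sphere, R, wall_eps, mobile):
    """One-shot force/energy evaluation with a freshly built neighbor list.

    Returns (status, forces, energies[fene, pair, bend, wall, diag]).
    """
    n = pos.shape[0]
    maxp = 60 * n + 1000
    pairs_i = np.empty(maxp, np.int64)
    pairs_j = np.empty(maxp, np.int64)
    npairs = _build_pairs(pos, rc, periodic, L, R, mobile, pairs_i, pairs_j)
    forces = np.zeros((n, 3))
    energies = np.zeros(5)
    if npairs < 0:
        return NEIGHBOR_OVERFLOW, forces, energies
    status = _compute_forces(pos, forces, pairs_i, pairs_j, npairs,
                             bonds, angles, angle_k,
                             fene_k, fene_r0, eps, sigma, rc,
                             periodic, L, sphere, R, wall_eps,
                             -1.0, energies)
    return status, forces, energies


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def md_run(pos, vel, mobile, bonds, angles, angle_k,
           periodic, L, sphere, R, wall_eps,
           fene_k, fene_r0, eps, sigma, rc,
           dt, n_steps, thermostat, T_target, Q, xi0,
           skin, sample_every, sample_pos, sample_vel):
    """Velocity-Verlet NVT/NVE loop, entirely compiled.

    A Verlet pair list with the given skin is rebuilt whenever the fastest
    particle has moved more than skin/2 since the last build.  With
    ``thermostat`` a single Nose-Hoover friction xi (initial ``xi0``)
    targets ``T_target``; otherwise the update is symplectic NVE.

    Samples are written every ``sample_every`` steps (after the step) into
    the pre-allocated ``sample_pos`` / ``sample_vel`` arrays.

    Returns (status, xi, n_samples, diag) where diag identifies the bond
    or particle on failure.
    """
    n = pos.shape[0]
    n_mobile = 0
    for i in range(n):
        if mobile[i]:
            n_mobile += 1
    ndof = 3.0 * n_mobile - 3.0
    if ndof <= 0.0:
        ndof = 1.0

    rlist = rc + skin
    maxp = 80 * n + 1000
    pairs_i = np.empty(maxp, np.int64)
    pairs_j = np.empty(maxp, np.int64)
    forces = np.zeros((n, 3))
    energies = np.zeros(5)
    ref = pos.copy()
    half_skin2 = 0.25 * skin * skin

    npairs = _build_pairs(pos, rlist, periodic, L, R, mobile, pairs_i, pairs_j)
    if npairs < 0:
        return NEIGHBOR_OVERFLOW, xi0, 0, -1.0
    status = _compute_forces(pos, forces, pairs_i, pairs_j, npairs,
                             bonds, angles, angle_k, fene_k, fene_r0,
                             eps, sigma, rc, periodic, L, sphere, R,
                             wall_eps, -1.0, energies)
    if status != OK:
        return status, xi0, 0, energies[4]

    xi = xi0
    half = 0.5 * dt
    quarter = 0.25 * dt
    n_samp = 0
    for step in range(n_steps):
        # thermostat half-step (symmetric MTK splitting: xi driven by the
        # on-step kinetic energy, velocities rescaled by exp(-xi dt/2))
        if thermostat:
            twoke = 0.0
            for i in range(n):
                if mobile[i]:
                    twoke += (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                              + vel[i, 2] * vel[i, 2])
            xi += quarter * (twoke - ndof * T_target) / Q
            s = np.exp(-half * xi)
            for i in range(n):
                if mobile[i]:
                    vel[i, 0] *= s
                    vel[i, 1] *= s
                    vel[i, 2] *= s
            twoke *= s * s
            xi += quarter * (twoke - ndof * T_target) / Q
        # first half-kick
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * forces[i, 0]
                vel[i, 1] += half * forces[i, 1]
                vel[i, 2] += half * forces[i, 2]
        # drift
        maxd2 = 0.0
        for i in range(n):
            if mobile[i]:
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]
                ddx = pos[i, 0] - ref[i, 0]
                ddy = pos[i, 1] - ref[i, 1]
                ddz = pos[i, 2] - ref[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > maxd2:
                    maxd2 = d2
        if maxd2 > half_skin2:
            npairs = _build_pairs(pos, rlist, periodic, L, R, mobile,
                                  pairs_i, pairs_j)
            if npairs < 0:
                return NEIGHBOR_OVERFLOW, xi, n_samp, -1.0
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        status = _compute_forces(pos, forces, pairs_i, pairs_j, npairs,
                                 bonds, angles, angle_k, fene_k, fene_r0,
                                 eps, sigma, rc, periodic, L, sphere, R,
                                 wall_eps, -1.0, energies)
        if status != OK:
            return status, xi, n_samp, energies[4]
        # second half-kick
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * forces[i, 0]
                vel[i, 1] += half * forces[i, 1]
                vel[i, 2] += half * forces[i, 2]
        # closing thermostat half-step (mirror of the opening one)
        if thermostat:
            twoke = 0.0
            for i in range(n):
                if mobile[i]:
                    twoke += (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                              + vel[i, 2] * vel[i, 2])
            xi += quarter * (twoke - ndof * T_target) / Q
            s = np.exp(-half * xi)
            for i in range(n):
                if mobile[i]:
                    vel[i, 0] *= s
                    vel[i, 1] *= s
                    vel[i, 2] *= s
            twoke *= s * s
            xi += quarter * (twoke - ndof * T_target) / Q
        if sample_every > 0 and (step + 1) % sample_every == 0:
            if n_samp < sample_pos.shape[0]:
                for i in range(n):
                    sample_pos[n_samp, i, 0] = pos[i, 0]
                    sample_pos[n_samp, i, 1] = pos[i, 1]
                    sample_pos[n_samp, i, 2] = pos[i, 2]
                    sample_vel[n_samp, i, 0] = vel[i, 0]
                    sample_vel[n_samp, i, 1] = vel[i, 1]
                    sample_vel[n_samp, i, 2] = vel[i, 2]
                n_samp += 1
    return OK, xi, n_samp, 0.0


@njit(cache=True, fastmath=True)
def pushoff(pos, mobile, bonds, angles, angle_k,
            periodic, L, sphere, R, wall_eps,
            fene_k, fene_r0, eps, sigma, rc,
            n_steps, fcap_start, fcap_end, mobility, max_disp):
    """Overdamped push-off: capped WCA repulsion ramped up to full strength.

    Each step moves particles by mobility*F, with per-particle displacement
    clamped to ``max_disp``; the pair/wall force cap grows geometrically
    from fcap_start to fcap_end so initial overlaps relax without kicks.
    """
    n = pos.shape[0]
    maxp = 80 * n + 1000
    pairs_i = np.empty(maxp, np.int64)
    pairs_j = np.empty(maxp, np.int64)
    forces = np.zeros((n, 3))
    energies = np.zeros(5)
    ratio = (fcap_end / fcap_start) ** (1.0 / max(n_steps - 1, 1))
    fcap = fcap_start
    for step in range(n_steps):
        npairs = _build_pairs(pos, rc, periodic, L, R, mobile,
                              pairs_i, pairs_j)
        if npairs < 0:
            return NEIGHBOR_OVERFLOW
        status = _compute_forces(pos, forces, pairs_i, pairs_j, npairs,
                                 bonds, angles, angle_k, fene_k, fene_r0,
                                 eps, sigma, rc, periodic, L, sphere, R,
                                 wall_eps, fcap, energies)
        if status != OK:
            return status
        for i in range(n):
            if mobile[i]:
                dx = mobility * forces[i, 0]
                dy = mobility * forces[i, 1]
                dz = mobility * forces[i, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d > max_disp:
                    s = max_disp / d
                    dx *= s
                    dy *= s
                    dz *= s
                pos[i, 0] += dx
                pos[i, 1] += dy
                pos[i, 2] += dz
        fcap *= ratio
    return OK


@njit(cache=True)
def min_pair_distance(pos, periodic, L, R, mobile):
    """Smallest inter-particle distance, via the same cell search."""
    n = pos.shape[0]
    maxp = 200 * n + 1000
    pairs_i = np.empty(maxp, np.int64)
    pairs_j = np.empty(maxp, np.int64)
    npairs = _build_pairs(pos, 2.0, periodic, L, R, mobile, pairs_i, pairs_j)
    best = 1e30
    if npairs < 0:  # very dense: fall back to brute force
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if periodic:
                    dx -= L * np.rint(dx / L)
                    dy -= L * np.rint(dy / L)
                    dz -= L * np.rint(dz / L)
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < best:
                    best = d2
        return np.sqrt(best)
    for k in range(npairs):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < best:
            best = d2
    return np.sqrt(best)
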