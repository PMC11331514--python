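"""Numba-compiled inner loops for the Monte Carlo engine.

All kernels work in the internal unit system (angstrom, k_BT, e0) and take
the model/geometry as a flat tuple of scalars so they stay cache-friendly:

    params = (is_slit, L, zmax, d, eps_c, eps_b, delta, lB1, lb_b)

where ``lB1 = e0^2/(4 pi eps0 k_B T)`` in angstrom is the Bjerrum length
at eps == 1, ``lb_b = lB1/eps_b``, and ``zmax = (H - d)/2`` is the wall
bound for ion centers (unused for bulk).

Slit electrostatics use the charged-sheet decomposition per pair: explicit
minimum-image point charge (with the dielectric ramp) + infinite sheet
minus central square patch at eps_b + a tabulated lattice-discreteness
residual ``rtab`` (see :func:`build_residual_table`), which restores the
difference between the true discrete image lattice and its sheet
continuum; the residual is smooth on the scale of L, so trilinear
interpolation reproduces explicit image summation to high accuracy.
Kernels that only serve bulk geometry take a dummy 1x1x1 ``rtab``.

Randomness: kernels draw from numba's internal Mersenne-Twister np.random
stream, seeded explicitly at the top of each sweep block by the caller
(the engine derives block seeds from its single master Generator), which
makes runs reproducible and checkpoint/resume bitwise identical at block
boundaries.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# params tuple indices
IS_SLIT, P_L, P_ZMAX, P_D, P_EPSC, P_EPSB, P_DELTA, P_LB1, P_LBB = range(9)


@njit(cache=True, inline="always")
def _wrap(x: float, L: float) -> float:
    return x - L * math.floor(x / L)


@njit(cache=True, inline="always")
def _mi(dx: float, L: float) -> float:
    return dx - L * math.floor(dx / L + 0.5)


@njit(cache=True, inline="always")
def _ramp_beta_u(qq: float, r: float, d: float, eps_c: float, eps_b: float,
                 delta: float, lB1: float) -> float:
    """beta*u for the direct (minimum-image) pair at separation r >= d."""
    if r >= d + delta:
        eps = eps_b
    elif r <= d:
        eps = eps_c
    else:
        eps = eps_c + (eps_b - eps_c) * (r - d) / delta
    return qq * lB1 / (eps * r)


@njit(cache=True)
def _patch_phi(dx: float, dy: float, dz: float, L: float) -> float:
    """Potential of a unit-charge square patch of side L centred at
    lateral offset (dx, dy), height dz from the field point (1/r units)."""
    h = abs(dz)
    u1 = dx - 0.5 * L
    u2 = dx + 0.5 * L
    v1 = dy - 0.5 * L
    v2 = dy + 0.5 * L
    val = 0.0
    # corner sum with alternating signs: (u2,v2) - (u1,v2) - (u2,v1) + (u1,v1)
    for k in range(4):
        if k == 0:
            u, v, s = u2, v2, 1.0
        elif k == 1:
            u, v, s = u1, v2, -1.0
        elif k == 2:
            u, v, s = u2, v1, -1.0
        else:
            u, v, s = u1, v1, 1.0
        r = math.sqrt(u * u + v * v + h * h)
        term = 0.0
        if v + r > 0.0:
            term += u * math.log(v + r)
        if u + r > 0.0:
            term += v * math.log(u + r)
        if h > 0.0:
            term -= h * math.atan2(u * v, h * r)
        val += s * term
    return val / (L * L)


@njit(cache=True)
def build_residual_table(L: float, zspan: float, ndx: int, ndz: int,
                         n_shells: int) -> np.ndarray:
    """Lattice-discreteness residual of the charged-sheet approximation.

    R(dx, dy, dz) = sum_{0 < |n|_inf <= M} 1/|u + nL|
                    - patch_{(2M+1)L}(u) + patch_L(u)

    i.e. the true discrete lateral image sum (out to M shells, the rest
    kept in continuum form) minus the infinite-sheet-minus-central-patch
    representation, with the divergent sheet constant cancelling exactly.
    Tabulated on a regular grid over dx, dy in [0, L/2] (symmetry) and
    dz in [0, zspan]; units of 1/length (multiply by l_B*q_i*q_j).
    """
    tab = np.empty((ndx, ndx, ndz))
    hx = (0.5 * L) / (ndx - 1)
    hz = zspan / (ndz - 1) if ndz > 1 else 1.0
    big = (2 * n_shells + 1) * L
    for ix in range(ndx):
        dx = ix * hx
        for iy in range(ndx):
            dy = iy * hx
            for iz in range(ndz):
                dz = iz * hz
                s = 0.0
                for nx in range(-n_shells, n_shells + 1):
                    for ny in range(-n_shells, n_shells + 1):
                        if nx == 0 and ny == 0:
                            continue
                        ux = dx + nx * L
                        uy = dy + ny * L
                        s += 1.0 / math.sqrt(ux * ux + uy * uy + dz * dz)
                s -= _patch_phi(dx, dy, dz, big) * big * big / (L * L)
                s += _patch_phi(dx, dy, dz, L)
                # midpoint-rule (curvature) correction for the continuum
                # tail beyond M shells: -(1/24) * integral of the lateral
                # Laplacian of 1/r over the exterior, square boundary
                # approximated by the equal-area disk
                r_eff = big / math.sqrt(math.pi)
                u0 = math.sqrt(r_eff * r_eff + dz * dz)
                s -= (2.0 * math.pi / 24.0) * (1.0 / u0 - dz * dz / u0**3)
                tab[ix, iy, iz] = s
    return tab


@njit(cache=True, inline="always")
def _residual_interp(rtab, dx: float, dy: float, dz: float,
                     L: float, zspan: float) -> float:
    """Trilinear interpolation of the residual table (abs-symmetric)."""
    ndx = rtab.shape[0]
    ndz = rtab.shape[2]
    hx = (0.5 * L) / (ndx - 1)
    hz = zspan / (ndz - 1) if ndz > 1 else 1.0
    x = abs(dx) / hx
    y = abs(dy) / hx
    z = abs(dz) / hz
    ix = int(x)
    iy = int(y)
    iz = int(z)
    if ix > ndx - 2:
        ix = ndx - 2
    if iy > ndx - 2:
        iy = ndx - 2
    if iz > ndz - 2:
        iz = ndz - 2
    fx = x - ix
    fy = y - iy
    fz = z - iz
    c00 = rtab[ix, iy, iz] * (1 - fx) + rtab[ix + 1, iy, iz] * fx
    c10 = rtab[ix, iy + 1, iz] * (1 - fx) + rtab[ix + 1, iy + 1, iz] * fx
    c01 = rtab[ix, iy, iz + 1] * (1 - fx) + rtab[ix + 1, iy, iz + 1] * fx
    c11 = rtab[ix, iy + 1, iz + 1] * (1 - fx) + rtab[ix + 1, iy + 1, iz + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True, inline="always")
def _image_phi(rtab, dx: float, dy: float, dz: float, L: float,
               zspan: float) -> float:
    """Potential (1/r units) of all out-of-cell lateral images of a unit
    charge: sheet minus central patch plus the discreteness residual."""
    return (-2.0 * math.pi * abs(dz) / (L * L)
            - _patch_phi(dx, dy, dz, L)
            + _residual_interp(rtab, dx, dy, dz, L, zspan))


@njit(cache=True)
def _pair_terms(xi: float, yi: float, zi: float, qi: float,
                xj: float, yj: float, zj: float, qj: float,
                params, rtab) -> float:
    """Full pair energy (direct MI + slit image terms), in k_BT.

    Returns -1.0e300 as an overlap sentinel (caller must check).
    """
    L = params[P_L]
    d = params[P_D]
    dx = _mi(xj - xi, L)
    dy = _mi(yj - yi, L)
    dz = zj - zi
    if params[IS_SLIT] == 0.0:
        dz = _mi(dz, L)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < d * d:
        return -1.0e300
    r = math.sqrt(r2)
    e = _ramp_beta_u(qi * qj, r, d, params[P_EPSC], params[P_EPSB],
                     params[P_DELTA], params[P_LB1])
    if params[IS_SLIT] != 0.0:
        zspan = 2.0 * params[P_ZMAX]
        e += qi * qj * params[P_LBB] * _image_phi(rtab, dx, dy, dz, L, zspan)
    return e


@njit(cache=True)
def particle_energy(pos, q, i, params, rtab) -> float:
    """Interaction energy of ion i with all others (k_BT); -1e300 on overlap."""
    n = pos.shape[0]
    tot = 0.0
    for j in range(n):
        if j == i:
            continue
        e = _pair_terms(pos[i, 0], pos[i, 1], pos[i, 2], q[i],
                        pos[j, 0], pos[j, 1], pos[j, 2], q[j], params, rtab)
        if e == -1.0e300:
            return -1.0e300
        tot += e
    return tot


@njit(cache=True)
def total_energy(pos, q, params, rtab) -> float:
    """Total configurational energy (k_BT); -1e300 on any overlap.

    For slit geometry this includes the configuration-independent
    self-image terms so that totals match explicit lateral image summation
    for electroneutral systems.
    """
    n = pos.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e = _pair_terms(pos[i, 0], pos[i, 1], pos[i, 2], q[i],
                            pos[j, 0], pos[j, 1], pos[j, 2], q[j],
                            params, rtab)
            if e == -1.0e300:
                return -1.0e300
            tot += e
    if params[IS_SLIT] != 0.0:
        zspan = 2.0 * params[P_ZMAX]
        phi0 = _image_phi(rtab, 0.0, 0.0, 0.0, params[P_L], zspan)
        for i in range(n):
            tot += 0.5 * q[i] * q[i] * params[P_LBB] * phi0
    return tot


@njit(cache=True)
def _trial_particle_energy(pos, q, i, x: float, y: float, z: float,
                           params, rtab) -> float:
    """Energy of ion i at a trial position against all others."""
    n = pos.shape[0]
    tot = 0.0
    for j in range(n):
        if j == i:
            continue
        e = _pair_terms(x, y, z, q[i],
                        pos[j, 0], pos[j, 1], pos[j, 2], q[j], params, rtab)
        if e == -1.0e300:
            return -1.0e300
        tot += e
    return tot


@njit(cache=True)
def _build_cluster(pos, params, seed_ion, delta_mv, members, member_flag, stack):
    """Connected component containing seed_ion under MI distance <= delta_mv.

    Fills ``members`` (indices) and ``member_flag``; returns the size.
    """
    n = pos.shape[0]
    L = params[P_L]
    is_slit = params[IS_SLIT] != 0.0
    for j in range(n):
        member_flag[j] = 0
    nm = 0
    sp = 0
    stack[sp] = seed_ion
    sp += 1
    member_flag[seed_ion] = 1
    d2 = delta_mv * delta_mv
    while sp > 0:
        sp -= 1
        i = stack[sp]
        members[nm] = i
        nm += 1
        for j in range(n):
            if member_flag[j] == 0:
                dx = _mi(pos[j, 0] - pos[i, 0], L)
                dy = _mi(pos[j, 1] - pos[i, 1], L)
                dz = pos[j, 2] - pos[i, 2]
                if not is_slit:
                    dz = _mi(dz, L)
                if dx * dx + dy * dy + dz * dz <= d2:
                    member_flag[j] = 1
                    stack[sp] = j
                    sp += 1
    return nm


@njit(cache=True)
def run_block(pos, q, params, rtab, nsweeps, max_step, cluster_frac,
              cluster_step, delta_mv, seed, energy_in):
    """Run ``nsweeps`` MC sweeps (N attempts each) in place.

    Returns (energy, disp_attempts, disp_accepts, cl_attempts, cl_accepts).
    Positions are modified in place; x, y (and z for bulk) are kept wrapped
    into [0, L).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    L = params[P_L]
    zmax = params[P_ZMAX]
    is_slit = params[IS_SLIT] != 0.0
    energy = energy_in
    disp_att = 0
    disp_acc = 0
    cl_att = 0
    cl_acc = 0
    members = np.empty(n, dtype=np.int64)
    member_flag = np.zeros(n, dtype=np.int8)
    stack = np.empty(n, dtype=np.int64)
    newpos = np.empty((n, 3), dtype=np.float64)

    for _ in range(nsweeps):
        for _attempt in range(n):
            if cluster_frac > 0.0 and np.random.random() < cluster_frac:
                # ---- cluster move: rigid translation of a connected component
                cl_att += 1
                s = np.random.randint(0, n)
                nm = _build_cluster(pos, params, s, delta_mv, members,
                                    member_flag, stack)
                tx = (np.random.random() - 0.5) * 2.0 * cluster_step
                ty = (np.random.random() - 0.5) * 2.0 * cluster_step
                tz = (np.random.random() - 0.5) * 2.0 * cluster_step
                ok = True
                for k in range(nm):
                    i = members[k]
                    zi = pos[i, 2] + tz
                    if is_slit:
                        if abs(zi) > zmax:
                            ok = False
                            break
                    else:
                        zi = _wrap(zi, L)
                    newpos[i, 0] = _wrap(pos[i, 0] + tx, L)
                    newpos[i, 1] = _wrap(pos[i, 1] + ty, L)
                    newpos[i, 2] = zi
                if not ok:
                    continue
                # merge-rejection guard: translated cluster must not gain members
                d2 = delta_mv * delta_mv
                for k in range(nm):
                    i = members[k]
                    for j in range(n):
                        if member_flag[j] == 0:
                            dx = _mi(pos[j, 0] - newpos[i, 0], L)
                            dy = _mi(pos[j, 1] - newpos[i, 1], L)
                            dz = pos[j, 2] - newpos[i, 2]
                            if not is_slit:
                                dz = _mi(dz, L)
                            if dx * dx + dy * dy + dz * dz <= d2:
                                ok = False
                                break
                    if not ok:
                        break
                if not ok:
                    continue
                # external energy change (internal pair terms are preserved
                # exactly by the rigid translation, including image terms)
                du = 0.0
                for k in range(nm):
                    i = members[k]
                    for j in range(n):
                        if member_flag[j] == 0:
                            e_new = _pair_terms(newpos[i, 0], newpos[i, 1],
                                                newpos[i, 2], q[i],
                                                pos[j, 0], pos[j, 1],
                                                pos[j, 2], q[j], params, rtab)
                            if e_new == -1.0e300:
                                ok = False
                                break
                            e_old = _pair_terms(pos[i, 0], pos[i, 1],
                                                pos[i, 2], q[i],
                                                pos[j, 0], pos[j, 1],
                                                pos[j, 2], q[j], params, rtab)
                            du += e_new - e_old
                    if not ok:
                        break
                if not ok:
                    continue
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    for k in range(nm):
                        i = members[k]
                        pos[i, 0] = newpos[i, 0]
                        pos[i, 1] = newpos[i, 1]
                        pos[i, 2] = newpos[i, 2]
                    energy += du
                    cl_acc += 1
            else:
                # ---- single-particle displacement
                disp_att += 1
                i = np.random.randint(0, n)
                x = pos[i, 0] + (np.random.random() - 0.5) * 2.0 * max_step
                y = pos[i, 1] + (np.random.random() - 0.5) * 2.0 * max_step
                z = pos[i, 2] + (np.random.random() - 0.5) * 2.0 * max_step
                x = _wrap(x, L)
                y = _wrap(y, L)
                if is_slit:
                    if abs(z) > zmax:
                        continue
                else:
                    z = _wrap(z, L)
                du = 0.0
                ok = True
                for j in range(n):
                    if j == i:
                        continue
                    e_new = _pair_terms(x, y, z, q[i],
                                        pos[j, 0], pos[j, 1], pos[j, 2],
                                        q[j], params, rtab)
                    if e_new == -1.0e300:
                        ok = False
                        break
                    du += e_new - _pair_terms(pos[i, 0], pos[i, 1], pos[i, 2],
                                              q[i], pos[j, 0], pos[j, 1],
                                              pos[j, 2], q[j], params, rtab)
                if not ok:
                    continue
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                    energy += du
                    disp_acc += 1
    return energy, disp_att, disp_acc, cl_att, cl_acc


@njit(cache=True)
def widom_pair_frame_multi(pos, q, params, rtab, r_seps, ninsert, qtest, seed):
    """Ghost +q/-q pair insertions into one frame at several separations.

    Common random numbers: each insertion draws one position for the +q
    ghost and one orientation, shared across all separations; the -q ghost
    is placed at distance r_k along that direction for each k.  The
    r-independent (solvation) part of dU — including rare near-contact
    Boltzmann spikes of the fixed ghost — is then identical across
    separations and cancels in referenced free-energy differences, which
    controls the heavy-tailed estimator variance at strong coupling.
    Returns the per-separation means of exp(-beta*dU_medium).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nk = r_seps.shape[0]
    L = params[P_L]
    acc = np.zeros(nk)
    for _ in range(ninsert):
        x1 = np.random.random() * L
        y1 = np.random.random() * L
        z1 = np.random.random() * L
        ct = 2.0 * np.random.random() - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct
        du1 = 0.0
        ok1 = True
        for j in range(n):
            e1 = _pair_terms(x1, y1, z1, qtest,
                             pos[j, 0], pos[j, 1], pos[j, 2], q[j],
                             params, rtab)
            if e1 == -1.0e300:
                ok1 = False
                break
            du1 += e1
        if not ok1:
            continue
        for k in range(nk):
            x2 = _wrap(x1 + r_seps[k] * ux, L)
            y2 = _wrap(y1 + r_seps[k] * uy, L)
            z2 = _wrap(z1 + r_seps[k] * uz, L)
            du2 = 0.0
            ok2 = True
            for j in range(n):
                e2 = _pair_terms(x2, y2, z2, -qtest,
                                 pos[j, 0], pos[j, 1], pos[j, 2], q[j],
                                 params, rtab)
                if e2 == -1.0e300:
                    ok2 = False
                    break
                du2 += e2
            if ok2:
                acc[k] += math.exp(-(du1 + du2))
    return acc / ninsert


@njit(cache=True)
def widom_pair_frame(pos, q, params, rtab, r_sep, ninsert, qtest, seed):
    """Ghost +q/-q pair insertions into one frame (bulk geometry).

    For each insertion the ghost pair is placed at a uniform random position
    and orientation with separation ``r_sep``; returns the mean over
    insertions of exp(-beta*dU_medium), where dU_medium is the interaction
    of both ghosts with the medium ions (the constant ghost-ghost term is
    added analytically by the caller).  Hard-core overlaps contribute 0.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    L = params[P_L]
    acc = 0.0
    for _ in range(ninsert):
        x1 = np.random.random() * L
        y1 = np.random.random() * L
        z1 = np.random.random() * L
        ct = 2.0 * np.random.random() - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * np.random.random()
        x2 = _wrap(x1 + r_sep * st * math.cos(phi), L)
        y2 = _wrap(y1 + r_sep * st * math.sin(phi), L)
        z2 = _wrap(z1 + r_sep * ct, L)
        du = 0.0
        ok = True
        for j in range(n):
            e1 = _pair_terms(x1, y1, z1, qtest,
                             pos[j, 0], pos[j, 1], pos[j, 2], q[j],
                             params, rtab)
            if e1 == -1.0e300:
                ok = False
                break
            e2 = _pair_terms(x2, y2, z2, -qtest,
                             pos[j, 0], pos[j, 1], pos[j, 2], q[j],
                             params, rtab)
            if e2 == -1.0e300:
                ok = False
                break
            du += e1 + e2
        if ok:
            acc += math.exp(-du)
    return acc / ninsert
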