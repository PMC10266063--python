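"""Numba kernels: pair forces (cell list) and the BAOAB Langevin stepper.

Scalar duplicates of the potentials in :mod:`stickerslab.model`; the
vectorized functions there are the reference, these are the hot path.
Status codes: 0 ok, 1 bond reached R0, 2 coincident same-type beads.
"""

import numpy as np
from numba import njit

_RC_FACT = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _mic(dx, L):
    return dx - L * np.floor(dx / L + 0.5)


@njit(cache=True, inline="always")
def _nb_pair(r2, same_type, u0eff, d, eps):
    """Nonbonded energy and force/r for one pair. Returns (e, fovr, status)."""
    if same_type:
        rc2 = (_RC_FACT * d) * (_RC_FACT * d)
        if r2 < rc2:
            if r2 < 1e-24:
                return 0.0, 0.0, 2
            s2 = d * d / r2
            s6 = s2 * s2 * s2
            e = 4.0 * eps * (s6 * s6 - s6 + 0.25)
            fovr = 4.0 * eps * (12.0 * s6 * s6 - 6.0 * s6) / r2
            return e, fovr, 0
    else:
        if u0eff != 0.0 and r2 < d * d:
            r = np.sqrt(r2)
            e = -0.5 * u0eff * (1.0 + np.cos(np.pi * r / d))
            if r > 1e-12:
                fovr = -0.5 * u0eff * np.pi * np.sin(np.pi * r / d) / (d * r)
            else:
                # sin(pi r/d)/r -> pi/d as r -> 0 (A-B beads may overlap)
                fovr = -0.5 * u0eff * np.pi * np.pi / (d * d)
            return e, fovr, 0
    return 0.0, 0.0, 0


@njit(cache=True)
def compute_forces(pos, box, types, bonds, chain_id, forces, virial,
                   kb, r0, u0eff, d, eps, excl_bonded):
    """Accumulate forces/virial in place; returns (potential, status)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    virial[0] = 0.0
    virial[1] = 0.0
    virial[2] = 0.0
    pe = 0.0

    # bonds
    r0sq = r0 * r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        x = r2 / r0sq
        if x >= 1.0:
            return pe, 1
        pe += -0.5 * kb * r0sq * np.log(1.0 - x)
        fovr = -kb / (1.0 - x)
        fx = fovr * dx
        fy = fovr * dy
        fz = fovr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz

    # nonbonded
    rc = _RC_FACT * d
    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    use_cells = n >= 400 and ncx >= 3 and ncy >= 3 and ncz >= 3

    if not use_cells:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if excl_bonded == 1 and chain_id[i] == chain_id[j] and j - i == 1:
                    continue
                dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                e, fovr, st = _nb_pair(r2, types[i] == types[j], u0eff, d, eps)
                if st != 0:
                    return pe, st
                if e != 0.0 or fovr != 0.0:
                    pe += e
                    fx = fovr * dx
                    fy = fovr * dy
                    fz = fovr * dz
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
                    virial[0] += dx * fx
                    virial[1] += dy * fy
                    virial[2] += dz * fz
        return pe, 0

    # cell list, rebuilt on every call (counting via linked list)
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        wx = pos[i, 0] - box[0] * np.floor(pos[i, 0] / box[0])
        wy = pos[i, 1] - box[1] * np.floor(pos[i, 1] / box[1])
        wz = pos[i, 2] - box[2] * np.floor(pos[i, 2] / box[2])
        ix = min(int(wx / box[0] * ncx), ncx - 1)
        iy = min(int(wy / box[1] * ncy), ncy - 1)
        iz = min(int(wz / box[2] * ncz), ncz - 1)
        cx[i] = ix
        cy[i] = iy
        cz[i] = iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i

    for i in range(n):
        ix = cx[i]
        iy = cy[i]
        iz = cz[i]
        for ox in range(-1, 2):
            jx = (ix + ox) % ncx
            for oy in range(-1, 2):
                jy = (iy + oy) % ncy
                for oz in range(-1, 2):
                    jz = (iz + oz) % ncz
                    j = head[(jx * ncy + jy) * ncz + jz]
                    while j != -1:
                        if j > i:
                            if not (
                                excl_bonded == 1
                                and chain_id[i] == chain_id[j]
                                and j - i == 1
                            ):
                                dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                                dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                                dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                e, fovr, st = _nb_pair(
                                    r2, types[i] == types[j], u0eff, d, eps,
                                )
                                if st != 0:
                                    return pe, st
                                if e != 0.0 or fovr != 0.0:
                                    pe += e
                                    fx = fovr * dx
                                    fy = fovr * dy
                                    fz = fovr * dz
                                    forces[i, 0] += fx
                                    forces[i, 1] += fy
                                    forces[i, 2] += fz
                                    forces[j, 0] -= fx
                                    forces[j, 1] -= fy
                                    forces[j, 2] -= fz
                                    virial[0] += dx * fx
                                    virial[1] += dy * fy
                                    virial[2] += dz * fz
                        j = nxt[j]
    return pe, 0


@njit(cache=True)
def _build_pairs(pos, box, chain_id, excl_bonded, rlist, pairs):
    """Fill ``pairs`` with all i<j within ``rlist`` (minimum image).

    Uses a cell list when the box allows >= 3 cells per axis, else O(N^2).
    Returns the pair count, or -1 on capacity overflow.
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    rl2 = rlist * rlist
    ncx = int(box[0] / rlist)
    ncy = int(box[1] / rlist)
    ncz = int(box[2] / rlist)
    npairs = 0
    if n < 200 or ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if excl_bonded == 1 and chain_id[i] == chain_id[j] and j - i == 1:
                    continue
                dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz < rl2:
                    if npairs >= cap:
                        return -1
                    pairs[npairs, 0] = i
                    pairs[npairs, 1] = j
                    npairs += 1
        return npairs

    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        wx = pos[i, 0] - box[0] * np.floor(pos[i, 0] / box[0])
        wy = pos[i, 1] - box[1] * np.floor(pos[i, 1] / box[1])
        wz = pos[i, 2] - box[2] * np.floor(pos[i, 2] / box[2])
        ix = min(int(wx / box[0] * ncx), ncx - 1)
        iy = min(int(wy / box[1] * ncy), ncy - 1)
        iz = min(int(wz / box[2] * ncz), ncz - 1)
        cx[i] = ix
        cy[i] = iy
        cz[i] = iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        ix = cx[i]
        iy = cy[i]
        iz = cz[i]
        for ox in range(-1, 2):
            jx = (ix + ox) % ncx
            for oy in range(-1, 2):
                jy = (iy + oy) % ncy
                for oz in range(-1, 2):
                    jz = (iz + oz) % ncz
                    j = head[(jx * ncy + jy) * ncz + jz]
                    while j != -1:
                        if j > i:
                            if not (
                                excl_bonded == 1
                                and chain_id[i] == chain_id[j]
                                and j - i == 1
                            ):
                                dx = _mic(pos[i, 0] - pos[j, 0], box[0])
                                dy = _mic(pos[i, 1] - pos[j, 1], box[1])
                                dz = _mic(pos[i, 2] - pos[j, 2], box[2])
                                if dx * dx + dy * dy + dz * dz < rl2:
                                    if npairs >= cap:
                                        return -1
                                    pairs[npairs, 0] = i
                                    pairs[npairs, 1] = j
                                    npairs += 1
                        j = nxt[j]
    return npairs


@njit(cache=True)
def _forces_from_pairs(pos, box, types, bonds, pairs, npairs, forces, virial,
                       kb, r0, u0eff, d, eps):
    """Forces/energy/virial from a prebuilt pair list (plus bonds)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    virial[0] = 0.0
    virial[1] = 0.0
    virial[2] = 0.0
    pe = 0.0
    r0sq = r0 * r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        x = r2 / r0sq
        if x >= 1.0:
            return pe, 1
        pe += -0.5 * kb * r0sq * np.log(1.0 - x)
        fovr = -kb / (1.0 - x)
        fx = fovr * dx
        fy = fovr * dy
        fz = fovr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _mic(pos[i, 0] - pos[j, 0], box[0])
        dy = _mic(pos[i, 1] - pos[j, 1], box[1])
        dz = _mic(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        e, fovr, st = _nb_pair(r2, types[i] == types[j], u0eff, d, eps)
        if st != 0:
            return pe, st
        if e != 0.0 or fovr != 0.0:
            pe += e
            fx = fovr * dx
            fy = fovr * dy
            fz = fovr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0] += dx * fx
            virial[1] += dy * fy
            virial[2] += dz * fz
    return pe, 0


@njit(cache=True)
def baoab_chunk(pos, vel, forces, virial, box, types, bonds, chain_id,
                mass, kT, friction, dt, u0eff, kb, r0, d, eps, excl_bonded,
                thermostat, use_walls, wall_lo, wall_hi,
                noise, step0, sample_every,
                frames, press, pes, sample_count, pair_cap):
    """Advance len(noise) BAOAB steps; sample every ``sample_every`` steps.

    ``forces`` must hold the forces for the entering ``pos``.  Samples are
    appended to ``frames``/``press``/``pes`` starting at ``sample_count``.
    A Verlet pair list (skin 0.3 nm) is rebuilt whenever any bead has moved
    more than 0.4*skin since the last build.  Returns
    (new_sample_count, steps_done, status, potential); status 3 means the
    pair-list capacity overflowed (caller enlarges and resumes).
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    skin = 0.3
    rlist = _RC_FACT * d + skin
    trigger2 = (0.4 * skin) * (0.4 * skin)
    pairs = np.empty((max(64, pair_cap), 2), dtype=np.int64)
    pos0 = pos.copy()
    npairs = _build_pairs(pos, box, chain_id, excl_bonded, rlist, pairs)
    if npairs < 0:
        return sample_count, 0, 3, 0.0
    half_dt = 0.5 * dt
    c1 = np.exp(-friction * dt) if thermostat == 1 else 1.0
    sigma = np.sqrt(kT / mass) * np.sqrt(max(0.0, 1.0 - c1 * c1))
    vol = box[0] * box[1] * box[2]
    pe = 0.0
    for s in range(nsteps):
        # refresh the pair list while the state is step-consistent
        need = False
        for i in range(n):
            ddx = pos[i, 0] - pos0[i, 0]
            ddy = pos[i, 1] - pos0[i, 1]
            ddz = pos[i, 2] - pos0[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > trigger2:
                need = True
                break
        if need:
            npairs = _build_pairs(pos, box, chain_id, excl_bonded, rlist, pairs)
            if npairs < 0:
                return sample_count, s, 3, pe
            for i in range(n):
                pos0[i, 0] = pos[i, 0]
                pos0[i, 1] = pos[i, 1]
                pos0[i, 2] = pos[i, 2]
        for i in range(n):
            vel[i, 0] += half_dt * forces[i, 0] / mass
            vel[i, 1] += half_dt * forces[i, 1] / mass
            vel[i, 2] += half_dt * forces[i, 2] / mass
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        if thermostat == 1:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + sigma * noise[s, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + sigma * noise[s, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + sigma * noise[s, i, 2]
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        if use_walls == 1:
            for i in range(n):
                if pos[i, 0] > wall_hi:
                    pos[i, 0] = 2.0 * wall_hi - pos[i, 0]
                    vel[i, 0] = -vel[i, 0]
                elif pos[i, 0] < wall_lo:
                    pos[i, 0] = 2.0 * wall_lo - pos[i, 0]
                    vel[i, 0] = -vel[i, 0]
        pe, status = _forces_from_pairs(pos, box, types, bonds, pairs, npairs,
                                        forces, virial, kb, r0, u0eff, d, eps)
        if status != 0:
            return sample_count, s, status, pe
        for i in range(n):
            vel[i, 0] += half_dt * forces[i, 0] / mass
            vel[i, 1] += half_dt * forces[i, 1] / mass
            vel[i, 2] += half_dt * forces[i, 2] / mass
        gstep = step0 + s + 1
        if sample_every > 0 and gstep % sample_every == 0:
            k = sample_count
            for i in range(n):
                frames[k, i, 0] = pos[i, 0]
                frames[k, i, 1] = pos[i, 1]
                frames[k, i, 2] = pos[i, 2]
            kx = 0.0
            ky = 0.0
            kz = 0.0
            for i in range(n):
                kx += mass * vel[i, 0] * vel[i, 0]
                ky += mass * vel[i, 1] * vel[i, 1]
                kz += mass * vel[i, 2] * vel[i, 2]
            press[k, 0] = (kx + virial[0]) / vol
            press[k, 1] = (ky + virial[1]) / vol
            press[k, 2] = (kz + virial[2]) / vol
            pes[k] = pe
            sample_count += 1
    return sample_count, nsteps, 0, pe
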