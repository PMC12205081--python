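"""Numba kernels for the coarse-grained Metropolis sampler.

All moves displace a subset of beads rigidly (single-bead displacement,
crankshaft rotation of one residue, pivot rotation of a chain arm, rigid
chain translation), so energy deltas only need the terms that cross the
moved/unmoved boundary; distances inside the moved subset are preserved by
construction and skipped.
"""

import numpy as np
from numba import njit

# move type codes
DISP, CRANK, PIVOT, TRANS = 0, 1, 2, 3


@njit(cache=True, fastmath=True)
def _min_image(d, box):
    return d - box * np.round(d / box)


@njit(cache=True, fastmath=True)
def _dist(ax, ay, az, bx, by, bz, box):
    dx = _min_image(ax - bx, box)
    dy = _min_image(ay - by, box)
    dz = _min_image(az - bz, box)
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, fastmath=True)
def _pair_u(r, sig, eps_ij, rc, krep):
    u = 0.0
    if r < sig:
        d = sig - r
        u += 0.5 * krep * d * d
    if eps_ij > 0.0 and r < rc:
        x = (r / rc) ** 2
        w = 1.0 - x
        u -= eps_ij * w * w
    return u


@njit(cache=True, fastmath=True)
def _smoothstep(x, lo, hi):
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    t = (x - lo) / (hi - lo)
    return t * t * (3.0 - 2.0 * t)


@njit(cache=True, fastmath=True)
def _lock_g(r, r0, w, rc, ext_i, ext_j, ext_lo, ext_hi):
    """Occupancy (0..1) of one registry pseudo-H-bond: a Gaussian well in
    the pair distance, gated by the local backbone extension of both
    partners — β-ladder bonds form only between locally extended strands."""
    if r >= rc:
        return 0.0
    d = r - r0
    g = _smoothstep(ext_i, ext_lo, ext_hi) * _smoothstep(ext_j, ext_lo, ext_hi)
    return g * np.exp(-d * d / (2.0 * w * w))


@njit(cache=True, fastmath=True)
def _angle_u(pix, piy, piz, pjx, pjy, pjz, pkx, pky, pkz, th0, ka, box):
    v1x = _min_image(pix - pjx, box)
    v1y = _min_image(piy - pjy, box)
    v1z = _min_image(piz - pjz, box)
    v2x = _min_image(pkx - pjx, box)
    v2y = _min_image(pky - pjy, box)
    v2z = _min_image(pkz - pjz, box)
    n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
    n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = np.arccos(c)
    d = th - th0
    return 0.5 * ka * d * d


@njit(cache=True, fastmath=True)
def _ext(pos, a, b, box):
    """Backbone extension |b(i-1) - b(i+1)|; 1.0 (fully open gate) when a
    neighbour is missing at a chain end."""
    if a < 0 or b < 0:
        return 1.0
    return _dist(pos[a, 0], pos[a, 1], pos[a, 2],
                 pos[b, 0], pos[b, 1], pos[b, 2], box)


@njit(cache=True, fastmath=True)
def _pickx(b, k, pos, newp, moved_mask):
    if moved_mask[b]:
        return newp[b, k]
    return pos[b, k]


@njit(cache=True, fastmath=True)
def _distm(a, b, pos, newp, moved_mask, box):
    return _dist(_pickx(a, 0, pos, newp, moved_mask),
                 _pickx(a, 1, pos, newp, moved_mask),
                 _pickx(a, 2, pos, newp, moved_mask),
                 _pickx(b, 0, pos, newp, moved_mask),
                 _pickx(b, 1, pos, newp, moved_mask),
                 _pickx(b, 2, pos, newp, moved_mask), box)


@njit(cache=True, fastmath=True)
def _extm(a, b, pos, newp, moved_mask, box):
    if a < 0 or b < 0:
        return 1.0
    return _distm(a, b, pos, newp, moved_mask, box)


@njit(cache=True, fastmath=True)
def lock_energy(pos, newp, moved_mask, box,
                lock_i, lock_j, lock_ip, lock_in, lock_jp, lock_jn,
                lock_nper, lock_eps1, lock_eps2,
                lock_r0, lock_w, lock_rc, lock_elo, lock_ehi):
    """Lock energy over registry blocks (one block per chain):
    ``-eps1 * sum_l g_l - eps2 * sum_l g_l * g_(l+1)`` with ``g_l`` the
    gated well occupancy of registry pair ``l``.  The cooperative second
    term rewards intact runs of the β-ladder and keeps isolated, crowding-
    induced near-contacts from registering as a lock.

    Mixed-coordinate evaluation: beads flagged in ``moved_mask`` are read
    from ``newp``; pass ``newp=pos`` with any mask for a plain evaluation.
    """
    e = 0.0
    n_pairs = lock_i.shape[0]
    if n_pairs == 0:
        return e
    for blk in range(n_pairs // lock_nper):
        gprev = 0.0
        for t in range(lock_nper):
            l = blk * lock_nper + t
            r = _distm(lock_i[l], lock_j[l], pos, newp, moved_mask, box)
            ei = _extm(lock_ip[l], lock_in[l], pos, newp, moved_mask, box)
            ej = _extm(lock_jp[l], lock_jn[l], pos, newp, moved_mask, box)
            g = _lock_g(r, lock_r0, lock_w, lock_rc, ei, ej, lock_elo, lock_ehi)
            e -= lock_eps1 * g
            if t > 0:
                e -= lock_eps2 * g * gprev
            gprev = g
    return e


@njit(cache=True, fastmath=True)
def total_energy(pos, box, sigma, eps, excl,
                 bond_i, bond_j, bond_r0, bond_k,
                 ang_i, ang_j, ang_k, ang_th0, ang_ka,
                 lock_i, lock_j, lock_ip, lock_in, lock_jp, lock_jn,
                 lock_nper, lock_beads, lock_eps1, lock_eps2,
                 lock_r0, lock_w, lock_rc, lock_elo, lock_ehi,
                 rc, krep):
    n = pos.shape[0]
    e = 0.0
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = _min_image(pos[i, 0] - pos[j, 0], box)
            dy = _min_image(pos[i, 1] - pos[j, 1], box)
            dz = _min_image(pos[i, 2] - pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            e += _pair_u(np.sqrt(r2), sigma[i] + sigma[j], eps[i, j], rc, krep)
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        r = _dist(pos[i, 0], pos[i, 1], pos[i, 2],
                  pos[j, 0], pos[j, 1], pos[j, 2], box)
        d = r - bond_r0[b]
        e += 0.5 * bond_k[b] * d * d
    for a in range(ang_i.shape[0]):
        i = ang_i[a]; j = ang_j[a]; k = ang_k[a]
        e += _angle_u(pos[i, 0], pos[i, 1], pos[i, 2],
                      pos[j, 0], pos[j, 1], pos[j, 2],
                      pos[k, 0], pos[k, 1], pos[k, 2],
                      ang_th0[a], ang_ka[a], box)
    if lock_i.shape[0] > 0:
        nomask = np.zeros(pos.shape[0], dtype=np.bool_)
        e += lock_energy(pos, pos, nomask, box,
                         lock_i, lock_j, lock_ip, lock_in, lock_jp, lock_jn,
                         lock_nper, lock_eps1, lock_eps2,
                         lock_r0, lock_w, lock_rc, lock_elo, lock_ehi)
    return e


@njit(cache=True, fastmath=True)
def _delta_energy(pos, newp, moved_idx, n_moved, moved_mask,
                  box, sigma, eps, excl,
                  bond_i, bond_j, bond_r0, bond_k,
                  ang_i, ang_j, ang_k, ang_th0, ang_ka,
                  lock_i, lock_j, lock_ip, lock_in, lock_jp, lock_jn,
                  lock_nper, lock_beads, lock_eps1, lock_eps2,
                  lock_r0, lock_w, lock_rc, lock_elo, lock_ehi,
                  rc, krep):
    n = pos.shape[0]
    de = 0.0
    # nonbonded cross terms; everything is zero beyond rc (sigma_ij < rc),
    # so pairs far away in both old and new positions are skipped pre-sqrt
    rc2 = rc * rc
    for t in range(n_moved):
        a = moved_idx[t]
        sa = sigma[a]
        ox = pos[a, 0]; oy = pos[a, 1]; oz = pos[a, 2]
        nx = newp[a, 0]; ny = newp[a, 1]; nz = newp[a, 2]
        for j in range(n):
            if moved_mask[j] or excl[a, j]:
                continue
            jx = pos[j, 0]; jy = pos[j, 1]; jz = pos[j, 2]
            dx = _min_image(ox - jx, box)
            dy = _min_image(oy - jy, box)
            dz = _min_image(oz - jz, box)
            r2o = dx * dx + dy * dy + dz * dz
            dx = _min_image(nx - jx, box)
            dy = _min_image(ny - jy, box)
            dz = _min_image(nz - jz, box)
            r2n = dx * dx + dy * dy + dz * dz
            if r2o >= rc2 and r2n >= rc2:
                continue
            sig = sa + sigma[j]
            e_ij = eps[a, j]
            de += _pair_u(np.sqrt(r2n), sig, e_ij, rc, krep) \
                - _pair_u(np.sqrt(r2o), sig, e_ij, rc, krep)
    # bonds crossing the boundary
    for b in range(bond_i.shape[0]):
        i = bond_i[b]; j = bond_j[b]
        mi = moved_mask[i]; mj = moved_mask[j]
        if mi == mj:
            continue
        r_old = _dist(pos[i, 0], pos[i, 1], pos[i, 2],
                      pos[j, 0], pos[j, 1], pos[j, 2], box)
        pix = newp[i, 0] if mi else pos[i, 0]
        piy = newp[i, 1] if mi else pos[i, 1]
        piz = newp[i, 2] if mi else pos[i, 2]
        pjx = newp[j, 0] if mj else pos[j, 0]
        pjy = newp[j, 1] if mj else pos[j, 1]
        pjz = newp[j, 2] if mj else pos[j, 2]
        r_new = _dist(pix, piy, piz, pjx, pjy, pjz, box)
        d_old = r_old - bond_r0[b]
        d_new = r_new - bond_r0[b]
        de += 0.5 * bond_k[b] * (d_new * d_new - d_old * d_old)
    # angles with a mixed moved/unmoved triple
    for a in range(ang_i.shape[0]):
        i = ang_i[a]; j = ang_j[a]; k = ang_k[a]
        nm = 0
        if moved_mask[i]:
            nm += 1
        if moved_mask[j]:
            nm += 1
        if moved_mask[k]:
            nm += 1
        if nm == 0 or nm == 3:
            continue
        e_old = _angle_u(pos[i, 0], pos[i, 1], pos[i, 2],
                         pos[j, 0], pos[j, 1], pos[j, 2],
                         pos[k, 0], pos[k, 1], pos[k, 2],
                         ang_th0[a], ang_ka[a], box)
        pix = newp[i, 0] if moved_mask[i] else pos[i, 0]
        piy = newp[i, 1] if moved_mask[i] else pos[i, 1]
        piz = newp[i, 2] if moved_mask[i] else pos[i, 2]
        pjx = newp[j, 0] if moved_mask[j] else pos[j, 0]
        pjy = newp[j, 1] if moved_mask[j] else pos[j, 1]
        pjz = newp[j, 2] if moved_mask[j] else pos[j, 2]
        pkx = newp[k, 0] if moved_mask[k] else pos[k, 0]
        pky = newp[k, 1] if moved_mask[k] else pos[k, 1]
        pkz = newp[k, 2] if moved_mask[k] else pos[k, 2]
        e_new = _angle_u(pix, piy, piz, pjx, pjy, pjz, pkx, pky, pkz,
                         ang_th0[a], ang_ka[a], box)
        de += e_new - e_old
    # the lock block couples registry pairs; recompute the whole block
    # energy when its involved beads straddle the moved/unmoved boundary
    if lock_beads.shape[0] > 0:
        nm = 0
        for t in range(lock_beads.shape[0]):
            if moved_mask[lock_beads[t]]:
                nm += 1
        if 0 < nm < lock_beads.shape[0]:
            de += lock_energy(pos, newp, moved_mask, box,
                              lock_i, lock_j, lock_ip, lock_in,
                              lock_jp, lock_jn, lock_nper,
                              lock_eps1, lock_eps2,
                              lock_r0, lock_w, lock_rc, lock_elo, lock_ehi) \
                - lock_energy(pos, pos, moved_mask, box,
                              lock_i, lock_j, lock_ip, lock_in,
                              lock_jp, lock_jn, lock_nper,
                              lock_eps1, lock_eps2,
                              lock_r0, lock_w, lock_rc, lock_elo, lock_ehi)
    return de


@njit(cache=True, fastmath=True)
def _gauss(rng):
    # Marsaglia polar method; keeps us on Generator.random() only
    while True:
        u = 2.0 * rng.random() - 1.0
        v = 2.0 * rng.random() - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            return u * np.sqrt(-2.0 * np.log(s) / s)


@njit(cache=True, fastmath=True)
def _random_unit(rng, out):
    n = 0.0
    while n < 1e-12:
        out[0] = _gauss(rng)
        out[1] = _gauss(rng)
        out[2] = _gauss(rng)
        n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    out[0] /= n
    out[1] /= n
    out[2] /= n


@njit(cache=True, fastmath=True)
def _rotate(px, py, pz, ox, oy, oz, ux, uy, uz, cphi, sphi):
    vx = px - ox
    vy = py - oy
    vz = pz - oz
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    rx = vx * cphi + cx * sphi + ux * dot * (1.0 - cphi)
    ry = vy * cphi + cy * sphi + uy * dot * (1.0 - cphi)
    rz = vz * cphi + cz * sphi + uz * dot * (1.0 - cphi)
    return ox + rx, oy + ry, oz + rz


@njit(cache=True, fastmath=True)
def run_sweeps(pos, n_sweeps, beta, box, sigma, eps, excl,
               bond_i, bond_j, bond_r0, bond_k,
               ang_i, ang_j, ang_k, ang_th0, ang_ka,
               lock_i, lock_j, lock_ip, lock_in, lock_jp, lock_jn,
               lock_nper, lock_beads, lock_eps1, lock_eps2,
               lock_r0, lock_w, lock_rc, lock_elo, lock_ehi,
               rc, krep,
               res_bb, res_sc, chain_of_res, nres_per_chain,
               w_cum, max_disp, max_pivot, max_trans, lattice_step,
               rng, e0, att, acc):
    """Run ``n_sweeps`` Metropolis sweeps in place.

    One sweep attempts ``n_beads`` moves.  ``w_cum`` holds cumulative
    probabilities for (displacement, crankshaft, pivot, translation);
    ``att``/``acc`` are 4-long attempt/accept counters updated in place.
    Returns the running potential energy.
    """
    n = pos.shape[0]
    n_res = res_bb.shape[0]
    newp = np.empty_like(pos)
    moved_idx = np.empty(n, dtype=np.int64)
    moved_mask = np.zeros(n, dtype=np.bool_)
    axis = np.empty(3)
    e = e0
    n_chains = chain_of_res[n_res - 1] + 1

    for _ in range(n_sweeps):
        for _m in range(n):
            u = rng.random()
            if u < w_cum[0]:
                mtype = DISP
            elif u < w_cum[1]:
                mtype = CRANK
            elif u < w_cum[2]:
                mtype = PIVOT
            else:
                mtype = TRANS

            n_moved = 0
            if mtype == DISP:
                k = int(rng.random() * n)
                if lattice_step > 0.0:
                    ax = int(rng.random() * 3)
                    sg = 1.0 if rng.random() < 0.5 else -1.0
                    newp[k, 0] = pos[k, 0]
                    newp[k, 1] = pos[k, 1]
                    newp[k, 2] = pos[k, 2]
                    newp[k, ax] = pos[k, ax] + sg * lattice_step
                else:
                    newp[k, 0] = pos[k, 0] + (2.0 * rng.random() - 1.0) * max_disp
                    newp[k, 1] = pos[k, 1] + (2.0 * rng.random() - 1.0) * max_disp
                    newp[k, 2] = pos[k, 2] + (2.0 * rng.random() - 1.0) * max_disp
                moved_idx[0] = k
                n_moved = 1
            elif mtype == CRANK:
                # interior residue of its chain
                while True:
                    g = int(rng.random() * n_res)
                    p = g - chain_of_res[g] * nres_per_chain
                    if 1 <= p <= nres_per_chain - 2:
                        break
                bb = res_bb[g]
                prev_bb = res_bb[g - 1]
                next_bb = res_bb[g + 1]
                axx = _min_image(pos[next_bb, 0] - pos[prev_bb, 0], box)
                axy = _min_image(pos[next_bb, 1] - pos[prev_bb, 1], box)
                axz = _min_image(pos[next_bb, 2] - pos[prev_bb, 2], box)
                nn = np.sqrt(axx * axx + axy * axy + axz * axz)
                if nn < 1e-9:
                    continue
                axx /= nn; axy /= nn; axz /= nn
                phi = (2.0 * rng.random() - 1.0) * np.pi
                cphi = np.cos(phi); sphi = np.sin(phi)
                ox = pos[prev_bb, 0]; oy = pos[prev_bb, 1]; oz = pos[prev_bb, 2]
                sc = res_sc[g]
                for b in (bb, sc):
                    if b == bb and n_moved > 0:
                        continue  # single-bead residues: sc aliases bb
                    x, y, z = _rotate(pos[b, 0], pos[b, 1], pos[b, 2],
                                      ox, oy, oz, axx, axy, axz, cphi, sphi)
                    newp[b, 0] = x; newp[b, 1] = y; newp[b, 2] = z
                    moved_idx[n_moved] = b
                    n_moved += 1
            elif mtype == PIVOT:
                while True:
                    g = int(rng.random() * n_res)
                    p = g - chain_of_res[g] * nres_per_chain
                    if 1 <= p <= nres_per_chain - 2:
                        break
                c = chain_of_res[g]
                _random_unit(rng, axis)
                phi = (2.0 * rng.random() - 1.0) * max_pivot
                cphi = np.cos(phi); sphi = np.sin(phi)
                bb = res_bb[g]
                ox = pos[bb, 0]; oy = pos[bb, 1]; oz = pos[bb, 2]
                # rotate the shorter arm (deterministic given the pivot
                # residue, so the proposal stays symmetric)
                if p <= nres_per_chain - 2 - p:
                    lo = c * nres_per_chain
                    hi = g  # head: residues lo..g-1
                else:
                    lo = g + 1
                    hi = (c + 1) * nres_per_chain
                for gg in range(lo, hi):
                    for b in (res_bb[gg], res_sc[gg]):
                        if b == res_bb[gg] and res_sc[gg] == res_bb[gg] \
                                and n_moved > 0 and moved_idx[n_moved - 1] == b:
                            continue
                        x, y, z = _rotate(pos[b, 0], pos[b, 1], pos[b, 2],
                                          ox, oy, oz,
                                          axis[0], axis[1], axis[2],
                                          cphi, sphi)
                        newp[b, 0] = x; newp[b, 1] = y; newp[b, 2] = z
                        moved_idx[n_moved] = b
                        n_moved += 1
                if n_moved == 0:
                    continue
            else:  # TRANS
                c = int(rng.random() * n_chains)
                dx = (2.0 * rng.random() - 1.0) * max_trans
                dy = (2.0 * rng.random() - 1.0) * max_trans
                dz = (2.0 * rng.random() - 1.0) * max_trans
                for gg in range(c * nres_per_chain, (c + 1) * nres_per_chain):
                    for b in (res_bb[gg], res_sc[gg]):
                        if b == res_bb[gg] and res_sc[gg] == res_bb[gg] \
                                and n_moved > 0 and moved_idx[n_moved - 1] == b:
                            continue
                        newp[b, 0] = pos[b, 0] + dx
                        newp[b, 1] = pos[b, 1] + dy
                        newp[b, 2] = pos[b, 2] + dz
                        moved_idx[n_moved] = b
                        n_moved += 1

            for t in range(n_moved):
                moved_mask[moved_idx[t]] = True

            de = _delta_energy(pos, newp, moved_idx, n_moved, moved_mask,
                               box, sigma, eps, excl,
                               bond_i, bond_j, bond_r0, bond_k,
                               ang_i, ang_j, ang_k, ang_th0, ang_ka,
                               lock_i, lock_j, lock_ip, lock_in,
                               lock_jp, lock_jn, lock_nper, lock_beads,
                               lock_eps1, lock_eps2,
                               lock_r0, lock_w, lock_rc, lock_elo, lock_ehi,
                               rc, krep)

            att[mtype] += 1
            accept = False
            if np.isfinite(de):
                if de <= 0.0:
                    accept = True
                elif rng.random() < np.exp(-beta * de):
                    accept = True
            if accept:
                for t in range(n_moved):
                    b = moved_idx[t]
                    pos[b, 0] = newp[b, 0]
                    pos[b, 1] = newp[b, 1]
                    pos[b, 2] = newp[b, 2]
                e += de
                acc[mtype] += 1

            for t in range(n_moved):
                moved_mask[moved_idx[t]] = False

    return e
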