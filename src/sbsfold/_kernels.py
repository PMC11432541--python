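"""Numba kernels for the Langevin bead-spring dynamics.

Conventions baked into the kernels (reduced units, sigma = m = k_B T = 1):

* FENE bonds between consecutive beads, U = -0.5 K R0^2 ln(1 - (r/R0)^2).
* Non-cognate pairs (bead-bead, binder-binder, non-cognate bead-binder)
  interact through a WCA potential: LJ truncated at 2^(1/6) sigma and
  shifted so U(cutoff) = 0.
* Cognate bead-binder pairs interact through a full Lennard-Jones potential
  of depth E_bb (the binder type's affinity), truncated at 1.5 sigma and
  shifted to zero at the cutoff; this channel replaces the WCA term for
  those pairs, as in standard LAMMPS-style SBS implementations.
* Minimum-image convention under cubic periodic boundaries.  The integrator
  carries two coordinate sets: unwrapped positions (analysis, FENE bonds —
  the chain stays spatially contiguous) and wrapped positions (neighbour
  search and non-bonded forces, where minimum image reduces to a single
  +-L branch).
* Langevin thermostat in the Duenweg-Paul form: friction -zeta*m*v plus
  uniform noise of per-component variance 2*zeta*m*kT/dt applied between
  the velocity-Verlet half-kicks.  Uniform noise with the exact matching
  variance yields the same stationary temperature as Gaussian noise (the
  velocity distribution is Gaussian by accumulation over many kicks) at a
  fraction of the cost; the uniform stream is an inline xorshift128+.

The neighbour search is a pair of Verlet lists (repulsive pairs within
r_rep + skin, cognate attractive pairs within r_att + skin) rebuilt from a
counting-sort cell grid whenever any particle has moved more than skin/2
since the last build.  Contract (tested): forces identical to a direct
all-pairs evaluation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_chunk
OK = 0
ERR_OVERFLOW = 1  # neighbour-list capacity exceeded; caller enlarges and retries
ERR_BOND = 2  # a FENE bond reached R0 (diverging force)
ERR_NAN = 3  # non-finite coordinate encountered


@njit(cache=True, inline="always")
def _xorshift128p(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _uniform01(state):
    return (_xorshift128p(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _seed_state(seed):
    # splitmix64 expansion of a small integer seed into the xorshift state
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for k in range(2):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = z
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
            0xFFFFFFFFFFFFFFFF
        )
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
            0xFFFFFFFFFFFFFFFF
        )
        state[k] = x ^ (x >> np.uint64(31))
    return state


@njit(cache=True, fastmath=True)
def _build_lists(
    wpos,
    L,
    n_beads,
    masks,
    is_binder,
    eps,
    r_rep_list,
    r_att_list,
    rep_i,
    rep_j,
    att_i,
    att_j,
    att_eps,
    counts,
):
    """Fill the repulsive and attractive Verlet lists from wrapped coords.

    counts[0] <- number of non-cognate pairs within r_rep_list,
    counts[1] <- number of cognate pairs within r_att_list.
    Returns OK or ERR_OVERFLOW.

    Particles are gathered into cell-sorted scratch arrays for cache
    locality; the cognate test uses a packed key (type mask shifted left,
    binder flag in bit 0): a pair is cognate iff the binder flags differ
    and the shifted masks intersect.
    """
    n = wpos.shape[0]
    rep_cap = rep_i.shape[0]
    att_cap = att_i.shape[0]
    r2rep = r_rep_list * r_rep_list
    r2att = r_att_list * r_att_list
    half = 0.5 * L
    nc = int(L / r_att_list)
    n_rep = 0
    n_att = 0
    key = np.empty(n, dtype=np.int64)
    for p in range(n):
        key[p] = (masks[p] << 1) | (np.int64(1) if is_binder[p] else np.int64(0))
    if nc < 3:
        for p in range(n):
            for q in range(p + 1, n):
                dx = wpos[p, 0] - wpos[q, 0]
                dy = wpos[p, 1] - wpos[q, 1]
                dz = wpos[p, 2] - wpos[q, 2]
                if dx > half:
                    dx -= L
                elif dx < -half:
                    dx += L
                if dy > half:
                    dy -= L
                elif dy < -half:
                    dy += L
                if dz > half:
                    dz -= L
                elif dz < -half:
                    dz += L
                r2 = dx * dx + dy * dy + dz * dz
                kp = key[p]
                kq = key[q]
                cog = ((kp ^ kq) & 1) != 0 and ((kp & kq) >> 1) != 0
                if cog:
                    if r2 < r2att:
                        if n_att >= att_cap:
                            return ERR_OVERFLOW
                        att_i[n_att] = p
                        att_j[n_att] = q
                        att_eps[n_att] = eps[p] + eps[q]
                        n_att += 1
                else:
                    if r2 < r2rep:
                        if n_rep >= rep_cap:
                            return ERR_OVERFLOW
                        rep_i[n_rep] = p
                        rep_j[n_rep] = q
                        n_rep += 1
        counts[0] = n_rep
        counts[1] = n_att
        return OK

    cw = L / nc
    ncell = nc * nc * nc
    cell_of = np.empty(n, dtype=np.int32)
    cnt = np.zeros(ncell + 1, dtype=np.int32)
    for p in range(n):
        x = wpos[p, 0]
        y = wpos[p, 1]
        z = wpos[p, 2]
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            return ERR_NAN
        if x < 0.0 or x >= L or y < 0.0 or y >= L or z < 0.0 or z >= L:
            return ERR_NAN  # coordinates escaped the box: integration diverged
        ix = int(x / cw)
        iy = int(y / cw)
        iz = int(z / cw)
        if ix >= nc:
            ix = nc - 1
        if iy >= nc:
            iy = nc - 1
        if iz >= nc:
            iz = nc - 1
        c = (ix * nc + iy) * nc + iz
        cell_of[p] = c
        cnt[c + 1] += 1
    for c in range(ncell):
        cnt[c + 1] += cnt[c]
    # gather particles into cell order (positions, keys, affinities, ids)
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    skey = np.empty(n, dtype=np.int64)
    seps = np.empty(n)
    sid = np.empty(n, dtype=np.int32)
    fill = cnt[:-1].copy()
    for p in range(n):
        c = cell_of[p]
        slot = fill[c]
        sx[slot] = wpos[p, 0]
        sy[slot] = wpos[p, 1]
        sz[slot] = wpos[p, 2]
        skey[slot] = key[p]
        seps[slot] = eps[p]
        sid[slot] = p
        fill[c] = slot + 1

    # half stencil: self cell (v > u) plus 13 distinct neighbour offsets,
    # neighbour cell ids precomputed once per build
    nbr = np.empty((ncell, 13), dtype=np.int32)
    for cx in range(nc):
        xm = cx - 1 if cx > 0 else nc - 1
        xp = cx + 1 if cx < nc - 1 else 0
        for cy in range(nc):
            ym = cy - 1 if cy > 0 else nc - 1
            yp = cy + 1 if cy < nc - 1 else 0
            for cz in range(nc):
                zm = cz - 1 if cz > 0 else nc - 1
                zp = cz + 1 if cz < nc - 1 else 0
                c = (cx * nc + cy) * nc + cz
                nbr[c, 0] = (cx * nc + cy) * nc + zp
                nbr[c, 1] = (cx * nc + yp) * nc + zm
                nbr[c, 2] = (cx * nc + yp) * nc + cz
                nbr[c, 3] = (cx * nc + yp) * nc + zp
                nbr[c, 4] = (xp * nc + ym) * nc + zm
                nbr[c, 5] = (xp * nc + ym) * nc + cz
                nbr[c, 6] = (xp * nc + ym) * nc + zp
                nbr[c, 7] = (xp * nc + cy) * nc + zm
                nbr[c, 8] = (xp * nc + cy) * nc + cz
                nbr[c, 9] = (xp * nc + cy) * nc + zp
                nbr[c, 10] = (xp * nc + yp) * nc + zm
                nbr[c, 11] = (xp * nc + yp) * nc + cz
                nbr[c, 12] = (xp * nc + yp) * nc + zp

    for c in range(ncell):
        a0 = cnt[c]
        a1 = cnt[c + 1]
        for u in range(a0, a1):
            px = sx[u]
            py = sy[u]
            pz = sz[u]
            ku = skey[u]
            # within-cell pairs
            for v in range(u + 1, a1):
                dx = px - sx[v]
                dy = py - sy[v]
                dz = pz - sz[v]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= r2att:
                    continue
                kv = skey[v]
                if ((ku ^ kv) & 1) != 0 and ((ku & kv) >> 1) != 0:
                    if n_att >= att_cap:
                        return ERR_OVERFLOW
                    att_i[n_att] = sid[u]
                    att_j[n_att] = sid[v]
                    att_eps[n_att] = seps[u] + seps[v]
                    n_att += 1
                elif r2 < r2rep:
                    if n_rep >= rep_cap:
                        return ERR_OVERFLOW
                    rep_i[n_rep] = sid[u]
                    rep_j[n_rep] = sid[v]
                    n_rep += 1
            # cross-cell pairs
            for o in range(13):
                b = nbr[c, o]
                for v in range(cnt[b], cnt[b + 1]):
                    dx = px - sx[v]
                    dy = py - sy[v]
                    dz = pz - sz[v]
                    if dx > half:
                        dx -= L
                    elif dx < -half:
                        dx += L
                    if dy > half:
                        dy -= L
                    elif dy < -half:
                        dy += L
                    if dz > half:
                        dz -= L
                    elif dz < -half:
                        dz += L
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= r2att:
                        continue
                    kv = skey[v]
                    if ((ku ^ kv) & 1) != 0 and ((ku & kv) >> 1) != 0:
                        if n_att >= att_cap:
                            return ERR_OVERFLOW
                        att_i[n_att] = sid[u]
                        att_j[n_att] = sid[v]
                        att_eps[n_att] = seps[u] + seps[v]
                        n_att += 1
                    elif r2 < r2rep:
                        if n_rep >= rep_cap:
                            return ERR_OVERFLOW
                        rep_i[n_rep] = sid[u]
                        rep_j[n_rep] = sid[v]
                        n_rep += 1
    counts[0] = n_rep
    counts[1] = n_att
    return OK


@njit(cache=True, fastmath=True)
def _pair_forces(
    wpos, forces, rep_i, rep_j, n_rep, att_i, att_j, att_eps, n_att, L, rc_rep, rc_att
):
    """Accumulate WCA + cognate-LJ forces from the Verlet lists."""
    half = 0.5 * L
    rc_rep2 = rc_rep * rc_rep
    rc_att2 = rc_att * rc_att
    for k in range(n_rep):
        i = rep_i[k]
        j = rep_j[k]
        dx = wpos[i, 0] - wpos[j, 0]
        dy = wpos[i, 1] - wpos[j, 1]
        dz = wpos[i, 2] - wpos[j, 2]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_rep2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            fmag = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    for k in range(n_att):
        i = att_i[k]
        j = att_j[k]
        dx = wpos[i, 0] - wpos[j, 0]
        dy = wpos[i, 1] - wpos[j, 1]
        dz = wpos[i, 2] - wpos[j, 2]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_att2:
            e = att_eps[k]
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            fmag = 24.0 * e * (2.0 * inv6 * inv6 - inv6) * inv2
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz


@njit(cache=True, fastmath=True)
def _fene_forces(pos, forces, n_beads, fene_k, fene_r0):
    """FENE bond forces on unwrapped bead coordinates.  Returns OK/ERR_BOND."""
    r02 = fene_r0 * fene_r0
    for i in range(n_beads - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return ERR_BOND
        fmag = -fene_k / (1.0 - r2 / r02)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[i + 1, 0] -= fmag * dx
        forces[i + 1, 1] -= fmag * dy
        forces[i + 1, 2] -= fmag * dz
    return OK


@njit(cache=True, fastmath=True)
def run_chunk(
    pos,
    wpos,
    vel,
    n_steps,
    L,
    dt,
    zeta,
    temp,
    mass,
    n_beads,
    masks,
    is_binder,
    eps,
    fene_k,
    fene_r0,
    rc_rep,
    rc_att,
    skin,
    seed,
    rep_cap,
    att_cap,
):
    """Advance the system n_steps; mutates pos, wpos, vel in place.

    Velocity-Verlet with the Langevin force (friction + uniform noise of
    variance 2 zeta m kT / dt per component) entering each force evaluation.
    Returns a status code.
    """
    n = pos.shape[0]
    state = _seed_state(seed)
    rep_i = np.empty(rep_cap, dtype=np.int32)
    rep_j = np.empty(rep_cap, dtype=np.int32)
    att_i = np.empty(att_cap, dtype=np.int32)
    att_j = np.empty(att_cap, dtype=np.int32)
    att_eps = np.empty(att_cap, dtype=np.float64)
    counts = np.zeros(2, dtype=np.int64)
    status = _build_lists(
        wpos, L, n_beads, masks, is_binder, eps, rc_rep + skin, rc_att + skin,
        rep_i, rep_j, att_i, att_j, att_eps, counts,
    )
    if status != OK:
        return status
    ref = wpos.copy()
    forces = np.zeros((n, 3), dtype=np.float64)
    _pair_forces(
        wpos, forces, rep_i, rep_j, counts[0], att_i, att_j, att_eps, counts[1],
        L, rc_rep, rc_att,
    )
    status = _fene_forces(pos, forces, n_beads, fene_k, fene_r0)
    if status != OK:
        return status
    # uniform noise with variance 2 zeta m kT / dt: amplitude sqrt(24 ...)
    amp = np.sqrt(24.0 * zeta * mass * temp / dt)
    for p in range(n):
        for d in range(3):
            forces[p, d] += -zeta * mass * vel[p, d] + amp * (_uniform01(state) - 0.5)
    half_kick = 0.5 * dt / mass
    trigger2 = (0.5 * skin) * (0.5 * skin)
    for _ in range(n_steps):
        maxd2 = 0.0
        for p in range(n):
            vx = vel[p, 0] + half_kick * forces[p, 0]
            vy = vel[p, 1] + half_kick * forces[p, 1]
            vz = vel[p, 2] + half_kick * forces[p, 2]
            vel[p, 0] = vx
            vel[p, 1] = vy
            vel[p, 2] = vz
            pos[p, 0] += dt * vx
            pos[p, 1] += dt * vy
            pos[p, 2] += dt * vz
            x = wpos[p, 0] + dt * vx
            y = wpos[p, 1] + dt * vy
            z = wpos[p, 2] + dt * vz
            if x >= L:
                x -= L
            elif x < 0.0:
                x += L
            if y >= L:
                y -= L
            elif y < 0.0:
                y += L
            if z >= L:
                z -= L
            elif z < 0.0:
                z += L
            wpos[p, 0] = x
            wpos[p, 1] = y
            wpos[p, 2] = z
            dx = x - ref[p, 0]
            dy = y - ref[p, 1]
            dz = z - ref[p, 2]
            # displacement since last build, minimum image (wrapped coords)
            if dx > 0.5 * L:
                dx -= L
            elif dx < -0.5 * L:
                dx += L
            if dy > 0.5 * L:
                dy -= L
            elif dy < -0.5 * L:
                dy += L
            if dz > 0.5 * L:
                dz -= L
            elif dz < -0.5 * L:
                dz += L
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > 4.0:
            return ERR_NAN  # a particle moved sigma-scale in one step: diverged
        if maxd2 > trigger2:
            status = _build_lists(
                wpos, L, n_beads, masks, is_binder, eps, rc_rep + skin,
                rc_att + skin, rep_i, rep_j, att_i, att_j, att_eps, counts,
            )
            if status != OK:
                return status
            for p in range(n):
                ref[p, 0] = wpos[p, 0]
                ref[p, 1] = wpos[p, 1]
                ref[p, 2] = wpos[p, 2]
        for p in range(n):
            forces[p, 0] = 0.0
            forces[p, 1] = 0.0
            forces[p, 2] = 0.0
        _pair_forces(
            wpos, forces, rep_i, rep_j, counts[0], att_i, att_j, att_eps,
            counts[1], L, rc_rep, rc_att,
        )
        status = _fene_forces(pos, forces, n_beads, fene_k, fene_r0)
        if status != OK:
            return status
        for p in range(n):
            for d in range(3):
                f = forces[p, d] - zeta * mass * vel[p, d] + amp * (
                    _uniform01(state) - 0.5
                )
                forces[p, d] = f
                vel[p, d] += half_kick * f
    if not np.isfinite(pos).all():
        return ERR_NAN
    return OK


# ---------------------------------------------------------------------------
# direct all-pairs evaluation (validation route for the list-based kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def energy_forces_allpairs(
    pos, L, n_beads, masks, is_binder, eps, fene_k, fene_r0, rc_rep, rc_att
):
    """Direct O(n^2) energies and forces under minimum image (np.round based).

    Returns (forces, e_fene, e_rep, e_att, status).  Positions may be
    wrapped or unwrapped; bonded beads must be unwrapped-contiguous.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3), dtype=np.float64)
    rc_rep2 = rc_rep * rc_rep
    rc_att2 = rc_att * rc_att
    inv6c = 1.0 / rc_att**6
    ljshift = 4.0 * (inv6c * inv6c - inv6c)
    e_rep = 0.0
    e_att = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 <= 1e-12:
                return forces, 0.0, 0.0, 0.0, ERR_NAN
            cognate = (is_binder[i] != is_binder[j]) and ((masks[i] & masks[j]) != 0)
            if cognate:
                if r2 < rc_att2:
                    e = eps[i] + eps[j]
                    inv2 = 1.0 / r2
                    inv6 = inv2 * inv2 * inv2
                    e_att += 4.0 * e * (inv6 * inv6 - inv6) - e * ljshift
                    fmag = 24.0 * e * (2.0 * inv6 * inv6 - inv6) * inv2
                    forces[i, 0] += fmag * dx
                    forces[i, 1] += fmag * dy
                    forces[i, 2] += fmag * dz
                    forces[j, 0] -= fmag * dx
                    forces[j, 1] -= fmag * dy
                    forces[j, 2] -= fmag * dz
            else:
                if r2 < rc_rep2:
                    inv2 = 1.0 / r2
                    inv6 = inv2 * inv2 * inv2
                    e_rep += 4.0 * (inv6 * inv6 - inv6) + 1.0
                    fmag = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
                    forces[i, 0] += fmag * dx
                    forces[i, 1] += fmag * dy
                    forces[i, 2] += fmag * dz
                    forces[j, 0] -= fmag * dx
                    forces[j, 1] -= fmag * dy
                    forces[j, 2] -= fmag * dz
    e_fene = 0.0
    r02 = fene_r0 * fene_r0
    for i in range(n_beads - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return forces, 0.0, 0.0, 0.0, ERR_BOND
        frac = 1.0 - r2 / r02
        e_fene += -0.5 * fene_k * r02 * np.log(frac)
        fmag = -fene_k / frac
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[i + 1, 0] -= fmag * dx
        forces[i + 1, 1] -= fmag * dy
        forces[i + 1, 2] -= fmag * dz
    return forces, e_fene, e_rep, e_att, status_ok()


@njit(cache=True, inline="always")
def status_ok():
    return OK


@njit(cache=True)
def list_forces(
    pos, wpos, L, n_beads, masks, is_binder, eps, fene_k, fene_r0, rc_rep, rc_att, skin
):
    """One-shot force evaluation through the Verlet-list path (for tests)."""
    n = pos.shape[0]
    rep_cap = max(200 * n, 10_000)
    att_cap = max(100 * n, 10_000)
    rep_i = np.empty(rep_cap, dtype=np.int32)
    rep_j = np.empty(rep_cap, dtype=np.int32)
    att_i = np.empty(att_cap, dtype=np.int32)
    att_j = np.empty(att_cap, dtype=np.int32)
    att_eps = np.empty(att_cap, dtype=np.float64)
    counts = np.zeros(2, dtype=np.int64)
    status = _build_lists(
        wpos, L, n_beads, masks, is_binder, eps, rc_rep + skin, rc_att + skin,
        rep_i, rep_j, att_i, att_j, att_eps, counts,
    )
    forces = np.zeros((n, 3), dtype=np.float64)
    if status != OK:
        return forces, status
    _pair_forces(
        wpos, forces, rep_i, rep_j, counts[0], att_i, att_j, att_eps, counts[1],
        L, rc_rep, rc_att,
    )
    status = _fene_forces(pos, forces, n_beads, fene_k, fene_r0)
    return forces, status
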