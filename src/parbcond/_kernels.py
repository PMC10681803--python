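"""Numba kernels for the Langevin bead-spring engine.

All kernels work in reduced simulation units (sigma = eps = k_BT = m = 1 by
default).  The integrator is velocity-Verlet with a Langevin thermostat applied
as friction + random forces (uniform random kicks with variance matched to
2*gamma*m*kBT/dt, the standard trick for speed; velocities become Gaussian by
accumulation over the ~1/gamma damping time).

The pair (Verlet) list covers only the purely repulsive LJ interactions; bridge
(Morse) pairs are passed in explicitly as index arrays and iterated directly.
Bonded 1-2 pairs are excluded from the pair list because the FENE bond term
already includes the LJ contribution of that pair; 1-3 pairs interact normally.
"""

import numpy as np
from numba import njit

__all__ = ["run_block", "compute_forces"]


@njit(cache=True, fastmath=True)
def _build_pair_list(pos, r_list):
    """Cell-binned neighbour pair list, excluding bonded (|i-j| == 1) pairs.

    Returns (pair_i, pair_j, n_pairs).  No periodic boundaries.
    """
    n = pos.shape[0]
    # bounding box
    mins = np.empty(3)
    maxs = np.empty(3)
    for d in range(3):
        mins[d] = pos[0, d]
        maxs[d] = pos[0, d]
    for i in range(1, n):
        for d in range(3):
            if pos[i, d] < mins[d]:
                mins[d] = pos[i, d]
            if pos[i, d] > maxs[d]:
                maxs[d] = pos[i, d]
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        nc[d] = max(1, int((maxs[d] - mins[d]) / r_list) + 1)
    ncells = nc[0] * nc[1] * nc[2]
    # counting sort of beads into cells
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - mins[0]) / r_list)
        cy = int((pos[i, 1] - mins[1]) / r_list)
        cz = int((pos[i, 2] - mins[2]) / r_list)
        if cx >= nc[0]:
            cx = nc[0] - 1
        if cy >= nc[1]:
            cy = nc[1] - 1
        if cz >= nc[2]:
            cz = nc[2] - 1
        c = (cx * nc[1] + cy) * nc[2] + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    start = count  # cumulative offsets, length ncells+1
    content = np.empty(n, dtype=np.int64)
    fill = np.zeros(ncells, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        content[start[c] + fill[c]] = i
        fill[c] += 1

    cap = 64 * n + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    npairs = 0
    rl2 = r_list * r_list
    for i in range(n):
        cx = int((pos[i, 0] - mins[0]) / r_list)
        cy = int((pos[i, 1] - mins[1]) / r_list)
        cz = int((pos[i, 2] - mins[2]) / r_list)
        if cx >= nc[0]:
            cx = nc[0] - 1
        if cy >= nc[1]:
            cy = nc[1] - 1
        if cz >= nc[2]:
            cz = nc[2] - 1
        for ox in range(-1, 2):
            x = cx + ox
            if x < 0 or x >= nc[0]:
                continue
            for oy in range(-1, 2):
                y = cy + oy
                if y < 0 or y >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    z = cz + oz
                    if z < 0 or z >= nc[2]:
                        continue
                    c = (x * nc[1] + y) * nc[2] + z
                    for k in range(start[c], start[c + 1]):
                        j = content[k]
                        if j <= i:
                            continue
                        if j - i == 1:
                            continue  # bonded pair: LJ folded into FENE term
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < rl2:
                            if npairs < cap:
                                pi[npairs] = i
                                pj[npairs] = j
                                npairs += 1
    return pi, pj, npairs


@njit(cache=True, fastmath=True)
def _eval_forces(pos, f, pi, pj, npairs, sigma, eps, k_fene, R0, k_theta,
                 d0, alpha_m, rc_bridge, br_i, br_j):
    """Conservative forces; returns 0 on success, 1 if a FENE bond overstretched."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    sig2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * sig2  # (2^(1/6) sigma)^2
    R02 = R0 * R0
    # FENE + LJ bonds
    for i in range(n - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return 1
        fmag = -k_fene / (1.0 - r2 / R02)  # dU/dr / r  (FENE, attractive)
        if r2 < rc2:
            s2 = sig2 / r2
            s6 = s2 * s2 * s2
            fmag += 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[i + 1, 0] -= fmag * dx
        f[i + 1, 1] -= fmag * dy
        f[i + 1, 2] -= fmag * dz
    # non-bonded LJ (WCA) from pair list
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            s2 = sig2 / r2
            s6 = s2 * s2 * s2
            fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz
    # bending: U = k_theta (1 - cos theta), theta = 0 when bonds are collinear
    for i in range(1, n - 1):
        b1x = pos[i, 0] - pos[i - 1, 0]
        b1y = pos[i, 1] - pos[i - 1, 1]
        b1z = pos[i, 2] - pos[i - 1, 2]
        b2x = pos[i + 1, 0] - pos[i, 0]
        b2y = pos[i + 1, 1] - pos[i, 1]
        b2z = pos[i + 1, 2] - pos[i, 2]
        l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        u1x = b1x / l1
        u1y = b1y / l1
        u1z = b1z / l1
        u2x = b2x / l2
        u2y = b2y / l2
        u2z = b2z / l2
        c = u1x * u2x + u1y * u2y + u1z * u2z
        # dU/d(cos) = -k_theta ; F = -dU/dr = k_theta * d(cos)/dr
        # d cos / d r_{i-1} = -(u2 - c u1)/l1 ; d cos / d r_{i+1} = (u1 - c u2)/l2
        gax = -(u2x - c * u1x) / l1
        gay = -(u2y - c * u1y) / l1
        gaz = -(u2z - c * u1z) / l1
        gcx = (u1x - c * u2x) / l2
        gcy = (u1y - c * u2y) / l2
        gcz = (u1z - c * u2z) / l2
        f[i - 1, 0] += k_theta * gax
        f[i - 1, 1] += k_theta * gay
        f[i - 1, 2] += k_theta * gaz
        f[i + 1, 0] += k_theta * gcx
        f[i + 1, 1] += k_theta * gcy
        f[i + 1, 2] += k_theta * gcz
        f[i, 0] -= k_theta * (gax + gcx)
        f[i, 1] -= k_theta * (gay + gcy)
        f[i, 2] -= k_theta * (gaz + gcz)
    # Morse bridges (active pairs only, cut at rc_bridge)
    for p in range(br_i.shape[0]):
        i = br_i[p]
        j = br_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_bridge * rc_bridge:
            continue
        r = np.sqrt(r2)
        if r < 1e-12:
            continue
        ea = np.exp(-alpha_m * r)
        # -dU/dr = 2 alpha D0 (exp(-2 a r) - exp(-a r))  (negative: attractive)
        fmag = 2.0 * alpha_m * d0 * (ea * ea - ea) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    return 0


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True)
def run_block(pos, vel, n_steps, dt, gamma, mass, kBT,
              sigma, eps, k_fene, R0, k_theta,
              d0, alpha_m, rc_bridge, br_i, br_j,
              ext_f, seed):
    """Integrate `n_steps` velocity-Verlet Langevin steps in place.

    Thermal kicks come from an inline xorshift128+ stream seeded via
    splitmix64 from `seed` (bit-reproducible; statistical quality is ample
    for a thermostat).  Returns 0 on success, or the (1-based) step index at
    which a FENE bond overstretched / coordinates blew up.
    """
    s0 = _splitmix64(np.uint64(seed))
    s1 = _splitmix64(s0)
    n = pos.shape[0]
    skin = 0.4 * sigma
    r_list = 2.0 ** (1.0 / 6.0) * sigma + skin
    half_skin2 = (0.5 * skin) ** 2
    pi, pj, npairs = _build_pair_list(pos, r_list)
    pos0 = pos.copy()

    fc = np.zeros((n, 3))
    status = _eval_forces(pos, fc, pi, pj, npairs, sigma, eps, k_fene, R0,
                          k_theta, d0, alpha_m, rc_bridge, br_i, br_j)
    if status != 0:
        return 1
    # uniform kicks with variance 2 gamma m kBT / dt
    amp = np.sqrt(24.0 * kBT * gamma * mass / dt) if dt > 0 else 0.0
    to_unit = 1.0 / 9007199254740992.0  # 2^-53
    f = np.empty((n, 3))
    for i in range(n):
        for d in range(3):
            x = s0
            y = s1
            s0 = y
            x = x ^ ((x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF))
            s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
            u = float((s1 + y) >> np.uint64(11)) * to_unit
            f[i, d] = fc[i, d] + ext_f[i, d] - gamma * mass * vel[i, d] \
                + amp * (u - 0.5)

    inv_m = 1.0 / mass
    for step in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d] * inv_m
                pos[i, d] += dt * vel[i, d]
        # pair-list refresh when anything moved more than half the skin
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos0[i, 0]
            dy = pos[i, 1] - pos0[i, 1]
            dz = pos[i, 2] - pos0[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            pi, pj, npairs = _build_pair_list(pos, r_list)
            for i in range(n):
                pos0[i, 0] = pos[i, 0]
                pos0[i, 1] = pos[i, 1]
                pos0[i, 2] = pos[i, 2]
        status = _eval_forces(pos, fc, pi, pj, npairs, sigma, eps, k_fene, R0,
                              k_theta, d0, alpha_m, rc_bridge, br_i, br_j)
        if status != 0:
            return step + 1
        for i in range(n):
            for d in range(3):
                x = s0
                y = s1
                s0 = y
                x = x ^ ((x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF))
                s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
                u = float((s1 + y) >> np.uint64(11)) * to_unit
                fi = fc[i, d] + ext_f[i, d] - gamma * mass * vel[i, d] \
                    + amp * (u - 0.5)
                vel[i, d] += 0.5 * dt * fi * inv_m
                f[i, d] = fi
        if not np.isfinite(pos[0, 0]):
            return step + 1
    return 0


@njit(cache=True, fastmath=True)
def compute_forces(pos, sigma, eps, k_fene, R0, k_theta,
                   d0, alpha_m, rc_bridge, br_i, br_j):
    """One-shot conservative force evaluation (fresh pair list)."""
    f = np.zeros((pos.shape[0], 3))
    r_list = 2.0 ** (1.0 / 6.0) * sigma + 0.1 * sigma
    pi, pj, npairs = _build_pair_list(pos, r_list)
    _eval_forces(pos, f, pi, pj, npairs, sigma, eps, k_fene, R0, k_theta,
                 d0, alpha_m, rc_bridge, br_i, br_j)
    return f
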