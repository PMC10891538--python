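"""Numba-compiled numerical kernels.

Everything here is a plain function of arrays and scalars; domain objects
and error handling live in the public modules.  Kernels that can fail
return an integer status (0 ok, 1 bond overstretch, 2 hard-core overlap,
3 escaped bead, -1 pair-buffer overflow) plus the offending index, and the
callers map these to typed exceptions.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_OVERLAP = 2
STATUS_ESCAPED = 3

_TWO_PI = 2.0 * math.pi


@nb.njit(cache=True)
def hosking_sample(gamma, z):
    """Exact stationary Gaussian sample via the Durbin-Levinson recursion.

    gamma : autocovariance at lags 0..n-1 (gamma[0] must be the variance)
    z     : n i.i.d. standard normals
    """
    n = z.shape[0]
    x = np.empty(n)
    x[0] = math.sqrt(gamma[0]) * z[0]
    if n == 1:
        return x
    phi = np.zeros(n)
    phi_prev = np.zeros(n)
    v = gamma[0]
    for t in range(1, n):
        acc = gamma[t]
        for j in range(1, t):
            acc -= phi_prev[j - 1] * gamma[t - j]
        a = acc / v
        for j in range(1, t):
            phi[j - 1] = phi_prev[j - 1] - a * phi_prev[t - 1 - j]
        phi[t - 1] = a
        v *= (1.0 - a * a)
        mu = 0.0
        for j in range(1, t + 1):
            mu += phi[j - 1] * x[t - j]
        x[t] = mu + math.sqrt(v) * z[t]
        for j in range(t):
            phi_prev[j] = phi[j]
    return x


@nb.njit(cache=True)
def build_pairs(pos, rc, max_pairs):
    """All i<j pairs with |r_i - r_j| <= rc, via a linked-cell grid.

    Returns (pairs, count); count == -1 signals buffer overflow (caller
    should retry with a larger max_pairs).
    """
    n = pos.shape[0]
    lo0 = lo1 = lo2 = 1.0e300
    hi0 = hi1 = hi2 = -1.0e300
    for i in range(n):
        if pos[i, 0] < lo0:
            lo0 = pos[i, 0]
        if pos[i, 0] > hi0:
            hi0 = pos[i, 0]
        if pos[i, 1] < lo1:
            lo1 = pos[i, 1]
        if pos[i, 1] > hi1:
            hi1 = pos[i, 1]
        if pos[i, 2] < lo2:
            lo2 = pos[i, 2]
        if pos[i, 2] > hi2:
            hi2 = pos[i, 2]
    nc0 = max(1, int((hi0 - lo0) / rc))
    nc1 = max(1, int((hi1 - lo1) / rc))
    nc2 = max(1, int((hi2 - lo2) / rc))
    w0 = (hi0 - lo0) / nc0 + 1e-12
    w1 = (hi1 - lo1) / nc1 + 1e-12
    w2 = (hi2 - lo2) / nc2 + 1e-12
    ncell = nc0 * nc1 * nc2

    cell_of = np.empty(n, np.int64)
    count = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        c0 = min(int((pos[i, 0] - lo0) / w0), nc0 - 1)
        c1 = min(int((pos[i, 1] - lo1) / w1), nc1 - 1)
        c2 = min(int((pos[i, 2] - lo2) / w2), nc2 - 1)
        c = (c0 * nc1 + c1) * nc2 + c2
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count[:ncell].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    pairs = np.empty((max_pairs, 2), np.int64)
    npair = 0
    rc2 = rc * rc
    for c0 in range(nc0):
        for c1 in range(nc1):
            for c2 in range(nc2):
                c = (c0 * nc1 + c1) * nc2 + c2
                for d0 in range(-1, 2):
                    e0 = c0 + d0
                    if e0 < 0 or e0 >= nc0:
                        continue
                    for d1 in range(-1, 2):
                        e1 = c1 + d1
                        if e1 < 0 or e1 >= nc1:
                            continue
                        for d2 in range(-1, 2):
                            e2 = c2 + d2
                            if e2 < 0 or e2 >= nc2:
                                continue
                            e = (e0 * nc1 + e1) * nc2 + e2
                            if e < c:
                                continue
                            for ii in range(count[c], count[c + 1]):
                                i = order[ii]
                                jstart = count[e]
                                if e == c:
                                    jstart = ii + 1
                                for jj in range(jstart, count[e + 1]):
                                    j = order[jj]
                                    dx = pos[i, 0] - pos[j, 0]
                                    dy = pos[i, 1] - pos[j, 1]
                                    dz = pos[i, 2] - pos[j, 2]
                                    if dx * dx + dy * dy + dz * dz <= rc2:
                                        if npair >= max_pairs:
                                            return pairs, -1
                                        if i < j:
                                            pairs[npair, 0] = i
                                            pairs[npair, 1] = j
                                        else:
                                            pairs[npair, 0] = j
                                            pairs[npair, 1] = i
                                        npair += 1
    return pairs, npair


@nb.njit(cache=True, inline="always")
def _is_bonded(adj, i, j):
    for a in range(adj.shape[1]):
        if adj[i, a] == j:
            return True
        if adj[i, a] < 0:
            return False
    return False


@nb.njit(cache=True)
def compute_forces(pos, bonds, adj, pairs, n_pairs,
                   use_fene, fene_K, fene_R, k_bond, eps, sigma,
                   wca_cutoff, use_walls, cyl_radius, half_length,
                   wall_cutoff, forces):
    """Total forces (negative energy gradient) and potential energy.

    Bonded pairs (1-2 neighbors) are excluded from the excluded-volume
    term.  Wall contributions from the cylindrical side surface and the
    two flat caps are evaluated separately and summed.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    # bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if use_fene:
            xr = (d - sigma) / fene_R
            x2 = xr * xr
            if x2 >= 1.0:
                return energy, STATUS_OVERSTRETCH, b
            energy += -0.5 * fene_K * fene_R * fene_R * math.log(1.0 - x2)
            g = fene_K * (d - sigma) / (1.0 - x2)
        else:
            energy += 0.5 * k_bond * (d - sigma) * (d - sigma)
            g = k_bond * (d - sigma)
        f = g / d
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # excluded volume (WCA), 1-2 exclusion
    wca2 = wca_cutoff * wca_cutoff
    floor = 1e-6 * sigma
    s2 = sigma * sigma
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if _is_bonded(adj, i, j):
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > wca2:
            continue
        if d2 < floor * floor:
            return energy, STATUS_OVERLAP, i
        sr2 = s2 / d2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += 4.0 * eps * (sr12 - sr6) + eps
        # dU/dd = -24 eps (2 sr12 - sr6)/d ; force on i is +g * u_ij
        g_over_d = -24.0 * eps * (2.0 * sr12 - sr6) / d2
        forces[i, 0] += g_over_d * dx
        forces[i, 1] += g_over_d * dy
        forces[i, 2] += g_over_d * dz
        forces[j, 0] -= g_over_d * dx
        forces[j, 1] -= g_over_d * dy
        forces[j, 2] -= g_over_d * dz

    # confinement
    if use_walls:
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            rho = math.sqrt(x * x + y * y)
            r_side = cyl_radius - rho
            if r_side <= 0.0:
                return energy, STATUS_ESCAPED, i
            if r_side <= wall_cutoff:
                sr = sigma / r_side
                sr2w = sr * sr
                sr4 = sr2w * sr2w
                sr10 = sr4 * sr4 * sr2w
                energy += _TWO_PI * eps * (0.4 * sr10 - sr4 + 0.6)
                dudr = (4.0 * _TWO_PI * eps / r_side) * (sr4 - sr10)
                fm = -dudr  # > 0: push inward (increasing r_side)
                if rho > 1e-12:
                    forces[i, 0] -= fm * x / rho
                    forces[i, 1] -= fm * y / rho
            r_top = half_length - z
            if r_top <= 0.0:
                return energy, STATUS_ESCAPED, i
            if r_top <= wall_cutoff:
                sr = sigma / r_top
                sr2w = sr * sr
                sr4 = sr2w * sr2w
                sr10 = sr4 * sr4 * sr2w
                energy += _TWO_PI * eps * (0.4 * sr10 - sr4 + 0.6)
                dudr = (4.0 * _TWO_PI * eps / r_top) * (sr4 - sr10)
                forces[i, 2] += dudr  # dudr < 0: push toward -z
            r_bot = z + half_length
            if r_bot <= 0.0:
                return energy, STATUS_ESCAPED, i
            if r_bot <= wall_cutoff:
                sr = sigma / r_bot
                sr2w = sr * sr
                sr4 = sr2w * sr2w
                sr10 = sr4 * sr4 * sr2w
                energy += _TWO_PI * eps * (0.4 * sr10 - sr4 + 0.6)
                dudr = (4.0 * _TWO_PI * eps / r_bot) * (sr4 - sr10)
                forces[i, 2] -= dudr

    return energy, STATUS_OK, -1


@nb.njit(cache=True)
def apply_update(pos, forces, noise, step, mobility, noise_scale, ref):
    """Overdamped position update with the step-``step`` noise slice.

    ``noise`` is (n_beads, 3, n_steps) so consecutive steps of one stream
    are memory-adjacent.  Returns the squared max displacement since
    ``ref`` (the neighbor-list rebuild criterion); NaN positions
    propagate into the return value, which callers check.
    """
    n = pos.shape[0]
    moved = 0.0
    for i in range(n):
        pos[i, 0] += mobility * forces[i, 0] + noise_scale * noise[i, 0, step]
        pos[i, 1] += mobility * forces[i, 1] + noise_scale * noise[i, 1, step]
        pos[i, 2] += mobility * forces[i, 2] + noise_scale * noise[i, 2, step]
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        m2 = dx * dx + dy * dy + dz * dz
        if not (m2 <= moved):   # also True for NaN
            moved = m2
    return moved


@nb.njit(cache=True)
def relax_overlaps(pos, bonds, adj, cyl_radius, half_length, wall_margin,
                   k_rep, rc_rep, k_bond, sigma, gamma_step, step_cap,
                   n_iter, rebuild_every, pair_rc, max_pairs):
    """Steepest-descent overlap removal for initial configurations.

    Soft linear-core repulsion below rc_rep, harmonic bonds toward sigma,
    and harmonic tethers keeping beads wall_margin inside the confinement.
    Displacements are capped at step_cap per iteration, so heavily
    overlapped starting structures inflate stably.

    Returns (min_nonbonded_distance, max_bond_deviation); (-1, -1) on
    pair-buffer overflow.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    pairs, npair = build_pairs(pos, pair_rc, max_pairs)
    if npair < 0:
        return -1.0, -1.0
    k_wall = 50.0
    rho_lim = cyl_radius - wall_margin
    z_lim = half_length - wall_margin
    for it in range(n_iter):
        if it > 0 and it % rebuild_every == 0:
            pairs, npair = build_pairs(pos, pair_rc, max_pairs)
            if npair < 0:
                return -1.0, -1.0
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        for p in range(npair):
            i = pairs[p, 0]
            j = pairs[p, 1]
            if _is_bonded(adj, i, j):
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= rc_rep:
                continue
            if d < 1e-9:
                # coincident beads: separate along a deterministic direction
                F[i, 2] -= k_rep
                F[j, 2] += k_rep
                continue
            f = k_rep * (rc_rep - d) / (rc_rep * d)
            F[i, 0] -= f * dx
            F[i, 1] -= f * dy
            F[i, 2] -= f * dz
            F[j, 0] += f * dx
            F[j, 1] += f * dy
            F[j, 2] += f * dz
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-9:
                continue
            f = k_bond * (d - sigma) / d
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            rho = math.sqrt(x * x + y * y)
            if rho > rho_lim and rho > 1e-12:
                f = k_wall * (rho - rho_lim) / rho
                F[i, 0] -= f * x
                F[i, 1] -= f * y
            if z > z_lim:
                F[i, 2] -= k_wall * (z - z_lim)
            elif z < -z_lim:
                F[i, 2] -= k_wall * (z + z_lim)
        for i in range(n):
            sx = gamma_step * F[i, 0]
            sy = gamma_step * F[i, 1]
            sz = gamma_step * F[i, 2]
            sn = math.sqrt(sx * sx + sy * sy + sz * sz)
            if sn > step_cap:
                sc = step_cap / sn
                sx *= sc
                sy *= sc
                sz *= sc
            pos[i, 0] += sx
            pos[i, 1] += sy
            pos[i, 2] += sz

    pairs, npair = build_pairs(pos, 1.3 * sigma, max_pairs)
    if npair < 0:
        return -1.0, -1.0
    min_nb = 1.0e300
    for p in range(npair):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if _is_bonded(adj, i, j):
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < min_nb:
            min_nb = d
    max_dev = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        dev = abs(d - sigma)
        if dev > max_dev:
            max_dev = dev
    return min_nb, max_dev
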