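"""Numba force/geometry kernels.

All kernels take flat parameter tables (species-pair matrices or per-type
arrays) prepared by :meth:`memwrap.forcefield.ForceField.tables`, accumulate
forces into a preallocated array, and return potential energy plus the
diagonal virial components needed for the lateral-pressure barostat.
Newton's third law is applied pairwise, so internal forces cancel exactly
in the total momentum.

Minimum-image displacements are computed by conditional folding, which
assumes |dx| < 2.5 L per axis; positions are kept wrapped by the engine
(rigid-body beads may stick out by at most the body radius, well inside
that margin).
"""

import numpy as np
from numba import njit

__all__ = [
    "pair_forces", "fene_forces", "angle_forces", "lr_bond_forces",
    "pair_distances", "candidate_filter", "form_bonds", "max_displacement_sq",
    "build_pair_list",
]


@njit(cache=True, fastmath=True, inline="always")
def _fold(d, L, halfL):
    if d > halfL:
        d -= L
        if d > halfL:
            d -= L
    elif d < -halfL:
        d += L
        if d < -halfL:
            d += L
    return d


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, pi, pj, species,
                wca_eps, wca_b2, wca_rc2, cos_rc2, cos_scale, cos_u, cos_fr,
                forces):
    """Nonbonded pair forces (WCA + tabulated cosine attractions).

    The cosine attractions come in as per-species-pair tables of U and F/r
    on a uniform r^2 grid (linear interpolation).  Pairs whose beads both
    belong to the nanoparticle surface must already be excluded from the
    list (rigid-internal forces are irrelevant).
    Returns (energy, Wxx, Wyy, Wzz).
    """
    e = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
        dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
        dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
        r2 = dx * dx + dy * dy + dz * dz
        s = species[i]
        t = species[j]
        fr = 0.0
        rc2 = wca_rc2[s, t]
        if r2 < rc2:
            sr2 = wca_b2[s, t] / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            eps = wca_eps[s, t]
            e += 4.0 * eps * (sr12 - sr6) + eps
            fr += 24.0 * eps * (2.0 * sr12 - sr6) / r2
        if r2 < cos_rc2[s, t]:
            x = r2 * cos_scale[s, t]
            i0 = int(x)
            frac = x - i0
            e += cos_u[s, t, i0] * (1.0 - frac) + cos_u[s, t, i0 + 1] * frac
            fr += cos_fr[s, t, i0]
        if fr != 0.0:
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            wxx += dx * fx
            wyy += dy * fy
            wzz += dz * fz
    return e, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def fene_forces(pos, box, bi, bj, btype, K, R0, eps, b2, forces):
    """FENE bond forces; returns (energy, Wxx, Wyy, Wzz, bad_index).

    ``bad_index`` is the index of the first overstretched bond (r >= R0),
    or -1 if all bonds are within range.
    """
    e = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    wca_fac = 2.0 ** (1.0 / 3.0)
    for k in range(bi.shape[0]):
        i = bi[k]
        j = bj[k]
        t = btype[k]
        dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
        dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
        dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
        r2 = dx * dx + dy * dy + dz * dz
        R02 = R0[t] * R0[t]
        x = r2 / R02
        if x >= 1.0:
            return e, wxx, wyy, wzz, k
        e += -0.5 * K[t] * R02 * np.log(1.0 - x)
        fr = -K[t] / (1.0 - x)
        if r2 < wca_fac * b2[t]:
            sr2 = b2[t] / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e += 4.0 * eps[t] * (sr12 - sr6) + eps[t]
            fr += 24.0 * eps[t] * (2.0 * sr12 - sr6) / r2
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += dx * fx
        wyy += dy * fy
        wzz += dz * fz
    return e, wxx, wyy, wzz, -1


@njit(cache=True, fastmath=True)
def angle_forces(pos, box, ai, aj, ak, K, theta0, forces):
    """Harmonic angle forces ``U = K (theta - theta0)^2`` (j is central)."""
    e = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for n in range(ai.shape[0]):
        i = ai[n]
        j = aj[n]
        k = ak[n]
        d1x = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
        d1y = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
        d1z = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
        d2x = _fold(pos[k, 0] - pos[j, 0], Lx, hx)
        d2y = _fold(pos[k, 1] - pos[j, 1], Ly, hy)
        d2z = _fold(pos[k, 2] - pos[j, 2], Lz, hz)
        r1sq = d1x * d1x + d1y * d1y + d1z * d1z
        r2sq = d2x * d2x + d2y * d2y + d2z * d2z
        r1 = np.sqrt(r1sq)
        r2 = np.sqrt(r2sq)
        c = (d1x * d2x + d1y * d2y + d1z * d2z) / (r1 * r2)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        theta = np.arccos(c)
        dtheta = theta - theta0
        e += K * dtheta * dtheta
        a = -2.0 * K * dtheta / s
        a11 = a * c / r1sq
        a12 = -a / (r1 * r2)
        a22 = a * c / r2sq
        f1x = a11 * d1x + a12 * d2x
        f1y = a11 * d1y + a12 * d2y
        f1z = a11 * d1z + a12 * d2z
        f2x = a22 * d2x + a12 * d1x
        f2y = a22 * d2y + a12 * d1y
        f2z = a22 * d2z + a12 * d1z
        forces[i, 0] += f1x
        forces[i, 1] += f1y
        forces[i, 2] += f1z
        forces[k, 0] += f2x
        forces[k, 1] += f2y
        forces[k, 2] += f2z
        forces[j, 0] -= f1x + f2x
        forces[j, 1] -= f1y + f2y
        forces[j, 2] -= f1z + f2z
        wxx += d1x * f1x + d2x * f2x
        wyy += d1y * f1y + d2y * f2y
        wzz += d1z * f1z + d2z * f2z
    return e, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def lr_bond_forces(pos, box, bl, br, eps, rc, wc, forces):
    """Dynamic ligand-receptor bond forces (cosine well, zero beyond support)."""
    e = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    outer = rc + wc
    half_pi = np.pi / 2.0
    for k in range(bl.shape[0]):
        i = bl[k]
        j = br[k]
        dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
        dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
        dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r <= rc:
            e -= eps
        elif r < outer:
            z = half_pi * (r - rc) / wc
            c = np.cos(z)
            e -= eps * c * c
            fr = -eps * np.pi * np.sin(2.0 * z) / (2.0 * wc * r)
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            wxx += dx * fx
            wyy += dy * fy
            wzz += dz * fz
    return e, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def pair_distances(pos, box, pi, pj):
    """Minimum-image distances for an index pair list."""
    n = pi.shape[0]
    out = np.empty(n)
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for k in range(n):
        i = pi[k]
        j = pj[k]
        dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
        dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
        dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
        out[k] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out


@njit(cache=True)
def candidate_filter(dist, r_form, lig, rec, live_keys, n_beads):
    """Indices of candidate pairs within ``r_form`` that are not already bonded.

    ``live_keys`` is a sorted array of ``lig * n_beads + rec`` keys of the
    live bonds.
    """
    n = dist.shape[0]
    keep = np.empty(n, dtype=np.int64)
    m = 0
    for k in range(n):
        if dist[k] < r_form:
            key = lig[k] * n_beads + rec[k]
            lo = np.searchsorted(live_keys, key)
            if lo < live_keys.shape[0] and live_keys[lo] == key:
                continue
            keep[m] = k
            m += 1
    return keep[:m]


@njit(cache=True)
def form_bonds(cand_l, cand_r, u, p_form, lig_count, rec_count, cap):
    """Visit candidates in order; each forms with probability ``p_form``
    while both partners remain below the valence cap.  Returns the indices
    of accepted candidates."""
    n = cand_l.shape[0]
    acc = np.empty(n, dtype=np.int64)
    m = 0
    for k in range(n):
        l = cand_l[k]
        r = cand_r[k]
        if lig_count[l] >= cap or rec_count[r] >= cap:
            continue
        if u[k] < p_form:
            lig_count[l] += 1
            rec_count[r] += 1
            acc[m] = k
            m += 1
    return acc[:m]


@njit(cache=True, fastmath=True)
def max_displacement_sq(pos, ref, box):
    """Two largest squared minimum-image displacements between snapshots.

    The Verlet list stays valid while the sum of the two largest bead
    displacements is below the skin.
    """
    best = 0.0
    second = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for i in range(pos.shape[0]):
        dx = _fold(pos[i, 0] - ref[i, 0], Lx, hx)
        dy = _fold(pos[i, 1] - ref[i, 1], Ly, hy)
        dz = _fold(pos[i, 2] - ref[i, 2], Lz, hz)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            second = best
            best = d2
        elif d2 > second:
            second = d2
    return best, second


@njit(cache=True, inline="always")
def _excluded(i, j, n_beads, excl_keys, span):
    # bonds join beads within one molecule, so pairs with a larger index
    # separation than any bond skip the binary search
    d = i - j
    if d > span or -d > span:
        return False
    if i < j:
        key = i * n_beads + j
    else:
        key = j * n_beads + i
    lo = np.searchsorted(excl_keys, key)
    return lo < excl_keys.shape[0] and excl_keys[lo] == key


@njit(cache=True)
def build_pair_list(pos, box, cutoff, cut2_tab, species, excl_keys, excl_span,
                    np_species_min):
    """Cell-list construction of the Verlet pair list.

    ``cutoff`` is the largest search radius (sets the cell size);
    ``cut2_tab`` holds the squared per-species-pair list radii, so pairs
    that interact only at short range do not bloat the list.  Excludes
    statically bonded pairs (sorted ``excl_keys``) and pairs internal to
    the rigid nanoparticle (both species >= np_species_min).  Falls back
    to an O(N^2) scan when the box holds fewer than three cells along some
    axis.
    """
    n = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    ncx = int(Lx / cutoff)
    ncy = int(Ly / cutoff)
    ncz = int(Lz / cutoff)

    cap = 16 + n * 120
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    m = 0

    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n):
            for j in range(i + 1, n):
                if species[i] >= np_species_min and species[j] >= np_species_min:
                    continue
                dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
                dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
                dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
                if dx * dx + dy * dy + dz * dz < cut2_tab[species[i], species[j]]:
                    if _excluded(i, j, n, excl_keys, excl_span):
                        continue
                    if m >= cap:
                        return pi[:0], pj[:0]
                    pi[m] = i
                    pj[m] = j
                    m += 1
        return pi[:m].copy(), pj[:m].copy()

    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] - Lx * np.floor(pos[i, 0] / Lx)
        y = pos[i, 1] - Ly * np.floor(pos[i, 1] / Ly)
        z = pos[i, 2] - Lz * np.floor(pos[i, 2] / Lz)
        cx = int(x / Lx * ncx)
        cy = int(y / Ly * ncy)
        cz = int(z / Lz * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell[i] = c
        nxt[i] = head[c]
        head[c] = i

    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(-1, 2):
                            # half stencil (self cell handled with ordering)
                            if ox < 0 or (ox == 0 and oy < 0) or \
                               (ox == 0 and oy == 0 and oz < 0):
                                continue
                            nx = (cx + ox) % ncx
                            ny = (cy + oy) % ncy
                            nz = (cz + oz) % ncz
                            nc = (nx * ncy + ny) * ncz + nz
                            same = nc == c
                            if (not same) and (ox == 0 and oy == 0 and oz == 0):
                                continue
                            i = head[c]
                            while i >= 0:
                                j = nxt[i] if same else head[nc]
                                while j >= 0:
                                    if not (species[i] >= np_species_min
                                            and species[j] >= np_species_min):
                                        dx = _fold(pos[i, 0] - pos[j, 0], Lx, hx)
                                        dy = _fold(pos[i, 1] - pos[j, 1], Ly, hy)
                                        dz = _fold(pos[i, 2] - pos[j, 2], Lz, hz)
                                        if dx * dx + dy * dy + dz * dz < \
                                                cut2_tab[species[i], species[j]]:
                                            if not _excluded(i, j, n, excl_keys, excl_span):
                                                if m >= cap:
                                                    return pi[:0], pj[:0]
                                                pi[m] = i
                                                pj[m] = j
                                                m += 1
                                    j = nxt[j]
                                i = nxt[i]
    return pi[:m].copy(), pj[:m].copy()
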