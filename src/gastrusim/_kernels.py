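"""Numba kernels for the lattice Monte Carlo core.

Everything in this module operates on flat numpy arrays so that the hot
loop (spin-copy attempts) stays inside compiled code.  The public,
documented surface lives in :mod:`gastrusim.lattice`,
:mod:`gastrusim.edgelist` and :mod:`gastrusim.simulation`; these kernels
are an implementation detail.

Conventions
-----------
* The lattice is ``spins[y, x]`` with a one-site frame (x==0, x==W-1,
  y==0 or y==H-1) that is permanently medium and excluded from all
  neighborhoods.
* The Moore neighborhood is enumerated in a fixed order (slots 0..7);
  ``REV[k]`` is the slot of the opposite direction.
* Edge index: ``i = (y*W + x)*8 + slot`` refers to the directed pair
  (site, its slot-neighbor).  ``edge_of_index`` maps i -> edge number or
  -1; ``index_of_edge`` maps edge number -> i (dense prefix of length
  |E|).  A spin copy is always "copy the neighbor's spin onto the site".
* RNG: xorshift128+ with a 2-word uint64 state, seeded from the Python
  level.  All randomness inside a run flows through this state.
"""

import numpy as np
from numba import njit

N_NB = 8
NBX = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
NBY = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
REV = np.array([7, 6, 5, 4, 3, 2, 1, 0], dtype=np.int64)

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always", fastmath=True)
def _rng_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 = s1 ^ (s1 << _U64(23))
    s1 = s1 ^ (s1 >> _U64(18))
    s1 = s1 ^ s0
    s1 = s1 ^ (s0 >> _U64(5))
    state[1] = s1
    return state[0] + state[1]


@njit(cache=True, inline="always", fastmath=True)
def _rng_uniform(state):
    return float(_rng_next(state) >> _U64(11)) * _INV53


@njit(cache=True, inline="always", fastmath=True)
def _rng_below(state, n):
    # floor(u*n); modulo-free, bias O(n/2^53) which is negligible here
    return int(_rng_uniform(state) * n)


def seed_rng_state(seed):
    """Build a non-degenerate xorshift128+ state from a Python integer."""
    # splitmix64 expansion of the seed (python ints, masked to 64 bits)
    mask = (1 << 64) - 1
    state = np.empty(2, dtype=np.uint64)
    z = int(seed) & mask
    for i in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        t = t ^ (t >> 31)
        state[i] = np.uint64(t)
    if state[0] == 0 and state[1] == 0:
        state[0] = _U64(1)
    return state


@njit(cache=True, inline="always", fastmath=True)
def _major_axis_length(A, SX, SY, SXX, SYY, SXY):
    """4*sqrt(largest eigenvalue of the site-coordinate covariance).

    Equals the diameter for a filled disc.  Returns 0 for cells with
    fewer than two sites (a single site has zero covariance).
    """
    if A <= 1:
        return 0.0
    inv = 1.0 / A
    mx = SX * inv
    my = SY * inv
    cxx = SXX * inv - mx * mx
    cyy = SYY * inv - my * my
    cxy = SXY * inv - mx * my
    h = 0.5 * (cxx + cyy)
    d = 0.5 * (cxx - cyy)
    lam = h + np.sqrt(d * d + cxy * cxy)
    if lam < 0.0:
        lam = 0.0
    return 4.0 * np.sqrt(lam)


@njit(cache=True, fastmath=True)
def build_edge_list(spins, edge_of_index, index_of_edge):
    """Scan the lattice and (re)build both edge arrays from scratch."""
    H, W = spins.shape
    edge_of_index[:] = -1
    index_of_edge[:] = -1
    n = 0
    for y in range(1, H - 1):
        for x in range(1, W - 1):
            s = spins[y, x]
            base = (y * W + x) * N_NB
            for k in range(N_NB):
                xn = x + NBX[k]
                yn = y + NBY[k]
                if xn <= 0 or xn >= W - 1 or yn <= 0 or yn >= H - 1:
                    continue
                if spins[yn, xn] != s:
                    edge_of_index[base + k] = n
                    index_of_edge[n] = base + k
                    n += 1
    return n


@njit(cache=True, inline="always", fastmath=True)
def _edge_add(i, edge_of_index, index_of_edge, n_edges):
    edge_of_index[i] = n_edges
    index_of_edge[n_edges] = i
    return n_edges + 1


@njit(cache=True, inline="always", fastmath=True)
def _edge_remove(i, edge_of_index, index_of_edge, n_edges):
    e = edge_of_index[i]
    last = n_edges - 1
    j = index_of_edge[last]
    index_of_edge[e] = j
    edge_of_index[j] = e
    index_of_edge[last] = -1
    edge_of_index[i] = -1
    return last


@njit(cache=True, fastmath=True)
def update_edges_after_copy(spins, x, y, edge_of_index, index_of_edge, n_edges):
    """Restore the edge-list invariant after the spin at (x, y) changed.

    Only the 8 directed pairs out of (x, y) and their 8 reverses can
    change.  Removed edges are back-filled from the dense tail so the
    ``index_of_edge`` prefix stays consecutive.
    """
    H, W = spins.shape
    s = spins[y, x]
    base = (y * W + x) * N_NB
    for k in range(N_NB):
        xn = x + NBX[k]
        yn = y + NBY[k]
        if xn <= 0 or xn >= W - 1 or yn <= 0 or yn >= H - 1:
            continue
        want = spins[yn, xn] != s
        i1 = base + k
        i2 = (yn * W + xn) * N_NB + REV[k]
        if want:
            if edge_of_index[i1] < 0:
                n_edges = _edge_add(i1, edge_of_index, index_of_edge, n_edges)
            if edge_of_index[i2] < 0:
                n_edges = _edge_add(i2, edge_of_index, index_of_edge, n_edges)
        else:
            if edge_of_index[i1] >= 0:
                n_edges = _edge_remove(i1, edge_of_index, index_of_edge, n_edges)
            if edge_of_index[i2] >= 0:
                n_edges = _edge_remove(i2, edge_of_index, index_of_edge, n_edges)
    return n_edges


@njit(cache=True, fastmath=True)
def delta_h_base(spins, ctype, area, sx, sy, sxx, syy, sxy,
                 J, lam1, lam2, AT, LT, x, y, s_new):
    """Energy change of copying spin ``s_new`` onto site (x, y).

    Computed locally: adhesion over the target site's Moore
    neighborhood (frame excluded) plus the area and length terms of the
    two affected cells.  Exactly equals the full-Hamiltonian difference.
    """
    H, W = spins.shape
    s_old = spins[y, x]
    t_old = ctype[s_old]
    t_new = ctype[s_new]
    dE = 0.0
    for k in range(N_NB):
        xn = x + NBX[k]
        yn = y + NBY[k]
        if xn <= 0 or xn >= W - 1 or yn <= 0 or yn >= H - 1:
            continue
        sn = spins[yn, xn]
        tn = ctype[sn]
        if sn != s_new:
            dE += J[t_new, tn]
        if sn != s_old:
            dE -= J[t_old, tn]
    fx = float(x)
    fy = float(y)
    if s_old != 0:
        A = area[s_old]
        dA = float(A) - AT
        dE += lam1 * ((dA - 1.0) * (dA - 1.0) - dA * dA)
        L0 = _major_axis_length(A, sx[s_old], sy[s_old],
                                sxx[s_old], syy[s_old], sxy[s_old])
        L1 = _major_axis_length(A - 1, sx[s_old] - fx, sy[s_old] - fy,
                                sxx[s_old] - fx * fx, syy[s_old] - fy * fy,
                                sxy[s_old] - fx * fy)
        dE += lam2 * ((L1 - LT) * (L1 - LT) - (L0 - LT) * (L0 - LT))
    if s_new != 0:
        A = area[s_new]
        dA = float(A) - AT
        dE += lam1 * ((dA + 1.0) * (dA + 1.0) - dA * dA)
        L0 = _major_axis_length(A, sx[s_new], sy[s_new],
                                sxx[s_new], syy[s_new], sxy[s_new])
        L1 = _major_axis_length(A + 1, sx[s_new] + fx, sy[s_new] + fy,
                                sxx[s_new] + fx * fx, syy[s_new] + fy * fy,
                                sxy[s_new] + fx * fy)
        dE += lam2 * ((L1 - LT) * (L1 - LT) - (L0 - LT) * (L0 - LT))
    return dE


@njit(cache=True, fastmath=True)
def delta_h_filopodia(area, sx, sy, comx, comy, lamF, fsrc, ftgt, lptr, lids,
                      x, y, s_old, s_new):
    """Pulling-force term: lamF * sum over affected links of (R_after - R_before).

    Only filopodia with an endpoint in one of the two affected cells can
    change length; all others contribute zero and are skipped.  Links
    whose endpoint cell would vanish (or is already dead) are ignored.
    ``comx``/``comy`` cache the centers of mass of unaffected cells.
    """
    n_old = (lptr[s_old + 1] - lptr[s_old]) if s_old != 0 else 0
    n_new = (lptr[s_new + 1] - lptr[s_new]) if s_new != 0 else 0
    if n_old == 0 and n_new == 0:
        return 0.0
    fx = float(x)
    fy = float(y)
    old_dead = False
    ox = oy = 0.0
    if s_old != 0:
        A1 = float(area[s_old]) - 1.0
        if A1 <= 0.0:
            old_dead = True
        else:
            ox = (sx[s_old] - fx) / A1
            oy = (sy[s_old] - fy) / A1
    nx = ny = 0.0
    if s_new != 0:
        A1 = float(area[s_new]) + 1.0
        nx = (sx[s_new] + fx) / A1
        ny = (sy[s_new] + fy) / A1
    total = 0.0
    for which in range(2):
        cell = s_old if which == 0 else s_new
        if cell == 0:
            continue
        for q in range(lptr[cell], lptr[cell + 1]):
            li = lids[q]
            a = fsrc[li]
            b = ftgt[li]
            if which == 1 and (a == s_old or b == s_old):
                continue  # link touches both cells; counted in first pass
            if area[a] <= 0 or area[b] <= 0:
                continue
            abx = comx[a]
            aby = comy[a]
            bbx = comx[b]
            bby = comy[b]
            if a == s_old:
                if old_dead:
                    continue
                aax, aay = ox, oy
            elif a == s_new:
                aax, aay = nx, ny
            else:
                aax, aay = abx, aby
            if b == s_old:
                if old_dead:
                    continue
                bax, bay = ox, oy
            elif b == s_new:
                bax, bay = nx, ny
            else:
                bax, bay = bbx, bby
            r_before = np.sqrt((abx - bbx) ** 2 + (aby - bby) ** 2)
            r_after = np.sqrt((aax - bax) ** 2 + (aay - bay) ** 2)
            total += r_after - r_before
    return lamF * total


@njit(cache=True, inline="always", fastmath=True)
def _apply_copy(spins, ctype, area, sx, sy, sxx, syy, sxy, comx, comy,
                x, y, s_new, edge_of_index, index_of_edge, n_edges):
    s_old = spins[y, x]
    fx = float(x)
    fy = float(y)
    spins[y, x] = s_new
    if s_old != 0:
        area[s_old] -= 1
        sx[s_old] -= fx
        sy[s_old] -= fy
        sxx[s_old] -= fx * fx
        syy[s_old] -= fy * fy
        sxy[s_old] -= fx * fy
        if area[s_old] > 0:
            comx[s_old] = sx[s_old] / area[s_old]
            comy[s_old] = sy[s_old] / area[s_old]
    if s_new != 0:
        area[s_new] += 1
        sx[s_new] += fx
        sy[s_new] += fy
        sxx[s_new] += fx * fx
        syy[s_new] += fy * fy
        sxy[s_new] += fx * fy
        comx[s_new] = sx[s_new] / area[s_new]
        comy[s_new] = sy[s_new] / area[s_new]
    return update_edges_after_copy(spins, x, y, edge_of_index,
                                   index_of_edge, n_edges)


@njit(cache=True, fastmath=True)
def _dh_base_cached(spins, ctype, area, sx, sy, sxx, syy, sxy, clen,
                    J, lam1, lam2, AT, LT, x, y, s_old, s_new):
    """delta_h_base using the cached current length; returns the energy
    change plus the two proposed lengths (for cache update on accept)."""
    H, W = spins.shape
    t_old = ctype[s_old]
    t_new = ctype[s_new]
    dE = 0.0
    for kk in range(N_NB):
        xn = x + NBX[kk]
        yn = y + NBY[kk]
        if xn <= 0 or xn >= W - 1 or yn <= 0 or yn >= H - 1:
            continue
        sn = spins[yn, xn]
        tn = ctype[sn]
        if sn != s_new:
            dE += J[t_new, tn]
        if sn != s_old:
            dE -= J[t_old, tn]
    fx = float(x)
    fy = float(y)
    l_old = 0.0
    l_new = 0.0
    if s_old != 0:
        A = area[s_old]
        dA = float(A) - AT
        dE += lam1 * ((dA - 1.0) * (dA - 1.0) - dA * dA)
        if lam2 != 0.0:
            l_old = _major_axis_length(
                A - 1, sx[s_old] - fx, sy[s_old] - fy,
                sxx[s_old] - fx * fx, syy[s_old] - fy * fy,
                sxy[s_old] - fx * fy)
            c0 = clen[s_old]
            dE += lam2 * ((l_old - LT) * (l_old - LT) - (c0 - LT) * (c0 - LT))
    if s_new != 0:
        A = area[s_new]
        dA = float(A) - AT
        dE += lam1 * ((dA + 1.0) * (dA + 1.0) - dA * dA)
        if lam2 != 0.0:
            l_new = _major_axis_length(
                A + 1, sx[s_new] + fx, sy[s_new] + fy,
                sxx[s_new] + fx * fx, syy[s_new] + fy * fy,
                sxy[s_new] + fx * fy)
            c0 = clen[s_new]
            dE += lam2 * ((l_new - LT) * (l_new - LT) - (c0 - LT) * (c0 - LT))
    return dE, l_old, l_new


@njit(cache=True, fastmath=True)
def _dh_pull_cached(area, sx, sy, comx, comy, rlen, lamF, fsrc, ftgt,
                    lptr, lids, x, y, s_old, s_new, tmp_ids, tmp_r):
    """Pulling term using cached link lengths; records the affected links'
    new lengths in the scratch buffers for cache update on accept."""
    m = 0
    n_t_old = (lptr[s_old + 1] - lptr[s_old]) if s_old != 0 else 0
    n_t_new = (lptr[s_new + 1] - lptr[s_new]) if s_new != 0 else 0
    if n_t_old + n_t_new == 0:
        return 0.0, 0
    fx = float(x)
    fy = float(y)
    old_dead = False
    ox = oy = nx = ny = 0.0
    if s_old != 0:
        A1 = float(area[s_old]) - 1.0
        if A1 <= 0.0:
            old_dead = True
        else:
            ox = (sx[s_old] - fx) / A1
            oy = (sy[s_old] - fy) / A1
    if s_new != 0:
        A1 = float(area[s_new]) + 1.0
        nx = (sx[s_new] + fx) / A1
        ny = (sy[s_new] + fy) / A1
    dpull = 0.0
    for which in range(2):
        cell = s_old if which == 0 else s_new
        if cell == 0:
            continue
        for q in range(lptr[cell], lptr[cell + 1]):
            li = lids[q]
            la = fsrc[li]
            lb = ftgt[li]
            if which == 1 and (la == s_old or lb == s_old):
                continue
            if area[la] <= 0 or area[lb] <= 0:
                continue
            if la == s_old:
                if old_dead:
                    continue
                aax, aay = ox, oy
            elif la == s_new:
                aax, aay = nx, ny
            else:
                aax, aay = comx[la], comy[la]
            if lb == s_old:
                if old_dead:
                    continue
                bax, bay = ox, oy
            elif lb == s_new:
                bax, bay = nx, ny
            else:
                bax, bay = comx[lb], comy[lb]
            r_after = np.sqrt((aax - bax) ** 2 + (aay - bay) ** 2)
            dpull += r_after - rlen[li]
            if m < 512:
                tmp_ids[m] = li
                tmp_r[m] = r_after
                m += 1
    return lamF * dpull, m



@njit(cache=True, fastmath=True)
def run_mcs(spins, ctype, area, sx, sy, sxx, syy, sxy, comx, comy,
            J, T, lam1, lam2, AT, LT,
            edge_of_index, index_of_edge, n_edges,
            lamF, fsrc, ftgt, lptr, lids,
            n_steps, rng_state):
    """Run ``n_steps`` Monte Carlo steps with the edge-list sampler.

    One MCS performs ceil(|E|/n_NB) copy attempts, re-reading |E| as it
    changes.  Returns (n_edges, attempts, accepted).
    """
    H, W = spins.shape
    attempts = 0
    accepted = 0
    # per-call caches: current major-axis length per cell, length per link.
    # Rebuilt on entry, kept exact by updating them on every accepted copy,
    # so each attempt only evaluates the *proposed* lengths.
    clen = np.zeros(len(area), dtype=np.float64)
    for c in range(1, len(area)):
        if area[c] > 0:
            clen[c] = _major_axis_length(area[c], sx[c], sy[c],
                                         sxx[c], syy[c], sxy[c])
    n_links = len(fsrc)
    rlen = np.zeros(max(n_links, 1), dtype=np.float64)
    for li in range(n_links):
        la = fsrc[li]
        lb = ftgt[li]
        if area[la] > 0 and area[lb] > 0:
            rlen[li] = np.sqrt((comx[la] - comx[lb]) ** 2
                               + (comy[la] - comy[lb]) ** 2)
    tmp_ids = np.empty(512, dtype=np.int64)
    tmp_r = np.empty(512, dtype=np.float64)

    for _ in range(n_steps):
        a = 0
        while True:
            E = n_edges
            if E == 0:
                break  # frozen configuration
            if a >= (E + N_NB - 1) // N_NB:
                break
            a += 1
            attempts += 1
            i = index_of_edge[_rng_below(rng_state, E)]
            p = i // N_NB
            k = i % N_NB
            x = p % W
            y = p // W
            xs = x + NBX[k]
            ys = y + NBY[k]
            s_new = spins[ys, xs]
            s_old = spins[y, x]
            dE, l_old, l_new = _dh_base_cached(
                spins, ctype, area, sx, sy, sxx, syy, sxy, clen,
                J, lam1, lam2, AT, LT, x, y, s_old, s_new)
            m = 0
            if lamF != 0.0 and n_links > 0:
                dpull, m = _dh_pull_cached(
                    area, sx, sy, comx, comy, rlen, lamF, fsrc, ftgt,
                    lptr, lids, x, y, s_old, s_new, tmp_ids, tmp_r)
                dE += dpull
            if dE <= 0.0 or _rng_uniform(rng_state) < np.exp(-dE / T):
                n_edges = _apply_copy(spins, ctype, area, sx, sy, sxx, syy,
                                      sxy, comx, comy, x, y, s_new,
                                      edge_of_index, index_of_edge, n_edges)
                if lam2 != 0.0:
                    if s_old != 0:
                        clen[s_old] = l_old
                    if s_new != 0:
                        clen[s_new] = l_new
                for t in range(m):
                    rlen[tmp_ids[t]] = tmp_r[t]
                accepted += 1
    return n_edges, attempts, accepted


@njit(cache=True, fastmath=True)
def run_mcs_conventional(spins, ctype, area, sx, sy, sxx, syy, sxy, comx, comy,
                         J, T, lam1, lam2, AT, LT,
                         edge_of_index, index_of_edge, n_edges,
                         n_steps, rng_state):
    """Conventional CPM sampler: |Lambda| random site-pair proposals per MCS.

    Used as the independent dynamics oracle for the edge-list sampler.
    Same-spin pairs are drawn and silently discarded, as in the
    conventional algorithm.  The edge list is kept up to date so the
    two samplers share all bookkeeping.
    """
    H, W = spins.shape
    n_sites = (H - 2) * (W - 2)
    attempts = 0
    accepted = 0
    for _ in range(n_steps):
        for _t in range(n_sites):
            attempts += 1
            p = _rng_below(rng_state, n_sites)
            x = p % (W - 2) + 1
            y = p // (W - 2) + 1
            k = _rng_below(rng_state, N_NB)
            xs = x + NBX[k]
            ys = y + NBY[k]
            if xs <= 0 or xs >= W - 1 or ys <= 0 or ys >= H - 1:
                continue
            s_new = spins[ys, xs]
            if s_new == spins[y, x]:
                continue
            dE = delta_h_base(spins, ctype, area, sx, sy, sxx, syy, sxy,
                              J, lam1, lam2, AT, LT, x, y, s_new)
            if dE <= 0.0 or _rng_uniform(rng_state) < np.exp(-dE / T):
                n_edges = _apply_copy(spins, ctype, area, sx, sy, sxx, syy,
                                      sxy, comx, comy, x, y, s_new,
                                      edge_of_index, index_of_edge, n_edges)
                accepted += 1
    return n_edges, attempts, accepted
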