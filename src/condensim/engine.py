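"""Jitted integration core of the overdamped-Langevin simulator.

All state lives in plain float64/int64 arrays so the time loop compiles to
machine code.  Randomness comes from a self-contained xoshiro256** stream
with a 128-layer ziggurat Gaussian sampler, which keeps runs bit-reproducible
for a given seed independent of NumPy/numba internals and is fast enough to
draw three fresh Gaussians per particle per 0.1 ms step.

Per-step draw order: thermal noise for all chain beads (row-major), then
condensin front feet, then rear feet; then mechanism uniforms — capture-pair
draws in ascending (site-sorted) pair order for diffusion capture, or
turnover draws (per extruder, plus one draw per relocation) followed by
translocation draws (front then rear, per extruder in load order) for loop
extrusion.  Mechanism bookkeeping (turnover, translocation) is resolved
before the step's forces are evaluated.

The excluded-volume search uses a linked-cell grid of edge ``d_rep0``
restricted to the chain's bounding box, rebuilt every step, with a
half-neighbour sweep so each unordered pair is visited once.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

MODE_FREE = 0
MODE_DC = 1
MODE_LE = 2

#: steps per jitted chunk; the Python driver logs between chunks
CHUNK_STEPS = 100_000


# ---------------------------------------------------------------------------
# ziggurat tables (Marsaglia & Tsang, 128 layers)
# ---------------------------------------------------------------------------

def _build_ziggurat():
    m1 = 2147483648.0
    dn = 3.442619855899
    tn = dn
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / math.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m1)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_KN, _WN, _FN = _build_ziggurat()
_ZIG_R = 3.442619855899


# ---------------------------------------------------------------------------
# xoshiro256** PRNG
# ---------------------------------------------------------------------------

@njit(cache=True)
def rng_state_from_seed(seed):
    """Initialize the four-word xoshiro256** state with splitmix64."""
    state = np.empty(4, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = w ^ (w >> np.uint64(31))
    return state


@njit(inline="always")
def _rng_next(state):
    s1 = state[1]
    result = s1 * np.uint64(5)
    result = ((result << np.uint64(7)) | (result >> np.uint64(57))) * np.uint64(9)
    t = s1 << np.uint64(17)
    state[2] ^= state[0]
    state[3] ^= state[1]
    state[1] ^= state[2]
    state[0] ^= state[3]
    state[2] ^= t
    state[3] = (state[3] << np.uint64(45)) | (state[3] >> np.uint64(19))
    return result


@njit(inline="always")
def rng_uniform(state):
    """Uniform double in [0, 1) from the top 53 bits."""
    return (_rng_next(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _rng_normal_tail(state, hz0, iz0):
    """Ziggurat rejection tail (cold path, ~3% of draws)."""
    kn, wn, fn = _KN, _WN, _FN
    hz = hz0
    iz = iz0
    while True:
        if iz == 0:
            while True:
                x = -math.log(rng_uniform(state) + 1e-300) * 0.2904764155684263
                y = -math.log(rng_uniform(state) + 1e-300)
                if y + y >= x * x:
                    break
            return _ZIG_R + x if hz > 0 else -(_ZIG_R + x)
        x = hz * wn[iz]
        if fn[iz] + rng_uniform(state) * (fn[iz - 1] - fn[iz]) < math.exp(-0.5 * x * x):
            return x
        u = _rng_next(state)
        hz = np.int32(np.uint32(u & np.uint64(0xFFFFFFFF)))
        iz = np.int64(hz & np.int32(127))
        ahz = np.int64(hz)
        if ahz < 0:
            ahz = -ahz
        if ahz < kn[iz]:
            return hz * wn[iz]


@njit(inline="always")
def rng_normal(state):
    """Standard normal via the 128-layer ziggurat (tables are globals,
    frozen into the compiled code)."""
    kn, wn = _KN, _WN
    u = _rng_next(state)
    hz = np.int32(np.uint32(u & np.uint64(0xFFFFFFFF)))
    iz = np.int64(hz & np.int32(127))
    ahz = np.int64(hz)
    if ahz < 0:
        ahz = -ahz
    if ahz < kn[iz]:
        return hz * wn[iz]
    return _rng_normal_tail(state, hz, iz)


@njit(cache=True)
def fill_normal(state, out):
    """Fill ``out`` with standard normals (fast path hand-inlined)."""
    kn, wn = _KN, _WN
    flat = out.reshape(out.size)
    for i in range(flat.size):
        u = _rng_next(state)
        hz = np.int32(np.uint32(u & np.uint64(0xFFFFFFFF)))
        iz = np.int64(hz & np.int32(127))
        ahz = np.int64(hz)
        if ahz < 0:
            ahz = -ahz
        if ahz < kn[iz]:
            flat[i] = hz * wn[iz]
        else:
            flat[i] = _rng_normal_tail(state, hz, iz)


@njit(cache=True)
def _fill_noise(state, out, sigma):
    """Scaled thermal-noise fill: out[i, :] = sigma * N(0, 1)."""
    kn, wn = _KN, _WN
    flat = out.reshape(out.size)
    for i in range(flat.size):
        u = _rng_next(state)
        hz = np.int32(np.uint32(u & np.uint64(0xFFFFFFFF)))
        iz = np.int64(hz & np.int32(127))
        ahz = np.int64(hz)
        if ahz < 0:
            ahz = -ahz
        if ahz < kn[iz]:
            flat[i] = sigma * (hz * wn[iz])
        else:
            flat[i] = sigma * _rng_normal_tail(state, hz, iz)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def _apply_boundary(pos, radius, reflect):
    n = pos.shape[0]
    for i in range(n):
        r2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
        if r2 > radius * radius:
            r = math.sqrt(r2)
            if reflect:
                s = (2.0 * radius - r) / r
                if s < 0.0:
                    s = 0.0
            else:
                s = radius / r
            pos[i, 0] *= s
            pos[i, 1] *= s
            pos[i, 2] *= s


@njit(cache=True)
def _add_tension(pos, force, k_ten, c2):
    """Hookean bonds between consecutive beads; pairwise antisymmetric."""
    n = pos.shape[0]
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d > 0.0:
            f = k_ten * (d - c2) / d
            force[i, 0] += f * dx
            force[i, 1] += f * dy
            force[i, 2] += f * dz
            force[i + 1, 0] -= f * dx
            force[i + 1, 1] -= f * dy
            force[i + 1, 2] -= f * dz


@njit(inline="always")
def _tiebreak_direction(i, j):
    """Deterministic unit vector for exactly coincident beads (pair hash)."""
    h = (i * np.int64(2654435761) + j * np.int64(40503)) % np.int64(6)
    v = np.zeros(3)
    v[h % 3] = 1.0 if h < 3 else -1.0
    return v



#: forward half-shell offsets (own cell first) for half-neighbour sweeps
_HALF_SHELL = np.array(
    [[0, 0, 0],
     [1, -1, -1], [1, -1, 0], [1, -1, 1],
     [1, 0, -1], [1, 0, 0], [1, 0, 1],
     [1, 1, -1], [1, 1, 0], [1, 1, 1],
     [0, 1, -1], [0, 1, 0], [0, 1, 1],
     [0, 0, 1]], dtype=np.int64)

@njit(cache=True)
def _add_repulsion(pos, force, c3, d_rep0, head, nxt):
    """Constant-magnitude excluded-volume force below the d_rep0 cutoff.

    Linked-cell grid of edge d_rep0 over the current bounding box; the own
    cell is swept with a j<i guard and 13 forward neighbour cells in full,
    so each unordered pair contributes exactly once.
    """
    n = pos.shape[0]
    minx = miny = minz = 1.0e300
    maxx = maxy = maxz = -1.0e300
    for i in range(n):
        if pos[i, 0] < minx:
            minx = pos[i, 0]
        if pos[i, 0] > maxx:
            maxx = pos[i, 0]
        if pos[i, 1] < miny:
            miny = pos[i, 1]
        if pos[i, 1] > maxy:
            maxy = pos[i, 1]
        if pos[i, 2] < minz:
            minz = pos[i, 2]
        if pos[i, 2] > maxz:
            maxz = pos[i, 2]
    inv = 1.0 / d_rep0
    sx = int((maxx - minx) * inv) + 1
    sy = int((maxy - miny) * inv) + 1
    sz = int((maxz - minz) * inv) + 1
    ncell = sx * sy * sz
    head[:ncell] = -1
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        c = (cx * sy + cy) * sz + cz
        nxt[i] = head[c]
        head[c] = i
    d2cut = d_rep0 * d_rep0
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        for off in range(14):
            x = cx + _HALF_SHELL[off, 0]
            y = cy + _HALF_SHELL[off, 1]
            z = cz + _HALF_SHELL[off, 2]
            if x < 0 or x >= sx or y < 0 or y >= sy or z < 0 or z >= sz:
                continue
            j = head[(x * sy + y) * sz + z]
            while j != -1:
                if off > 0 or j < i:
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < d2cut:
                        if d2 > 0.0:
                            f = c3 / math.sqrt(d2)
                            force[i, 0] += f * dx
                            force[i, 1] += f * dy
                            force[i, 2] += f * dz
                            force[j, 0] -= f * dx
                            force[j, 1] -= f * dy
                            force[j, 2] -= f * dz
                        else:
                            lo = i if i < j else j
                            hi = j if i < j else i
                            v = _tiebreak_direction(lo, hi)
                            force[i, 0] += c3 * v[0]
                            force[i, 1] += c3 * v[1]
                            force[i, 2] += c3 * v[2]
                            force[j, 0] -= c3 * v[0]
                            force[j, 1] -= c3 * v[1]
                            force[j, 2] -= c3 * v[2]
                j = nxt[j]


@njit(cache=True)
def _build_pairs(pos, r_verlet, start, cur, order, cellidx, pair_i, pair_j):
    """Collect all unordered pairs with centre distance < r_verlet.

    Counting-sort cell grid (edge r_verlet, restricted to the bounding box):
    beads are binned into contiguous per-cell slices so the half-neighbour
    sweep touches memory sequentially.  Returns the pair count; a count
    above capacity signals overflow (the caller must grow the arrays —
    nothing is dropped silently).
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    minx = miny = minz = 1.0e300
    maxx = maxy = maxz = -1.0e300
    for i in range(n):
        if pos[i, 0] < minx:
            minx = pos[i, 0]
        if pos[i, 0] > maxx:
            maxx = pos[i, 0]
        if pos[i, 1] < miny:
            miny = pos[i, 1]
        if pos[i, 1] > maxy:
            maxy = pos[i, 1]
        if pos[i, 2] < minz:
            minz = pos[i, 2]
        if pos[i, 2] > maxz:
            maxz = pos[i, 2]
    inv = 1.0 / r_verlet
    sx = int((maxx - minx) * inv) + 1
    sy = int((maxy - miny) * inv) + 1
    sz = int((maxz - minz) * inv) + 1
    ncell = sx * sy * sz
    start[:ncell + 1] = 0
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        c = (cx * sy + cy) * sz + cz
        cellidx[i] = c
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
        cur[c] = start[c]
    for i in range(n):
        c = cellidx[i]
        order[cur[c]] = i
        cur[c] += 1
    r2 = r_verlet * r_verlet
    count = 0
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        for off in range(14):
            x = cx + _HALF_SHELL[off, 0]
            y = cy + _HALF_SHELL[off, 1]
            z = cz + _HALF_SHELL[off, 2]
            if x < 0 or x >= sx or y < 0 or y >= sy or z < 0 or z >= sz:
                continue
            cc = (x * sy + y) * sz + z
            for t in range(start[cc], start[cc + 1]):
                j = order[t]
                if off > 0 or j < i:
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    if dx * dx + dy * dy + dz * dz < r2:
                        if count < cap:
                            pair_i[count] = i
                            pair_j[count] = j
                        count += 1
    return count


@njit(cache=True)
def _pair_repulsion(pos, force, c3, d_rep0, pair_i, pair_j, n_pairs):
    """Apply the constant-magnitude repulsion over a prebuilt pair list."""
    d2cut = d_rep0 * d_rep0
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < d2cut:
            if d2 > 0.0:
                f = c3 / math.sqrt(d2)
                force[i, 0] += f * dx
                force[i, 1] += f * dy
                force[i, 2] += f * dz
                force[j, 0] -= f * dx
                force[j, 1] -= f * dy
                force[j, 2] -= f * dz
            else:
                lo = i if i < j else j
                hi = j if i < j else i
                v = _tiebreak_direction(lo, hi)
                force[i, 0] += c3 * v[0]
                force[i, 1] += c3 * v[1]
                force[i, 2] += c3 * v[2]
                force[j, 0] -= c3 * v[0]
                force[j, 1] -= c3 * v[1]
                force[j, 2] -= c3 * v[2]


@njit(cache=True)
def _max_drift2(pos, ref_pos):
    """Largest squared bead displacement since the last pair-list rebuild."""
    worst = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref_pos[i, 0]
        dy = pos[i, 1] - ref_pos[i, 1]
        dz = pos[i, 2] - ref_pos[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > worst:
            worst = d2
    return worst


@njit(inline="always")
def _add_spring(pa, fa, pb, fb, ia, ib, k, eq):
    """Hookean spring between row ia of (pa, fa) and row ib of (pb, fb)."""
    dx = pb[ib, 0] - pa[ia, 0]
    dy = pb[ib, 1] - pa[ia, 1]
    dz = pb[ib, 2] - pa[ia, 2]
    d = math.sqrt(dx * dx + dy * dy + dz * dz)
    if d > 0.0:
        f = k * (d - eq) / d
        fa[ia, 0] += f * dx
        fa[ia, 1] += f * dy
        fa[ia, 2] += f * dz
        fb[ib, 0] -= f * dx
        fb[ib, 1] -= f * dy
        fb[ib, 2] -= f * dz


@njit(cache=True)
def _dc_capture(state, front, f_front, k_cond, c5, d_cut, p_assoc, invert):
    """Pairwise capture springs between in-range front feet; one uniform
    draw per in-range unordered pair, ascending pair order."""
    nc = front.shape[0]
    d2cut = d_cut * d_cut
    for a in range(nc - 1):
        for b in range(a + 1, nc):
            dx = front[b, 0] - front[a, 0]
            dy = front[b, 1] - front[a, 1]
            dz = front[b, 2] - front[a, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < d2cut:
                r = rng_uniform(state)
                active = r < p_assoc
                if invert:
                    active = not active
                if active and d2 > 0.0:
                    d = math.sqrt(d2)
                    f = k_cond * (d - c5) / d
                    f_front[a, 0] += f * dx
                    f_front[a, 1] += f * dy
                    f_front[a, 2] += f * dz
                    f_front[b, 0] -= f * dx
                    f_front[b, 1] -= f * dy
                    f_front[b, 2] -= f * dz


@njit(cache=True)
def _count_capture_pairs(front, d_cut):
    nc = front.shape[0]
    d2cut = d_cut * d_cut
    count = 0
    for a in range(nc - 1):
        for b in range(a + 1, nc):
            dx = front[b, 0] - front[a, 0]
            dy = front[b, 1] - front[a, 1]
            dz = front[b, 2] - front[a, 2]
            if dx * dx + dy * dy + dz * dz < d2cut:
                count += 1
    return count


@njit(cache=True)
def _le_turnover(state, load, fa, ra, front, rear, stall_f, stall_r, occ,
                 pos, all_sites, p_onoff):
    """Unload/reload sweep; empty = binding site with no anchored foot."""
    ne = load.shape[0]
    ns = all_sites.shape[0]
    for k in range(ne):
        if rng_uniform(state) < p_onoff:
            occ[fa[k]] -= 1
            occ[ra[k]] -= 1
            n_empty = 0
            for s in range(ns):
                if occ[all_sites[s]] == 0:
                    n_empty += 1
            new_site = load[k]
            if n_empty > 0:
                pick = np.int64(rng_uniform(state) * n_empty)
                if pick >= n_empty:
                    pick = n_empty - 1
                seen = 0
                for s in range(ns):
                    if occ[all_sites[s]] == 0:
                        if seen == pick:
                            new_site = all_sites[s]
                            break
                        seen += 1
            load[k] = new_site
            fa[k] = new_site
            ra[k] = new_site
            occ[new_site] += 2
            for d in range(3):
                front[k, d] = pos[new_site, d]
                rear[k, d] = pos[new_site, d]
            stall_f[k] = False
            stall_r[k] = False


@njit(cache=True)
def _le_translocate(state, fa, ra, stall_f, stall_r, occ, p_slide, n_beads,
                    buffer):
    """One translocation sweep; every foot consumes one uniform draw.

    A move is blocked when the destination bead, or any of the ``buffer``
    beads beyond it (foot exclusion zone), is anchored by another foot.
    """
    ne = fa.shape[0]
    for k in range(ne):
        if rng_uniform(state) < p_slide:
            dest = fa[k] + 1
            blocked = dest >= n_beads
            if not blocked:
                for b in range(buffer + 1):
                    probe = dest + b
                    if probe < n_beads and occ[probe] > 0:
                        blocked = True
                        break
            if blocked:
                stall_f[k] = True
            else:
                occ[fa[k]] -= 1
                fa[k] = dest
                occ[dest] += 1
                stall_f[k] = False
        if rng_uniform(state) < p_slide:
            dest = ra[k] - 1
            blocked = dest < 0
            if not blocked:
                for b in range(buffer + 1):
                    probe = dest - b
                    if probe >= 0 and occ[probe] > 0:
                        blocked = True
                        break
            if blocked:
                stall_r[k] = True
            else:
                occ[ra[k]] -= 1
                ra[k] = dest
                occ[dest] += 1
                stall_r[k] = False


# ---------------------------------------------------------------------------
# time loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _advance(rng, pos, front, rear, load, fa, ra, stall_f, stall_r, occ,
             mode, step0, nsteps,
             dt, lam, sigma, k_ten, c2, c3, d_rep0, radius, reflect,
             dc_site, k_cond, c5, d_cut, p_assoc, invert_p,
             p_slide, t_exch_steps, p_onoff, le_buffer, all_sites,
             force, f_front, f_rear, cstart, ccur, corder, ccellidx,
             ref_pos, pair_i, pair_j, n_pairs_arr, r_verlet, drift_max2,
             snap_every, snap_pos, snap_front, snap_rear, pair_count,
             snap_load, snap_fa, snap_ra, snap_stf, snap_str,
             snap_lf, snap_lr,
             track_idx, track_every, trk):
    n = pos.shape[0]
    nc = front.shape[0]
    scale = dt / lam
    nt = track_idx.shape[0]
    for b in range(nsteps):
        g = step0 + b + 1
        # thermal noise -> force accumulators
        _fill_noise(rng, force, sigma)
        _fill_noise(rng, f_front, sigma)
        _fill_noise(rng, f_rear, sigma)

        if mode == MODE_LE:
            if t_exch_steps > 0 and g % t_exch_steps == 0:
                _le_turnover(rng, load, fa, ra, front, rear, stall_f,
                             stall_r, occ, pos, all_sites, p_onoff)
            _le_translocate(rng, fa, ra, stall_f, stall_r, occ, p_slide,
                            n, le_buffer)

        _add_tension(pos, force, k_ten, c2)
        # Verlet-listed repulsion: rebuild when any bead drifted > skin/2
        if _max_drift2(pos, ref_pos) > drift_max2:
            cnt = _build_pairs(pos, r_verlet, cstart, ccur, corder,
                               ccellidx, pair_i, pair_j)
            if cnt > pair_i.shape[0]:
                raise RuntimeError("pair list capacity exceeded")
            n_pairs_arr[0] = cnt
            ref_pos[:, :] = pos
        _pair_repulsion(pos, force, c3, d_rep0, pair_i, pair_j,
                        n_pairs_arr[0])

        if mode == MODE_DC:
            for k in range(nc):
                _add_spring(front, f_front, rear, f_rear, k, k, k_ten, 0.0)
                s = dc_site[k]
                _add_spring(front, f_front, pos, force, k, s, k_ten, 0.0)
                _add_spring(rear, f_rear, pos, force, k, s, k_ten, 0.0)
            _dc_capture(rng, front, f_front, k_cond, c5, d_cut, p_assoc,
                        invert_p)
        elif mode == MODE_LE:
            for k in range(nc):
                _add_spring(front, f_front, rear, f_rear, k, k, k_ten, 0.0)
                _add_spring(front, f_front, pos, force, k, fa[k], k_ten, 0.0)
                _add_spring(rear, f_rear, pos, force, k, ra[k], k_ten, 0.0)

        for i in range(n):
            pos[i, 0] += force[i, 0] * scale
            pos[i, 1] += force[i, 1] * scale
            pos[i, 2] += force[i, 2] * scale
        _apply_boundary(pos, radius, reflect)
        if nc > 0:
            for k in range(nc):
                front[k, 0] += f_front[k, 0] * scale
                front[k, 1] += f_front[k, 1] * scale
                front[k, 2] += f_front[k, 2] * scale
                rear[k, 0] += f_rear[k, 0] * scale
                rear[k, 1] += f_rear[k, 1] * scale
                rear[k, 2] += f_rear[k, 2] * scale
            _apply_boundary(front, radius, reflect)
            _apply_boundary(rear, radius, reflect)

        if g % snap_every == 0:
            s = g // snap_every
            snap_pos[s] = pos
            if mode == MODE_DC:
                snap_front[s] = front
                snap_rear[s] = rear
                pair_count[s] = _count_capture_pairs(front, d_cut)
            elif mode == MODE_LE:
                snap_load[s] = load
                snap_fa[s] = fa
                snap_ra[s] = ra
                snap_stf[s] = stall_f
                snap_str[s] = stall_r
                snap_lf[s] = front
                snap_lr[s] = rear
        if nt > 0 and track_every > 0 and g % track_every == 0:
            s = g // track_every
            for t in range(nt):
                trk[s, t, 0] = pos[track_idx[t], 0]
                trk[s, t, 1] = pos[track_idx[t], 1]
                trk[s, t, 2] = pos[track_idx[t], 2]


def integrate(pos0, mode, n_steps, dt, lam, sigma, k_ten, c2, c3, d_rep0,
              radius, reflect, seed,
              dc_site=None, dc_front0=None, dc_rear0=None, k_cond=0.0,
              c5=0.0, d_cut=0.0, p_assoc=0.0, invert_p=False,
              le_load0=None, le_fa0=None, le_ra0=None, p_slide=0.0,
              t_exch_steps=0, p_onoff=0.0, le_buffer=1, all_sites=None,
              snap_every=1, track_idx=None, track_every=0,
              r_verlet=None, logger=None):
    """Python driver: allocates outputs, runs jitted chunks, logs progress.

    Returns a dict of snapshot/track arrays (see keys below).  All mutable
    state persists across chunks, so results are independent of chunking.
    """
    n = pos0.shape[0]
    pos = np.ascontiguousarray(pos0, dtype=np.float64).copy()
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty((0, 3), dtype=np.float64)

    dc_site = empty_i if dc_site is None else np.asarray(dc_site, np.int64)
    all_sites = empty_i if all_sites is None else np.asarray(all_sites, np.int64)
    if mode == MODE_DC:
        front = np.asarray(dc_front0, np.float64).reshape(-1, 3).copy()
        rear = np.asarray(dc_rear0, np.float64).reshape(-1, 3).copy()
    elif mode == MODE_LE:
        le_load0 = np.asarray(le_load0, np.int64)
        le_fa0 = np.asarray(le_fa0, np.int64)
        le_ra0 = np.asarray(le_ra0, np.int64)
        front = pos[le_fa0].copy() if le_fa0.size else empty_f.copy()
        rear = pos[le_ra0].copy() if le_ra0.size else empty_f.copy()
    else:
        front = empty_f.copy()
        rear = empty_f.copy()
    nc = front.shape[0]

    load = le_load0.copy() if mode == MODE_LE else empty_i.copy()
    fa = le_fa0.copy() if mode == MODE_LE else empty_i.copy()
    ra = le_ra0.copy() if mode == MODE_LE else empty_i.copy()
    stall_f = np.zeros(nc, dtype=np.bool_)
    stall_r = np.zeros(nc, dtype=np.bool_)
    occ = np.zeros(n, dtype=np.int64)
    if mode == MODE_LE:
        for k in range(nc):
            occ[fa[k]] += 1
            occ[ra[k]] += 1

    force = np.zeros((n, 3))
    f_front = np.zeros((nc, 3))
    f_rear = np.zeros((nc, 3))
    # Verlet pair list with a two-cutoff skin; the grid uses the list cutoff
    if r_verlet is None:
        r_verlet = 4.0 * d_rep0
    skin_half = 0.5 * (r_verlet - d_rep0)
    if skin_half <= 0:
        raise ValueError("r_verlet must exceed d_rep0")
    side_max = int(math.ceil(2.0 * radius / r_verlet)) + 2
    cstart = np.zeros(side_max ** 3 + 1, dtype=np.int32)
    ccur = np.zeros(side_max ** 3, dtype=np.int32)
    corder = np.empty(n, dtype=np.int32)
    ccellidx = np.empty(n, dtype=np.int32)
    pair_cap = max(128 * n, 4096)
    pair_i = np.empty(pair_cap, dtype=np.int32)
    pair_j = np.empty(pair_cap, dtype=np.int32)
    n_pairs_arr = np.zeros(1, dtype=np.int64)
    ref_pos = np.full((n, 3), np.inf)  # forces an initial rebuild

    n_snaps = n_steps // snap_every + 1
    snap_pos = np.zeros((n_snaps, n, 3))
    snap_front = np.zeros((n_snaps, nc, 3) if mode == MODE_DC else (n_snaps, 0, 3))
    snap_rear = np.zeros_like(snap_front)
    pair_count = np.zeros(n_snaps, dtype=np.int64)
    ne_snap = nc if mode == MODE_LE else 0
    snap_load = np.zeros((n_snaps, ne_snap), dtype=np.int64)
    snap_fa = np.zeros((n_snaps, ne_snap), dtype=np.int64)
    snap_ra = np.zeros((n_snaps, ne_snap), dtype=np.int64)
    snap_stf = np.zeros((n_snaps, ne_snap), dtype=np.bool_)
    snap_str = np.zeros((n_snaps, ne_snap), dtype=np.bool_)
    snap_lf = np.zeros((n_snaps, ne_snap, 3))
    snap_lr = np.zeros((n_snaps, ne_snap, 3))

    track_idx = empty_i if track_idx is None else np.asarray(track_idx, np.int64)
    if track_every > 0 and track_idx.size > 0:
        n_trk = n_steps // track_every + 1
    else:
        n_trk = 0
    trk = np.zeros((n_trk, track_idx.size, 3))

    # initial state at index 0
    snap_pos[0] = pos
    if mode == MODE_DC:
        snap_front[0] = front
        snap_rear[0] = rear
        pair_count[0] = _count_capture_pairs(front, d_cut) if nc else 0
    elif mode == MODE_LE:
        snap_load[0] = load
        snap_fa[0] = fa
        snap_ra[0] = ra
        snap_lf[0] = front
        snap_lr[0] = rear
    if n_trk > 0:
        trk[0] = pos[track_idx]

    rng = rng_state_from_seed(seed)
    done = 0
    while done < n_steps:
        todo = min(CHUNK_STEPS, n_steps - done)
        _advance(rng, pos, front, rear, load, fa, ra, stall_f, stall_r, occ,
                 mode, done, todo,
                 dt, lam, sigma, k_ten, c2, c3, d_rep0, radius, reflect,
                 dc_site, k_cond, c5, d_cut, p_assoc, invert_p,
                 p_slide, t_exch_steps, p_onoff, le_buffer, all_sites,
                 force, f_front, f_rear, cstart, ccur, corder, ccellidx,
                 ref_pos, pair_i, pair_j, n_pairs_arr, r_verlet,
                 skin_half * skin_half,
                 snap_every, snap_pos, snap_front, snap_rear, pair_count,
                 snap_load, snap_fa, snap_ra, snap_stf, snap_str,
                 snap_lf, snap_lr,
                 track_idx, track_every, trk)
        done += todo
        if logger is not None:
            logger.info("step %d/%d (t=%.1f s)", done, n_steps, done * dt)
        if not np.all(np.isfinite(pos)):
            bad = int(np.argwhere(~np.isfinite(pos))[0][0])
            raise FloatingPointError(
                f"non-finite position for bead {bad} at step {done}")

    return {
        "snap_pos": snap_pos, "snap_front": snap_front,
        "snap_rear": snap_rear, "pair_count": pair_count,
        "snap_load": snap_load, "snap_fa": snap_fa, "snap_ra": snap_ra,
        "snap_stf": snap_stf, "snap_str": snap_str,
        "snap_lf": snap_lf, "snap_lr": snap_lr, "trk": trk,
    }
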