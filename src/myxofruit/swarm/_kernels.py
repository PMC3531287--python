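"""Numba kernels for the 2D flexible-rod swarm simulator.

All kernels operate on a struct-of-arrays state:

- ``pos``      (n, 3, 2) float64 node coordinates; node 1 is the middle.
  Bodies are stored contiguously (never wrapped across the periodic seam);
  the whole body is translated when its midpoint leaves the domain.
- ``headend``  (n,) int8, 0 or 2: which end node is currently the head.
- ``state``    (n,) uint8, 0 = motile, 1 = spore (all nodes collapsed onto
  the spore center).
- ``counter``  (n,) int64 C-signal contact counter.
- ``next_rev`` (n,) float64 absolute time (min) of the next reversal.
- ``conv_step`` (n,) int64 step of sporulation, -1 while motile.

Scalar parameters travel in a flat float64 config vector indexed by the
``C_*`` constants below (built by :func:`myxofruit.swarm.model.config_vector`).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# config vector layout
C_DOMAIN = 0
C_L0 = 1
C_WIDTH = 2
C_SPEED = 3
C_DT = 4
C_KB = 5
C_KS = 6
C_WA = 7
C_WS = 8
C_WT = 9
C_WNOISE = 10
C_REV_MEAN = 11
C_REV_SD = 12
C_ALIGN_MAX_RAD = 13
C_THRESHOLD = 14
C_CONTACT_DIST = 15
C_SPORE_RADIUS = 16
C_TEMP = 17
C_PROP_SD = 18
C_PROP_BUDGET = 19
C_SLIME_RES = 20
C_SLIME_DECAY = 21
C_SENSE_LEN = 22
C_SENSE_HALFW = 23
C_BIN_SIZE = 24
CFG_LEN = 25

MOTILE = 0
SPORE = 1


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def trunc_normal(mean, sd):
    """Normal variate truncated to positive values (redraw)."""
    for _ in range(100):
        x = np.random.normal(mean, sd)
        if x > 0.0:
            return x
    return mean


@njit(cache=True)
def mimg(d, domain):
    """Minimum-image convention for a coordinate difference."""
    return d - domain * math.floor(d / domain + 0.5)


@njit(cache=True)
def _point_seg_d2(px, py, ax, ay, bx, by):
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    vv = vx * vx + vy * vy
    if vv <= 1e-24:
        return wx * wx + wy * wy
    t = (wx * vx + wy * vy) / vv
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    dx = wx - t * vx
    dy = wy - t * vy
    return dx * dx + dy * dy


@njit(cache=True)
def _orient(ax, ay, bx, by, cx, cy):
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


@njit(cache=True)
def _segs_intersect(p1x, p1y, p2x, p2y, q1x, q1y, q2x, q2y):
    d1 = _orient(q1x, q1y, q2x, q2y, p1x, p1y)
    d2 = _orient(q1x, q1y, q2x, q2y, p2x, p2y)
    d3 = _orient(p1x, p1y, p2x, p2y, q1x, q1y)
    d4 = _orient(p1x, p1y, p2x, p2y, q2x, q2y)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    return False


@njit(cache=True)
def seg_seg_dist(p1x, p1y, p2x, p2y, q1x, q1y, q2x, q2y):
    """Minimum distance between two 2D segments."""
    if _segs_intersect(p1x, p1y, p2x, p2y, q1x, q1y, q2x, q2y):
        return 0.0
    d2 = _point_seg_d2(p1x, p1y, q1x, q1y, q2x, q2y)
    t = _point_seg_d2(p2x, p2y, q1x, q1y, q2x, q2y)
    if t < d2:
        d2 = t
    t = _point_seg_d2(q1x, q1y, p1x, p1y, p2x, p2y)
    if t < d2:
        d2 = t
    t = _point_seg_d2(q2x, q2y, p1x, p1y, p2x, p2y)
    if t < d2:
        d2 = t
    return math.sqrt(d2)


@njit(cache=True)
def elastic_energy_nodes(x0, y0, x1, y1, x2, y2, kb, ks, l0):
    """Harmonic bending + stretching energy of a three-node body.

    theta is the deviation-from-straight angle between the two segments.
    Returns -1.0 for a degenerate (zero-length) segment.
    """
    ax, ay = x1 - x0, y1 - y0
    bx, by = x2 - x1, y2 - y1
    la = math.hypot(ax, ay)
    lb = math.hypot(bx, by)
    if la <= 1e-12 or lb <= 1e-12:
        return -1.0
    c = (ax * bx + ay * by) / (la * lb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = math.acos(c)
    return 0.5 * kb * theta * theta + 0.5 * ks * ((la - l0) ** 2 + (lb - l0) ** 2)


@njit(cache=True)
def build_hash(pos, state, domain, bin_size):
    """Counting-sort spatial hash of body midpoints (wrapped)."""
    n = pos.shape[0]
    nb = int(math.ceil(domain / bin_size))
    if nb < 1:
        nb = 1
    start = np.zeros(nb * nb + 1, dtype=np.int64)
    binidx = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 1, 0] % domain
        y = pos[i, 1, 1] % domain
        ix = int(x / bin_size)
        iy = int(y / bin_size)
        if ix >= nb:
            ix = nb - 1
        if iy >= nb:
            iy = nb - 1
        b = ix * nb + iy
        binidx[i] = b
        start[b + 1] += 1
    for b in range(nb * nb):
        start[b + 1] += start[b]
    items = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        items[fill[binidx[i]]] = i
        fill[binidx[i]] += 1
    return nb, start, items


@njit(cache=True)
def _body_clearance(
    cand, i, pos, state, nb, start, items, domain, width, spore_radius
):
    """Min clearance of candidate body ``cand`` (3,2) of cell i to all others.

    Clearance = surface separation: pair distance minus the required contact
    distance (width for cell-cell, width/2 + spore radius for cell-spore).
    Searches +-2 hash bins around the candidate midpoint; exact within that
    radius.
    """
    best = 1e30
    bin_size = domain / nb if nb > 0 else domain
    mx = cand[1, 0] % domain
    my = cand[1, 1] % domain
    ix = int(mx / bin_size)
    iy = int(my / bin_size)
    for dxb in range(-2, 3):
        for dyb in range(-2, 3):
            bx = (ix + dxb) % nb
            by = (iy + dyb) % nb
            b = bx * nb + by
            for k in range(start[b], start[b + 1]):
                j = items[k]
                if j == i:
                    continue
                # shift j's body by minimum image of the midpoint offset
                sx = mimg(pos[j, 1, 0] - cand[1, 0], domain) - (pos[j, 1, 0] - cand[1, 0])
                sy = mimg(pos[j, 1, 1] - cand[1, 1], domain) - (pos[j, 1, 1] - cand[1, 1])
                if state[j] == SPORE:
                    px = pos[j, 1, 0] + sx
                    py = pos[j, 1, 1] + sy
                    d2a = _point_seg_d2(px, py, cand[0, 0], cand[0, 1], cand[1, 0], cand[1, 1])
                    d2b = _point_seg_d2(px, py, cand[1, 0], cand[1, 1], cand[2, 0], cand[2, 1])
                    d = math.sqrt(min(d2a, d2b)) - (0.5 * width + spore_radius)
                else:
                    d = 1e30
                    for sa in range(2):
                        for sb in range(2):
                            t = seg_seg_dist(
                                cand[sa, 0], cand[sa, 1], cand[sa + 1, 0], cand[sa + 1, 1],
                                pos[j, sb, 0] + sx, pos[j, sb, 1] + sy,
                                pos[j, sb + 1, 0] + sx, pos[j, sb + 1, 1] + sy,
                            )
                            if t < d:
                                d = t
                    d -= width
                if d < best:
                    best = d
    return best


@njit(cache=True)
def _slime_direction(hx, hy, axx, axy, slime_w, slime_vx, slime_vy, domain, res):
    """Weight-averaged trail direction near the head, sign-rectified to axis."""
    g = slime_w.shape[0]
    ix = int((hx % domain) / res)
    iy = int((hy % domain) / res)
    sx = 0.0
    sy = 0.0
    for dxb in range(-1, 2):
        for dyb in range(-1, 2):
            jx = (ix + dxb) % g
            jy = (iy + dyb) % g
            sx += slime_vx[jx, jy]
            sy += slime_vy[jx, jy]
    nrm = math.hypot(sx, sy)
    if nrm < 1e-12:
        return 0.0, 0.0
    sx /= nrm
    sy /= nrm
    if sx * axx + sy * axy < 0.0:
        sx = -sx
        sy = -sy
    return sx, sy


@njit(cache=True)
def compute_direction_kernel(
    i, pos, headend, state, slime_w, slime_vx, slime_vy, cfg,
    nb, start, items, use_noise,
):
    """Unit movement direction of motile cell i (weighted factor sum)."""
    domain = cfg[C_DOMAIN]
    h = headend[i]
    t = 2 - h
    axx = pos[i, h, 0] - pos[i, t, 0]
    axy = pos[i, h, 1] - pos[i, t, 1]
    nrm = math.hypot(axx, axy)
    if nrm < 1e-12:
        return 1.0, 0.0
    axx /= nrm
    axy /= nrm
    hx = pos[i, h, 0]
    hy = pos[i, h, 1]

    # S-motility: mean sign-rectified orientation of motile cells whose body
    # comes within SENSE_HALFW of the forward corridor segment
    sx = 0.0
    sy = 0.0
    ns = 0
    sense_len = cfg[C_SENSE_LEN]
    halfw = cfg[C_SENSE_HALFW]
    fx = hx + axx * sense_len
    fy = hy + axy * sense_len
    bin_size = domain / nb if nb > 0 else domain
    ix = int((pos[i, 1, 0] % domain) / bin_size)
    iy = int((pos[i, 1, 1] % domain) / bin_size)
    for dxb in range(-2, 3):
        for dyb in range(-2, 3):
            bx = (ix + dxb) % nb
            by = (iy + dyb) % nb
            b = bx * nb + by
            for k in range(start[b], start[b + 1]):
                j = items[k]
                if j == i or state[j] != MOTILE:
                    continue
                shx = mimg(pos[j, 1, 0] - pos[i, 1, 0], domain) - (pos[j, 1, 0] - pos[i, 1, 0])
                shy = mimg(pos[j, 1, 1] - pos[i, 1, 1], domain) - (pos[j, 1, 1] - pos[i, 1, 1])
                dmin = 1e30
                for sb in range(2):
                    d = seg_seg_dist(
                        hx, hy, fx, fy,
                        pos[j, sb, 0] + shx, pos[j, sb, 1] + shy,
                        pos[j, sb + 1, 0] + shx, pos[j, sb + 1, 1] + shy,
                    )
                    if d < dmin:
                        dmin = d
                if dmin < halfw:
                    hj = headend[j]
                    tj = 2 - hj
                    ox = pos[j, hj, 0] - pos[j, tj, 0]
                    oy = pos[j, hj, 1] - pos[j, tj, 1]
                    on = math.hypot(ox, oy)
                    if on > 1e-12:
                        ox /= on
                        oy /= on
                        if ox * axx + oy * axy < 0.0:
                            ox = -ox
                            oy = -oy
                        sx += ox
                        sy += oy
                        ns += 1
    if ns > 0:
        nrm = math.hypot(sx, sy)
        if nrm > 1e-12:
            sx /= nrm
            sy /= nrm

    tx, ty = _slime_direction(
        hx, hy, axx, axy, slime_w, slime_vx, slime_vy, domain, cfg[C_SLIME_RES]
    )

    ex = 0.0
    ey = 0.0
    if use_noise == 1 and cfg[C_WNOISE] > 0.0:
        ang = np.random.uniform(0.0, 2.0 * math.pi)
        ex = math.cos(ang)
        ey = math.sin(ang)

    dx = cfg[C_WA] * axx + cfg[C_WS] * sx + cfg[C_WT] * tx + cfg[C_WNOISE] * ex
    dy = cfg[C_WA] * axy + cfg[C_WS] * sy + cfg[C_WT] * ty + cfg[C_WNOISE] * ey
    nrm = math.hypot(dx, dy)
    if nrm < 1e-12:
        return axx, axy
    return dx / nrm, dy / nrm


@njit(cache=True)
def relax_cell_kernel(i, pos, state, cfg, nb, start, items, new_hx, new_hy, head):
    """Metropolis relaxation of the trailing nodes after a head displacement.

    Trial 0 rigidly translates the trailing nodes by the head displacement
    (zero energy change for a body at its rest shape); subsequent trials draw
    Gaussian displacements (sd = PROP_SD) about the pre-move positions.
    Candidates that deepen an overlap with any other body are rejected as
    collisions; otherwise standard Metropolis acceptance on the elastic
    energy change at temperature TEMP.  Returns 1 if a candidate was
    accepted (pos updated), 0 if the cell stalls (pos untouched).
    """
    domain = cfg[C_DOMAIN]
    width = cfg[C_WIDTH]
    srad = cfg[C_SPORE_RADIUS]
    kb = cfg[C_KB]
    ks = cfg[C_KS]
    l0 = cfg[C_L0]
    temp = cfg[C_TEMP]
    budget = int(cfg[C_PROP_BUDGET])
    sd = cfg[C_PROP_SD]

    mid = 1
    tail = 2 - head
    old = pos[i].copy()
    h_pre = elastic_energy_nodes(
        old[head, 0], old[head, 1], old[mid, 0], old[mid, 1],
        old[tail, 0], old[tail, 1], kb, ks, l0,
    )
    clear_pre = _body_clearance(old, i, pos, state, nb, start, items, domain, width, srad)
    dhx = new_hx - old[head, 0]
    dhy = new_hy - old[head, 1]

    cand = old.copy()
    cand[head, 0] = new_hx
    cand[head, 1] = new_hy
    for trial in range(budget):
        if trial == 0:
            cand[mid, 0] = old[mid, 0] + dhx
            cand[mid, 1] = old[mid, 1] + dhy
            cand[tail, 0] = old[tail, 0] + dhx
            cand[tail, 1] = old[tail, 1] + dhy
        else:
            cand[mid, 0] = old[mid, 0] + np.random.normal(0.0, sd)
            cand[mid, 1] = old[mid, 1] + np.random.normal(0.0, sd)
            cand[tail, 0] = old[tail, 0] + np.random.normal(0.0, sd)
            cand[tail, 1] = old[tail, 1] + np.random.normal(0.0, sd)
        h_c = elastic_energy_nodes(
            cand[head, 0], cand[head, 1], cand[mid, 0], cand[mid, 1],
            cand[tail, 0], cand[tail, 1], kb, ks, l0,
        )
        if h_c < 0.0:
            continue  # degenerate geometry
        clear_c = _body_clearance(cand, i, pos, state, nb, start, items, domain, width, srad)
        if clear_c < 0.0 and clear_c < clear_pre - 1e-9:
            continue  # would create or deepen an overlap
        dh = h_c - h_pre
        if dh <= 0.0 or np.random.random() < math.exp(-dh / temp):
            pos[i, 0, 0] = cand[0, 0]
            pos[i, 0, 1] = cand[0, 1]
            pos[i, 1, 0] = cand[1, 0]
            pos[i, 1, 1] = cand[1, 1]
            pos[i, 2, 0] = cand[2, 0]
            pos[i, 2, 1] = cand[2, 1]
            # keep the stored body near the primary domain image
            wx = pos[i, 1, 0] % domain - pos[i, 1, 0]
            wy = pos[i, 1, 1] % domain - pos[i, 1, 1]
            if wx != 0.0 or wy != 0.0:
                for nn in range(3):
                    pos[i, nn, 0] += wx
                    pos[i, nn, 1] += wy
            return 1
    return 0


@njit(cache=True)
def detect_contacts_kernel(pos, headend, state, cfg, nb, start, items, pairs):
    """End-to-end aligned contact pairs among motile cells.

    A pair qualifies if some end node of one body lies within CONTACT_DIST of
    an end node of the other, the acute angle between the body axes is below
    ALIGN_MAX_RAD (polarity ignored), and the midpoints are farther apart
    than one segment length (excludes side-by-side lateral contact).
    Writes (i, j) rows with i < j into ``pairs`` and returns the count.
    """
    domain = cfg[C_DOMAIN]
    cdist = cfg[C_CONTACT_DIST]
    amax = cfg[C_ALIGN_MAX_RAD]
    l0 = cfg[C_L0]
    n = pos.shape[0]
    bin_size = domain / nb if nb > 0 else domain
    cnt = 0
    maxp = pairs.shape[0]
    for i in range(n):
        if state[i] != MOTILE:
            continue
        axx = pos[i, 2, 0] - pos[i, 0, 0]
        axy = pos[i, 2, 1] - pos[i, 0, 1]
        na = math.hypot(axx, axy)
        if na < 1e-12:
            continue
        ix = int((pos[i, 1, 0] % domain) / bin_size)
        iy = int((pos[i, 1, 1] % domain) / bin_size)
        for dxb in range(-2, 3):
            for dyb in range(-2, 3):
                bx = (ix + dxb) % nb
                by = (iy + dyb) % nb
                b = bx * nb + by
                for k in range(start[b], start[b + 1]):
                    j = items[k]
                    if j <= i or state[j] != MOTILE:
                        continue
                    shx = mimg(pos[j, 1, 0] - pos[i, 1, 0], domain) - (
                        pos[j, 1, 0] - pos[i, 1, 0]
                    )
                    shy = mimg(pos[j, 1, 1] - pos[i, 1, 1], domain) - (
                        pos[j, 1, 1] - pos[i, 1, 1]
                    )
                    # midpoint separation: lateral-contact exclusion
                    mdx = pos[j, 1, 0] + shx - pos[i, 1, 0]
                    mdy = pos[j, 1, 1] + shy - pos[i, 1, 1]
                    if math.hypot(mdx, mdy) <= l0:
                        continue
                    # end-node proximity
                    near = False
                    for ea in (0, 2):
                        for eb in (0, 2):
                            ddx = pos[j, eb, 0] + shx - pos[i, ea, 0]
                            ddy = pos[j, eb, 1] + shy - pos[i, ea, 1]
                            if math.hypot(ddx, ddy) < cdist:
                                near = True
                    if not near:
                        continue
                    bxx = pos[j, 2, 0] - pos[j, 0, 0]
                    bxy = pos[j, 2, 1] - pos[j, 0, 1]
                    nb2 = math.hypot(bxx, bxy)
                    if nb2 < 1e-12:
                        continue
                    cosang = abs((axx * bxx + axy * bxy) / (na * nb2))
                    if cosang > 1.0:
                        cosang = 1.0
                    if math.acos(cosang) < amax:
                        if cnt < maxp:
                            pairs[cnt, 0] = i
                            pairs[cnt, 1] = j
                        cnt += 1
    return cnt


@njit(cache=True)
def _deposit_slime(i, pos, headend, slime_w, slime_vx, slime_vy, domain, res):
    """Deposit the cell's orientation with unit weight under its body."""
    g = slime_w.shape[0]
    h = headend[i]
    t = 2 - h
    ox = pos[i, h, 0] - pos[i, t, 0]
    oy = pos[i, h, 1] - pos[i, t, 1]
    nrm = math.hypot(ox, oy)
    if nrm < 1e-12:
        return
    ox /= nrm
    oy /= nrm
    # five samples: nodes and segment midpoints
    for s in range(5):
        f = s / 4.0
        if f <= 0.5:
            xx = pos[i, 0, 0] + (pos[i, 1, 0] - pos[i, 0, 0]) * (f * 2.0)
            yy = pos[i, 0, 1] + (pos[i, 1, 1] - pos[i, 0, 1]) * (f * 2.0)
        else:
            xx = pos[i, 1, 0] + (pos[i, 2, 0] - pos[i, 1, 0]) * ((f - 0.5) * 2.0)
            yy = pos[i, 1, 1] + (pos[i, 2, 1] - pos[i, 1, 1]) * ((f - 0.5) * 2.0)
        jx = int((xx % domain) / res) % g
        jy = int((yy % domain) / res) % g
        slime_w[jx, jy] += 1.0
        # nematic deposit: align stored vector with the new contribution
        if slime_vx[jx, jy] * ox + slime_vy[jx, jy] * oy < 0.0:
            slime_vx[jx, jy] -= ox
            slime_vy[jx, jy] -= oy
        else:
            slime_vx[jx, jy] += ox
            slime_vy[jx, jy] += oy


@njit(cache=True)
def step_kernel(
    pos, headend, state, counter, next_rev, conv_step,
    slime_w, slime_vx, slime_vy, cfg, t_now, step_idx, pairs_buf,
):
    """One full simulation step; returns (n_contacts, n_new_spores, n_stalled).

    Phases: per-cell (shuffled order) reversal -> direction -> head move ->
    Metropolis relaxation -> slime deposit; then one contact-detection and
    signaling/sporulation pass; then slime decay.
    """
    n = pos.shape[0]
    domain = cfg[C_DOMAIN]
    vdt = cfg[C_SPEED] * cfg[C_DT]
    res = cfg[C_SLIME_RES]

    nb, start, items = build_hash(pos, state, domain, cfg[C_BIN_SIZE])
    order = np.arange(n)
    np.random.shuffle(order)
    n_stalled = 0
    for oi in range(n):
        i = order[oi]
        if state[i] != MOTILE:
            continue
        if t_now >= next_rev[i]:
            headend[i] = 2 - headend[i]
            next_rev[i] = next_rev[i] + trunc_normal(cfg[C_REV_MEAN], cfg[C_REV_SD])
        dx, dy = compute_direction_kernel(
            i, pos, headend, state, slime_w, slime_vx, slime_vy, cfg,
            nb, start, items, 1,
        )
        h = headend[i]
        new_hx = pos[i, h, 0] + vdt * dx
        new_hy = pos[i, h, 1] + vdt * dy
        ok = relax_cell_kernel(i, pos, state, cfg, nb, start, items, new_hx, new_hy, h)
        if ok == 0:
            n_stalled += 1
        _deposit_slime(i, pos, headend, slime_w, slime_vx, slime_vy, domain, res)

    # signaling: one increment per eligible pair per step
    nb, start, items = build_hash(pos, state, domain, cfg[C_BIN_SIZE])
    ncont = detect_contacts_kernel(pos, headend, state, cfg, nb, start, items, pairs_buf)
    m = min(ncont, pairs_buf.shape[0])
    for k in range(m):
        counter[pairs_buf[k, 0]] += 1
        counter[pairs_buf[k, 1]] += 1
    threshold = cfg[C_THRESHOLD]
    n_new = 0
    for i in range(n):
        if state[i] == MOTILE and counter[i] >= threshold:
            state[i] = SPORE
            mx = pos[i, 1, 0] % domain
            my = pos[i, 1, 1] % domain
            for nn in range(3):
                pos[i, nn, 0] = mx
                pos[i, nn, 1] = my
            conv_step[i] = step_idx
            n_new += 1

    decay = cfg[C_SLIME_DECAY]
    g = slime_w.shape[0]
    for a in range(g):
        for b in range(g):
            slime_w[a, b] *= decay
            slime_vx[a, b] *= decay
            slime_vy[a, b] *= decay
    return ncont, n_new, n_stalled
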