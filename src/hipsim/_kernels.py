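"""Low-level numba kernels: triangle primitives and AABB-tree queries.

Everything here operates on raw float64 arrays and scalar tuples so the
hot loops (pose sweeps run thousands of contact queries) stay
allocation-free.  The public surface lives in :mod:`hipsim.mesh_core`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# scalar triangle primitives (tuple in / tuple out, no heap allocation)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _cpt_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest point on triangle abc to point p (Ericson, RTCD 5.1.5)."""
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    acx = cx - ax
    acy = cy - ay
    acz = cz - az
    apx = px - ax
    apy = py - ay
    apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx = px - bx
    bpy = py - by
    bpz = pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return ax + v * abx, ay + v * aby, az + v * abz
    cpx = px - cx
    cpy = py - cy
    cpz = pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return ax + w * acx, ay + w * acy, az + w * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return bx + w * (cx - bx), by + w * (cy - by), bz + w * (cz - bz)
    if va + vb + vc == 0.0:  # degenerate (collinear) triangle
        return ax, ay, az
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (
        ax + abx * v + acx * w,
        ay + aby * v + acy * w,
        az + abz * v + acz * w,
    )


@njit(cache=True, fastmath=False)
def _css(p1x, p1y, p1z, q1x, q1y, q1z, p2x, p2y, p2z, q2x, q2y, q2z):
    """Closest points between two segments (RTCD 5.1.9)."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d1z = q1z - p1z
    d2x = q2x - p2x
    d2y = q2y - p2y
    d2z = q2z - p2z
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    eps = 1e-14
    if a <= eps and e <= eps:
        s = 0.0
        t = 0.0
    elif a <= eps:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > eps:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    return (
        p1x + s * d1x,
        p1y + s * d1y,
        p1z + s * d1z,
        p2x + t * d2x,
        p2y + t * d2y,
        p2z + t * d2z,
    )


@njit(cache=True, fastmath=False)
def _tri_tri_closest(
    a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
    b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z,
):
    """Feature-based closest points of two triangles.

    Minimum over the 9 edge-edge and 6 vertex-face candidates.  For
    *disjoint* triangles this is the exact closest-point pair; crossing
    triangles (which may have positive feature distance) are detected
    separately by :func:`_tri_tri_intersect`.

    Returns (squared distance, p1x, p1y, p1z, p2x, p2y, p2z).
    """
    best = 1e300
    r1x = a0x
    r1y = a0y
    r1z = a0z
    r2x = b0x
    r2y = b0y
    r2z = b0z
    # edge-edge candidates
    for i in range(3):
        if i == 0:
            e1ax, e1ay, e1az, e1bx, e1by, e1bz = a0x, a0y, a0z, a1x, a1y, a1z
        elif i == 1:
            e1ax, e1ay, e1az, e1bx, e1by, e1bz = a1x, a1y, a1z, a2x, a2y, a2z
        else:
            e1ax, e1ay, e1az, e1bx, e1by, e1bz = a2x, a2y, a2z, a0x, a0y, a0z
        for j in range(3):
            if j == 0:
                e2ax, e2ay, e2az, e2bx, e2by, e2bz = b0x, b0y, b0z, b1x, b1y, b1z
            elif j == 1:
                e2ax, e2ay, e2az, e2bx, e2by, e2bz = b1x, b1y, b1z, b2x, b2y, b2z
            else:
                e2ax, e2ay, e2az, e2bx, e2by, e2bz = b2x, b2y, b2z, b0x, b0y, b0z
            c1x, c1y, c1z, c2x, c2y, c2z = _css(
                e1ax, e1ay, e1az, e1bx, e1by, e1bz,
                e2ax, e2ay, e2az, e2bx, e2by, e2bz,
            )
            dx = c1x - c2x
            dy = c1y - c2y
            dz = c1z - c2z
            dd = dx * dx + dy * dy + dz * dz
            if dd < best:
                best = dd
                r1x, r1y, r1z, r2x, r2y, r2z = c1x, c1y, c1z, c2x, c2y, c2z
    # vertices of A against B
    for i in range(3):
        if i == 0:
            px, py, pz = a0x, a0y, a0z
        elif i == 1:
            px, py, pz = a1x, a1y, a1z
        else:
            px, py, pz = a2x, a2y, a2z
        qx, qy, qz = _cpt_tri(px, py, pz, b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z)
        dx = px - qx
        dy = py - qy
        dz = pz - qz
        dd = dx * dx + dy * dy + dz * dz
        if dd < best:
            best = dd
            r1x, r1y, r1z, r2x, r2y, r2z = px, py, pz, qx, qy, qz
    # vertices of B against A
    for j in range(3):
        if j == 0:
            px, py, pz = b0x, b0y, b0z
        elif j == 1:
            px, py, pz = b1x, b1y, b1z
        else:
            px, py, pz = b2x, b2y, b2z
        qx, qy, qz = _cpt_tri(px, py, pz, a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z)
        dx = qx - px
        dy = qy - py
        dz = qz - pz
        dd = dx * dx + dy * dy + dz * dz
        if dd < best:
            best = dd
            r1x, r1y, r1z, r2x, r2y, r2z = qx, qy, qz, px, py, pz
    return best, r1x, r1y, r1z, r2x, r2y, r2z


# ---------------------------------------------------------------------------
# triangle-triangle intersection (touching counts)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _orient2d(ax, ay, bx, by, cx, cy):
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


@njit(cache=True, fastmath=False)
def _seg_seg_2d(p1x, p1y, p2x, p2y, q1x, q1y, q2x, q2y):
    d1 = _orient2d(q1x, q1y, q2x, q2y, p1x, p1y)
    d2 = _orient2d(q1x, q1y, q2x, q2y, p2x, p2y)
    d3 = _orient2d(p1x, p1y, p2x, p2y, q1x, q1y)
    d4 = _orient2d(p1x, p1y, p2x, p2y, q2x, q2y)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    if (
        d1 == 0.0
        and min(q1x, q2x) <= p1x <= max(q1x, q2x)
        and min(q1y, q2y) <= p1y <= max(q1y, q2y)
    ):
        return True
    if (
        d2 == 0.0
        and min(q1x, q2x) <= p2x <= max(q1x, q2x)
        and min(q1y, q2y) <= p2y <= max(q1y, q2y)
    ):
        return True
    if (
        d3 == 0.0
        and min(p1x, p2x) <= q1x <= max(p1x, p2x)
        and min(p1y, p2y) <= q1y <= max(p1y, p2y)
    ):
        return True
    if (
        d4 == 0.0
        and min(p1x, p2x) <= q2x <= max(p1x, p2x)
        and min(p1y, p2y) <= q2y <= max(p1y, p2y)
    ):
        return True
    return False


@njit(cache=True, fastmath=False)
def _point_in_tri_2d(px, py, ax, ay, bx, by, cx, cy):
    d1 = _orient2d(ax, ay, bx, by, px, py)
    d2 = _orient2d(bx, by, cx, cy, px, py)
    d3 = _orient2d(cx, cy, ax, ay, px, py)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


@njit(cache=True, fastmath=False)
def _seg_tri_cross(
    ax, ay, az, bx, by, bz,
    p0x, p0y, p0z, p1x, p1y, p1z, p2x, p2y, p2z,
    nx, ny, nz,
):
    """Does segment a-b cross triangle p0p1p2 (normal n)?  Touching counts.

    Segments (near) parallel to the plane are ignored; coplanar contact
    is handled by the coplanar branch of :func:`_tri_tri_intersect`.
    """
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    denom = nx * abx + ny * aby + nz * abz
    if abs(denom) < 1e-14:
        return False
    t = (nx * (p0x - ax) + ny * (p0y - ay) + nz * (p0z - az)) / denom
    if t < 0.0 or t > 1.0:
        return False
    xx = ax + t * abx
    xy = ay + t * aby
    xz = az + t * abz
    v0x = p1x - p0x
    v0y = p1y - p0y
    v0z = p1z - p0z
    v1x = p2x - p0x
    v1y = p2y - p0y
    v1z = p2z - p0z
    v2x = xx - p0x
    v2y = xy - p0y
    v2z = xz - p0z
    d00 = v0x * v0x + v0y * v0y + v0z * v0z
    d01 = v0x * v1x + v0y * v1y + v0z * v1z
    d11 = v1x * v1x + v1y * v1y + v1z * v1z
    d20 = v2x * v0x + v2y * v0y + v2z * v0z
    d21 = v2x * v1x + v2y * v1y + v2z * v1z
    den = d00 * d11 - d01 * d01
    if abs(den) < 1e-300:
        return False
    u = (d11 * d20 - d01 * d21) / den
    v = (d00 * d21 - d01 * d20) / den
    eps = -1e-12
    return u >= eps and v >= eps and (u + v) <= 1.0 - eps


@njit(cache=True, fastmath=False)
def _tri_tri_intersect(
    a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
    b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z,
):
    """Do two triangles intersect (touching counts)?"""
    # normals
    n1x = (a1y - a0y) * (a2z - a0z) - (a1z - a0z) * (a2y - a0y)
    n1y = (a1z - a0z) * (a2x - a0x) - (a1x - a0x) * (a2z - a0z)
    n1z = (a1x - a0x) * (a2y - a0y) - (a1y - a0y) * (a2x - a0x)
    n2x = (b1y - b0y) * (b2z - b0z) - (b1z - b0z) * (b2y - b0y)
    n2y = (b1z - b0z) * (b2x - b0x) - (b1x - b0x) * (b2z - b0z)
    n2z = (b1x - b0x) * (b2y - b0y) - (b1y - b0y) * (b2x - b0x)
    # plane rejection: A against plane of B
    s0 = n2x * (a0x - b0x) + n2y * (a0y - b0y) + n2z * (a0z - b0z)
    s1 = n2x * (a1x - b0x) + n2y * (a1y - b0y) + n2z * (a1z - b0z)
    s2 = n2x * (a2x - b0x) + n2y * (a2y - b0y) + n2z * (a2z - b0z)
    if (s0 > 0 and s1 > 0 and s2 > 0) or (s0 < 0 and s1 < 0 and s2 < 0):
        return False
    u0 = n1x * (b0x - a0x) + n1y * (b0y - a0y) + n1z * (b0z - a0z)
    u1 = n1x * (b1x - a0x) + n1y * (b1y - a0y) + n1z * (b1z - a0z)
    u2 = n1x * (b2x - a0x) + n1y * (b2y - a0y) + n1z * (b2z - a0z)
    if (u0 > 0 and u1 > 0 and u2 > 0) or (u0 < 0 and u1 < 0 and u2 < 0):
        return False
    nn2 = abs(n2x) + abs(n2y) + abs(n2z)
    diag = abs(a0x - b0x) + abs(a0y - b0y) + abs(a0z - b0z) + 1.0
    if abs(s0) + abs(s1) + abs(s2) <= 1e-12 * nn2 * diag:
        # coplanar: 2D overlap after projecting out the dominant axis
        axn = abs(n2x)
        ayn = abs(n2y)
        azn = abs(n2z)
        if axn >= ayn and axn >= azn:
            t1 = (a0y, a0z, a1y, a1z, a2y, a2z)
            t2 = (b0y, b0z, b1y, b1z, b2y, b2z)
        elif ayn >= azn:
            t1 = (a0x, a0z, a1x, a1z, a2x, a2z)
            t2 = (b0x, b0z, b1x, b1z, b2x, b2z)
        else:
            t1 = (a0x, a0y, a1x, a1y, a2x, a2y)
            t2 = (b0x, b0y, b1x, b1y, b2x, b2y)
        for i in range(3):
            i2 = (i + 1) % 3
            for j in range(3):
                j2 = (j + 1) % 3
                if _seg_seg_2d(
                    t1[2 * i], t1[2 * i + 1], t1[2 * i2], t1[2 * i2 + 1],
                    t2[2 * j], t2[2 * j + 1], t2[2 * j2], t2[2 * j2 + 1],
                ):
                    return True
        if _point_in_tri_2d(t1[0], t1[1], t2[0], t2[1], t2[2], t2[3], t2[4], t2[5]):
            return True
        if _point_in_tri_2d(t2[0], t2[1], t1[0], t1[1], t1[2], t1[3], t1[4], t1[5]):
            return True
        return False
    # general position: edge-through-triangle both ways
    for i in range(3):
        if i == 0:
            e0x, e0y, e0z, e1x, e1y, e1z = a0x, a0y, a0z, a1x, a1y, a1z
            f0x, f0y, f0z, f1x, f1y, f1z = b0x, b0y, b0z, b1x, b1y, b1z
        elif i == 1:
            e0x, e0y, e0z, e1x, e1y, e1z = a1x, a1y, a1z, a2x, a2y, a2z
            f0x, f0y, f0z, f1x, f1y, f1z = b1x, b1y, b1z, b2x, b2y, b2z
        else:
            e0x, e0y, e0z, e1x, e1y, e1z = a2x, a2y, a2z, a0x, a0y, a0z
            f0x, f0y, f0z, f1x, f1y, f1z = b2x, b2y, b2z, b0x, b0y, b0z
        if _seg_tri_cross(
            e0x, e0y, e0z, e1x, e1y, e1z,
            b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z,
            n2x, n2y, n2z,
        ):
            return True
        if _seg_tri_cross(
            f0x, f0y, f0z, f1x, f1y, f1z,
            a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
            n1x, n1y, n1z,
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# AABB tree (flat arrays, parent stored before children)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _refit(nmin, nmax, left, right, start, count, order, tris):
    """Recompute node boxes bottom-up for current triangle coordinates."""
    n = nmin.shape[0]
    for k in range(n - 1, -1, -1):
        if count[k] > 0:  # leaf
            for d in range(3):
                nmin[k, d] = 1e300
                nmax[k, d] = -1e300
            for t in range(start[k], start[k] + count[k]):
                f = order[t]
                for v in range(3):
                    for d in range(3):
                        x = tris[f, v, d]
                        if x < nmin[k, d]:
                            nmin[k, d] = x
                        if x > nmax[k, d]:
                            nmax[k, d] = x
        else:
            l = left[k]
            r = right[k]
            for d in range(3):
                nmin[k, d] = min(nmin[l, d], nmin[r, d])
                nmax[k, d] = max(nmax[l, d], nmax[r, d])


@njit(cache=True, fastmath=False)
def _aabb_dist2(aminA, amaxA, aminB, amaxB, ia, ib, off):
    d2 = 0.0
    for k in range(3):
        lo_a = aminA[ia, k]
        hi_a = amaxA[ia, k]
        lo_b = aminB[ib, k] + off[k]
        hi_b = amaxB[ib, k] + off[k]
        if hi_a < lo_b:
            g = lo_b - hi_a
            d2 += g * g
        elif hi_b < lo_a:
            g = lo_a - hi_b
            d2 += g * g
    return d2


@njit(cache=True, fastmath=False)
def _pair_query(
    aminA, amaxA, leftA, rightA, startA, countA, orderA, trisA,
    aminB, amaxB, leftB, rightB, startB, countB, orderB, trisB,
    off, collect_tol, dcap, pi, pj, pd, xi, xj,
):
    """Dual-tree contact traversal.

    Triangles of B are translated by ``off`` on the fly.  ``dcap`` caps
    the reported separation distance: the search never explores beyond
    max(collect_tol, dcap), so the returned distance equals the true
    minimum only when that is below the cap (pass a huge dcap for the
    exact distance).  Close pairs (feature distance <= collect_tol) go
    into pi/pj/pd; crossing pairs into xi/xj.

    Returns (min_distance, best_i, best_j, n_close, n_cross, overflow).
    """
    best = dcap * dcap
    bi = -1
    bj = -1
    n_close = 0
    n_x = 0
    overflow = 0
    cap_close = pi.shape[0]
    cap_x = xi.shape[0]
    tol2 = collect_tol * collect_tol
    ox = off[0]
    oy = off[1]
    oz = off[2]

    stack = np.empty((4096, 2), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        ia = stack[sp, 0]
        ib = stack[sp, 1]
        d2 = _aabb_dist2(aminA, amaxA, aminB, amaxB, ia, ib, off)
        bound = best if best > tol2 else tol2
        if d2 > bound:
            continue
        leafA = countA[ia] > 0
        leafB = countB[ib] > 0
        if leafA and leafB:
            for ti in range(startA[ia], startA[ia] + countA[ia]):
                fi = orderA[ti]
                a0x = trisA[fi, 0, 0]
                a0y = trisA[fi, 0, 1]
                a0z = trisA[fi, 0, 2]
                a1x = trisA[fi, 1, 0]
                a1y = trisA[fi, 1, 1]
                a1z = trisA[fi, 1, 2]
                a2x = trisA[fi, 2, 0]
                a2y = trisA[fi, 2, 1]
                a2z = trisA[fi, 2, 2]
                alox = min(a0x, min(a1x, a2x))
                ahix = max(a0x, max(a1x, a2x))
                aloy = min(a0y, min(a1y, a2y))
                ahiy = max(a0y, max(a1y, a2y))
                aloz = min(a0z, min(a1z, a2z))
                ahiz = max(a0z, max(a1z, a2z))
                for tj in range(startB[ib], startB[ib] + countB[ib]):
                    fj = orderB[tj]
                    b0x = trisB[fj, 0, 0] + ox
                    b0y = trisB[fj, 0, 1] + oy
                    b0z = trisB[fj, 0, 2] + oz
                    b1x = trisB[fj, 1, 0] + ox
                    b1y = trisB[fj, 1, 1] + oy
                    b1z = trisB[fj, 1, 2] + oz
                    b2x = trisB[fj, 2, 0] + ox
                    b2y = trisB[fj, 2, 1] + oy
                    b2z = trisB[fj, 2, 2] + oz
                    # per-pair box rejection
                    blox = min(b0x, min(b1x, b2x))
                    bhix = max(b0x, max(b1x, b2x))
                    bloy = min(b0y, min(b1y, b2y))
                    bhiy = max(b0y, max(b1y, b2y))
                    bloz = min(b0z, min(b1z, b2z))
                    bhiz = max(b0z, max(b1z, b2z))
                    g = 0.0
                    if ahix < blox:
                        g += (blox - ahix) * (blox - ahix)
                    elif bhix < alox:
                        g += (alox - bhix) * (alox - bhix)
                    if ahiy < bloy:
                        g += (bloy - ahiy) * (bloy - ahiy)
                    elif bhiy < aloy:
                        g += (aloy - bhiy) * (aloy - bhiy)
                    if ahiz < bloz:
                        g += (bloz - ahiz) * (bloz - ahiz)
                    elif bhiz < aloz:
                        g += (aloz - bhiz) * (aloz - bhiz)
                    bound = best if best > tol2 else tol2
                    if g > bound:
                        continue
                    dd, _p, _q, _r, _s, _t, _u = _tri_tri_closest(
                        a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                        b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z,
                    )
                    if dd < best:
                        best = dd
                        bi = fi
                        bj = fj
                    if dd <= tol2:
                        if n_close < cap_close:
                            pi[n_close] = fi
                            pj[n_close] = fj
                            pd[n_close] = np.sqrt(dd)
                            n_close += 1
                        else:
                            overflow = 1
                    if g == 0.0:
                        # overlapping boxes: run the exact crossing test
                        if _tri_tri_intersect(
                            a0x, a0y, a0z, a1x, a1y, a1z, a2x, a2y, a2z,
                            b0x, b0y, b0z, b1x, b1y, b1z, b2x, b2y, b2z,
                        ):
                            if n_x < cap_x:
                                xi[n_x] = fi
                                xj[n_x] = fj
                                n_x += 1
                            else:
                                overflow = 1
                            best = 0.0
                            bi = fi
                            bj = fj
            continue
        descend_a = not leafA
        if descend_a and not leafB:
            ea = 0.0
            eb = 0.0
            for k in range(3):
                ea += amaxA[ia, k] - aminA[ia, k]
                eb += amaxB[ib, k] - aminB[ib, k]
            descend_a = ea >= eb
        if sp > 4090:
            overflow = 1
            continue
        if descend_a:
            stack[sp, 0] = leftA[ia]
            stack[sp, 1] = ib
            sp += 1
            stack[sp, 0] = rightA[ia]
            stack[sp, 1] = ib
            sp += 1
        else:
            stack[sp, 0] = ia
            stack[sp, 1] = leftB[ib]
            sp += 1
            stack[sp, 0] = ia
            stack[sp, 1] = rightB[ib]
            sp += 1
    return np.sqrt(best), bi, bj, n_close, n_x, overflow


@njit(cache=True, fastmath=False)
def _points_query(points, amin, amax, left, right, start, count, order, tris):
    """Unsigned distance, closest point and face index for each query point."""
    npts = points.shape[0]
    dist = np.empty(npts)
    closest = np.empty((npts, 3))
    fidx = np.empty(npts, np.int64)
    stack = np.empty(1024, np.int64)
    for q in range(npts):
        px = points[q, 0]
        py = points[q, 1]
        pz = points[q, 2]
        best = 1e300
        bf = -1
        bx = 0.0
        by = 0.0
        bz = 0.0
        stack[0] = 0
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack[sp]
            d2 = 0.0
            for k in range(3):
                v = points[q, k]
                if v < amin[node, k]:
                    g = amin[node, k] - v
                    d2 += g * g
                elif v > amax[node, k]:
                    g = v - amax[node, k]
                    d2 += g * g
            if d2 > best:
                continue
            if count[node] > 0:
                for t in range(start[node], start[node] + count[node]):
                    f = order[t]
                    cx, cy, cz = _cpt_tri(
                        px, py, pz,
                        tris[f, 0, 0], tris[f, 0, 1], tris[f, 0, 2],
                        tris[f, 1, 0], tris[f, 1, 1], tris[f, 1, 2],
                        tris[f, 2, 0], tris[f, 2, 1], tris[f, 2, 2],
                    )
                    dx = px - cx
                    dy = py - cy
                    dz = pz - cz
                    dd = dx * dx + dy * dy + dz * dz
                    if dd < best:
                        best = dd
                        bf = f
                        bx = cx
                        by = cy
                        bz = cz
            else:
                stack[sp] = left[node]
                sp += 1
                stack[sp] = right[node]
                sp += 1
        dist[q] = np.sqrt(best)
        closest[q, 0] = bx
        closest[q, 1] = by
        closest[q, 2] = bz
        fidx[q] = bf
    return dist, closest, fidx


@njit(cache=True, fastmath=False)
def _brute_min_distance(trisA, trisB):
    """Exhaustive all-pairs feature distance (test oracle for small meshes)."""
    best = 1e300
    for i in range(trisA.shape[0]):
        for j in range(trisB.shape[0]):
            dd = _tri_tri_closest(
                trisA[i, 0, 0], trisA[i, 0, 1], trisA[i, 0, 2],
                trisA[i, 1, 0], trisA[i, 1, 1], trisA[i, 1, 2],
                trisA[i, 2, 0], trisA[i, 2, 1], trisA[i, 2, 2],
                trisB[j, 0, 0], trisB[j, 0, 1], trisB[j, 0, 2],
                trisB[j, 1, 0], trisB[j, 1, 1], trisB[j, 1, 2],
                trisB[j, 2, 0], trisB[j, 2, 1], trisB[j, 2, 2],
            )[0]
            if dd < best:
                best = dd
    return np.sqrt(best)


@njit(cache=True, fastmath=False)
def _winding_numbers(points, tris):
    """Generalized winding number of each point w.r.t. a triangle soup.

    Sum of signed solid angles (van Oosterom & Strackee) over faces,
    divided by 4*pi.  ~1 inside a closed outward-wound surface, ~0
    outside; robust to the query point being near (not on) the surface.
    """
    npts = points.shape[0]
    nf = tris.shape[0]
    w = np.zeros(npts)
    for q in range(npts):
        px = points[q, 0]
        py = points[q, 1]
        pz = points[q, 2]
        total = 0.0
        for f in range(nf):
            ax = tris[f, 0, 0] - px
            ay = tris[f, 0, 1] - py
            az = tris[f, 0, 2] - pz
            bx = tris[f, 1, 0] - px
            by = tris[f, 1, 1] - py
            bz = tris[f, 1, 2] - pz
            cx = tris[f, 2, 0] - px
            cy = tris[f, 2, 1] - py
            cz = tris[f, 2, 2] - pz
            la = np.sqrt(ax * ax + ay * ay + az * az)
            lb = np.sqrt(bx * bx + by * by + bz * bz)
            lc = np.sqrt(cx * cx + cy * cy + cz * cz)
            det = (
                ax * (by * cz - bz * cy)
                - ay * (bx * cz - bz * cx)
                + az * (bx * cy - by * cx)
            )
            ab = ax * bx + ay * by + az * bz
            bc = bx * cx + by * cy + bz * cz
            ca = cx * ax + cy * ay + cz * az
            denom = la * lb * lc + ab * lc + bc * la + ca * lb
            total += 2.0 * np.arctan2(det, denom)
        w[q] = total / (4.0 * np.pi)
    return w


def build_bvh(tris: np.ndarray, leaf_size: int = 4):
    """Build a flat AABB tree over triangles (n, 3, 3).

    Median split on the longest centroid axis.  Returns a dict of flat
    arrays with parents stored before children (so a reverse scan is a
    valid bottom-up order for refitting).
    """
    n = tris.shape[0]
    if n == 0:
        raise ValueError("cannot build a BVH over zero triangles")
    centroids = tris.mean(axis=1)
    order = np.arange(n, dtype=np.int64)

    nmin_l, nmax_l, left_l, right_l, start_l, count_l = [], [], [], [], [], []

    def new_node():
        left_l.append(-1)
        right_l.append(-1)
        start_l.append(-1)
        count_l.append(0)
        return len(left_l) - 1

    root = new_node()
    work = [(root, 0, n)]
    while work:
        node, lo, hi = work.pop()
        if hi - lo <= leaf_size:
            start_l[node] = lo
            count_l[node] = hi - lo
            continue
        cen = centroids[order[lo:hi]]
        ext = cen.max(axis=0) - cen.min(axis=0)
        axis = int(np.argmax(ext))
        mid = (lo + hi) // 2
        sel = np.argpartition(cen[:, axis], mid - lo)
        order[lo:hi] = order[lo:hi][sel]
        l_id = new_node()
        r_id = new_node()
        left_l[node] = l_id
        right_l[node] = r_id
        work.append((l_id, lo, mid))
        work.append((r_id, mid, hi))

    m = len(left_l)
    bvh = {
        "nmin": np.empty((m, 3)),
        "nmax": np.empty((m, 3)),
        "left": np.array(left_l, dtype=np.int64),
        "right": np.array(right_l, dtype=np.int64),
        "start": np.array(start_l, dtype=np.int64),
        "count": np.array(count_l, dtype=np.int64),
        "order": order,
        "tris": np.ascontiguousarray(tris.astype(np.float64)),
    }
    _refit(bvh["nmin"], bvh["nmax"], bvh["left"], bvh["right"],
           bvh["start"], bvh["count"], bvh["order"], bvh["tris"])
    return bvh
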