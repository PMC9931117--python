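"""Numba-compiled geometric kernels shared by the public geometry API and the simulator.

Everything here works on raw float64 arrays; unit vectors are length-3 arrays
with Euclidean norm 1, caps are (center, theta) pairs with theta the angular
radius in radians.  The public wrappers in :mod:`ambiflock.sphere_geometry`
add validation and dataclass packaging.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _norm3(v):
    return np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


@njit(cache=True)
def _unit3(v):
    out = np.empty(3)
    n = _norm3(v)
    if n < _EPS:
        out[0] = 1.0
        out[1] = 0.0
        out[2] = 0.0
        return out
    out[0] = v[0] / n
    out[1] = v[1] / n
    out[2] = v[2] / n
    return out


@njit(cache=True)
def _dot3(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _cross3(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _angle3(a, b):
    d = _dot3(a, b)
    if d > 1.0:
        d = 1.0
    elif d < -1.0:
        d = -1.0
    return np.arccos(d)


@njit(cache=True)
def _perp3(a):
    """Deterministic unit vector perpendicular to ``a`` (smallest-|component| basis axis, orthogonalized)."""
    k = 0
    best = abs(a[0])
    if abs(a[1]) < best:
        k = 1
        best = abs(a[1])
    if abs(a[2]) < best:
        k = 2
    e = np.zeros(3)
    e[k] = 1.0
    d = _dot3(e, a)
    out = np.empty(3)
    out[0] = e[0] - d * a[0]
    out[1] = e[1] - d * a[1]
    out[2] = e[2] - d * a[2]
    return _unit3(out)


@njit(cache=True)
def _perp3_s(ax, ay, az):
    """Scalar form of :func:`_perp3`."""
    k = 0
    best = abs(ax)
    if abs(ay) < best:
        k = 1
        best = abs(ay)
    if abs(az) < best:
        k = 2
    ex = 1.0 if k == 0 else 0.0
    ey = 1.0 if k == 1 else 0.0
    ez = 1.0 if k == 2 else 0.0
    d = ex * ax + ey * ay + ez * az
    ox = ex - d * ax
    oy = ey - d * ay
    oz = ez - d * az
    nm = np.sqrt(ox * ox + oy * oy + oz * oz)
    return ox / nm, oy / nm, oz / nm


@njit(cache=True)
def _rodrigues(axis, angle, v):
    """Rotate ``v`` by ``angle`` about unit ``axis``."""
    c = np.cos(angle)
    s = np.sin(angle)
    kxv = _cross3(axis, v)
    kdv = _dot3(axis, v)
    out = np.empty(3)
    for d in range(3):
        out[d] = v[d] * c + kxv[d] * s + axis[d] * kdv * (1.0 - c)
    return out


# ---------------------------------------------------------------------------
# Minimal enclosing spherical cap (Welzl-style incremental + brute fallback)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cap_two_cos(a, b):
    """Smallest cap with both points on its boundary: geodesic-midpoint center.
    Returns (center, cos_theta)."""
    m = np.empty(3)
    m[0] = a[0] + b[0]
    m[1] = a[1] + b[1]
    m[2] = a[2] + b[2]
    n = _norm3(m)
    if n < 1e-9:
        # antipodal pair: any perpendicular axis works; pick deterministically
        c = _perp3(a)
        return c, 0.0
    c = np.empty(3)
    c[0] = m[0] / n
    c[1] = m[1] / n
    c[2] = m[2] / n
    return c, _dot3(c, a)


@njit(cache=True)
def _cap_three_cos(a, b, c):
    """Cap whose boundary passes through three points; smaller-theta sign.
    Returns (center, cos_theta)."""
    u = np.empty(3)
    v = np.empty(3)
    for d in range(3):
        u[d] = b[d] - a[d]
        v[d] = c[d] - a[d]
    n = _cross3(u, v)
    nn = _norm3(n)
    if nn < 1e-12:
        # (near-)collinear on the sphere: fall back to widest pair cap
        cab, tab = _cap_two_cos(a, b)
        cac, tac = _cap_two_cos(a, c)
        cbc, tbc = _cap_two_cos(b, c)
        if tab <= tac and tab <= tbc:
            return cab, tab
        if tac <= tbc:
            return cac, tac
        return cbc, tbc
    ctr = np.empty(3)
    ctr[0] = n[0] / nn
    ctr[1] = n[1] / nn
    ctr[2] = n[2] / nn
    if _dot3(ctr, a) < 0.0:
        ctr[0] = -ctr[0]
        ctr[1] = -ctr[1]
        ctr[2] = -ctr[2]
    return ctr, _dot3(ctr, a)


@njit(cache=True)
def _contains(center, theta, p, tol):
    return _angle3(center, p) <= theta + tol


@njit(cache=True)
def _check_better(pts, cx, cy, cz, ccos, best_cos, best_cx, best_cy, best_cz):
    """If candidate (c, ccos) covers all points and is smaller than the current
    best, adopt it.  Returns the (possibly updated) best tuple."""
    if ccos <= best_cos:  # candidate not smaller than current best
        return best_cos, best_cx, best_cy, best_cz
    thr = ccos - 1e-10
    for p in range(pts.shape[0]):
        if cx * pts[p, 0] + cy * pts[p, 1] + cz * pts[p, 2] < thr:
            return best_cos, best_cx, best_cy, best_cz
    return ccos, cx, cy, cz


@njit(cache=True)
def _brute_cap(pts):
    """Exhaustive candidate enumeration over boundary-support sets of size <= 3.

    The minimal enclosing cap always has a support set of at most three
    points on its boundary, so scanning pair midpoints (both orientations)
    and triple circumcenters (both signs) and keeping the smallest covering
    candidate is exact.  Used for point sets spreading beyond a hemisphere,
    where the incremental scan can fail.  Allocation-free scalar arithmetic:
    this runs in the simulator's inner loop.
    """
    n = pts.shape[0]
    if n == 1:
        return pts[0].copy(), 0.0
    best_cos = -2.0  # cos(theta) of best covering cap so far (larger = smaller cap)
    bx = 0.0
    by = 0.0
    bz = 1.0
    for i in range(n):
        ax = pts[i, 0]
        ay = pts[i, 1]
        az = pts[i, 2]
        for j in range(i + 1, n):
            mx = ax + pts[j, 0]
            my = ay + pts[j, 1]
            mz = az + pts[j, 2]
            nm = np.sqrt(mx * mx + my * my + mz * mz)
            if nm < 1e-9:
                # antipodal pair: hemisphere about a deterministic perpendicular
                px, py, pz = _perp3_s(ax, ay, az)
                best_cos, bx, by, bz = _check_better(pts, px, py, pz, 0.0, best_cos, bx, by, bz)
                continue
            cx = mx / nm
            cy = my / nm
            cz = mz / nm
            ccos = cx * ax + cy * ay + cz * az
            best_cos, bx, by, bz = _check_better(pts, cx, cy, cz, ccos, best_cos, bx, by, bz)
            best_cos, bx, by, bz = _check_better(pts, -cx, -cy, -cz, -ccos, best_cos, bx, by, bz)
    for i in range(n):
        ax = pts[i, 0]
        ay = pts[i, 1]
        az = pts[i, 2]
        for j in range(i + 1, n):
            ux = pts[j, 0] - ax
            uy = pts[j, 1] - ay
            uz = pts[j, 2] - az
            for k in range(j + 1, n):
                vx = pts[k, 0] - ax
                vy = pts[k, 1] - ay
                vz = pts[k, 2] - az
                cx = uy * vz - uz * vy
                cy = uz * vx - ux * vz
                cz = ux * vy - uy * vx
                nm = np.sqrt(cx * cx + cy * cy + cz * cz)
                if nm < 1e-12:
                    continue  # collinear: its cap reduces to a pair candidate
                cx /= nm
                cy /= nm
                cz /= nm
                ccos = cx * ax + cy * ay + cz * az
                best_cos, bx, by, bz = _check_better(pts, cx, cy, cz, ccos, best_cos, bx, by, bz)
                best_cos, bx, by, bz = _check_better(pts, -cx, -cy, -cz, -ccos, best_cos, bx, by, bz)
    if best_cos < -1.5:
        # pathological: fall back to mean direction
        mean = np.zeros(3)
        for i in range(n):
            mean += pts[i]
        c = _unit3(mean)
        t = 0.0
        for i in range(n):
            a = _angle3(c, pts[i])
            if a > t:
                t = a
        return c, t
    out = np.empty(3)
    out[0] = bx
    out[1] = by
    out[2] = bz
    if best_cos > 1.0:
        best_cos = 1.0
    elif best_cos < -1.0:
        best_cos = -1.0
    return out, np.arccos(best_cos)


@njit(cache=True)
def _min_cap(pts):
    """Minimal enclosing spherical cap of unit vectors (n, 3) -> (center, theta).

    Deterministic incremental Welzl scan (ties broken by input order) with a
    final containment verification; falls back to exhaustive enumeration when
    verification fails (which happens only for spreads beyond a hemisphere).
    """
    n = pts.shape[0]
    if n == 1:
        return pts[0].copy(), 0.0
    center, ctheta = _cap_two_cos(pts[0], pts[1])
    for i in range(2, n):
        if _dot3(center, pts[i]) >= ctheta - 1e-12:
            continue
        # recompute with pts[i] on the boundary
        q = pts[i]
        center, ctheta = _cap_two_cos(pts[0], q)
        for j in range(1, i):
            if _dot3(center, pts[j]) >= ctheta - 1e-12:
                continue
            q2 = pts[j]
            center, ctheta = _cap_two_cos(q, q2)
            for k in range(j):
                if _dot3(center, pts[k]) >= ctheta - 1e-12:
                    continue
                center, ctheta = _cap_three_cos(q, q2, pts[k])
    # verification
    worst = 1.0
    for i in range(n):
        d = _dot3(center, pts[i])
        if d < worst:
            worst = d
    if worst < ctheta - 1e-9:
        return _brute_cap(pts)
    if ctheta > 1.0:
        ctheta = 1.0
    elif ctheta < -1.0:
        ctheta = -1.0
    return center, np.arccos(ctheta)


# ---------------------------------------------------------------------------
# Maximal inscribed cap of a two-cap intersection
# ---------------------------------------------------------------------------


@njit(cache=True)
def _slerp(a, b, d, x):
    """Point on the geodesic from a to b (angular separation d) at angle x from a."""
    if d < 1e-12:
        return a.copy()
    sd = np.sin(d)
    if sd < 1e-9:
        # antipodal endpoints: no unique geodesic; rotate about a deterministic axis
        e = _perp3(a)
        out = np.empty(3)
        for k in range(3):
            out[k] = np.cos(x) * a[k] + np.sin(x) * e[k]
        return _unit3(out)
    sa = np.sin(d - x) / sd
    sb = np.sin(x) / sd
    out = np.empty(3)
    for k in range(3):
        out[k] = sa * a[k] + sb * b[k]
    return _unit3(out)


@njit(cache=True)
def _max_inscribed(ca, ta, cb, tb):
    """Largest cap inside the intersection of caps (ca, ta) and (cb, tb)."""
    d = _angle3(ca, cb)
    if d + tb <= ta:  # b inside a
        return cb.copy(), tb
    if d + ta <= tb:  # a inside b
        return ca.copy(), ta
    if d > ta + tb:
        # empty intersection: zero-radius cap at the angular-excess equalizer
        x = 0.5 * (d + ta - tb)
        if x < 0.0:
            x = 0.0
        elif x > d:
            x = d
        return _slerp(ca, cb, d, x), 0.0
    t = 0.5 * (ta + tb - d)
    x = ta - t
    if x < 0.0:
        x = 0.0
    elif x > d:
        x = d
    return _slerp(ca, cb, d, x), t


# ---------------------------------------------------------------------------
# von Mises-Fisher sampling from two uniforms
# ---------------------------------------------------------------------------


@njit(cache=True)
def _vmf_from_uniforms(mean, kappa, u1, u2):
    """Inverse-CDF vMF draw about ``mean`` using two U(0,1) variates."""
    if kappa > 1e12:
        return mean.copy()
    # W ~ marginal of the polar cosine; exact inverse CDF for vMF on S^2
    e2k = np.exp(-2.0 * kappa)
    arg = u1 + (1.0 - u1) * e2k
    if arg < 1e-300:
        w = -1.0
    else:
        w = 1.0 + np.log(arg) / kappa
    if w > 1.0:
        w = 1.0
    elif w < -1.0:
        w = -1.0
    s = np.sqrt(max(0.0, 1.0 - w * w))
    phi = 2.0 * np.pi * u2
    e1 = _perp3(mean)
    e2 = _cross3(mean, e1)
    out = np.empty(3)
    for k in range(3):
        out[k] = w * mean[k] + s * (np.cos(phi) * e1[k] + np.sin(phi) * e2[k])
    return _unit3(out)


# ---------------------------------------------------------------------------
# Ray-sphere exit
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ray_exit_unit(origin, direction, center, radius):
    """Unit vector (relative to ``center``) of the forward exit of a ray from a
    sphere of ``radius``; origins on/outside the surface exit at themselves."""
    w = np.empty(3)
    for k in range(3):
        w[k] = origin[k] - center[k]
    b = _dot3(w, direction)
    q = _dot3(w, w) - radius * radius
    if q > 0.0:
        q = 0.0  # clamp marginally-outside origins onto the surface
    disc = b * b - q
    s = -b + np.sqrt(disc)
    if s < 0.0:
        s = 0.0
    out = np.empty(3)
    for k in range(3):
        out[k] = w[k] + s * direction[k]
    return _unit3(out)


# ---------------------------------------------------------------------------
# Simulator phase-2 kernel: caps and synchronous velocity update
# ---------------------------------------------------------------------------


@njit(cache=True)
def _turning_prediction(traj, cur, t, j, dt, vmax):
    """Rotation-extrapolated position of agent j after dt more steps.

    The turning rotation over the lag ``dt`` is reconstructed from the two
    successive lag-dt displacement directions and applied once to the current
    lag-dt direction; agents without enough history (or stationary over the
    lag) extrapolate straight along their current lag direction.
    """
    t1 = t - dt
    t2 = t - 2 * dt
    if t1 < 0:
        t1 = 0
    if t2 < 0:
        t2 = 0
    vc = np.empty(3)
    vp = np.empty(3)
    for k in range(3):
        vc[k] = cur[j, k] - traj[t1, j, k]
        vp[k] = traj[t1, j, k] - traj[t2, j, k]
    nc = _norm3(vc)
    npv = _norm3(vp)
    out = np.empty(3)
    if nc < 1e-12:
        # stationary over the lag: no direction information, predict in place
        for k in range(3):
            out[k] = cur[j, k]
        return out
    vch = np.empty(3)
    for k in range(3):
        vch[k] = vc[k] / nc
    if npv < 1e-12 or t1 == t2:
        head = vch
    else:
        vph = np.empty(3)
        for k in range(3):
            vph[k] = vp[k] / npv
        axis = _cross3(vph, vch)
        sn = _norm3(axis)
        cs = _dot3(vph, vch)
        if sn < 1e-12:
            if cs > 0.0:
                head = vch
            else:
                head = vch  # direction reversal: identity is the only continuous choice
        else:
            for k in range(3):
                axis[k] = axis[k] / sn
            ang = np.arctan2(sn, cs)
            head = _rodrigues(axis, ang, vch)
    for k in range(3):
        out[k] = cur[j, k] + vmax * dt * head[k]
    return out


@njit(cache=True)
def _phase2_kernel(
    traj,
    cur,
    t,
    vel,
    indptr,
    indices,
    vmax,
    max_turn,
    max_dt,
    kappa_power,
    kappa_scale,
    uniforms,
    active,
    new_vel,
    cap_theta_out,
):
    """Quasi-attraction/alignment update for all ``active`` agents.

    ``traj`` holds the position log up to (and excluding) the current
    mid-step positions ``cur`` (post-avoidance).  ``vel`` are the current
    velocities.  Writes the next velocity of each active agent into
    ``new_vel`` and the sampled interaction-cap angular radius into
    ``cap_theta_out`` (diagnostic).
    """
    n = cur.shape[0]
    # interaction sphere radii
    rmax = np.zeros(n)
    for i in range(n):
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            d = 0.0
            for k in range(3):
                dd = cur[j, k] - cur[i, k]
                d += dd * dd
            d = np.sqrt(d)
            if d > rmax[i]:
                rmax[i] = d

    # quasi-attraction caps
    catr_c = np.empty((n, 3))
    catr_t = np.empty(n)
    for i in range(n):
        if not active[i]:
            continue
        deg = indptr[i + 1] - indptr[i]
        pts = np.empty((deg + 1, 3))
        pts[0] = _unit3(vel[i])  # own exit: the focal agent sits at the center
        m = 1
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            vj = _unit3(vel[j])
            pts[m] = _ray_exit_unit(cur[j], vj, cur[i], rmax[i])
            m += 1
        c, th = _min_cap(pts)
        catr_c[i] = c
        catr_t[i] = th

    # quasi-alignment caps: shared per-lag predictions, per-agent Delta_min
    calg_c = np.empty((n, 3))
    calg_t = np.empty(n)
    done = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        if not active[i]:
            done[i] = True
    pred = np.empty((n, 3))
    for dt in range(1, max_dt + 1):
        all_done = True
        for i in range(n):
            if not done[i]:
                all_done = False
                break
        if all_done:
            break
        for j in range(n):
            pred[j] = _turning_prediction(traj, cur, t, j, dt, vmax)
        for i in range(n):
            if done[i]:
                continue
            outside = True
            # self-prediction must leave the interaction sphere too
            d = 0.0
            for k in range(3):
                dd = pred[i, k] - cur[i, k]
                d += dd * dd
            if np.sqrt(d) <= rmax[i]:
                outside = False
            if outside:
                for p in range(indptr[i], indptr[i + 1]):
                    j = indices[p]
                    d = 0.0
                    for k in range(3):
                        dd = pred[j, k] - cur[i, k]
                        d += dd * dd
                    if np.sqrt(d) <= rmax[i]:
                        outside = False
                        break
            if not outside:
                continue
            deg = indptr[i + 1] - indptr[i]
            pts = np.empty((deg + 1, 3))
            w = np.empty(3)
            for k in range(3):
                w[k] = pred[i, k] - cur[i, k]
            pts[0] = _unit3(w)
            m = 1
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                for k in range(3):
                    w[k] = pred[j, k] - cur[i, k]
                pts[m] = _unit3(w)
                m += 1
            c, th = _min_cap(pts)
            calg_c[i] = c
            calg_t[i] = th
            done[i] = True
    # fallback: straight-line extrapolation far enough to guarantee exit
    for i in range(n):
        if done[i]:
            continue
        steps = rmax[i] * 2.0 / vmax + 2.0
        deg = indptr[i + 1] - indptr[i]
        pts = np.empty((deg + 1, 3))
        w = np.empty(3)
        vh = _unit3(vel[i])
        for k in range(3):
            w[k] = vmax * steps * vh[k]
        pts[0] = _unit3(w)
        m = 1
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            vh = _unit3(vel[j])
            for k in range(3):
                w[k] = cur[j, k] + vmax * steps * vh[k] - cur[i, k]
            pts[m] = _unit3(w)
            m += 1
        c, th = _min_cap(pts)
        calg_c[i] = c
        calg_t[i] = th

    # combine caps, sample, clamp turn, apply speed rule
    for i in range(n):
        if not active[i]:
            continue
        c, th = _max_inscribed(catr_c[i], catr_t[i], calg_c[i], calg_t[i])
        cap_theta_out[i] = th
        if th < 1e-6:
            d = c
        else:
            kappa = kappa_scale * th ** (-kappa_power)
            d = _vmf_from_uniforms(c, kappa, uniforms[i, 0], uniforms[i, 1])
        vh = _unit3(vel[i])
        dth = _angle3(vh, d)
        if dth > max_turn:
            axis = _cross3(vh, d)
            sn = _norm3(axis)
            if sn < 1e-12:
                axis = _perp3(vh)
            else:
                for k in range(3):
                    axis[k] = axis[k] / sn
            d = _rodrigues(axis, max_turn, vh)
            dth = max_turn
        speed = vmax * np.cos(0.5 * dth)
        for k in range(3):
            new_vel[i, k] = speed * d[k]
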