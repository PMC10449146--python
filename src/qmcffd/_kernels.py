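"""Compiled transport kernels.

Everything here is numba ``@njit`` code operating on flat arrays packed
by :class:`qmcffd.transport.TransportTables`.  The Python-facing physics
(log-log attenuation tables, adaptive RITA construction, spectrum alias
tables) lives in the sibling modules; these kernels consume dense
resampled copies for O(1) lookups inside the photon loop.

Detector orientation is fixed to the package's world frame: plane normal
along -y (facing the source), in-plane axes +x and +z.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .raytrace import _march_forced, _march_lengths
from .xsection import MEC2_KEV, R_E2_BARN

_TINY_TAU = 1e-12


@njit(cache=True, fastmath=True)
def _mu_at(tab, mat, e, e0, de):
    """Linear interpolation of a dense (n_mat, nE) table at energy e."""
    x = (e - e0) / de
    n = tab.shape[1]
    if x <= 0.0:
        return tab[mat, 0]
    i = int(x)
    if i >= n - 1:
        return tab[mat, n - 1]
    f = x - i
    return tab[mat, i] * (1.0 - f) + tab[mat, i + 1] * f


@njit(cache=True, fastmath=True)
def _kn_dcs(e, c):
    k = e / MEC2_KEV
    ratio = 1.0 / (1.0 + k * (1.0 - c))
    sin2 = 1.0 - c * c
    return 0.5 * R_E2_BARN * ratio * ratio * (ratio + 1.0 / ratio - sin2)


@njit(cache=True, fastmath=True)
def _kn_total(e):
    k = e / MEC2_KEV
    t = 1.0 + 2.0 * k
    lg = math.log(t)
    term = ((1.0 + k) / (k * k)) * (2.0 * (1.0 + k) / t - lg / k)
    return 2.0 * math.pi * R_E2_BARN * (
        term + lg / (2.0 * k) - (1.0 + 3.0 * k) / (t * t))


@njit(cache=True, fastmath=True)
def _compton_e(e, c):
    return e / (1.0 + (e / MEC2_KEV) * (1.0 - c))


@njit(cache=True, fastmath=True)
def _rayleigh_dcs(e, c, zeff, gscreen):
    s2 = 0.5 * (1.0 - c)
    if s2 < 0.0:
        s2 = 0.0
    x = math.sqrt(s2) * e / 12.39842  # momentum transfer, 1/Angstrom
    u = x / (gscreen * zeff ** (1.0 / 3.0))
    f = zeff / ((1.0 + u * u) * (1.0 + u * u))
    return 0.5 * R_E2_BARN * (1.0 + c * c) * f * f


@njit(cache=True, fastmath=True)
def _tau_at(lengths, mu_tot, e, e0, de):
    tau = 0.0
    for m in range(lengths.size):
        if lengths[m] > 0.0:
            tau += lengths[m] * _mu_at(mu_tot, m, e, e0, de)
    return tau


@njit(cache=True, fastmath=True)
def _alias_draw(cut, alias, u):
    k = cut.size
    x = u * k
    j = int(x)
    if j > k - 1:
        j = k - 1
    if x - j < cut[j]:
        return j
    return alias[j]


@njit(cache=True, fastmath=True)
def _rita_draw(xk, xik, ak, bk, nk, u):
    """Rational inverse transform on a packed knot row."""
    lo = 0
    hi = nk - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xik[mid] <= u:
            lo = mid
        else:
            hi = mid
    dxi = xik[lo + 1] - xik[lo]
    if dxi <= 0.0:
        return xk[lo]
    tau = (u - xik[lo]) / dxi
    num = (1.0 + ak[lo] + bk[lo]) * tau
    den = 1.0 + ak[lo] * tau + bk[lo] * tau * tau
    step = tau if den == 0.0 else num / den
    if step < 0.0:
        step = 0.0
    elif step > 1.0:
        step = 1.0
    return xk[lo] + step * (xk[lo + 1] - xk[lo])


@njit(cache=True, fastmath=True)
def _rotate(wx, wy, wz, cost, phi):
    """Deflect unit vector w by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(1.0 - cost * cost, 0.0))
    # auxiliary axis: smallest-component trick
    ax, ay, az = abs(wx), abs(wy), abs(wz)
    if ax <= ay and ax <= az:
        bx, by, bz = 1.0, 0.0, 0.0
    elif ay <= az:
        bx, by, bz = 0.0, 1.0, 0.0
    else:
        bx, by, bz = 0.0, 0.0, 1.0
    # e1 = normalize(cross(w, b)), e2 = cross(w, e1)
    e1x = wy * bz - wz * by
    e1y = wz * bx - wx * bz
    e1z = wx * by - wy * bx
    n = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= n
    e1y /= n
    e1z /= n
    e2x = wy * e1z - wz * e1y
    e2y = wz * e1x - wx * e1z
    e2z = wx * e1y - wy * e1x
    cp = math.cos(phi)
    sp = math.sin(phi)
    ox = cost * wx + sint * (cp * e1x + sp * e2x)
    oy = cost * wy + sint * (cp * e1y + sp * e2y)
    oz = cost * wz + sint * (cp * e1z + sp * e2z)
    n = math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox / n, oy / n, oz / n


@njit(cache=True, fastmath=True)
def _aabb_entry_exit(ox, oy, oz, dx, dy, dz, bx0, by0, bz0, bx1, by1, bz1):
    t0 = 0.0
    t1 = math.inf
    for axis in range(3):
        if axis == 0:
            o, d, lo, hi = ox, dx, bx0, bx1
        elif axis == 1:
            o, d, lo, hi = oy, dy, by0, by1
        else:
            o, d, lo, hi = oz, dz, bz0, bz1
        if -1e-12 < d < 1e-12:
            if o < lo or o >= hi:
                return 1.0, -1.0
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 > t1:
        return 1.0, -1.0
    return t0, t1


@njit(cache=True, fastmath=True)
def _splat(px, py, pz, wx, wy, wz, e_pre, weight, order_row, sq_row,
           ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
           mu_tot, mu_pe, mu_c, mu_r, e0, de,
           ray_norm, zeff, gscreen,
           detcx, detcy, detcz, pitch, nu, nv,
           e_floor, lengths):
    """Forced-fixed-detection splat from one interaction point.

    Adds, for every detector pixel j, the probability that the photon
    scatters from (px,py,pz) toward the pixel and escapes unattenuated:
    weight * sum_delta pT_delta * ptheta_delta * exp(-tau) * Omega_j.
    """
    ix = int(math.floor((px - bx0) / hx))
    iy = int(math.floor((py - by0) / hy))
    iz = int(math.floor((pz - bz0) / hz))
    nx, ny, nz = ids.shape
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
        return
    mat = ids[ix, iy, iz]
    mtot = _mu_at(mu_tot, mat, e_pre, e0, de)
    if mtot <= 0.0:
        return
    p_t0 = _mu_at(mu_c, mat, e_pre, e0, de) / mtot
    p_t1 = _mu_at(mu_r, mat, e_pre, e0, de) / mtot
    kn_norm = _kn_total(e_pre)
    rnorm = _mu_at(ray_norm, mat, e_pre, e0, de)
    ze = zeff[mat]
    half_u = 0.5 * (nu - 1)
    half_v = 0.5 * (nv - 1)
    area = pitch * pitch
    for ju in range(nu):
        qx = detcx + (ju - half_u) * pitch
        for jv in range(nv):
            qz = detcz + (jv - half_v) * pitch
            vx = qx - px
            vy = detcy - py
            vz = qz - pz
            r2 = vx * vx + vy * vy + vz * vz
            r = math.sqrt(r2)
            ox = vx / r
            oy = vy / r
            oz = vz / r
            cosa = oy  # detector normal faces the source along -y
            if cosa <= 0.0:
                continue
            cost = ox * wx + oy * wy + oz * wz
            # attenuation path to the phantom boundary along the pixel ray
            t0, t1 = _aabb_entry_exit(px, py, pz, ox, oy, oz,
                                      bx0, by0, bz0, bx1, by1, bz1)
            for m in range(lengths.size):
                lengths[m] = 0.0
            if t1 > t0:
                _march_lengths(ids, bx0, by0, bz0, hx, hy, hz,
                               px, py, pz, ox, oy, oz, t0, t1, lengths)
            term = 0.0
            if p_t0 > 0.0:
                e_c = _compton_e(e_pre, cost)
                if e_c < e_floor:
                    e_c = e_floor
                pdf_c = _kn_dcs(e_pre, cost) / kn_norm
                tau_c = _tau_at(lengths, mu_tot, e_c, e0, de)
                term += p_t0 * pdf_c * math.exp(-tau_c)
            if p_t1 > 0.0 and rnorm > 0.0:
                pdf_r = _rayleigh_dcs(e_pre, cost, ze, gscreen) / rnorm
                tau_r = _tau_at(lengths, mu_tot, e_pre, e0, de)
                term += p_t1 * pdf_r * math.exp(-tau_r)
            contrib = weight * term * cosa * area / r2
            order_row[ju, jv] += contrib
            sq_row[ju, jv] += contrib * contrib


@njit(cache=True, fastmath=True)
def _history(u, ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
             mu_tot, mu_pe, mu_c, mu_r, e0, de,
             ray_norm, zeff, gscreen,
             spec_e, spec_cut, spec_alias,
             srcx, srcy, srcz, recty, rectx0, rectx1, rectz0, rectz1,
             detcx, detcy, detcz, pitch, nu, nv,
             rc_x, rc_xi, rc_a, rc_b, rc_nk,
             rr_x, rr_xi, rr_a, rr_b, rr_nk,
             eg_ln0, eg_dln,
             n_orders, e_floor, kill_floor,
             out_sum, out_sq, mu_vec, lengths,
             trace_pos, trace_w, trace_e):
    """One full forced-fixed-detection history driven by a 4n point.

    Accumulates per-order pixel contributions into ``out_sum`` (and their
    squares into ``out_sq``) and records the chain trace (interaction
    positions, weights W_i, pre-collision energies) for diagnostics.
    Returns the number of orders actually splatted.
    """
    n_eg = rc_nk.size
    # --- variates 1-3: source energy and emission direction -------------
    e_cur = spec_e[_alias_draw(spec_cut, spec_alias, u[0])]
    tx = rectx0 + (rectx1 - rectx0) * u[1]
    tz = rectz0 + (rectz1 - rectz0) * u[2]
    dx = tx - srcx
    dy = recty - srcy
    dz = tz - srcz
    n = math.sqrt(dx * dx + dy * dy + dz * dz)
    wx, wy, wz = dx / n, dy / n, dz / n
    t0, t1 = _aabb_entry_exit(srcx, srcy, srcz, wx, wy, wz,
                              bx0, by0, bz0, bx1, by1, bz1)
    if t0 > t1:
        return 0
    px = srcx + t0 * wx
    py = srcy + t0 * wy
    pz = srcz + t0 * wz
    seg = t1 - t0
    weight = 1.0  # W_0 = I_0 = 1 per emitted cone photon
    done = 0
    for order in range(1, n_orders + 1):
        # escape probability along the current direction from the current
        # position, then force the next interaction inside the phantom
        for m in range(mu_vec.size):
            mu_vec[m] = _mu_at(mu_tot, m, e_cur, e0, de)
        for m in range(lengths.size):
            lengths[m] = 0.0
        _march_lengths(ids, bx0, by0, bz0, hx, hy, hz,
                       px, py, pz, wx, wy, wz, 0.0, seg, lengths)
        tau_tot = 0.0
        for m in range(mu_vec.size):
            tau_tot += lengths[m] * mu_vec[m]
        if tau_tot <= _TINY_TAU:
            break  # effectively vacuum: cannot force an interaction
        p_esc = math.exp(-tau_tot)
        weight *= 1.0 - p_esc
        uf = u[4 * (order - 1) + 3]
        target = -math.log1p(-(1.0 - p_esc) * uf)
        t_i = _march_forced(ids, bx0, by0, bz0, hx, hy, hz, mu_vec,
                            px, py, pz, wx, wy, wz, seg, target)
        if t_i < 0.0:
            t_i = seg * (1.0 - 1e-12)
        px += t_i * wx
        py += t_i * wy
        pz += t_i * wz
        trace_pos[order - 1, 0] = px
        trace_pos[order - 1, 1] = py
        trace_pos[order - 1, 2] = pz
        trace_w[order - 1] = weight
        trace_e[order - 1] = e_cur
        _splat(px, py, pz, wx, wy, wz, e_cur, weight,
               out_sum[order - 1], out_sq[order - 1],
               ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
               mu_tot, mu_pe, mu_c, mu_r, e0, de,
               ray_norm, zeff, gscreen,
               detcx, detcy, detcz, pitch, nu, nv, e_floor, lengths)
        done = order
        if order == n_orders:
            break
        # --- continuation: scatter type, direction, energy ---------------
        ix = int(math.floor((px - bx0) / hx))
        iy = int(math.floor((py - by0) / hy))
        iz = int(math.floor((pz - bz0) / hz))
        mat = ids[ix, iy, iz]
        mtot = _mu_at(mu_tot, mat, e_cur, e0, de)
        if mtot <= 0.0:
            break
        pc = _mu_at(mu_c, mat, e_cur, e0, de) / mtot
        pr = _mu_at(mu_r, mat, e_cur, e0, de) / mtot
        survival = pc + pr
        if survival <= 0.0:
            break
        ut = u[4 * order]
        # nearest log-energy RITA table
        ig = int(round((math.log(e_cur) - eg_ln0) / eg_dln))
        if ig < 0:
            ig = 0
        elif ig >= n_eg:
            ig = n_eg - 1
        if ut * survival < pc:  # Compton
            cost = _rita_draw(rc_x[ig], rc_xi[ig], rc_a[ig], rc_b[ig],
                              rc_nk[ig], u[4 * order + 1])
            e_new = _compton_e(e_cur, cost)
            if e_new < e_floor:
                if kill_floor:
                    break
                e_new = e_floor
        else:  # Rayleigh, energy unchanged
            cost = _rita_draw(rr_x[mat, ig], rr_xi[mat, ig], rr_a[mat, ig],
                              rr_b[mat, ig], rr_nk[mat, ig],
                              u[4 * order + 1])
            e_new = e_cur
        phi = 2.0 * math.pi * u[4 * order + 2]
        wx, wy, wz = _rotate(wx, wy, wz, cost, phi)
        weight *= survival
        e_cur = e_new
        t0b, seg = _aabb_entry_exit(px, py, pz, wx, wy, wz,
                                    bx0, by0, bz0, bx1, by1, bz1)
        if t0b > seg:
            break
    return done


@njit(cache=True, fastmath=True)
def _run_batch(points, ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
               mu_tot, mu_pe, mu_c, mu_r, e0, de,
               ray_norm, zeff, gscreen,
               spec_e, spec_cut, spec_alias,
               srcx, srcy, srcz, recty, rectx0, rectx1, rectz0, rectz1,
               detcx, detcy, detcz, pitch, nu, nv,
               rc_x, rc_xi, rc_a, rc_b, rc_nk,
               rr_x, rr_xi, rr_a, rr_b, rr_nk,
               eg_ln0, eg_dln,
               n_orders, e_floor, kill_floor,
               out_sum, out_sq):
    n_mat = mu_tot.shape[0]
    mu_vec = np.zeros(n_mat)
    lengths = np.zeros(n_mat)
    trace_pos = np.zeros((n_orders, 3))
    trace_w = np.zeros(n_orders)
    trace_e = np.zeros(n_orders)
    for i in range(points.shape[0]):
        _history(points[i], ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
                 mu_tot, mu_pe, mu_c, mu_r, e0, de,
                 ray_norm, zeff, gscreen,
                 spec_e, spec_cut, spec_alias,
                 srcx, srcy, srcz, recty, rectx0, rectx1, rectz0, rectz1,
                 detcx, detcy, detcz, pitch, nu, nv,
                 rc_x, rc_xi, rc_a, rc_b, rc_nk,
                 rr_x, rr_xi, rr_a, rr_b, rr_nk,
                 eg_ln0, eg_dln,
                 n_orders, e_floor, kill_floor,
                 out_sum, out_sq, mu_vec, lengths,
                 trace_pos, trace_w, trace_e)


@njit(cache=True, fastmath=True)
def _primary(ids, bx0, by0, bz0, hx, hy, hz, bx1, by1, bz1,
             mu_tot, e0, de,
             spec_e, spec_w,
             srcx, srcy, srcz,
             detcx, detcy, detcz, pitch, nu, nv, out):
    """Deterministic Lambert-Beer primary image, one ray per pixel center."""
    n_mat = mu_tot.shape[0]
    lengths = np.zeros(n_mat)
    half_u = 0.5 * (nu - 1)
    half_v = 0.5 * (nv - 1)
    for ju in range(nu):
        qx = detcx + (ju - half_u) * pitch
        for jv in range(nv):
            qz = detcz + (jv - half_v) * pitch
            dx = qx - srcx
            dy = detcy - srcy
            dz = qz - srcz
            n = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= n
            dy /= n
            dz /= n
            t0, t1 = _aabb_entry_exit(srcx, srcy, srcz, dx, dy, dz,
                                      bx0, by0, bz0, bx1, by1, bz1)
            for m in range(n_mat):
                lengths[m] = 0.0
            if t1 > t0:
                _march_lengths(ids, bx0, by0, bz0, hx, hy, hz,
                               srcx, srcy, srcz, dx, dy, dz, t0, t1, lengths)
            val = 0.0
            for k in range(spec_e.size):
                tau = _tau_at(lengths, mu_tot, spec_e[k], e0, de)
                val += spec_w[k] * math.exp(-tau)
            out[ju, jv] = val


@njit(cache=True, fastmath=True)
def _analog_batch(n_hist, seed, ids, bx0, by0, bz0, hx, hy, hz,
                  bx1, by1, bz1,
                  mu_tot, mu_pe, mu_c, mu_r, e0, de,
                  zeff, gscreen,
                  spec_e, spec_cut, spec_alias,
                  srcx, srcy, srcz, recty, rectx0, rectx1, rectz0, rectz1,
                  detcx, detcy, detcz, pitch, nu, nv,
                  max_order, e_floor, hits):
    """Unbiased analog Monte Carlo: free flights from the untruncated
    exponential law, explicit absorption, binary detector hits.

    ``hits[order, ju, jv]`` counts photons crossing pixel (ju, jv) after
    exactly ``order`` scatters (order 0 = primary).  Angles are sampled
    by rejection directly from the differential cross sections, so this
    path shares no sampling machinery with the forced-detection chain.
    """
    np.random.seed(seed)
    n_mat = mu_tot.shape[0]
    mu_vec = np.zeros(n_mat)
    half_u = 0.5 * nu
    half_v = 0.5 * nv
    for _ in range(n_hist):
        e_cur = spec_e[_alias_draw(spec_cut, spec_alias,
                                   np.random.random())]
        tx = rectx0 + (rectx1 - rectx0) * np.random.random()
        tz = rectz0 + (rectz1 - rectz0) * np.random.random()
        dx = tx - srcx
        dy = recty - srcy
        dz = tz - srcz
        n = math.sqrt(dx * dx + dy * dy + dz * dz)
        wx, wy, wz = dx / n, dy / n, dz / n
        px, py, pz = srcx, srcy, srcz
        order = 0
        alive = True
        while alive:
            t0, t1 = _aabb_entry_exit(px, py, pz, wx, wy, wz,
                                      bx0, by0, bz0, bx1, by1, bz1)
            escaped = False
            if t0 > t1:
                escaped = True
            else:
                for m in range(n_mat):
                    mu_vec[m] = _mu_at(mu_tot, m, e_cur, e0, de)
                target = -math.log(1.0 - np.random.random())
                # advance to the segment entry, then march
                ex = px + t0 * wx
                ey = py + t0 * wy
                ez = pz + t0 * wz
                t_i = _march_forced(ids, bx0, by0, bz0, hx, hy, hz, mu_vec,
                                    ex, ey, ez, wx, wy, wz, t1 - t0, target)
                if t_i < 0.0:
                    escaped = True
                else:
                    px = ex + t_i * wx
                    py = ey + t_i * wy
                    pz = ez + t_i * wz
            if escaped:
                if wy > 1e-12 and order <= max_order:
                    tp = (detcy - py) / wy
                    if tp >= 0.0:
                        qx = px + tp * wx
                        qz = pz + tp * wz
                        ju = int(math.floor((qx - detcx) / pitch + half_u))
                        jv = int(math.floor((qz - detcz) / pitch + half_v))
                        if 0 <= ju < nu and 0 <= jv < nv:
                            hits[order, ju, jv] += 1
                break
            # interaction: absorb or scatter
            ix = int(math.floor((px - bx0) / hx))
            iy = int(math.floor((py - by0) / hy))
            iz = int(math.floor((pz - bz0) / hz))
            mat = ids[ix, iy, iz]
            mtot = _mu_at(mu_tot, mat, e_cur, e0, de)
            r = np.random.random() * mtot
            m_pe = _mu_at(mu_pe, mat, e_cur, e0, de)
            m_co = _mu_at(mu_c, mat, e_cur, e0, de)
            if r < m_pe:
                break  # photoelectric absorption
            order += 1
            if order > max_order:
                break  # deeper orders are not tallied
            if r < m_pe + m_co:
                # Compton: rejection from Klein-Nishina (max at cos=1)
                env = _kn_dcs(e_cur, 1.0)
                while True:
                    c = 2.0 * np.random.random() - 1.0
                    if np.random.random() * env <= _kn_dcs(e_cur, c):
                        break
                e_cur = _compton_e(e_cur, c)
                if e_cur < e_floor:
                    e_cur = e_floor
            else:
                # Rayleigh: rejection from Thomson x form factor^2
                ze = zeff[mat]
                env = _rayleigh_dcs(e_cur, 1.0, ze, gscreen)
                while True:
                    c = 2.0 * np.random.random() - 1.0
                    if np.random.random() * env <= _rayleigh_dcs(
                            e_cur, c, ze, gscreen):
                        break
            phi = 2.0 * math.pi * np.random.random()
            wx, wy, wz = _rotate(wx, wy, wz, c, phi)
    return hits
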