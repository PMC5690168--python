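"""Numba-jitted analog photon-transport kernel.

Flattened-scene representation: quadric surfaces, priority-ordered cells
grouped into objects with bounding spheres (surface tracking with per-object
early-outs). Interaction physics: photoelectric absorption with optional
K/L fluorescence lines, incoherent scattering sampled from the Klein-Nishina
kernel with incoherent-function rejection, coherent scattering from the
form-factor-weighted Thomson kernel. Scoring is a track-length kerma
estimator (chord length x E x mu_en/rho of the scoring medium / volume).

All energies keV, lengths cm. Single threaded; the RNG is numpy's global
MT19937 seeded inside the kernel, so runs are bit-reproducible for a fixed
seed and correlated sampling across scenes is the default when the same seed
is passed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1.0e30
EPS = 1.0e-7
HC_KEV_A = 12.39841984
MEC2_KEV = 510.99895

S_SPHERE, S_PLANE, S_CYL, S_ELLIPSOID, S_CONE = 0, 1, 2, 3, 4
R_BOX, R_WASHER, R_SPHERE, R_SHELL = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _surf_eval(st, par, x, y, z):
    if st == S_SPHERE:
        dx = x - par[0]
        dy = y - par[1]
        dz = z - par[2]
        return dx * dx + dy * dy + dz * dz - par[3] * par[3]
    if st == S_PLANE:
        return par[0] * x + par[1] * y + par[2] * z - par[3]
    if st == S_CYL:
        wx = x - par[0]
        wy = y - par[1]
        wz = z - par[2]
        wa = wx * par[3] + wy * par[4] + wz * par[5]
        return wx * wx + wy * wy + wz * wz - wa * wa - par[6] * par[6]
    if st == S_ELLIPSOID:
        dx = (x - par[0]) / par[3]
        dy = (y - par[1]) / par[4]
        dz = (z - par[2]) / par[5]
        return dx * dx + dy * dy + dz * dz - 1.0
    # cone: f = cos2a*|w|^2 - (w.a)^2  (negative inside either nappe)
    wx = x - par[0]
    wy = y - par[1]
    wz = z - par[2]
    wa = wx * par[3] + wy * par[4] + wz * par[5]
    return par[6] * (wx * wx + wy * wy + wz * wz) - wa * wa


@njit(cache=True, inline="always")
def _quad_min_root(a, b, c):
    """Smallest root > EPS of a t^2 + 2 b t + c = 0, else INF."""
    if a == 0.0:
        if b == 0.0:
            return INF
        t = -c / (2.0 * b)
        return t if t > EPS else INF
    disc = b * b - a * c
    if disc <= 0.0:
        return INF
    sq = np.sqrt(disc)
    if a > 0.0:
        t1 = (-b - sq) / a
        t2 = (-b + sq) / a
    else:
        t1 = (-b + sq) / a
        t2 = (-b - sq) / a
    if t1 > EPS:
        return t1
    if t2 > EPS:
        return t2
    return INF


@njit(cache=True, inline="always")
def _surf_dist(st, par, x, y, z, dx, dy, dz):
    if st == S_PLANE:
        denom = par[0] * dx + par[1] * dy + par[2] * dz
        if denom == 0.0:
            return INF
        t = (par[3] - (par[0] * x + par[1] * y + par[2] * z)) / denom
        return t if t > EPS else INF
    if st == S_SPHERE:
        wx = x - par[0]
        wy = y - par[1]
        wz = z - par[2]
        b = wx * dx + wy * dy + wz * dz
        c = wx * wx + wy * wy + wz * wz - par[3] * par[3]
        return _quad_min_root(1.0, b, c)
    if st == S_CYL:
        wx = x - par[0]
        wy = y - par[1]
        wz = z - par[2]
        da = dx * par[3] + dy * par[4] + dz * par[5]
        wa = wx * par[3] + wy * par[4] + wz * par[5]
        a = 1.0 - da * da
        b = wx * dx + wy * dy + wz * dz - wa * da
        c = wx * wx + wy * wy + wz * wz - wa * wa - par[6] * par[6]
        return _quad_min_root(a, b, c)
    if st == S_ELLIPSOID:
        px = (x - par[0]) / par[3]
        py = (y - par[1]) / par[4]
        pz = (z - par[2]) / par[5]
        qx = dx / par[3]
        qy = dy / par[4]
        qz = dz / par[5]
        a = qx * qx + qy * qy + qz * qz
        b = px * qx + py * qy + pz * qz
        c = px * px + py * py + pz * pz - 1.0
        return _quad_min_root(a, b, c)
    # cone
    wx = x - par[0]
    wy = y - par[1]
    wz = z - par[2]
    da = dx * par[3] + dy * par[4] + dz * par[5]
    wa = wx * par[3] + wy * par[4] + wz * par[5]
    c2 = par[6]
    a = c2 - da * da
    b = c2 * (wx * dx + wy * dy + wz * dz) - wa * da
    c = c2 * (wx * wx + wy * wy + wz * wz) - wa * wa
    return _quad_min_root(a, b, c)


@njit(cache=True)
def locate(x, y, z, surf_type, surf_par, obj_bound, obj_cell_ptr,
           cell_surf_ptr, cell_surf_idx, cell_surf_sign):
    n_obj = obj_bound.shape[0]
    for o in range(n_obj):
        br = obj_bound[o, 3]
        if br < INF:
            bx = x - obj_bound[o, 0]
            by = y - obj_bound[o, 1]
            bz = z - obj_bound[o, 2]
            if bx * bx + by * by + bz * bz > br * br:
                continue
        for c in range(obj_cell_ptr[o], obj_cell_ptr[o + 1]):
            ok = True
            for k in range(cell_surf_ptr[c], cell_surf_ptr[c + 1]):
                si = cell_surf_idx[k]
                f = _surf_eval(surf_type[si], surf_par[si], x, y, z)
                if f * cell_surf_sign[k] <= 0.0:
                    ok = False
                    break
            if ok:
                return c
    return -1


@njit(cache=True)
def boundary_distance(x, y, z, dx, dy, dz, surf_type, surf_par, obj_bound,
                      obj_surf_ptr, obj_surf_idx):
    tmin = INF
    n_obj = obj_bound.shape[0]
    for o in range(n_obj):
        br = obj_bound[o, 3]
        if br < INF:
            bx = obj_bound[o, 0] - x
            by = obj_bound[o, 1] - y
            bz = obj_bound[o, 2] - z
            b = bx * dx + by * dy + bz * dz
            c0 = bx * bx + by * by + bz * bz - br * br
            if c0 > 0.0:
                if b < 0.0:
                    continue
                disc = b * b - c0
                if disc <= 0.0:
                    continue
                if b - np.sqrt(disc) > tmin:
                    continue
        for k in range(obj_surf_ptr[o], obj_surf_ptr[o + 1]):
            si = obj_surf_idx[k]
            t = _surf_dist(surf_type[si], surf_par[si], x, y, z, dx, dy, dz)
            if t < tmin:
                tmin = t
    return tmin


@njit(cache=True, inline="always")
def _interp_loglin(le, lx, ly, lo, hi):
    """Linear interpolation of ly vs lx (both log) on slice [lo, hi)."""
    n = hi - lo
    if le <= lx[lo]:
        return ly[lo]
    if le >= lx[hi - 1]:
        return ly[hi - 1]
    a = lo
    b = hi - 1
    while b - a > 1:
        m = (a + b) // 2
        if lx[m] <= le:
            a = m
        else:
            b = m
    f = (le - lx[a]) / (lx[b] - lx[a])
    return ly[a] + f * (ly[b] - ly[a])


@njit(cache=True, inline="always")
def _seg_interval_quad(a, b, c, t0, t1):
    """Overlap of [t0,t1] with {t: a t^2 + 2 b t + c <= 0}. Returns (lo, hi)
    (possibly empty lo>hi). Assumes the set is a single interval (a>=0)."""
    if a <= 1.0e-14:
        if c <= 0.0:
            return t0, t1
        return 1.0, 0.0
    disc = b * b - a * c
    if disc <= 0.0:
        return 1.0, 0.0
    sq = np.sqrt(disc)
    lo = (-b - sq) / a
    hi = (-b + sq) / a
    if lo < t0:
        lo = t0
    if hi > t1:
        hi = t1
    return lo, hi


@njit(cache=True)
def _region_chord(rt, par, x, y, z, dx, dy, dz, length):
    """Chord length of segment [p, p+length*d] inside the region."""
    if rt == R_BOX:
        t0 = 0.0
        t1 = length
        for ax in range(3):
            if ax == 0:
                pc = x - par[0]
                dc = dx
            elif ax == 1:
                pc = y - par[1]
                dc = dy
            else:
                pc = z - par[2]
                dc = dz
            h = par[3 + ax]
            if dc == 0.0:
                if pc < -h or pc > h:
                    return 0.0
            else:
                ta = (-h - pc) / dc
                tb = (h - pc) / dc
                if ta > tb:
                    tmp = ta
                    ta = tb
                    tb = tmp
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
                if t0 >= t1:
                    return 0.0
        return t1 - t0
    if rt == R_SPHERE or rt == R_SHELL:
        wx = x - par[0]
        wy = y - par[1]
        wz = z - par[2]
        b = wx * dx + wy * dy + wz * dz
        c0 = wx * wx + wy * wy + wz * wz
        if rt == R_SPHERE:
            lo, hi = _seg_interval_quad(1.0, b, c0 - par[3] * par[3],
                                        0.0, length)
            return hi - lo if hi > lo else 0.0
        lo_o, hi_o = _seg_interval_quad(1.0, b, c0 - par[4] * par[4],
                                        0.0, length)
        outer = hi_o - lo_o if hi_o > lo_o else 0.0
        lo_i, hi_i = _seg_interval_quad(1.0, b, c0 - par[3] * par[3],
                                        0.0, length)
        inner = hi_i - lo_i if hi_i > lo_i else 0.0
        return outer - inner
    # washer: |axial| <= hw and (r-hw) <= cyl radius <= (r+hw)
    ux = par[3]
    uy = par[4]
    uz = par[5]
    wx = x - par[0]
    wy = y - par[1]
    wz = z - par[2]
    wa = wx * ux + wy * uy + wz * uz
    da = dx * ux + dy * uy + dz * uz
    hw = par[8]
    t0 = 0.0
    t1 = length
    if da == 0.0:
        if wa < -hw or wa > hw:
            return 0.0
    else:
        ta = (-hw - wa) / da
        tb = (hw - wa) / da
        if ta > tb:
            tmp = ta
            ta = tb
            tb = tmp
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
        if t0 >= t1:
            return 0.0
    a = 1.0 - da * da
    b = wx * dx + wy * dy + wz * dz - wa * da
    cperp = wx * wx + wy * wy + wz * wz - wa * wa
    rout = par[7] + hw
    rin = par[7] - hw
    lo_o, hi_o = _seg_interval_quad(a, b, cperp - rout * rout, t0, t1)
    outer = hi_o - lo_o if hi_o > lo_o else 0.0
    if outer <= 0.0:
        return 0.0
    lo_i, hi_i = _seg_interval_quad(a, b, cperp - rin * rin, t0, t1)
    inner = hi_i - lo_i if hi_i > lo_i else 0.0
    return outer - inner


@njit(cache=True)
def _region_contains(rt, par, x, y, z):
    if rt == R_BOX:
        return (abs(x - par[0]) <= par[3] and abs(y - par[1]) <= par[4]
                and abs(z - par[2]) <= par[5])
    wx = x - par[0]
    wy = y - par[1]
    wz = z - par[2]
    r2 = wx * wx + wy * wy + wz * wz
    if rt == R_SPHERE:
        return r2 <= par[3] * par[3]
    if rt == R_SHELL:
        return par[3] * par[3] <= r2 <= par[4] * par[4]
    wa = wx * par[3] + wy * par[4] + wz * par[5]
    if abs(wa) > par[8]:
        return False
    rho = np.sqrt(max(0.0, r2 - wa * wa))
    return par[7] - par[8] <= rho <= par[7] + par[8]


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) < 0.99999:
        a = np.sqrt(1.0 - uz * uz)
        nx = ux * cost + sint * (ux * uz * cosp - uy * sinp) / a
        ny = uy * cost + sint * (uy * uz * cosp + ux * sinp) / a
        nz = uz * cost - a * sint * cosp
    else:
        sgn = 1.0 if uz > 0.0 else -1.0
        nx = sint * cosp
        ny = sgn * sint * sinp
        nz = sgn * cost
    norm = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * norm, ny * norm, nz * norm


@njit(cache=True)
def run_kernel(
    # scene
    surf_type, surf_par, obj_bound, obj_cell_ptr,
    cell_surf_ptr, cell_surf_idx, cell_surf_sign, cell_mat,
    obj_surf_ptr, obj_surf_idx,
    # materials
    mat_ptr, mat_le, mat_lpe, mat_linc, mat_lcoh, mat_ltot, mat_lmuen,
    sx_grid, mat_sfrac, x2_grid, mat_fcum,
    fl_ptr, fl_e, fl_pp_ptr, fl_p,
    # source (src_mode: 0 = 6711 rod surface, 1 = point isotropic,
    #         2 = pencil beam along the source axis)
    src_mode, src_pos, src_ax, src_e1, src_e2, rod_r, rod_h,
    spec_e, spec_cdf,
    # tallies
    reg_type, reg_par, reg_bound, reg_matref, reg_gbound,
    # run config
    histories, nbatch, cutoff, rngseed,
):
    np.random.seed(rngseed)
    n_reg = reg_type.shape[0]
    n_src = src_pos.shape[0]
    reg_scores = np.zeros((nbatch, n_reg))
    reg_prim = np.zeros((nbatch, n_reg))  # uncollided component
    reg_coll = np.zeros((nbatch, n_reg))  # collision-estimator cross-check
    reg_hits = np.zeros(n_reg, dtype=np.int64)
    ebook = np.zeros((nbatch, 3))  # emitted, deposited, escaped
    lost = 0
    uncollided_escapes = 0
    per_batch = histories // nbatch
    side_area = 2.0 * np.pi * rod_r * (2.0 * rod_h)
    end_area = 2.0 * np.pi * rod_r * rod_r
    p_side = side_area / (side_area + end_area) if rod_r > 0.0 else 0.0
    n_spec = spec_e.shape[0]

    for batch in range(nbatch):
        for h in range(per_batch):
            gh = batch * per_batch + h
            s = gh % n_src
            # --- emission
            if src_mode == 0 and rod_r > 0.0:
                u = np.random.random()
                if u < p_side:
                    zl = (2.0 * np.random.random() - 1.0) * rod_h
                    phi = 2.0 * np.pi * np.random.random()
                    rr = rod_r
                else:
                    zl = rod_h if np.random.random() < 0.5 else -rod_h
                    rr = rod_r * np.sqrt(np.random.random())
                    phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                x = (src_pos[s, 0] + rr * (cp * src_e1[s, 0]
                     + sp * src_e2[s, 0]) + zl * src_ax[s, 0])
                y = (src_pos[s, 1] + rr * (cp * src_e1[s, 1]
                     + sp * src_e2[s, 1]) + zl * src_ax[s, 1])
                z = (src_pos[s, 2] + rr * (cp * src_e1[s, 2]
                     + sp * src_e2[s, 2]) + zl * src_ax[s, 2])
            else:
                x = src_pos[s, 0]
                y = src_pos[s, 1]
                z = src_pos[s, 2]
            if src_mode == 2:
                dx = src_ax[s, 0]
                dy = src_ax[s, 1]
                dz = src_ax[s, 2]
            else:
                cost = 2.0 * np.random.random() - 1.0
                sint = np.sqrt(1.0 - cost * cost)
                phi = 2.0 * np.pi * np.random.random()
                dx = sint * np.cos(phi)
                dy = sint * np.sin(phi)
                dz = cost
            ue = np.random.random()
            e = spec_e[n_spec - 1]
            for i in range(n_spec):
                if ue <= spec_cdf[i]:
                    e = spec_e[i]
                    break
            w = 1.0
            ncoll = 0
            ebook[batch, 0] += w * e
            x += dx * EPS
            y += dy * EPS
            z += dz * EPS
            cell = locate(x, y, z, surf_type, surf_par, obj_bound,
                          obj_cell_ptr, cell_surf_ptr, cell_surf_idx,
                          cell_surf_sign)
            steps = 0
            while True:
                steps += 1
                if steps > 100000 or cell < 0:
                    lost += 1
                    break
                m = cell_mat[cell]
                le = np.log(e)
                if m >= 0:
                    mu = np.exp(_interp_loglin(le, mat_le, mat_ltot,
                                               mat_ptr[m], mat_ptr[m + 1]))
                    s_col = -np.log(np.random.random()) / mu
                else:
                    s_col = INF
                d_b = boundary_distance(x, y, z, dx, dy, dz, surf_type,
                                        surf_par, obj_bound, obj_surf_ptr,
                                        obj_surf_idx)
                step = s_col if s_col < d_b else d_b
                if step >= INF:
                    lost += 1
                    break
                # --- score track segment (skip if outside all regions)
                gbx = reg_gbound[0] - x
                gby = reg_gbound[1] - y
                gbz = reg_gbound[2] - z
                gt = gbx * dx + gby * dy + gbz * dz
                if gt < 0.0:
                    gt = 0.0
                elif gt > step:
                    gt = step
                gqx = gbx - gt * dx
                gqy = gby - gt * dy
                gqz = gbz - gt * dz
                if (gqx * gqx + gqy * gqy + gqz * gqz
                        > reg_gbound[3] * reg_gbound[3]):
                    n_loop = 0
                else:
                    n_loop = n_reg
                for r in range(n_loop):
                    rb = reg_bound[r, 3]
                    bx = reg_bound[r, 0] - x
                    by = reg_bound[r, 1] - y
                    bz = reg_bound[r, 2] - z
                    tb = bx * dx + by * dy + bz * dz
                    if tb < 0.0:
                        tb = 0.0
                    elif tb > step:
                        tb = step
                    qx = bx - tb * dx
                    qy = by - tb * dy
                    qz = bz - tb * dz
                    if qx * qx + qy * qy + qz * qz > rb * rb:
                        continue
                    chord = _region_chord(reg_type[r], reg_par[r], x, y, z,
                                          dx, dy, dz, step)
                    if chord > 0.0:
                        mref = reg_matref[r]
                        if mref < 0:
                            mref = m
                        if mref >= 0:
                            muen = np.exp(_interp_loglin(
                                le, mat_le, mat_lmuen, mat_ptr[mref],
                                mat_ptr[mref + 1]))
                            reg_scores[batch, r] += w * e * chord * muen
                            if ncoll == 0:
                                reg_prim[batch, r] += w * e * chord * muen
                            reg_hits[r] += 1
                x += dx * step
                y += dy * step
                z += dz * step
                if s_col >= d_b:
                    # boundary crossing: nudge and relocate
                    x += dx * EPS
                    y += dy * EPS
                    z += dz * EPS
                    cell = locate(x, y, z, surf_type, surf_par, obj_bound,
                                  obj_cell_ptr, cell_surf_ptr, cell_surf_idx,
                                  cell_surf_sign)
                    if cell < 0:
                        ebook[batch, 2] += w * e
                        if ncoll == 0:
                            uncollided_escapes += 1
                        break
                    continue
                # --- collision; collision-density kerma cross-check first
                ncoll += 1
                gbx = x - reg_gbound[0]
                gby = y - reg_gbound[1]
                gbz = z - reg_gbound[2]
                if (gbx * gbx + gby * gby + gbz * gbz
                        > reg_gbound[3] * reg_gbound[3]):
                    n_loop = 0
                else:
                    n_loop = n_reg
                for r in range(n_loop):
                    if reg_matref[r] >= 0 and reg_matref[r] != m:
                        continue
                    bx = x - reg_bound[r, 0]
                    by = y - reg_bound[r, 1]
                    bz = z - reg_bound[r, 2]
                    if (bx * bx + by * by + bz * bz
                            > reg_bound[r, 3] * reg_bound[r, 3]):
                        continue
                    if _region_contains(reg_type[r], reg_par[r], x, y, z):
                        muen = np.exp(_interp_loglin(
                            le, mat_le, mat_lmuen, mat_ptr[m],
                            mat_ptr[m + 1]))
                        reg_coll[batch, r] += w * e * muen / mu
                lpe = np.exp(_interp_loglin(le, mat_le, mat_lpe, mat_ptr[m],
                                            mat_ptr[m + 1]))
                linc = np.exp(_interp_loglin(le, mat_le, mat_linc, mat_ptr[m],
                                             mat_ptr[m + 1]))
                lcoh = np.exp(_interp_loglin(le, mat_le, mat_lcoh, mat_ptr[m],
                                             mat_ptr[m + 1]))
                xi = np.random.random() * (lpe + linc + lcoh)
                if xi < lpe:
                    # photoelectric: maybe emit a fluorescence line
                    uf = np.random.random()
                    cum = 0.0
                    emitted_line = -1
                    for l in range(fl_ptr[m], fl_ptr[m + 1]):
                        # line probabilities are stored per line, aligned to
                        # the material's energy-grid knots
                        ngrid = mat_ptr[m + 1] - mat_ptr[m]
                        pl = _interp_loglin(
                            le, mat_le[mat_ptr[m]:mat_ptr[m + 1]],
                            fl_p[fl_pp_ptr[l]:fl_pp_ptr[l] + ngrid],
                            0, ngrid)
                        cum += pl
                        if uf < cum and fl_e[l] < e:
                            emitted_line = l
                            break
                    if emitted_line >= 0:
                        ebook[batch, 1] += w * (e - fl_e[emitted_line])
                        e = fl_e[emitted_line]
                        cost = 2.0 * np.random.random() - 1.0
                        phi = 2.0 * np.pi * np.random.random()
                        sint = np.sqrt(1.0 - cost * cost)
                        dx = sint * np.cos(phi)
                        dy = sint * np.sin(phi)
                        dz = cost
                        if e < cutoff:
                            ebook[batch, 1] += w * e
                            break
                        continue
                    ebook[batch, 1] += w * e
                    break
                if xi < lpe + linc:
                    # incoherent: KN x S(x) rejection
                    k = e / MEC2_KEV
                    while True:
                        cmu = 2.0 * np.random.random() - 1.0
                        kr = 1.0 / (1.0 + k * (1.0 - cmu))
                        fkn = kr * kr * (kr + 1.0 / kr - (1.0 - cmu * cmu))
                        if np.random.random() * 2.0 >= fkn:
                            continue
                        xmt = (e / HC_KEV_A) * np.sqrt((1.0 - cmu) / 2.0)
                        sfr = np.interp(xmt, sx_grid, mat_sfrac[m])
                        if np.random.random() < sfr:
                            break
                    enew = e * kr
                    ebook[batch, 1] += w * (e - enew)
                    e = enew
                    phi = 2.0 * np.pi * np.random.random()
                    dx, dy, dz = _rotate(dx, dy, dz, cmu, phi)
                    if e < cutoff:
                        ebook[batch, 1] += w * e
                        break
                    continue
                # coherent: sample x^2 from cumulative F^2, reject Thomson
                x2max = (e / HC_KEV_A) ** 2
                cmax = np.interp(x2max, x2_grid, mat_fcum[m])
                while True:
                    uc = np.random.random() * cmax
                    # invert cumulative
                    arr = mat_fcum[m]
                    a = 0
                    b = arr.shape[0] - 1
                    while b - a > 1:
                        mid = (a + b) // 2
                        if arr[mid] <= uc:
                            a = mid
                        else:
                            b = mid
                    if arr[b] > arr[a]:
                        frac = (uc - arr[a]) / (arr[b] - arr[a])
                    else:
                        frac = 0.0
                    x2 = x2_grid[a] + frac * (x2_grid[b] - x2_grid[a])
                    cmu = 1.0 - 2.0 * x2 / x2max
                    if cmu < -1.0:
                        cmu = -1.0
                    if np.random.random() < 0.5 * (1.0 + cmu * cmu):
                        break
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cmu, phi)
    return reg_scores, reg_prim, reg_coll, reg_hits, ebook, lost, \
        uncollided_escapes


@njit(cache=True)
def sample_emissions(n, src_pos, src_ax, src_e1, src_e2, rod_r, rod_h,
                     spec_e, spec_cdf, rngseed):
    """Source-sampling helper for tests: positions, directions, energies."""
    np.random.seed(rngseed)
    side_area = 2.0 * np.pi * rod_r * (2.0 * rod_h)
    end_area = 2.0 * np.pi * rod_r * rod_r
    p_side = side_area / (side_area + end_area)
    pos = np.empty((n, 3))
    dirs = np.empty((n, 3))
    es = np.empty(n)
    n_spec = spec_e.shape[0]
    for i in range(n):
        u = np.random.random()
        if u < p_side:
            zl = (2.0 * np.random.random() - 1.0) * rod_h
            rr = rod_r
        else:
            zl = rod_h if np.random.random() < 0.5 else -rod_h
            rr = rod_r * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        cp = np.cos(phi)
        sp = np.sin(phi)
        for ax in range(3):
            pos[i, ax] = (src_pos[0, ax] + rr * (cp * src_e1[0, ax]
                          + sp * src_e2[0, ax]) + zl * src_ax[0, ax])
        cost = 2.0 * np.random.random() - 1.0
        sint = np.sqrt(1.0 - cost * cost)
        phi = 2.0 * np.pi * np.random.random()
        dirs[i, 0] = sint * np.cos(phi)
        dirs[i, 1] = sint * np.sin(phi)
        dirs[i, 2] = cost
        ue = np.random.random()
        es[i] = spec_e[n_spec - 1]
        for j in range(n_spec):
            if ue <= spec_cdf[j]:
                es[i] = spec_e[j]
                break
    return pos, dirs, es
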