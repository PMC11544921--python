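"""Numba kernels for the explicit central-difference solver.

Everything here works in SI units (m, kg, s, Pa).  The public module
`explicit_fem` prepares the arrays and converts to/from reporting units.

Voigt order for symmetric tensors: (xx, yy, zz, xy, yz, zx), with shear
components stored as tensor (not engineering) components.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_INVERTED = 1
STATUS_NAN = 2


@njit(cache=True, fastmath=False)
def _tet_geometry(x, conn, gN, vol):
    """Shape-function gradients and volumes at the current configuration.

    Returns the index of an inverted element, or -1.
    """
    ne = conn.shape[0]
    for e in range(ne):
        n0, n1, n2, n3 = conn[e, 0], conn[e, 1], conn[e, 2], conn[e, 3]
        d00 = x[n1, 0] - x[n0, 0]
        d10 = x[n1, 1] - x[n0, 1]
        d20 = x[n1, 2] - x[n0, 2]
        d01 = x[n2, 0] - x[n0, 0]
        d11 = x[n2, 1] - x[n0, 1]
        d21 = x[n2, 2] - x[n0, 2]
        d02 = x[n3, 0] - x[n0, 0]
        d12 = x[n3, 1] - x[n0, 1]
        d22 = x[n3, 2] - x[n0, 2]
        # cofactors of D (columns = edge vectors)
        c00 = d11 * d22 - d12 * d21
        c01 = d12 * d20 - d10 * d22
        c02 = d10 * d21 - d11 * d20
        det = d00 * c00 + d01 * c01 + d02 * c02
        if det <= 0.0:
            return e
        vol[e] = det / 6.0
        inv = 1.0 / det
        # rows of D^-1
        i00 = c00 * inv
        i01 = (d02 * d21 - d01 * d22) * inv
        i02 = (d01 * d12 - d02 * d11) * inv
        i10 = c01 * inv
        i11 = (d00 * d22 - d02 * d20) * inv
        i12 = (d02 * d10 - d00 * d12) * inv
        i20 = c02 * inv
        i21 = (d01 * d20 - d00 * d21) * inv
        i22 = (d00 * d11 - d01 * d10) * inv
        gN[e, 1, 0] = i00
        gN[e, 1, 1] = i01
        gN[e, 1, 2] = i02
        gN[e, 2, 0] = i10
        gN[e, 2, 1] = i11
        gN[e, 2, 2] = i12
        gN[e, 3, 0] = i20
        gN[e, 3, 1] = i21
        gN[e, 3, 2] = i22
        gN[e, 0, 0] = -(i00 + i10 + i20)
        gN[e, 0, 1] = -(i01 + i11 + i21)
        gN[e, 0, 2] = -(i02 + i12 + i22)
    return -1


@njit(cache=True, fastmath=False)
def _return_map_3d(s, de, lam, mu, sy, H, eqps):
    """J2 radial return with linear isotropic hardening on one point.

    s : stress Voigt-6 (modified in place is avoided; returns new tuple)
    de : strain increment Voigt-6 (tensor shear).
    Returns (s_new 6-tuple, eqps_new, dgamma, vm_new).
    """
    tre = de[0] + de[1] + de[2]
    t0 = s[0] + lam * tre + 2.0 * mu * de[0]
    t1 = s[1] + lam * tre + 2.0 * mu * de[1]
    t2 = s[2] + lam * tre + 2.0 * mu * de[2]
    t3 = s[3] + 2.0 * mu * de[3]
    t4 = s[4] + 2.0 * mu * de[4]
    t5 = s[5] + 2.0 * mu * de[5]
    mean = (t0 + t1 + t2) / 3.0
    d0 = t0 - mean
    d1 = t1 - mean
    d2 = t2 - mean
    vm = np.sqrt(1.5 * (d0 * d0 + d1 * d1 + d2 * d2 + 2.0 * (t3 * t3 + t4 * t4 + t5 * t5)))
    dg = 0.0
    if sy < 1e30:
        f = vm - (sy + H * eqps)
        if f > 0.0:
            dg = f / (3.0 * mu + H)
            fac = 3.0 * mu * dg / vm
            t0 -= fac * d0
            t1 -= fac * d1
            t2 -= fac * d2
            t3 -= fac * t3
            t4 -= fac * t4
            t5 -= fac * t5
            vm = vm - 3.0 * mu * dg
            eqps = eqps + dg
    return t0, t1, t2, t3, t4, t5, eqps, dg, vm


@njit(cache=True, fastmath=False)
def _membrane_return(s, dexx, deyy, dexy, lam, mu, sy, H, eqps):
    """Plane-stress return: find the out-of-plane strain increment that
    zeroes the normal stress, then apply the 3D radial return.

    s : local stress (sxx, syy, szz, sxy).  Returns (4 stresses, eqps,
    dgamma, vm, dezz).
    """
    de = np.zeros(6)
    de[0] = dexx
    de[1] = deyy
    de[3] = dexy
    s6 = np.zeros(6)
    s6[0] = s[0]
    s6[1] = s[1]
    s6[2] = s[2]
    s6[3] = s[3]
    # elastic predictor for the through-thickness strain
    dezz = -(s[2] + lam * (dexx + deyy)) / (lam + 2.0 * mu)
    tol = 1e-9 * (2.0 * mu) + 1e-12
    t0 = t1 = t2 = t3 = 0.0
    eq = eqps
    dg = 0.0
    vm = 0.0
    for _ in range(25):
        de[2] = dezz
        r0, r1, r2, r3, r4, r5, eq, dg, vm = _return_map_3d(
            s6, de, lam, mu, sy, H, eqps
        )
        t0, t1, t2, t3 = r0, r1, r2, r3
        if abs(r2) < tol:
            break
        # numerical derivative d(sigma_zz)/d(dezz)
        h = 1e-8 + 1e-6 * abs(dezz)
        de[2] = dezz + h
        p0, p1, p2, p3, p4, p5, _eq, _dg, _vm = _return_map_3d(
            s6, de, lam, mu, sy, H, eqps
        )
        dsz = (p2 - r2) / h
        if dsz == 0.0:
            break
        dezz = dezz - r2 / dsz
    return t0, t1, t2, t3, eq, dg, vm, dezz


@njit(cache=True, fastmath=False)
def run_explicit(
    x,
    v,
    mass,
    # tetrahedra
    conn,
    lam_e,
    mu_e,
    sy_e,
    h_e,
    rho_e,
    lchar_e,
    # membrane triangles
    tri,
    tlam,
    tmu,
    tsy,
    th_h,
    tthk,
    trho,
    # contact
    surf_nodes,
    trib_area,
    kfound,
    # controls
    grav,
    dt,
    nsteps,
    out_every,
    b1,
    npa,
    # state (in/out)
    sig,
    eqps,
    qvisc,
    peak_vm,
    sig_tri,
    eqps_tri,
    peak_vm_tri,
    # outputs
    times,
    fc_out,
    vcom_out,
    ke_out,
    ie_out,
    ue_out,
    wp_out,
    ce_out,
    qv_out,
    wg_out,
    err_out,
):
    nn = x.shape[0]
    ne = conn.shape[0]
    nt = tri.shape[0]
    ns = surf_nodes.shape[0]

    gN = np.zeros((ne, 4, 3))
    vol = np.zeros(ne)
    bad = _tet_geometry(x, conn, gN, vol)
    if bad >= 0:
        return STATUS_INVERTED, 0

    f = np.zeros((nn, 3))
    trl_e = np.zeros(ne)
    node_trl = np.zeros(nn)
    node_vw = np.zeros(nn)

    mtot = 0.0
    for i in range(nn):
        mtot += mass[i]

    ie_acc = 0.0
    wp_acc = 0.0
    qv_acc = 0.0
    wg_acc = 0.0
    ke0 = 0.0
    for i in range(nn):
        ke0 += 0.5 * mass[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)

    n_rec = 0
    for step in range(nsteps):
        # ---- pass A: nodal forces at the current configuration -----------
        for i in range(nn):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = -mass[i] * grav

        if npa:
            # adjoint of the volumetric-strain nodal averaging: forces are
            # computed from the nodal-averaged pressure (consistent virtual
            # work; the pressure update in pass B uses the averaged strain)
            for i in range(nn):
                node_trl[i] = 0.0
                node_vw[i] = 0.0
            for e in range(ne):
                pe = (sig[e, 0] + sig[e, 1] + sig[e, 2]) / 3.0
                for a in range(4):
                    na = conn[e, a]
                    node_trl[na] += vol[e] * pe
                    node_vw[na] += vol[e]
            for i in range(nn):
                if node_vw[i] > 0.0:
                    node_trl[i] /= node_vw[i]

        ue = 0.0
        for e in range(ne):
            ve = vol[e]
            q = qvisc[e]
            p_shift = 0.0
            if npa:
                pbar = 0.25 * (
                    node_trl[conn[e, 0]]
                    + node_trl[conn[e, 1]]
                    + node_trl[conn[e, 2]]
                    + node_trl[conn[e, 3]]
                )
                p_shift = pbar - (sig[e, 0] + sig[e, 1] + sig[e, 2]) / 3.0
            s0 = sig[e, 0] - q + p_shift
            s1 = sig[e, 1] - q + p_shift
            s2 = sig[e, 2] - q + p_shift
            s3 = sig[e, 3]
            s4 = sig[e, 4]
            s5 = sig[e, 5]
            for a in range(4):
                na = conn[e, a]
                g0 = gN[e, a, 0]
                g1 = gN[e, a, 1]
                g2 = gN[e, a, 2]
                f[na, 0] -= ve * (s0 * g0 + s3 * g1 + s5 * g2)
                f[na, 1] -= ve * (s3 * g0 + s1 * g1 + s4 * g2)
                f[na, 2] -= ve * (s5 * g0 + s4 * g1 + s2 * g2)
            # elastic strain energy from the current stress (linear isotropic)
            lam = lam_e[e]
            mu = mu_e[e]
            young = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
            nu = lam / (2.0 * (lam + mu))
            ss = (
                sig[e, 0] ** 2 + sig[e, 1] ** 2 + sig[e, 2] ** 2
                + 2.0 * (sig[e, 3] ** 2 + sig[e, 4] ** 2 + sig[e, 5] ** 2)
            )
            tr = sig[e, 0] + sig[e, 1] + sig[e, 2]
            ue += ve * ((1.0 + nu) * ss - nu * tr * tr) / (2.0 * young)

        # membrane forces
        for e in range(nt):
            n0, n1, n2 = tri[e, 0], tri[e, 1], tri[e, 2]
            e1x = x[n1, 0] - x[n0, 0]
            e1y = x[n1, 1] - x[n0, 1]
            e1z = x[n1, 2] - x[n0, 2]
            rx = x[n2, 0] - x[n0, 0]
            ry = x[n2, 1] - x[n0, 1]
            rz = x[n2, 2] - x[n0, 2]
            nx_ = e1y * rz - e1z * ry
            ny_ = e1z * rx - e1x * rz
            nz_ = e1x * ry - e1y * rx
            nlen = np.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
            area = 0.5 * nlen
            if area <= 0.0:
                return STATUS_INVERTED, n_rec
            l1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            u1x, u1y, u1z = e1x / l1, e1y / l1, e1z / l1
            wx, wy, wz = nx_ / nlen, ny_ / nlen, nz_ / nlen
            u2x = wy * u1z - wz * u1y
            u2y = wz * u1x - wx * u1z
            u2z = wx * u1y - wy * u1x
            # local 2D coordinates
            p1 = l1
            q1x = rx * u1x + ry * u1y + rz * u1z
            q1y = rx * u2x + ry * u2y + rz * u2z
            a2 = 2.0 * area
            # CST gradients from local node coords (0,0),(p1,0),(q1x,q1y):
            # Nk,x = (y_{k+1} - y_{k+2}) / 2A ; Nk,y = (x_{k+2} - x_{k+1}) / 2A
            y0, y1, y2 = 0.0, 0.0, q1y
            x0_, x1_, x2_ = 0.0, p1, q1x
            g0x = (y1 - y2) / a2
            g0y = (x2_ - x1_) / a2
            g1x = (y2 - y0) / a2
            g1y = (x0_ - x2_) / a2
            g2x = (y0 - y1) / a2
            g2y = (x1_ - x0_) / a2
            sxx = sig_tri[e, 0]
            syy = sig_tri[e, 1]
            sxy = sig_tri[e, 3]
            vt = area * tthk[e]
            # nodal forces: f_loc_a = -vt * (sigma . gradN_a)
            for a in range(3):
                if a == 0:
                    gx, gy = g0x, g0y
                    na = n0
                elif a == 1:
                    gx, gy = g1x, g1y
                    na = n1
                else:
                    gx, gy = g2x, g2y
                    na = n2
                flx = -vt * (sxx * gx + sxy * gy)
                fly = -vt * (sxy * gx + syy * gy)
                f[na, 0] += flx * u1x + fly * u2x
                f[na, 1] += flx * u1y + fly * u2y
                f[na, 2] += flx * u1z + fly * u2z
            lam = tlam[e]
            mu = tmu[e]
            young = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
            nu = lam / (2.0 * (lam + mu))
            ss = (
                sig_tri[e, 0] ** 2 + sig_tri[e, 1] ** 2 + sig_tri[e, 2] ** 2
                + 2.0 * sig_tri[e, 3] ** 2
            )
            tr = sig_tri[e, 0] + sig_tri[e, 1] + sig_tri[e, 2]
            ue += vt * ((1.0 + nu) * ss - nu * tr * tr) / (2.0 * young)

        # contact (elastic foundation below z=0, frictionless)
        fc = 0.0
        ce = 0.0
        for si in range(ns):
            i = surf_nodes[si]
            z = x[i, 2]
            if z < 0.0:
                k = kfound * trib_area[si]
                fz = -k * z
                f[i, 2] += fz
                fc += fz
                ce += 0.5 * k * z * z

        # ---- integrate ----------------------------------------------------
        ke = 0.0
        vcx = 0.0
        vcy = 0.0
        vcz = 0.0
        for i in range(nn):
            m = mass[i]
            ax = f[i, 0] / m
            ay = f[i, 1] / m
            az = f[i, 2] / m
            vx_old = v[i, 0]
            vy_old = v[i, 1]
            vz_old = v[i, 2]
            v[i, 0] = vx_old + dt * ax
            v[i, 1] = vy_old + dt * ay
            v[i, 2] = vz_old + dt * az
            vmx = 0.5 * (vx_old + v[i, 0])
            vmy = 0.5 * (vy_old + v[i, 1])
            vmz = 0.5 * (vz_old + v[i, 2])
            ke += 0.5 * m * (vmx * vmx + vmy * vmy + vmz * vmz)
            vcx += m * vmx
            vcy += m * vmy
            vcz += m * vmz

        # ---- record at time t_n (state before the position update) -------
        if step % out_every == 0 or step == nsteps - 1:
            times[n_rec] = step * dt
            fc_out[n_rec] = fc
            vcom_out[n_rec, 0] = vcx / mtot
            vcom_out[n_rec, 1] = vcy / mtot
            vcom_out[n_rec, 2] = vcz / mtot
            ke_out[n_rec] = ke
            ie_out[n_rec] = ie_acc
            ue_out[n_rec] = ue
            wp_out[n_rec] = wp_acc
            ce_out[n_rec] = ce
            qv_out[n_rec] = qv_acc
            wg_out[n_rec] = wg_acc
            err_out[n_rec] = (ke + ie_acc + ce + qv_acc) - (ke0 + wg_acc)
            if not np.isfinite(ke + ie_acc + ce):
                return STATUS_NAN, n_rec + 1
            n_rec += 1

        for i in range(nn):
            x[i, 0] += dt * v[i, 0]
            x[i, 1] += dt * v[i, 1]
            x[i, 2] += dt * v[i, 2]
            wg_acc += -mass[i] * grav * dt * v[i, 2]

        # ---- pass B: update geometry, strains, stresses -------------------
        bad = _tet_geometry(x, conn, gN, vol)
        if bad >= 0:
            return STATUS_INVERTED, n_rec

        if npa:
            # nodal averaging of the volumetric strain rate
            for i in range(nn):
                node_trl[i] = 0.0
                node_vw[i] = 0.0
            for e in range(ne):
                l00 = 0.0
                l11 = 0.0
                l22 = 0.0
                for a in range(4):
                    na = conn[e, a]
                    l00 += v[na, 0] * gN[e, a, 0]
                    l11 += v[na, 1] * gN[e, a, 1]
                    l22 += v[na, 2] * gN[e, a, 2]
                trl_e[e] = l00 + l11 + l22
                for a in range(4):
                    na = conn[e, a]
                    node_trl[na] += vol[e] * trl_e[e]
                    node_vw[na] += vol[e]
            for i in range(nn):
                if node_vw[i] > 0.0:
                    node_trl[i] /= node_vw[i]

        for e in range(ne):
            n0, n1, n2, n3 = conn[e, 0], conn[e, 1], conn[e, 2], conn[e, 3]
            l00 = 0.0
            l01 = 0.0
            l02 = 0.0
            l10 = 0.0
            l11 = 0.0
            l12 = 0.0
            l20 = 0.0
            l21 = 0.0
            l22 = 0.0
            for a in range(4):
                na = conn[e, a]
                g0 = gN[e, a, 0]
                g1 = gN[e, a, 1]
                g2 = gN[e, a, 2]
                l00 += v[na, 0] * g0
                l01 += v[na, 0] * g1
                l02 += v[na, 0] * g2
                l10 += v[na, 1] * g0
                l11 += v[na, 1] * g1
                l12 += v[na, 1] * g2
                l20 += v[na, 2] * g0
                l21 += v[na, 2] * g1
                l22 += v[na, 2] * g2
            de0 = dt * l00
            de1 = dt * l11
            de2 = dt * l22
            de3 = dt * 0.5 * (l01 + l10)
            de4 = dt * 0.5 * (l12 + l21)
            de5 = dt * 0.5 * (l02 + l20)
            trl = l00 + l11 + l22
            if npa:
                avg = 0.25 * (
                    node_trl[n0] + node_trl[n1] + node_trl[n2] + node_trl[n3]
                )
                corr = dt * (avg - trl) / 3.0
                de0 += corr
                de1 += corr
                de2 += corr
                trl = avg
            # Jaumann rotation of the stored stress
            a_ = dt * 0.5 * (l01 - l10)
            b_ = dt * 0.5 * (l02 - l20)
            c_ = dt * 0.5 * (l12 - l21)
            s0 = sig[e, 0]
            s1 = sig[e, 1]
            s2 = sig[e, 2]
            s3 = sig[e, 3]
            s4 = sig[e, 4]
            s5 = sig[e, 5]
            r0 = s0 + 2.0 * (a_ * s3 + b_ * s5)
            r1 = s1 + 2.0 * (-a_ * s3 + c_ * s4)
            r2 = s2 - 2.0 * (b_ * s5 + c_ * s4)
            r3 = s3 + a_ * (s1 - s0) + b_ * s4 + c_ * s5
            r4 = s4 - a_ * s5 - b_ * s3 + c_ * (s2 - s1)
            r5 = s5 + a_ * s4 + b_ * (s2 - s0) - c_ * s3
            srot = np.empty(6)
            srot[0] = r0
            srot[1] = r1
            srot[2] = r2
            srot[3] = r3
            srot[4] = r4
            srot[5] = r5
            de = np.empty(6)
            de[0] = de0
            de[1] = de1
            de[2] = de2
            de[3] = de3
            de[4] = de4
            de[5] = de5
            t0, t1, t2, t3, t4, t5, eq_new, dg, vm = _return_map_3d(
                srot, de, lam_e[e], mu_e[e], sy_e[e], h_e[e], eqps[e]
            )
            ve = vol[e]
            ie_acc += ve * 0.5 * (
                (r0 + t0) * de0
                + (r1 + t1) * de1
                + (r2 + t2) * de2
                + 2.0 * ((r3 + t3) * de3 + (r4 + t4) * de4 + (r5 + t5) * de5)
            )
            if dg > 0.0:
                wp_acc += ve * vm * dg
                eqps[e] = eq_new
            sig[e, 0] = t0
            sig[e, 1] = t1
            sig[e, 2] = t2
            sig[e, 3] = t3
            sig[e, 4] = t4
            sig[e, 5] = t5
            if vm > peak_vm[e]:
                peak_vm[e] = vm
            # viscous dissipation of the pressure applied this step,
            # then the new viscous pressure for the next force pass
            q = qvisc[e]
            if q != 0.0:
                qv_acc += q * (-trl) * ve * dt
            if trl < 0.0:
                qvisc[e] = b1 * rho_e[e] * lchar_e[e] * np.sqrt(
                    (lam_e[e] + 2.0 * mu_e[e]) / rho_e[e]
                ) * (-trl)
            else:
                qvisc[e] = 0.0

        # membrane update
        for e in range(nt):
            n0, n1, n2 = tri[e, 0], tri[e, 1], tri[e, 2]
            e1x = x[n1, 0] - x[n0, 0]
            e1y = x[n1, 1] - x[n0, 1]
            e1z = x[n1, 2] - x[n0, 2]
            rx = x[n2, 0] - x[n0, 0]
            ry = x[n2, 1] - x[n0, 1]
            rz = x[n2, 2] - x[n0, 2]
            nx_ = e1y * rz - e1z * ry
            ny_ = e1z * rx - e1x * rz
            nz_ = e1x * ry - e1y * rx
            nlen = np.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
            area = 0.5 * nlen
            if area <= 0.0:
                return STATUS_INVERTED, n_rec
            l1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            u1x, u1y, u1z = e1x / l1, e1y / l1, e1z / l1
            wx, wy, wz = nx_ / nlen, ny_ / nlen, nz_ / nlen
            u2x = wy * u1z - wz * u1y
            u2y = wz * u1x - wx * u1z
            u2z = wx * u1y - wy * u1x
            p1 = l1
            q1x = rx * u1x + ry * u1y + rz * u1z
            q1y = rx * u2x + ry * u2y + rz * u2z
            a2 = 2.0 * area
            y0, y1, y2 = 0.0, 0.0, q1y
            x0_, x1_, x2_ = 0.0, p1, q1x
            g0x = (y1 - y2) / a2
            g0y = (x2_ - x1_) / a2
            g1x = (y2 - y0) / a2
            g1y = (x0_ - x2_) / a2
            g2x = (y0 - y1) / a2
            g2y = (x1_ - x0_) / a2
            lxx = 0.0
            lxy = 0.0
            lyx = 0.0
            lyy = 0.0
            for a in range(3):
                if a == 0:
                    gx, gy = g0x, g0y
                    na = n0
                elif a == 1:
                    gx, gy = g1x, g1y
                    na = n1
                else:
                    gx, gy = g2x, g2y
                    na = n2
                vlx = v[na, 0] * u1x + v[na, 1] * u1y + v[na, 2] * u1z
                vly = v[na, 0] * u2x + v[na, 1] * u2y + v[na, 2] * u2z
                lxx += vlx * gx
                lxy += vlx * gy
                lyx += vly * gx
                lyy += vly * gy
            dexx = dt * lxx
            deyy = dt * lyy
            dexy = dt * 0.5 * (lxy + lyx)
            s_old0 = sig_tri[e, 0]
            s_old1 = sig_tri[e, 1]
            s_old2 = sig_tri[e, 2]
            s_old3 = sig_tri[e, 3]
            sloc = np.empty(4)
            sloc[0] = s_old0
            sloc[1] = s_old1
            sloc[2] = s_old2
            sloc[3] = s_old3
            t0, t1, t2, t3, eq_new, dg, vm, dezz = _membrane_return(
                sloc, dexx, deyy, dexy, tlam[e], tmu[e], tsy[e], th_h[e], eqps_tri[e]
            )
            vt = area * tthk[e]
            ie_acc += vt * 0.5 * (
                (s_old0 + t0) * dexx
                + (s_old1 + t1) * deyy
                + (s_old2 + t2) * dezz
                + 2.0 * (s_old3 + t3) * dexy
            )
            if dg > 0.0:
                wp_acc += vt * vm * dg
                eqps_tri[e] = eq_new
            sig_tri[e, 0] = t0
            sig_tri[e, 1] = t1
            sig_tri[e, 2] = t2
            sig_tri[e, 3] = t3
            if vm > peak_vm_tri[e]:
                peak_vm_tri[e] = vm

    return STATUS_OK, n_rec
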