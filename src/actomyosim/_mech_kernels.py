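"""Numba kernels for the elastic network energy and its relaxation.

The relaxation is a monotone Barzilai-Borwein descent with Armijo
backtracking: every accepted step strictly lowers the energy, displacement
per iteration is capped so excluded-volume contacts cannot be jumped, and
iteration stops when the largest per-bead residual force falls below the
tolerance or the iteration cap is reached.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["energy_grad_kernel", "relax_kernel"]


@njit(cache=True)
def energy_grad_kernel(
    X, G,
    seg_i, seg_j, l0, k_stretch,
    bend_a, bend_b, bend_c, k_bend,
    sp_i0, sp_i1, sp_j0, sp_j1, sp_sa, sp_sb, sp_k, sp_rest,
    ev_i, ev_j, d_clear, k_ev,
    lx, ly, lz, k_wall,
):
    n = X.shape[0]
    for i in range(n):
        G[i, 0] = 0.0
        G[i, 1] = 0.0
        G[i, 2] = 0.0
    E = 0.0

    for s in range(seg_i.shape[0]):
        i = seg_i[s]
        j = seg_j[s]
        dx = X[j, 0] - X[i, 0]
        dy = X[j, 1] - X[i, 1]
        dz = X[j, 2] - X[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-9:
            L = 1e-9
        dL = L - l0
        E += 0.5 * k_stretch * dL * dL
        c = k_stretch * dL / L
        G[j, 0] += c * dx
        G[j, 1] += c * dy
        G[j, 2] += c * dz
        G[i, 0] -= c * dx
        G[i, 1] -= c * dy
        G[i, 2] -= c * dz

    for s in range(bend_a.shape[0]):
        a = bend_a[s]
        b = bend_b[s]
        c3 = bend_c[s]
        ux = X[b, 0] - X[a, 0]
        uy = X[b, 1] - X[a, 1]
        uz = X[b, 2] - X[a, 2]
        vx = X[c3, 0] - X[b, 0]
        vy = X[c3, 1] - X[b, 1]
        vz = X[c3, 2] - X[b, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-9:
            nu = 1e-9
        if nv < 1e-9:
            nv = 1e-9
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        cos = uhx * vhx + uhy * vhy + uhz * vhz
        E += k_bend * (1.0 - cos)
        # dE/du = -k (vh - cos*uh)/nu ; dE/dv = -k (uh - cos*vh)/nv
        dux = -k_bend * (vhx - cos * uhx) / nu
        duy = -k_bend * (vhy - cos * uhy) / nu
        duz = -k_bend * (vhz - cos * uhz) / nu
        dvx = -k_bend * (uhx - cos * vhx) / nv
        dvy = -k_bend * (uhy - cos * vhy) / nv
        dvz = -k_bend * (uhz - cos * vhz) / nv
        G[a, 0] -= dux
        G[a, 1] -= duy
        G[a, 2] -= duz
        G[b, 0] += dux - dvx
        G[b, 1] += duy - dvy
        G[b, 2] += duz - dvz
        G[c3, 0] += dvx
        G[c3, 1] += dvy
        G[c3, 2] += dvz

    for s in range(sp_k.shape[0]):
        i0, i1, j0, j1 = sp_i0[s], sp_i1[s], sp_j0[s], sp_j1[s]
        sa, sb = sp_sa[s], sp_sb[s]
        pax = (1 - sa) * X[i0, 0] + sa * X[i1, 0]
        pay = (1 - sa) * X[i0, 1] + sa * X[i1, 1]
        paz = (1 - sa) * X[i0, 2] + sa * X[i1, 2]
        pbx = (1 - sb) * X[j0, 0] + sb * X[j1, 0]
        pby = (1 - sb) * X[j0, 1] + sb * X[j1, 1]
        pbz = (1 - sb) * X[j0, 2] + sb * X[j1, 2]
        dx = pbx - pax
        dy = pby - pay
        dz = pbz - paz
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            d = 1e-9
        dd = d - sp_rest[s]
        E += 0.5 * sp_k[s] * dd * dd
        c = sp_k[s] * dd / d
        fx, fy, fz = c * dx, c * dy, c * dz
        G[j0, 0] += (1 - sb) * fx
        G[j0, 1] += (1 - sb) * fy
        G[j0, 2] += (1 - sb) * fz
        G[j1, 0] += sb * fx
        G[j1, 1] += sb * fy
        G[j1, 2] += sb * fz
        G[i0, 0] -= (1 - sa) * fx
        G[i0, 1] -= (1 - sa) * fy
        G[i0, 2] -= (1 - sa) * fz
        G[i1, 0] -= sa * fx
        G[i1, 1] -= sa * fy
        G[i1, 2] -= sa * fz

    for s in range(ev_i.shape[0]):
        i = ev_i[s]
        j = ev_j[s]
        dx = X[j, 0] - X[i, 0]
        dy = X[j, 1] - X[i, 1]
        dz = X[j, 2] - X[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            d = 1e-9
        pen = d_clear - d
        if pen > 0:
            E += 0.5 * k_ev * pen * pen
            c = -k_ev * pen / d
            G[j, 0] += c * dx
            G[j, 1] += c * dy
            G[j, 2] += c * dz
            G[i, 0] -= c * dx
            G[i, 1] -= c * dy
            G[i, 2] -= c * dz

    for i in range(n):
        for k in range(3):
            lim = lx if k == 0 else (ly if k == 1 else lz)
            x = X[i, k]
            if x < 0.0:
                E += 0.5 * k_wall * x * x
                G[i, k] += k_wall * x
            elif x > lim:
                E += 0.5 * k_wall * (x - lim) * (x - lim)
                G[i, k] += k_wall * (x - lim)

    return E


@njit(cache=True)
def relax_kernel(
    X0,
    seg_i, seg_j, l0, k_stretch,
    bend_a, bend_b, bend_c, k_bend,
    sp_i0, sp_i1, sp_j0, sp_j1, sp_sa, sp_sb, sp_k, sp_rest,
    ev_i, ev_j, d_clear, k_ev,
    lx, ly, lz, k_wall,
    force_tol, max_iter, max_disp,
):
    """Monotone BB descent; returns (X, E, iterations used)."""
    n = X0.shape[0]
    X = X0.copy()
    G = np.zeros((n, 3))
    Xn = np.zeros((n, 3))
    Gn = np.zeros((n, 3))

    def _eval(Y, Gout):
        return energy_grad_kernel(
            Y, Gout, seg_i, seg_j, l0, k_stretch,
            bend_a, bend_b, bend_c, k_bend,
            sp_i0, sp_i1, sp_j0, sp_j1, sp_sa, sp_sb, sp_k, sp_rest,
            ev_i, ev_j, d_clear, k_ev, lx, ly, lz, k_wall,
        )

    E = _eval(X, G)
    step = 1e-2
    it = 0
    while it < max_iter:
        gmax2 = 0.0
        gnorm2 = 0.0
        for i in range(n):
            m2 = G[i, 0] ** 2 + G[i, 1] ** 2 + G[i, 2] ** 2
            gnorm2 += m2
            if m2 > gmax2:
                gmax2 = m2
        if gmax2 <= force_tol * force_tol:
            break
        # cap the displacement of the largest-force bead
        s = step
        if s * np.sqrt(gmax2) > max_disp:
            s = max_disp / np.sqrt(gmax2)
        # Armijo backtracking on the descent direction -G
        accepted = False
        for _bt in range(30):
            for i in range(n):
                Xn[i, 0] = X[i, 0] - s * G[i, 0]
                Xn[i, 1] = X[i, 1] - s * G[i, 1]
                Xn[i, 2] = X[i, 2] - s * G[i, 2]
            En = _eval(Xn, Gn)
            if En <= E - 1e-4 * s * gnorm2:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        # BB1 step from the accepted move
        sy = 0.0
        ss = 0.0
        for i in range(n):
            for k in range(3):
                ds = Xn[i, k] - X[i, k]
                dy = Gn[i, k] - G[i, k]
                sy += ds * dy
                ss += ds * ds
        step = ss / sy if sy > 1e-30 else s * 2.0
        if step <= 0 or step > 1.0:
            step = 1e-2
        for i in range(n):
            for k in range(3):
                X[i, k] = Xn[i, k]
                G[i, k] = Gn[i, k]
        E = En
        it += 1
    return X, E, it
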