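"""Numba stencil kernels for the staggered-grid pressure-velocity FDTD scheme.

Sixth-order central differences in space on a staggered lattice, leapfrog in
time.  Pressure is split per axis (split-field PML); absorption enters as a
matched loss term ``a = alpha * c`` applied to both pressure and velocity,
which gives a spatial decay of exactly ``alpha`` Np/m for a travelling wave
with no phase-speed error.  Damping is integrated semi-implicitly
(Crank-Nicolson on the loss term).
"""

import numpy as np
from numba import njit

# 6th-order staggered first-derivative coefficients (half-node offsets 1/2, 3/2, 5/2)
C1 = 75.0 / 64.0
C2 = -25.0 / 384.0
C3 = 3.0 / 640.0

#: sum of |coefficients|, enters the CFL bound cfl < 1/(S*sqrt(ndim))
STENCIL_L1 = C1 - C2 + C3


@njit(cache=True, fastmath=True)
def step_1d(p, vx, rhoh, kap, att, atth, sgp, sgv, bn, dx, dt):
    n = p.shape[0]
    for i in range(2, n - 3):
        dpdx = (C1 * (p[i + 1] - p[i]) + C2 * (p[i + 2] - p[i - 1])
                + C3 * (p[i + 3] - p[i - 2])) / dx
        d = (sgv[i] + atth[i]) * dt
        vx[i] = ((1.0 - 0.5 * d) * vx[i] - dt * dpdx / rhoh[i]) / (1.0 + 0.5 * d)
    for i in range(3, n - 2):
        dvdx = (C1 * (vx[i] - vx[i - 1]) + C2 * (vx[i + 1] - vx[i - 2])
                + C3 * (vx[i + 2] - vx[i - 3])) / dx
        d = (sgp[i] + att[i]) * dt
        nl = 1.0 + bn[i] * p[i]
        p[i] = ((1.0 - 0.5 * d) * p[i] - dt * kap[i] * nl * dvdx) / (1.0 + 0.5 * d)


@njit(cache=True, fastmath=True)
def step_2d(p, p1, p2, vx, vz, rhoxh, rhozh, kap, att, attxh, attzh,
            sgx_p, sgx_v, sgz_p, sgz_v, bn, dx, dt):
    nx, nz = p.shape
    for i in range(2, nx - 3):
        for j in range(nz):
            dpdx = (C1 * (p[i + 1, j] - p[i, j]) + C2 * (p[i + 2, j] - p[i - 1, j])
                    + C3 * (p[i + 3, j] - p[i - 2, j])) / dx
            d = (sgx_v[i] + attxh[i, j]) * dt
            vx[i, j] = ((1.0 - 0.5 * d) * vx[i, j] - dt * dpdx / rhoxh[i, j]) / (1.0 + 0.5 * d)
    for i in range(nx):
        for j in range(2, nz - 3):
            dpdz = (C1 * (p[i, j + 1] - p[i, j]) + C2 * (p[i, j + 2] - p[i, j - 1])
                    + C3 * (p[i, j + 3] - p[i, j - 2])) / dx
            d = (sgz_v[j] + attzh[i, j]) * dt
            vz[i, j] = ((1.0 - 0.5 * d) * vz[i, j] - dt * dpdz / rhozh[i, j]) / (1.0 + 0.5 * d)
    for i in range(3, nx - 2):
        for j in range(3, nz - 2):
            divx = (C1 * (vx[i, j] - vx[i - 1, j]) + C2 * (vx[i + 1, j] - vx[i - 2, j])
                    + C3 * (vx[i + 2, j] - vx[i - 3, j])) / dx
            divz = (C1 * (vz[i, j] - vz[i, j - 1]) + C2 * (vz[i, j + 1] - vz[i, j - 2])
                    + C3 * (vz[i, j + 2] - vz[i, j - 3])) / dx
            nl = 1.0 + bn[i, j] * p[i, j]
            dkn = dt * kap[i, j] * nl
            d1 = (sgx_p[i] + att[i, j]) * dt
            p1[i, j] = ((1.0 - 0.5 * d1) * p1[i, j] - dkn * divx) / (1.0 + 0.5 * d1)
            d2 = (sgz_p[j] + att[i, j]) * dt
            p2[i, j] = ((1.0 - 0.5 * d2) * p2[i, j] - dkn * divz) / (1.0 + 0.5 * d2)
            p[i, j] = p1[i, j] + p2[i, j]


@njit(cache=True, fastmath=True)
def step_3d(p, p1, p2, p3, vx, vy, vz, rhoxh, rhoyh, rhozh, kap, att,
            sgx_p, sgx_v, sgy_p, sgy_v, sgz_p, sgz_v, bn, dx, dt):
    nx, ny, nz = p.shape
    for i in range(2, nx - 3):
        for j in range(ny):
            for k in range(nz):
                dpdx = (C1 * (p[i + 1, j, k] - p[i, j, k])
                        + C2 * (p[i + 2, j, k] - p[i - 1, j, k])
                        + C3 * (p[i + 3, j, k] - p[i - 2, j, k])) / dx
                d = (sgx_v[i] + att[i, j, k]) * dt
                vx[i, j, k] = ((1.0 - 0.5 * d) * vx[i, j, k]
                               - dt * dpdx / rhoxh[i, j, k]) / (1.0 + 0.5 * d)
    for i in range(nx):
        for j in range(2, ny - 3):
            for k in range(nz):
                dpdy = (C1 * (p[i, j + 1, k] - p[i, j, k])
                        + C2 * (p[i, j + 2, k] - p[i, j - 1, k])
                        + C3 * (p[i, j + 3, k] - p[i, j - 2, k])) / dx
                d = (sgy_v[j] + att[i, j, k]) * dt
                vy[i, j, k] = ((1.0 - 0.5 * d) * vy[i, j, k]
                               - dt * dpdy / rhoyh[i, j, k]) / (1.0 + 0.5 * d)
    for i in range(nx):
        for j in range(ny):
            for k in range(2, nz - 3):
                dpdz = (C1 * (p[i, j, k + 1] - p[i, j, k])
                        + C2 * (p[i, j, k + 2] - p[i, j, k - 1])
                        + C3 * (p[i, j, k + 3] - p[i, j, k - 2])) / dx
                d = (sgz_v[k] + att[i, j, k]) * dt
                vz[i, j, k] = ((1.0 - 0.5 * d) * vz[i, j, k]
                               - dt * dpdz / rhozh[i, j, k]) / (1.0 + 0.5 * d)
    for i in range(3, nx - 2):
        for j in range(3, ny - 2):
            for k in range(3, nz - 2):
                divx = (C1 * (vx[i, j, k] - vx[i - 1, j, k])
                        + C2 * (vx[i + 1, j, k] - vx[i - 2, j, k])
                        + C3 * (vx[i + 2, j, k] - vx[i - 3, j, k])) / dx
                divy = (C1 * (vy[i, j, k] - vy[i, j - 1, k])
                        + C2 * (vy[i, j + 1, k] - vy[i, j - 2, k])
                        + C3 * (vy[i, j + 2, k] - vy[i, j - 3, k])) / dx
                divz = (C1 * (vz[i, j, k] - vz[i, j, k - 1])
                        + C2 * (vz[i, j, k + 1] - vz[i, j, k - 2])
                        + C3 * (vz[i, j, k + 2] - vz[i, j, k - 3])) / dx
                nl = 1.0 + bn[i, j, k] * p[i, j, k]
                dkn = dt * kap[i, j, k] * nl
                d1 = (sgx_p[i] + att[i, j, k]) * dt
                p1[i, j, k] = ((1.0 - 0.5 * d1) * p1[i, j, k] - dkn * divx) / (1.0 + 0.5 * d1)
                d2 = (sgy_p[j] + att[i, j, k]) * dt
                p2[i, j, k] = ((1.0 - 0.5 * d2) * p2[i, j, k] - dkn * divy) / (1.0 + 0.5 * d2)
                d3 = (sgz_p[k] + att[i, j, k]) * dt
                p3[i, j, k] = ((1.0 - 0.5 * d3) * p3[i, j, k] - dkn * divz) / (1.0 + 0.5 * d3)
                p[i, j, k] = p1[i, j, k] + p2[i, j, k] + p3[i, j, k]


@njit(cache=True, fastmath=True)
def accumulate_window(p, msq, peak):
    flat_p = p.ravel()
    flat_m = msq.ravel()
    flat_k = peak.ravel()
    for i in range(flat_p.size):
        v = flat_p[i]
        flat_m[i] += v * v
        a = abs(v)
        if a > flat_k[i]:
            flat_k[i] = a
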