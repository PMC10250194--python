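"""Numba kernels: density-conserving splat convection and real-space projection.

Convection is a forward splat: each canonical voxel y deposits its density at
the mapped position u(y) = y + d(y) through an interpolation kernel, so total
mass is conserved whenever the deposit stays inside the grid.  Projection is
rotate-then-sum with trilinear resampling; its adjoint splats an image back
along the rays.  All kernels are single-threaded and deterministic.

Array conventions: volumes are [z, y, x]; displacement fields are
[z, y, x, (dx, dy, dz)]; images are [y, x].  Rotation matrices map
canonical-frame coordinates to the microscope frame, about the center voxel
c = N // 2; shifts are in pixels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OPTS = dict(cache=True, fastmath=True)


# ---------------------------------------------------------------------------
# trilinear splat (convection) and its gradients


@njit(**_OPTS)
def splat_trilinear(V, disp):
    n = V.shape[0]
    W = np.zeros((n, n, n))
    for z in range(n):
        for y in range(n):
            for x in range(n):
                v = V[z, y, x]
                px = x + disp[z, y, x, 0]
                py = y + disp[z, y, x, 1]
                pz = z + disp[z, y, x, 2]
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                fx = px - ix
                fy = py - iy
                fz = pz - iz
                for dz in range(2):
                    wz = fz if dz == 1 else 1.0 - fz
                    zz = iz + dz
                    if zz < 0 or zz >= n:
                        continue
                    for dy in range(2):
                        wy = fy if dy == 1 else 1.0 - fy
                        yy = iy + dy
                        if yy < 0 or yy >= n:
                            continue
                        wzy = wz * wy * v
                        for dx in range(2):
                            wx = fx if dx == 1 else 1.0 - fx
                            xx = ix + dx
                            if 0 <= xx < n:
                                W[zz, yy, xx] += wzy * wx
    return W


@njit(**_OPTS)
def splat_trilinear_backward(V, disp, gW, need_gd):
    """Gradients of sum(gW * W) w.r.t. V and the displacement field."""
    n = V.shape[0]
    gV = np.zeros((n, n, n))
    gd = np.zeros((n, n, n, 3))
    for z in range(n):
        for y in range(n):
            for x in range(n):
                v = V[z, y, x]
                px = x + disp[z, y, x, 0]
                py = y + disp[z, y, x, 1]
                pz = z + disp[z, y, x, 2]
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                fx = px - ix
                fy = py - iy
                fz = pz - iz
                acc = 0.0
                ax = 0.0
                ay = 0.0
                az = 0.0
                for dz in range(2):
                    wz = fz if dz == 1 else 1.0 - fz
                    dwz = 1.0 if dz == 1 else -1.0
                    zz = iz + dz
                    if zz < 0 or zz >= n:
                        continue
                    for dy in range(2):
                        wy = fy if dy == 1 else 1.0 - fy
                        dwy = 1.0 if dy == 1 else -1.0
                        yy = iy + dy
                        if yy < 0 or yy >= n:
                            continue
                        for dx in range(2):
                            wx = fx if dx == 1 else 1.0 - fx
                            dwx = 1.0 if dx == 1 else -1.0
                            xx = ix + dx
                            if 0 <= xx < n:
                                g = gW[zz, yy, xx]
                                acc += g * wx * wy * wz
                                if need_gd:
                                    ax += g * dwx * wy * wz
                                    ay += g * wx * dwy * wz
                                    az += g * wx * wy * dwz
                gV[z, y, x] = acc
                if need_gd:
                    gd[z, y, x, 0] = v * ax
                    gd[z, y, x, 1] = v * ay
                    gd[z, y, x, 2] = v * az
    return gV, gd


# ---------------------------------------------------------------------------
# tricubic (Keys, a = -0.5) splat


@njit(inline="always", **_OPTS)
def _keys_weights(f, w, dw):
    """Keys cubic kernel weights and derivatives at taps floor-1 .. floor+2."""
    a = -0.5
    for i in range(4):
        t = f - (i - 1.0)  # signed distance from tap
        at = abs(t)
        s = 1.0 if t >= 0 else -1.0
        if at <= 1.0:
            w[i] = (a + 2.0) * at**3 - (a + 3.0) * at**2 + 1.0
            dwdat = 3.0 * (a + 2.0) * at**2 - 2.0 * (a + 3.0) * at
        elif at < 2.0:
            w[i] = a * at**3 - 5.0 * a * at**2 + 8.0 * a * at - 4.0 * a
            dwdat = 3.0 * a * at**2 - 10.0 * a * at + 8.0 * a
        else:
            w[i] = 0.0
            dwdat = 0.0
        # d/d(f) = d/d(t); tap positions are fixed so dt/df = 1
        dw[i] = s * dwdat


@njit(**_OPTS)
def splat_tricubic(V, disp):
    n = V.shape[0]
    W = np.zeros((n, n, n))
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    d0 = np.empty(4)
    for z in range(n):
        for y in range(n):
            for x in range(n):
                v = V[z, y, x]
                px = x + disp[z, y, x, 0]
                py = y + disp[z, y, x, 1]
                pz = z + disp[z, y, x, 2]
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                _keys_weights(px - ix, wx, d0)
                _keys_weights(py - iy, wy, d0)
                _keys_weights(pz - iz, wz, d0)
                for dz in range(4):
                    zz = iz - 1 + dz
                    if zz < 0 or zz >= n:
                        continue
                    for dy in range(4):
                        yy = iy - 1 + dy
                        if yy < 0 or yy >= n:
                            continue
                        wzy = wz[dz] * wy[dy] * v
                        for dx in range(4):
                            xx = ix - 1 + dx
                            if 0 <= xx < n:
                                W[zz, yy, xx] += wzy * wx[dx]
    return W


@njit(**_OPTS)
def splat_tricubic_backward(V, disp, gW, need_gd):
    n = V.shape[0]
    gV = np.zeros((n, n, n))
    gd = np.zeros((n, n, n, 3))
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    dwx = np.empty(4)
    dwy = np.empty(4)
    dwz = np.empty(4)
    for z in range(n):
        for y in range(n):
            for x in range(n):
                v = V[z, y, x]
                px = x + disp[z, y, x, 0]
                py = y + disp[z, y, x, 1]
                pz = z + disp[z, y, x, 2]
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                _keys_weights(px - ix, wx, dwx)
                _keys_weights(py - iy, wy, dwy)
                _keys_weights(pz - iz, wz, dwz)
                acc = 0.0
                ax = 0.0
                ay = 0.0
                az = 0.0
                for dz in range(4):
                    zz = iz - 1 + dz
                    if zz < 0 or zz >= n:
                        continue
                    for dy in range(4):
                        yy = iy - 1 + dy
                        if yy < 0 or yy >= n:
                            continue
                        for dx in range(4):
                            xx = ix - 1 + dx
                            if 0 <= xx < n:
                                g = gW[zz, yy, xx]
                                acc += g * wx[dx] * wy[dy] * wz[dz]
                                if need_gd:
                                    ax += g * dwx[dx] * wy[dy] * wz[dz]
                                    ay += g * wx[dx] * dwy[dy] * wz[dz]
                                    az += g * wx[dx] * wy[dy] * dwz[dz]
                gV[z, y, x] = acc
                if need_gd:
                    gd[z, y, x, 0] = v * ax
                    gd[z, y, x, 1] = v * ay
                    gd[z, y, x, 2] = v * az
    return gV, gd


# ---------------------------------------------------------------------------
# projection (rotate about center, sum along z, shift) and adjoint


@njit(**_OPTS)
def project_forward(W, R, shift_px):
    """Image (N, N): img[qy, qx] = sum_qz W(R^T (q - t - c) + c), trilinear."""
    n = W.shape[0]
    c = n // 2
    img = np.zeros((n, n))
    # canonical-frame step per unit qz is row 2 of R
    sx = R[2, 0]
    sy = R[2, 1]
    sz = R[2, 2]
    for qy in range(n):
        uy = qy - shift_px[1] - c
        for qx in range(n):
            ux = qx - shift_px[0] - c
            # p at qz = 0: R^T (ux, uy, -c) + c
            px = R[0, 0] * ux + R[1, 0] * uy + R[2, 0] * (-c) + c
            py = R[0, 1] * ux + R[1, 1] * uy + R[2, 1] * (-c) + c
            pz = R[0, 2] * ux + R[1, 2] * uy + R[2, 2] * (-c) + c
            acc = 0.0
            for qz in range(n):
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                if -1 <= ix < n and -1 <= iy < n and -1 <= iz < n:
                    fx = px - ix
                    fy = py - iy
                    fz = pz - iz
                    for dz in range(2):
                        zz = iz + dz
                        if zz < 0 or zz >= n:
                            continue
                        wz = fz if dz == 1 else 1.0 - fz
                        for dy in range(2):
                            yy = iy + dy
                            if yy < 0 or yy >= n:
                                continue
                            wzy = wz * (fy if dy == 1 else 1.0 - fy)
                            for dx in range(2):
                                xx = ix + dx
                                if 0 <= xx < n:
                                    acc += wzy * (fx if dx == 1 else 1.0 - fx) * W[zz, yy, xx]
                px += sx
                py += sy
                pz += sz
            img[qy, qx] = acc
    return img


@njit(**_OPTS)
def project_adjoint(g_img, R, shift_px, n):
    """Adjoint of :func:`project_forward`: smear an image back into a volume."""
    c = n // 2
    gW = np.zeros((n, n, n))
    sx = R[2, 0]
    sy = R[2, 1]
    sz = R[2, 2]
    for qy in range(n):
        uy = qy - shift_px[1] - c
        for qx in range(n):
            g = g_img[qy, qx]
            if g == 0.0:
                ux = qx - shift_px[0] - c  # still advance nothing; skip
                continue
            ux = qx - shift_px[0] - c
            px = R[0, 0] * ux + R[1, 0] * uy + R[2, 0] * (-c) + c
            py = R[0, 1] * ux + R[1, 1] * uy + R[2, 1] * (-c) + c
            pz = R[0, 2] * ux + R[1, 2] * uy + R[2, 2] * (-c) + c
            for qz in range(n):
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                if -1 <= ix < n and -1 <= iy < n and -1 <= iz < n:
                    fx = px - ix
                    fy = py - iy
                    fz = pz - iz
                    for dz in range(2):
                        zz = iz + dz
                        if zz < 0 or zz >= n:
                            continue
                        wz = fz if dz == 1 else 1.0 - fz
                        for dy in range(2):
                            yy = iy + dy
                            if yy < 0 or yy >= n:
                                continue
                            wzy = g * wz * (fy if dy == 1 else 1.0 - fy)
                            for dx in range(2):
                                xx = ix + dx
                                if 0 <= xx < n:
                                    gW[zz, yy, xx] += wzy * (fx if dx == 1 else 1.0 - fx)
                px += sx
                py += sy
                pz += sz
    return gW


@njit(**_OPTS)
def project_forward_cubic(W, R, shift_px):
    """Rotate-and-sum projection with Keys tricubic resampling."""
    n = W.shape[0]
    c = n // 2
    img = np.zeros((n, n))
    sx = R[2, 0]
    sy = R[2, 1]
    sz = R[2, 2]
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    d0 = np.empty(4)
    for qy in range(n):
        uy = qy - shift_px[1] - c
        for qx in range(n):
            ux = qx - shift_px[0] - c
            px = R[0, 0] * ux + R[1, 0] * uy + R[2, 0] * (-c) + c
            py = R[0, 1] * ux + R[1, 1] * uy + R[2, 1] * (-c) + c
            pz = R[0, 2] * ux + R[1, 2] * uy + R[2, 2] * (-c) + c
            acc = 0.0
            for qz in range(n):
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                if -2 <= ix < n + 1 and -2 <= iy < n + 1 and -2 <= iz < n + 1:
                    _keys_weights(px - ix, wx, d0)
                    _keys_weights(py - iy, wy, d0)
                    _keys_weights(pz - iz, wz, d0)
                    for dz in range(4):
                        zz = iz - 1 + dz
                        if zz < 0 or zz >= n:
                            continue
                        for dy in range(4):
                            yy = iy - 1 + dy
                            if yy < 0 or yy >= n:
                                continue
                            wzy = wz[dz] * wy[dy]
                            for dx in range(4):
                                xx = ix - 1 + dx
                                if 0 <= xx < n:
                                    acc += wzy * wx[dx] * W[zz, yy, xx]
                px += sx
                py += sy
                pz += sz
            img[qy, qx] = acc
    return img


@njit(**_OPTS)
def project_adjoint_cubic(g_img, R, shift_px, n):
    c = n // 2
    gW = np.zeros((n, n, n))
    sx = R[2, 0]
    sy = R[2, 1]
    sz = R[2, 2]
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    d0 = np.empty(4)
    for qy in range(n):
        uy = qy - shift_px[1] - c
        for qx in range(n):
            g = g_img[qy, qx]
            if g == 0.0:
                continue
            ux = qx - shift_px[0] - c
            px = R[0, 0] * ux + R[1, 0] * uy + R[2, 0] * (-c) + c
            py = R[0, 1] * ux + R[1, 1] * uy + R[2, 1] * (-c) + c
            pz = R[0, 2] * ux + R[1, 2] * uy + R[2, 2] * (-c) + c
            for qz in range(n):
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                if -2 <= ix < n + 1 and -2 <= iy < n + 1 and -2 <= iz < n + 1:
                    _keys_weights(px - ix, wx, d0)
                    _keys_weights(py - iy, wy, d0)
                    _keys_weights(pz - iz, wz, d0)
                    for dz in range(4):
                        zz = iz - 1 + dz
                        if zz < 0 or zz >= n:
                            continue
                        for dy in range(4):
                            yy = iy - 1 + dy
                            if yy < 0 or yy >= n:
                                continue
                            wzy = g * wz[dz] * wy[dy]
                            for dx in range(4):
                                xx = ix - 1 + dx
                                if 0 <= xx < n:
                                    gW[zz, yy, xx] += wzy * wx[dx]
                px += sx
                py += sy
                pz += sz
    return gW


@njit(**_OPTS)
def rotate_volume(V, R):
    """Trilinear resample of V under x -> R x about the center voxel.

    out(q) = V(R^T (q - c) + c); used for Cn symmetrization.
    """
    n = V.shape[0]
    c = n // 2
    out = np.zeros((n, n, n))
    for qz in range(n):
        for qy in range(n):
            for qx in range(n):
                ux = qx - c
                uy = qy - c
                uz = qz - c
                px = R[0, 0] * ux + R[1, 0] * uy + R[2, 0] * uz + c
                py = R[0, 1] * ux + R[1, 1] * uy + R[2, 1] * uz + c
                pz = R[0, 2] * ux + R[1, 2] * uy + R[2, 2] * uz + c
                ix = int(np.floor(px))
                iy = int(np.floor(py))
                iz = int(np.floor(pz))
                if ix < -1 or ix >= n or iy < -1 or iy >= n or iz < -1 or iz >= n:
                    continue
                fx = px - ix
                fy = py - iy
                fz = pz - iz
                acc = 0.0
                for dz in range(2):
                    zz = iz + dz
                    if zz < 0 or zz >= n:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        yy = iy + dy
                        if yy < 0 or yy >= n:
                            continue
                        wzy = wz * (fy if dy == 1 else 1.0 - fy)
                        for dx in range(2):
                            xx = ix + dx
                            if 0 <= xx < n:
                                acc += wzy * (fx if dx == 1 else 1.0 - fx) * V[zz, yy, xx]
                out[qz, qy, qx] = acc
    return out
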