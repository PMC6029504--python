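"""Compiled Joseph ray-tracing kernels.

Voxel-driven interpolating projection: each ray is sampled once per slice,
the slice is bilinearly interpolated at the intersection point, and the sum
is weighted by the slant path length through one slice.  The backprojector
scatters with exactly the weights the projector gathers, so the pair is an
exact adjoint up to floating-point rounding.  Rays (or slice samples)
falling outside the grid contribute exactly zero.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(fastmath=False)
def joseph_forward(vol, det_x, det_y, src, z0, dz, dy, dx):
    nz, ny, nx = vol.shape
    nr = det_y.size
    nc = det_x.size
    sx, sy, sz = src[0], src[1], src[2]
    t = np.empty(nz)
    for k in range(nz):
        t[k] = (sz - (z0 + (k + 0.5) * dz)) / sz
    out = np.zeros((nr, nc))
    for r in range(nr):
        yd = det_y[r]
        for c in range(nc):
            xd = det_x[c]
            acc = 0.0
            for k in range(nz):
                u = (sx + (xd - sx) * t[k]) / dx + (nx - 1) / 2.0
                v = (sy + (yd - sy) * t[k]) / dy + (ny - 1) / 2.0
                j0 = int(np.floor(u))
                i0 = int(np.floor(v))
                fu = u - j0
                fv = v - i0
                if 0 <= i0 < ny:
                    if 0 <= j0 < nx:
                        acc += (1.0 - fv) * (1.0 - fu) * vol[k, i0, j0]
                    if 0 <= j0 + 1 < nx:
                        acc += (1.0 - fv) * fu * vol[k, i0, j0 + 1]
                if 0 <= i0 + 1 < ny:
                    if 0 <= j0 < nx:
                        acc += fv * (1.0 - fu) * vol[k, i0 + 1, j0]
                    if 0 <= j0 + 1 < nx:
                        acc += fv * fu * vol[k, i0 + 1, j0 + 1]
            ray_len = np.sqrt((xd - sx) ** 2 + (yd - sy) ** 2 + sz * sz)
            out[r, c] = acc * dz * ray_len / sz
    return out


@numba.njit(fastmath=False)
def joseph_back(arr, vol_shape, det_x, det_y, src, z0, dz, dy, dx):
    nz, ny, nx = vol_shape
    nr = det_y.size
    nc = det_x.size
    sx, sy, sz = src[0], src[1], src[2]
    t = np.empty(nz)
    for k in range(nz):
        t[k] = (sz - (z0 + (k + 0.5) * dz)) / sz
    out = np.zeros((nz, ny, nx))
    for r in range(nr):
        yd = det_y[r]
        for c in range(nc):
            xd = det_x[c]
            ray_len = np.sqrt((xd - sx) ** 2 + (yd - sy) ** 2 + sz * sz)
            contrib = arr[r, c] * dz * ray_len / sz
            for k in range(nz):
                u = (sx + (xd - sx) * t[k]) / dx + (nx - 1) / 2.0
                v = (sy + (yd - sy) * t[k]) / dy + (ny - 1) / 2.0
                j0 = int(np.floor(u))
                i0 = int(np.floor(v))
                fu = u - j0
                fv = v - i0
                if 0 <= i0 < ny:
                    if 0 <= j0 < nx:
                        out[k, i0, j0] += (1.0 - fv) * (1.0 - fu) * contrib
                    if 0 <= j0 + 1 < nx:
                        out[k, i0, j0 + 1] += (1.0 - fv) * fu * contrib
                if 0 <= i0 + 1 < ny:
                    if 0 <= j0 < nx:
                        out[k, i0 + 1, j0] += fv * (1.0 - fu) * contrib
                    if 0 <= j0 + 1 < nx:
                        out[k, i0 + 1, j0 + 1] += fv * fu * contrib
    return out
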