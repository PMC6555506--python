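"""Fused Monte-Carlo reduction kernels (optional numba acceleration).

One pass per snake batch: linear interpolation of the image at the sample
positions, evaluation of the radial weight and its derivatives, and the
five (2D: four) weighted reductions needed for the energy and gradient.
Accumulation is in double precision; sample coordinates and the image are
single precision.  The numpy fallback in :mod:`snakuscules.sampling`
computes identical quantities (up to rounding) when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, prange

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap

    prange = range


@njit(cache=True, parallel=True)
def mc_reduce_3d(arr, offs, centers, R, dR, dr, rho, B, dB):  # pragma: no cover
    m, ns = offs.shape[0], offs.shape[1]
    nz, ny, nx = arr.shape
    out = np.zeros((m, 5))
    for i in prange(m):
        Ri = R[i]
        so = Ri - 0.5 * dR
        si = rho * Ri - 0.5 * dr
        cz = centers[i, 0]
        cy = centers[i, 1]
        cx = centers[i, 2]
        t0 = 0.0
        tR = 0.0
        tz = 0.0
        ty = 0.0
        tx = 0.0
        for k in range(ns):
            oz = np.float64(offs[i, k, 0])
            oy = np.float64(offs[i, k, 1])
            ox = np.float64(offs[i, k, 2])
            z = oz + cz
            y = oy + cy
            x = ox + cx
            # trilinear interpolation, zero outside the domain
            iz = int(np.floor(z))
            iy = int(np.floor(y))
            ix = int(np.floor(x))
            fz = z - iz
            fy = y - iy
            fx = x - ix
            val = 0.0
            for bz in range(2):
                zz = iz + bz
                if zz < 0 or zz >= nz:
                    continue
                wz = fz if bz == 1 else 1.0 - fz
                for by in range(2):
                    yy = iy + by
                    if yy < 0 or yy >= ny:
                        continue
                    wy = fy if by == 1 else 1.0 - fy
                    for bx in range(2):
                        xx = ix + bx
                        if xx < 0 or xx >= nx:
                            continue
                        wx = fx if bx == 1 else 1.0 - fx
                        val += wz * wy * wx * np.float64(arr[zz, yy, xx])
            if val == 0.0:
                continue
            r = np.sqrt(oz * oz + oy * oy + ox * ox)
            to = (r - so) / dR
            if to <= 0.0:
                h_o = 0.0
                hp_o = 0.0
            elif to >= 1.0:
                h_o = 1.0
                hp_o = 0.0
            else:
                h_o = to * to * (3.0 - 2.0 * to)
                hp_o = 6.0 * to * (1.0 - to) / dR
            ti = (r - si) / dr
            if ti <= 0.0:
                h_i = 0.0
                hp_i = 0.0
            elif ti >= 1.0:
                h_i = 1.0
                hp_i = 0.0
            else:
                h_i = ti * ti * (3.0 - 2.0 * ti)
                hp_i = 6.0 * ti * (1.0 - ti) / dr
            g_i = 1.0 - h_i
            S = (1.0 - h_o) - B * g_i
            Sr = B * hp_i - hp_o
            SR = hp_o - dB * g_i - (B * rho) * hp_i
            t0 += S * val
            tR += SR * val
            if r > 1e-12:
                c = Sr * val / r
                tz += c * oz
                ty += c * oy
                tx += c * ox
        out[i, 0] = t0
        out[i, 1] = tR
        out[i, 2] = tz
        out[i, 3] = ty
        out[i, 4] = tx
    return out


@njit(cache=True, parallel=True)
def mc_reduce_2d(arr, offs, centers, R, dR, dr, rho, B, dB):  # pragma: no cover
    m, ns = offs.shape[0], offs.shape[1]
    ny, nx = arr.shape
    out = np.zeros((m, 4))
    for i in prange(m):
        Ri = R[i]
        so = Ri - 0.5 * dR
        si = rho * Ri - 0.5 * dr
        cy = centers[i, 0]
        cx = centers[i, 1]
        t0 = 0.0
        tR = 0.0
        ty = 0.0
        tx = 0.0
        for k in range(ns):
            oy = np.float64(offs[i, k, 0])
            ox = np.float64(offs[i, k, 1])
            y = oy + cy
            x = ox + cx
            iy = int(np.floor(y))
            ix = int(np.floor(x))
            fy = y - iy
            fx = x - ix
            val = 0.0
            for by in range(2):
                yy = iy + by
                if yy < 0 or yy >= ny:
                    continue
                wy = fy if by == 1 else 1.0 - fy
                for bx in range(2):
                    xx = ix + bx
                    if xx < 0 or xx >= nx:
                        continue
                    wx = fx if bx == 1 else 1.0 - fx
                    val += wy * wx * np.float64(arr[yy, xx])
            if val == 0.0:
                continue
            r = np.sqrt(oy * oy + ox * ox)
            to = (r - so) / dR
            if to <= 0.0:
                h_o = 0.0
                hp_o = 0.0
            elif to >= 1.0:
                h_o = 1.0
                hp_o = 0.0
            else:
                h_o = to * to * (3.0 - 2.0 * to)
                hp_o = 6.0 * to * (1.0 - to) / dR
            ti = (r - si) / dr
            if ti <= 0.0:
                h_i = 0.0
                hp_i = 0.0
            elif ti >= 1.0:
                h_i = 1.0
                hp_i = 0.0
            else:
                h_i = ti * ti * (3.0 - 2.0 * ti)
                hp_i = 6.0 * ti * (1.0 - ti) / dr
            g_i = 1.0 - h_i
            S = (1.0 - h_o) - B * g_i
            Sr = B * hp_i - hp_o
            SR = hp_o - dB * g_i - (B * rho) * hp_i
            t0 += S * val
            tR += SR * val
            if r > 1e-12:
                c = Sr * val / r
                ty += c * oy
                tx += c * ox
        out[i, 0] = t0
        out[i, 1] = tR
        out[i, 2] = ty
        out[i, 3] = tx
    return out
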