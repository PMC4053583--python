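"""Ray-traversal kernels for the fan-beam system matrix.

All operators traverse the pixel grid with the same Siddon-style
parametric stepping (Amanatides & Woo grid marching with exact
intersection lengths).  Because forward projection, backprojection, row
norms, ART updates and sparse assembly all call the single `_traverse`
routine, the forward/backprojection pair is an exact adjoint and the
assembled sparse matrix reproduces the matrix-free operators bit for bit.

Grid convention: pixel (iy, ix) covers
x in [xmin + ix*h, xmin + (ix+1)*h), y likewise, with xmin = -n*h/2.
Rays exactly on a pixel boundary generate zero-length segments on one
side, which is the half-open convention in effect.
"""

import math

import numpy as np
from numba import njit

_BIG = 1e30


@njit(cache=True)
def _traverse(img, coef, mode, n, xmin, h, sx, sy, ex, ey):
    """March one ray (segment source -> detector element) across the grid.

    mode 0: return sum(len * img[iy, ix])        (forward projection)
    mode 1: img[iy, ix] += coef * len; return 0  (backprojection / update)
    mode 2: return sum(len**2)                   (row squared norm)
    """
    rx = ex - sx
    ry = ey - sy
    length = math.sqrt(rx * rx + ry * ry)
    xmax = xmin + n * h

    t0 = 0.0
    t1 = 1.0
    if rx != 0.0:
        ta = (xmin - sx) / rx
        tb = (xmax - sx) / rx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sx <= xmin or sx >= xmax:
        return 0.0
    if ry != 0.0:
        ta = (xmin - sy) / ry
        tb = (xmax - sy) / ry
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sy <= xmin or sy >= xmax:
        return 0.0
    if t1 <= t0:
        return 0.0

    ix = int(math.floor((sx + t0 * rx - xmin) / h))
    iy = int(math.floor((sy + t0 * ry - xmin) / h))
    if ix < 0:
        ix = 0
    elif ix > n - 1:
        ix = n - 1
    if iy < 0:
        iy = 0
    elif iy > n - 1:
        iy = n - 1

    if rx > 0.0:
        step_x = 1
        dtx = h / rx
        tnx = (xmin + (ix + 1) * h - sx) / rx
    elif rx < 0.0:
        step_x = -1
        dtx = -h / rx
        tnx = (xmin + ix * h - sx) / rx
    else:
        step_x = 0
        dtx = _BIG
        tnx = _BIG
    if ry > 0.0:
        step_y = 1
        dty = h / ry
        tny = (xmin + (iy + 1) * h - sy) / ry
    elif ry < 0.0:
        step_y = -1
        dty = -h / ry
        tny = (xmin + iy * h - sy) / ry
    else:
        step_y = 0
        dty = _BIG
        tny = _BIG

    t = t0
    acc = 0.0
    while True:
        tn = tnx if tnx < tny else tny
        if tn > t1:
            tn = t1
        seg = (tn - t) * length
        if seg > 0.0:
            if mode == 0:
                acc += seg * img[iy, ix]
            elif mode == 1:
                img[iy, ix] += coef * seg
            else:
                acc += seg * seg
        if tn >= t1 - 1e-12:
            break
        if tnx <= tny:
            ix += step_x
            tnx += dtx
        else:
            iy += step_y
            tny += dty
        t = tn
        if ix < 0 or ix >= n or iy < 0 or iy >= n:
            break
    return acc


@njit(cache=True)
def _endpoints(c, s, sod, sdd, n_det, pitch, d):
    sx = sod * c
    sy = sod * s
    px = (sod - sdd) * c
    py = (sod - sdd) * s
    u = (d - (n_det - 1) / 2.0) * pitch
    ex = px - u * s
    ey = py + u * c
    return sx, sy, ex, ey


@njit(cache=True)
def forward_kernel(img, angles, sod, sdd, n_det, pitch, n, h, out):
    xmin = -0.5 * n * h
    for v in range(angles.shape[0]):
        c = math.cos(angles[v])
        s = math.sin(angles[v])
        for d in range(n_det):
            sx, sy, ex, ey = _endpoints(c, s, sod, sdd, n_det, pitch, d)
            out[v, d] = _traverse(img, 0.0, 0, n, xmin, h, sx, sy, ex, ey)


@njit(cache=True)
def back_kernel(sino, angles, sod, sdd, n_det, pitch, n, h, out_img):
    xmin = -0.5 * n * h
    for v in range(angles.shape[0]):
        c = math.cos(angles[v])
        s = math.sin(angles[v])
        for d in range(n_det):
            val = sino[v, d]
            if val != 0.0:
                sx, sy, ex, ey = _endpoints(c, s, sod, sdd, n_det, pitch, d)
                _traverse(out_img, val, 1, n, xmin, h, sx, sy, ex, ey)


@njit(cache=True)
def row_norms_kernel(angles, sod, sdd, n_det, pitch, n, h, out):
    xmin = -0.5 * n * h
    dummy = np.zeros((1, 1))
    for v in range(angles.shape[0]):
        c = math.cos(angles[v])
        s = math.sin(angles[v])
        for d in range(n_det):
            sx, sy, ex, ey = _endpoints(c, s, sod, sdd, n_det, pitch, d)
            out[v, d] = _traverse(dummy, 0.0, 2, n, xmin, h, sx, sy, ex, ey)


@njit(cache=True)
def art_sweep_kernel(img, sino, row_norms, order, angles, sod, sdd, n_det, pitch, n, h, lam):
    """One Kaczmarz pass over the rays listed in `order` (flat indices
    view * n_det + det), updating `img` in place.  Returns the number of
    zero-norm rays skipped."""
    xmin = -0.5 * n * h
    skipped = 0
    for k in range(order.shape[0]):
        idx = order[k]
        v = idx // n_det
        d = idx % n_det
        nrm = row_norms[v, d]
        if nrm <= 0.0:
            skipped += 1
            continue
        c = math.cos(angles[v])
        s = math.sin(angles[v])
        sx, sy, ex, ey = _endpoints(c, s, sod, sdd, n_det, pitch, d)
        p = _traverse(img, 0.0, 0, n, xmin, h, sx, sy, ex, ey)
        coef = lam * (sino[v, d] - p) / nrm
        _traverse(img, coef, 1, n, xmin, h, sx, sy, ex, ey)
    return skipped


@njit(cache=True)
def entries_kernel(angles, sod, sdd, n_det, pitch, n, h, rows, cols, vals):
    """Assemble the system matrix in COO form by probing each ray with
    single-pixel basis updates.  Returns the entry count.

    The per-entry weights are produced by the same `_traverse` marching as
    the matrix-free operators (mode 1 scatter of unit coefficient into a
    scratch image), so assembled and matrix-free results agree exactly.
    """
    xmin = -0.5 * n * h
    scratch = np.zeros((n, n))
    cnt = 0
    for v in range(angles.shape[0]):
        c = math.cos(angles[v])
        s = math.sin(angles[v])
        for d in range(n_det):
            sx, sy, ex, ey = _endpoints(c, s, sod, sdd, n_det, pitch, d)
            _traverse(scratch, 1.0, 1, n, xmin, h, sx, sy, ex, ey)
            ray = v * n_det + d
            for iy in range(n):
                for ix in range(n):
                    w = scratch[iy, ix]
                    if w != 0.0:
                        rows[cnt] = ray
                        cols[cnt] = iy * n + ix
                        vals[cnt] = w
                        cnt += 1
                        scratch[iy, ix] = 0.0
    return cnt
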