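"""Brute-force per-voxel reference implementations.

Deliberately naive (explicit Python loops, textbook formulas) so they are
independent of the vectorized code paths they check.
"""

import math

import numpy as np


def com_2d(proj, mask, pixel_size):
    """Intensity-weighted center of mass by explicit accumulation."""
    sy = sx = tot = 0.0
    ny, nx = proj.shape
    for y in range(ny):
        for x in range(nx):
            if mask is None or mask[y, x]:
                v = float(proj[y, x])
                tot += v
                sy += v * y
                sx += v * x
    return np.array([sy / tot, sx / tot]) * pixel_size


def polarity(proj, mask, pixel_size, cell_center, bead_center):
    """|CL| cos(theta) / |CB| via the explicit cosine formula."""
    cl = com_2d(proj, mask, pixel_size) - np.asarray(cell_center)
    cb = np.asarray(bead_center) - np.asarray(cell_center)
    ncl, ncb = np.linalg.norm(cl), np.linalg.norm(cb)
    if ncl == 0:
        return 0.0
    cos_theta = float(np.dot(cl, cb) / (ncl * ncb))
    return ncl * cos_theta / ncb


def recruitment(proj, synapse_mask, cell_mask):
    num = den = 0.0
    ny, nx = proj.shape
    for y in range(ny):
        for x in range(nx):
            v = float(proj[y, x])
            if synapse_mask[y, x]:
                num += v
            if synapse_mask[y, x] or cell_mask[y, x]:
                den += v
    return num / den


def enrichment(plane, cell_mask, central_mask):
    fc = ft = 0.0
    ac = at = 0
    ny, nx = plane.shape
    for y in range(ny):
        for x in range(nx):
            if central_mask[y, x]:
                fc += float(plane[y, x])
                ac += 1
            if cell_mask[y, x]:
                ft += float(plane[y, x])
                at += 1
    return (fc / ac) / (ft / at) - 1.0


def z_mfi(volume, mask):
    out = []
    for sl in volume:
        vals = [float(sl[y, x]) for y, x in zip(*np.nonzero(mask))]
        out.append(sum(vals) / len(vals))
    return out


def bottom_top(mfi):
    n = len(mfi)
    half, odd = divmod(n, 2)
    bottom = sum(mfi[:half])
    top = sum(mfi[half + odd :])
    if odd:
        bottom += mfi[half] / 2
        top += mfi[half] / 2
    return math.inf if top == 0 else bottom / top


def manders_m1(proj_a, proj_b, mask, thr_b):
    num = den = 0.0
    ny, nx = proj_a.shape
    for y in range(ny):
        for x in range(nx):
            if mask is None or mask[y, x]:
                v = float(proj_a[y, x])
                den += v
                if proj_b[y, x] > thr_b:
                    num += v
    return num / den
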