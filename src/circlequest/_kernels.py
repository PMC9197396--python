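"""Compiled hot loops for the grid observer.

These kernels are plain distance arithmetic; everything scientific lives in
:mod:`circlequest.observer`. They are jitted because the expected-error map
is a dense point-to-point distance reduction evaluated hundreds of
thousands of times in cohort-scale simulations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def ee_values(px, py, w, cx, cy):
    """Expected error at each candidate: sum_i w_i * |c - p_i|."""
    m = cx.shape[0]
    n = px.shape[0]
    out = np.empty(m)
    for j in range(m):
        acc = 0.0
        xj = cx[j]
        yj = cy[j]
        for i in range(n):
            dx = xj - px[i]
            dy = yj - py[i]
            acc += w[i] * np.sqrt(dx * dx + dy * dy)
        out[j] = acc
    return out


@njit(cache=True, fastmath=True)
def ee_min(px, py, w, cx, cy):
    """Minimum expected error over candidates and its index."""
    vals = ee_values(px, py, w, cx, cy)
    best = 0
    for j in range(1, vals.shape[0]):
        if vals[j] < vals[best]:
            best = j
    return vals[best], best


@njit(cache=True, fastmath=True)
def ee_at_centroid(px, py, w):
    """Expected error at the posterior mean (cheap Weber-point surrogate)."""
    n = px.shape[0]
    mx = 0.0
    my = 0.0
    for i in range(n):
        mx += w[i] * px[i]
        my += w[i] * py[i]
    acc = 0.0
    for i in range(n):
        dx = mx - px[i]
        dy = my - py[i]
        acc += w[i] * np.sqrt(dx * dx + dy * dy)
    return acc


@njit(cache=True, fastmath=True)
def best_expected_ee(px, py, w, qx, qy, r):
    """Greedy touch choice: index and value of the proposal minimising
    the outcome-averaged posterior EE, with each outcome branch scored at
    its centroid.

    For proposal q, the posterior splits into the points inside/outside
    the disk of radius r around q; the expected EE is
    sum_i w_i * |c_{b(i)} - p_i| with c_b the branch centroids.
    """
    n = px.shape[0]
    m = qx.shape[0]
    best_j = -1
    best_ee = np.inf
    r2 = r * r
    for j in range(m):
        xq = qx[j]
        yq = qy[j]
        w_in = 0.0
        mx_in = 0.0
        my_in = 0.0
        mx_out = 0.0
        my_out = 0.0
        for i in range(n):
            dx = px[i] - xq
            dy = py[i] - yq
            if dx * dx + dy * dy <= r2:
                w_in += w[i]
                mx_in += w[i] * px[i]
                my_in += w[i] * py[i]
            else:
                mx_out += w[i] * px[i]
                my_out += w[i] * py[i]
        w_out = 1.0 - w_in
        if w_in > 0.0:
            mx_in /= w_in
            my_in /= w_in
        if w_out > 0.0:
            mx_out /= w_out
            my_out /= w_out
        ee = 0.0
        for i in range(n):
            dx = px[i] - xq
            dy = py[i] - yq
            if dx * dx + dy * dy <= r2:
                ex = mx_in - px[i]
                ey = my_in - py[i]
            else:
                ex = mx_out - px[i]
                ey = my_out - py[i]
            ee += w[i] * np.sqrt(ex * ex + ey * ey)
        if ee < best_ee:
            best_ee = ee
            best_j = j
    return best_j, best_ee


@njit(cache=True)
def inside_disk(px, py, cx, cy, r):
    """Boolean mask of points within (inclusive) radius r of (cx, cy)."""
    n = px.shape[0]
    out = np.empty(n, dtype=np.bool_)
    r2 = r * r
    for i in range(n):
        dx = px[i] - cx
        dy = py[i] - cy
        out[i] = dx * dx + dy * dy <= r2
    return out
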