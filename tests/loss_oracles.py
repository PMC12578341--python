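"""Independent scalar-loop oracles for the loss functions.

Pure Python loops over small float64 arrays; shared by the unit tests
and the acceptance suite.  Nothing here touches the autodiff engine.
"""

import numpy as np


def o_dist(a, b, kind):
    total = 0.0
    fa, fb = np.asarray(a).reshape(-1), np.asarray(b).reshape(-1)
    for x, y in zip(fa, fb):
        d = x - y
        total += abs(d) if kind == "L1" else d * d
    return total / fa.size


def o_apply_mask(arr, mask2d):
    arr = np.asarray(arr)
    out = np.empty_like(arr)
    n, c, h, w = arr.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    out[ni, ci, i, j] = arr[ni, ci, i, j] * mask2d[i, j]
    return out


def o_masked_triple(a, b, mask2d, alpha, beta, kind):
    mbar = 1.0 - mask2d
    return alpha * o_dist(o_apply_mask(a, mask2d), o_apply_mask(b, mask2d), kind) + \
        beta * o_dist(o_apply_mask(a, mbar), o_apply_mask(b, mbar), kind)


def o_target(d, mask2d, target):
    d = np.asarray(d)
    if mask2d is not None:
        d = o_apply_mask(d, mask2d)
    return o_dist(d, np.full_like(d, target), "MSE")


def o_pool3s2(arr2d):
    arr2d = np.asarray(arr2d)
    h, w = arr2d.shape
    oh, ow = (h - 3) // 2 + 1, (w - 3) // 2 + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            s = 0.0
            for di in range(3):
                for dj in range(3):
                    s += arr2d[2 * i + di, 2 * j + dj]
            out[i, j] = s / 9.0
    return out
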