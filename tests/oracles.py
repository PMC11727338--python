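"""Independent brute-force reference implementations used only by tests.

Deliberately naive (nested loops, all-pairs distances, flood fill) so they
share no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def confusion_bruteforce(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def dsc_bruteforce(pred, truth):
    a = {(i, j) for i in range(pred.shape[0]) for j in range(pred.shape[1]) if pred[i, j]}
    b = {(i, j) for i in range(truth.shape[0]) for j in range(truth.shape[1]) if truth[i, j]}
    if not a and not b:
        return 1.0
    return 2 * len(a & b) / (len(a) + len(b))


def auc_pairwise(scores, labels):
    """Mann-Whitney rank statistic over all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def boundary_4conn(mask):
    """Foreground pixels with at least one 4-neighbour that is background."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if ni < 0 or nj < 0 or ni >= h or nj >= w or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def hd95_bruteforce(pred, truth):
    """All-pairs Euclidean distances between boundary pixel sets."""
    bp = np.argwhere(boundary_4conn(pred.astype(bool)))
    bt = np.argwhere(boundary_4conn(truth.astype(bool)))

    def directed(a, b):
        dists = [min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in b) for p in a]
        return float(np.percentile(dists, 95))

    return max(directed(bp, bt), directed(bt, bp))


def flood_fill_components(mask, connectivity=8):
    """BFS labeling; returns (labels, sizes) with labels in scan order."""
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    sizes = []
    next_label = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                next_label += 1
                size = 0
                queue = deque([(i, j)])
                labels[i, j] = next_label
                while queue:
                    ci, cj = queue.popleft()
                    size += 1
                    for di, dj in nbrs:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and labels[ni, nj] == 0:
                            labels[ni, nj] = next_label
                            queue.append((ni, nj))
                sizes.append(size)
    return labels, sizes


def conv2d_naive(x, w, b):
    """Nested-loop same-padded stride-1 correlation; x (C,H,W), w (O,C,kh,kw)."""
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((c, h + 2 * ph, wd + 2 * pw))
    xp[:, ph : ph + h, pw : pw + wd] = x
    y = np.zeros((o, h, wd))
    for oo in range(o):
        for i in range(h):
            for j in range(wd):
                acc = b[oo]
                for cc in range(c):
                    for a in range(kh):
                        for bb in range(kw):
                            acc += w[oo, cc, a, bb] * xp[cc, i + a, j + bb]
                y[oo, i, j] = acc
    return y


def pool_naive(x, k, op):
    """x (C,H,W) -> (C,H/k,W/k) with op = max or mean over each window."""
    c, h, w = x.shape
    y = np.zeros((c, h // k, w // k))
    for cc in range(c):
        for i in range(h // k):
            for j in range(w // k):
                y[cc, i, j] = op(x[cc, i * k : (i + 1) * k, j * k : (j + 1) * k])
    return y
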