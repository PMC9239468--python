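"""Independent brute-force oracles for the spatial estimators.

Deliberately written as plain Python double loops over point pairs, with
no shared code with the package's vectorized implementations.
"""

import math

import numpy as np


def _tau(window, dx, dy, correction):
    if correction == "none":
        return 1.0
    a = window.xmax - window.xmin
    b = window.ymax - window.ymin
    return (a * b) / ((a - abs(dx)) * (b - abs(dy)))


def _epanechnikov(u, h):
    t = u / h
    if abs(t) >= 1.0:
        return 0.0
    return 0.75 / h * (1.0 - t * t)


def k_oracle(pattern, r, types=None, correction="translation"):
    """Direct enumeration K(r) (types=None) or cross K_ij(r) (types=(i, j))."""
    win = pattern.window
    area = win.area
    total = 0.0
    if types is None:
        n = pattern.n
        for p in range(n):
            for q in range(n):
                if p == q:
                    continue
                dx = pattern.x[p] - pattern.x[q]
                dy = pattern.y[p] - pattern.y[q]
                if math.hypot(dx, dy) <= r:
                    total += _tau(win, dx, dy, correction)
        lam = n / area
        return total / (lam * lam * area)
    i, j = types
    labels = pattern.types.astype(str)
    idx_i = np.where(labels == i)[0]
    idx_j = np.where(labels == j)[0]
    for p in idx_i:
        for q in idx_j:
            dx = pattern.x[p] - pattern.x[q]
            dy = pattern.y[p] - pattern.y[q]
            if math.hypot(dx, dy) <= r:
                total += _tau(win, dx, dy, correction)
    lam_i = idx_i.size / area
    lam_j = idx_j.size / area
    return total / (lam_i * lam_j * area)


def g_oracle(pattern, r, h, types=None, correction="translation"):
    """Direct kernel-sum pair correlation at distance r."""
    win = pattern.window
    area = win.area
    total = 0.0
    if types is None:
        n = pattern.n
        for p in range(n):
            for q in range(n):
                if p == q:
                    continue
                dx = pattern.x[p] - pattern.x[q]
                dy = pattern.y[p] - pattern.y[q]
                total += _epanechnikov(math.hypot(dx, dy) - r, h) * _tau(
                    win, dx, dy, correction
                )
        lam2 = (n / area) ** 2
    else:
        i, j = types
        labels = pattern.types.astype(str)
        idx_i = np.where(labels == i)[0]
        idx_j = np.where(labels == j)[0]
        for p in idx_i:
            for q in idx_j:
                dx = pattern.x[p] - pattern.x[q]
                dy = pattern.y[p] - pattern.y[q]
                total += _epanechnikov(math.hypot(dx, dy) - r, h) * _tau(
                    win, dx, dy, correction
                )
        lam2 = (idx_i.size / area) * (idx_j.size / area)
    return total / (2.0 * math.pi * r * lam2 * area)


def mcf_oracle(pattern, i, j, r, h, normalised=True, correction="translation"):
    """Mark connection at r: ratio of cross to pooled pair correlation."""
    pooled = pattern.subset(i, j)
    g_ij = g_oracle(pooled, r, h, types=(i, j), correction=correction)
    g_all = g_oracle(pooled, r, h, types=None, correction=correction)
    if g_all == 0.0:
        return float("nan")
    value = g_ij / g_all
    if not normalised:
        area = pooled.window.area
        labels = pooled.types.astype(str)
        lam_i = (labels == i).sum() / area
        lam_j = (labels == j).sum() / area
        value *= lam_i * lam_j / (lam_i + lam_j)
    return value


def moran_oracle(pattern, i, j, mark, r, hw):
    """Distance-band Moran's I at r by direct enumeration of cross pairs."""
    labels = pattern.types.astype(str)
    idx_i = np.where(labels == i)[0]
    idx_j = np.where(labels == j)[0]
    m = pattern.marks[mark]
    m_i, m_j = m[idx_i], m[idx_j]
    mean_i, mean_j = m_i.mean(), m_j.mean()
    pool = np.concatenate([m_i, m_j])
    mean_pool = pool.mean()
    denom = float(((pool - mean_pool) ** 2).sum())
    num = 0.0
    count = 0
    for a, p in enumerate(idx_i):
        for b, q in enumerate(idx_j):
            d = math.hypot(pattern.x[p] - pattern.x[q], pattern.y[p] - pattern.y[q])
            if abs(d - r) <= hw:
                num += (m_i[a] - mean_i) * (m_j[b] - mean_j)
                count += 1
    if denom == 0.0:
        return float("nan"), count
    return num / denom, count
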