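"""Independent brute-force oracles used to validate the implementation.

Each oracle re-derives a quantity by the most literal method available —
exhaustive search, flood fill, direct covariance — sharing no code with the
implementation path it checks.
"""

from collections import deque

import numpy as np


def brute_force_otsu(values: np.ndarray, nbins: int = 256):
    """Exhaustively minimize the within-class variance of the raw pixel
    values over all 256 candidate gray-level thresholds; returns
    (set of optimal thresholds, optimal variance).  Intended for
    integer-valued (8-bit-style) images, where the candidate set is the
    gray levels themselves."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.min() == values.max():
        return {float(values.min())}, 0.0
    best, best_t = np.inf, set()
    for t in range(nbins):
        lo_cls = values[values <= t]
        hi_cls = values[values > t]
        if lo_cls.size == 0 or hi_cls.size == 0:
            continue
        w = (lo_cls.size * lo_cls.var() + hi_cls.size * hi_cls.var()) / values.size
        if w < best - 1e-9:
            best, best_t = w, {float(t)}
        elif abs(w - best) <= 1e-9:
            best_t.add(float(t))
    return best_t, best


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labels by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or labels[r, c]:
                continue
            current += 1
            queue = deque([(r, c)])
            labels[r, c] = current
            while queue:
                rr, cc = queue.popleft()
                for dr, dc in steps:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not labels[nr, nc]:
                        labels[nr, nc] = current
                        queue.append((nr, nc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label images induce the same partition of foreground."""
    fa, fb = a > 0, b > 0
    if not np.array_equal(fa, fb):
        return False
    pairs = set(zip(a[fa].ravel(), b[fb].ravel()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def covariance_moments(rows: np.ndarray, cols: np.ndarray):
    """Second central moments + 1/12 pixel correction via the literal sums."""
    rows = np.asarray(rows, float)
    cols = np.asarray(cols, float)
    n = rows.size
    mr, mc = rows.sum() / n, cols.sum() / n
    cxx = ((cols - mc) ** 2).sum() / n + 1.0 / 12.0
    cyy = ((rows - mr) ** 2).sum() / n + 1.0 / 12.0
    cxy = ((cols - mc) * (rows - mr)).sum() / n
    return cxx, cyy, cxy


def eccentricity_from_moments(cxx: float, cyy: float, cxy: float) -> float:
    tr, det = cxx + cyy, cxx * cyy - cxy**2
    disc = np.sqrt(max(tr * tr / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    return float(np.sqrt(max(1 - lam2 / lam1, 0.0)))


def quartile_fence(values, multiplier: float = 1.5) -> float:
    """Tukey upper fence by direct interpolated order statistics."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    return q3 + multiplier * (q3 - q1)


def rasterize_axis_aligned(cx, cy, a, b, shape):
    """Brute-force rasterization of an axis-aligned ellipse by checking
    every pixel center in the image."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            if ((c - cx) / a) ** 2 + ((r - cy) / b) ** 2 <= 1.0:
                mask[r, c] = True
    return mask
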