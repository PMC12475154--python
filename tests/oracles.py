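"""Independent brute-force oracles used only by the tests.

Everything here is written in the most literal way possible (explicit
loops, flood fill, textbook formulas) and stays independent of the
package's vectorised implementations.
"""

import math

import numpy as np


def months_suitable_loop(pool, world, mask):
    """Naive per-(niche, cell, month) triple loop."""
    cells = np.argwhere(mask.cells)
    out = np.zeros((len(pool), len(cells)), dtype=int)
    for k in range(len(pool)):
        lo, hi = pool.lower[k], pool.upper[k]
        for c, (i, j) in enumerate(cells):
            n = 0
            for m in range(12):
                t = world.sst[i, j, m]
                if np.isfinite(t) and lo <= t <= hi:
                    n += 1
            out[k, c] = n
    return out


def monthly_mean_richness_loop(pool, world, mask):
    """Per cell: mean over months of the count of suitable niches."""
    cells = np.argwhere(mask.cells)
    vals = np.zeros(len(cells))
    for c, (i, j) in enumerate(cells):
        total = 0
        for m in range(12):
            t = world.sst[i, j, m]
            if not np.isfinite(t):
                continue
            for k in range(len(pool)):
                if pool.lower[k] <= t <= pool.upper[k]:
                    total += 1
        vals[c] = total / 12.0
    return vals


def flood_fill_patches(occ, connectivity=2):
    """Stack-based flood fill with explicit longitude wrap adjacency."""
    occ = np.asarray(occ, dtype=bool)
    n_lat, n_lon = occ.shape
    seen = np.zeros_like(occ)
    if connectivity == 2:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for i0 in range(n_lat):
        for j0 in range(n_lon):
            if not occ[i0, j0] or seen[i0, j0]:
                continue
            count += 1
            stack = [(i0, j0)]
            seen[i0, j0] = True
            while stack:
                i, j = stack.pop()
                for di, dj in steps:
                    ni, nj = i + di, (j + dj) % n_lon
                    if 0 <= ni < n_lat and occ[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
    return count


def chebyshev_dist_periodic(land, i, j):
    """Brute-force Chebyshev distance from (i, j) to the nearest land
    cell on a grid periodic in the second axis."""
    n_lat, n_lon = land.shape
    best = math.inf
    for a in range(n_lat):
        for b in range(n_lon):
            if land[a, b]:
                dlon = min(abs(j - b), n_lon - abs(j - b))
                best = min(best, max(abs(i - a), dlon))
    return best


def pchip_fritsch_carlson(x, y, xq):
    """Monotone piecewise-cubic Hermite interpolation, Fritsch-Carlson
    derivative limiting, written from the published recipe."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    h = np.diff(x)
    delta = np.diff(y) / h
    d = np.zeros(n)
    # interior slopes: weighted harmonic mean when deltas share a sign
    for i in range(1, n - 1):
        if delta[i - 1] * delta[i] > 0:
            w1 = 2 * h[i] + h[i - 1]
            w2 = h[i] + 2 * h[i - 1]
            d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])
        else:
            d[i] = 0.0
    # one-sided endpoint formula with monotonicity clamps
    def endpoint(h0, h1, d0, d1):
        s = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if s * d0 <= 0:
            return 0.0
        if d0 * d1 < 0 and abs(s) > 3 * abs(d0):
            return 3 * d0
        return s

    d[0] = endpoint(h[0], h[1] if n > 2 else h[0], delta[0], delta[1] if n > 2 else delta[0])
    d[-1] = endpoint(h[-1], h[-2] if n > 2 else h[-1], delta[-1],
                     delta[-2] if n > 2 else delta[-1])
    xq = np.asarray(xq, float)
    out = np.empty(xq.shape)
    for k, xv in enumerate(xq):
        i = min(max(np.searchsorted(x, xv) - 1, 0), n - 2)
        t = (xv - x[i]) / h[i]
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[k] = (h00 * y[i] + h10 * h[i] * d[i] + h01 * y[i + 1] + h11 * h[i] * d[i + 1])
    return out


def pca_eig(Z):
    """Explained-variance fractions and PC1 from an explicit
    eigendecomposition of the correlation matrix."""
    n = Z.shape[0]
    C = (Z.T @ Z) / (n - 1)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    frac = w / w.sum()
    pc1 = Z @ v[:, 0]
    return frac, pc1


def pearson_textbook(x, y):
    """r, p from the covariance formula and the t CDF."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    mx, my = x.mean(), y.mean()
    r = float(np.sum((x - mx) * (y - my))
              / math.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)))
    df = n - 2
    tval = abs(r) * math.sqrt(df / (1 - r * r))
    return r, 2 * float(tdist.sf(tval, df))
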