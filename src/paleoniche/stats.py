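"""Correlation statistics with autocorrelation corrections.

Pearson correlations between age series (or between maps over their
shared mask) with three significance diagnostics:

* ``p`` — the ordinary two-tailed p-value at df = n - 2;
* ``p_acf`` — the p-value after reducing the degrees of freedom for
  serial autocorrelation with the effective-sample-size formula of
  Pyper & Peterman:  1/N* = 1/N + (2/N) * sum_j rho_xx(j) rho_yy(j),
  truncated at J = floor(N/5) lags with biased (1/N) autocorrelations;
* ``df_star`` — the minimal degrees of freedom at which the observed r
  would remain significant at p <= 0.05; a small df* means even heavy
  autocorrelation could not overturn the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
DF_STAR_CAP = 10_000_000


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float
    df_adj: int | None = None
    p_acf: float | None = None
    df_star: int | None = None


def _two_tailed_p(r: float, df: int) -> float:
    if df < 1:
        return 1.0
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    return 2.0 * float(sps.t.sf(t, df))


def correlate(x, y) -> CorrelationResult:
    """Pearson r with the ordinary t-based two-tailed p at df = n - 2."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be matching 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    return CorrelationResult(r=r, n=n, df=df, p=_two_tailed_p(r, df))


def _acf_biased(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 1..max_lag, 1/N normalisation."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    n = x.size
    out = np.zeros(max_lag)
    if denom == 0:
        return out
    for j in range(1, max_lag + 1):
        out[j - 1] = float(np.dot(x[:-j], x[j:])) / denom
    return out


def adjusted_p(x, y, result: CorrelationResult | None = None) -> CorrelationResult:
    """Fill df_adj and p_acf using the effective-sample-size correction."""
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    yv = np.asarray(getattr(y, "values", y), dtype=float)
    if result is None:
        result = correlate(xv, yv)
    n = result.n
    j_max = n // 5
    rx = _acf_biased(xv, j_max)
    ry = _acf_biased(yv, j_max)
    inv_nstar = 1.0 / n + (2.0 / n) * float(np.dot(rx, ry))
    n_star = 1.0 / inv_nstar if inv_nstar > 0 else float(n)
    df_adj = max(2, int(math.floor(n_star)) - 2)
    return replace(result, df_adj=df_adj, p_acf=_two_tailed_p(result.r, df_adj))


def minimal_df(r: float, cap: int = DF_STAR_CAP) -> int | None:
    """Smallest integer df >= 1 keeping the two-tailed p at or below 0.05.

    Returns None when no df up to ``cap`` achieves significance (always
    the case for r = 0).
    """
    if r == 0:
        return None
    if abs(r) >= 1.0:
        return 1
    lo, hi = 1, 1
    # exponential search for an upper bracket, then bisection
    while _two_tailed_p(r, hi) > ALPHA:
        if hi >= cap:
            return None
        lo = hi + 1
        hi = min(hi * 2, cap)
    while lo < hi:
        mid = (lo + hi) // 2
        if _two_tailed_p(r, mid) <= ALPHA:
            hi = mid
        else:
            lo = mid + 1
    return lo


def correlate_maps(a, b) -> CorrelationResult:
    """Pearson correlation between two richness maps over their shared
    masked cells, with df_star for the obtained r."""
    joint = a.mask_cells & b.mask_cells
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly masked cells")
    res = correlate(a.richness[joint], b.richness[joint])
    return replace(res, df_star=minimal_df(res.r))
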