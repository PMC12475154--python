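"""Random rectangular thermal niches.

A niche is a temperature interval [lower, upper] drawn from a stochastic
recipe with five parameters: organismal thermal limits alpha < beta, a
minimum and maximum tolerance-range width gamma <= delta, and the pool
size N.  Each niche draws two uniforms d1, d2; d1 sets the breadth X and
d2 places the centre Y uniformly in the admissible band so the interval
stays inside [alpha, beta]:

    X = d1 * (delta - gamma) + gamma          (default, "corrected")
    Y = d2 * (beta - X/2 - (alpha + X/2)) + (alpha + X/2)
    niche = [Y - X/2, Y + X/2]

An alternative breadth formula, X = d1 * (delta - gamma) + delta, is kept
behind ``breadth_formula="verbatim"``; it yields X in [delta, 2*delta -
gamma], inconsistent with gamma/delta being the breadth bounds, and is
provided only for comparison.

Because the centre is re-drawn uniformly within a band that depends on X,
the probability that a fixed temperature t is covered by a random niche
peaks at the mid-domain (alpha + beta) / 2 — a mid-domain effect living in
niche space rather than geographic space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ALPHA = -2.0   # deg C, sea water always frozen below
DEFAULT_BETA = 44.0    # deg C, metazoan reproductive ceiling
DEFAULT_GAMMA = 4.0    # deg C, minimum tolerance-range width
DEFAULT_DELTA = 20.0   # deg C, maximum tolerance-range width
DEFAULT_N = 100_000


@dataclass(frozen=True)
class NicheParams:
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    delta: float = DEFAULT_DELTA
    n_niches: int = DEFAULT_N
    seed: int = 0
    breadth_formula: str = "corrected"  # or "verbatim"

    def __post_init__(self) -> None:
        if not self.alpha < self.beta:
            raise ValueError("alpha must be < beta")
        if not (0 < self.gamma <= self.delta):
            raise ValueError("need 0 < gamma <= delta")
        if self.delta > self.beta - self.alpha:
            raise ValueError("delta exceeds the thermal domain width")
        if self.n_niches < 1:
            raise ValueError("n_niches must be >= 1")
        if self.breadth_formula not in ("corrected", "verbatim"):
            raise ValueError("breadth_formula must be 'corrected' or 'verbatim'")


@dataclass(frozen=True)
class NichePool:
    params: NicheParams
    lower: np.ndarray
    upper: np.ndarray

    def __len__(self) -> int:
        return self.lower.size

    @property
    def breadth(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


def niche_from_uniforms(d1, d2, params: NicheParams):
    """Map uniform draws (d1, d2) to (lower, upper); vectorised."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    p = params
    if p.breadth_formula == "corrected":
        x = d1 * (p.delta - p.gamma) + p.gamma
    else:
        x = d1 * (p.delta - p.gamma) + p.delta
    lo_c = p.alpha + x / 2.0
    hi_c = p.beta - x / 2.0
    y = d2 * (hi_c - lo_c) + lo_c
    return y - x / 2.0, y + x / 2.0


def generate_niche_pool(params: NicheParams) -> NichePool:
    """Draw the pool; deterministic for a fixed seed.

    Draw order is fixed: for each niche in sequence, d1 then d2, so a
    smaller pool with the same seed is a prefix of a larger one.
    """
    rng = np.random.default_rng(params.seed)
    draws = rng.random((params.n_niches, 2))
    lower, upper = niche_from_uniforms(draws[:, 0], draws[:, 1], params)
    return NichePool(params=params, lower=lower, upper=upper)


def suitability(pool: NichePool, temperature: float) -> np.ndarray:
    """Boolean per niche: does the (closed) interval cover temperature?"""
    t = float(temperature)
    if not np.isfinite(t):
        raise ValueError("temperature must be finite")
    return (pool.lower <= t) & (t <= pool.upper)


def coverage_probability(t, params: NicheParams, n_grid: int = 4001) -> np.ndarray:
    """P(lower <= t <= upper) for a random niche, by numerical integration.

    Conditional on breadth X, the centre Y is uniform on
    [alpha + X/2, beta - X/2]; the coverage probability is the measure of
    centres within X/2 of t, integrated over the distribution of X.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = params
    if p.breadth_formula == "corrected":
        x_lo, x_hi = p.gamma, p.delta
    else:
        x_lo, x_hi = p.delta, 2 * p.delta - p.gamma
    xs = np.linspace(x_lo, x_hi, n_grid)
    out = np.empty(t.shape)
    for i, ti in enumerate(t):
        lo = np.maximum(p.alpha + xs / 2.0, ti - xs / 2.0)
        hi = np.minimum(p.beta - xs / 2.0, ti + xs / 2.0)
        width = np.maximum(hi - lo, 0.0)
        band = p.beta - p.alpha - xs
        cond = np.where(band > 0, width / np.maximum(band, 1e-300), 1.0 * (width >= 0))
        out[i] = np.trapezoid(cond, xs) / (x_hi - x_lo) if x_hi > x_lo else cond[0]
    return float(out[0]) if scalar else out


def pool_to_csv(pool: NichePool, path) -> None:
    pd.DataFrame(
        {"niche_id": np.arange(len(pool)), "lower": pool.lower, "upper": pool.upper}
    ).to_csv(path, index=False)


def pool_from_csv(path, params: NicheParams | None = None) -> NichePool:
    df = pd.read_csv(path)
    lower = df["lower"].to_numpy(dtype=float)
    upper = df["upper"].to_numpy(dtype=float)
    if params is None:
        params = NicheParams(
            alpha=float(np.floor(lower.min())),
            beta=float(np.ceil(upper.max())),
            gamma=max(float((upper - lower).min()), 1e-9),
            delta=float((upper - lower).max()),
            n_niches=len(df),
        )
    return NichePool(params=params, lower=lower, upper=upper)
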