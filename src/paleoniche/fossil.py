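"""Fossil species richness index.

Several fossil diversity curves (genus- or species-level richness on an
age axis) are combined into a single composite: each curve is rescaled
to [0, 1], interpolated onto a common set of ages with shape-preserving
cubic interpolation, and the columns are z-scored before a principal
component analysis (i.e. PCA of the correlation matrix).  The first
component, with its sign oriented to track the across-curve mean, is the
fossil species richness index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .indices import AgeSeries, interpolate_to_ages


def standardise_01(series: AgeSeries) -> AgeSeries:
    """Affine rescale so the minimum maps to 0 and the maximum to 1."""
    lo, hi = series.values.min(), series.values.max()
    if hi == lo:
        raise ValueError("degenerate range: constant series cannot be standardised")
    return AgeSeries(series.ages, (series.values - lo) / (hi - lo), series.label)


@dataclass(frozen=True)
class FossilIndex:
    index: AgeSeries
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray  # PC1 loading per input curve
    curve_labels: tuple[str, ...]


def build_fossil_index(curves, target_ages) -> FossilIndex:
    """Standardise, interpolate, z-score and extract the oriented PC1.

    Parameters
    ----------
    curves : sequence of AgeSeries (at least two) whose common age span
        covers ``target_ages``.
    target_ages : ages (Ma) of the composite index.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two fossil curves")
    target = np.asarray(target_ages, dtype=float)
    cols = []
    for c in curves:
        std = standardise_01(c)
        cols.append(interpolate_to_ages(std, target).values)
    X = np.column_stack(cols)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a curve is constant over the target ages")
    Z = (X - mu) / sd

    pca = PCA(n_components=min(Z.shape))
    scores = pca.fit_transform(Z)
    pc1 = scores[:, 0]
    loadings = pca.components_[0].copy()

    # sign convention: PC1 tracks the mean of the standardised curves
    ref = Z.mean(axis=1)
    c = float(np.dot(pc1 - pc1.mean(), ref - ref.mean()))
    if c < 0 or (c == 0 and loadings[0] < 0):
        pc1 = -pc1
        loadings = -loadings

    return FossilIndex(
        index=AgeSeries(target, pc1, label="fossil_richness_index"),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        curve_labels=tuple(c.label for c in curves),
    )
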