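"""Tipping-point corroboration diagnostics.

Two independent lines of evidence that a detected breakpoint is a genuine
tipping point rather than a fitting artifact:

* a rising-variance early-warning profile: replicate variance of the
  response per gradient level, smoothed along the gradient — variance is
  expected to swell as the pressure approaches the threshold;
* multimodality of the pooled response distribution (alternative states),
  assessed with Hartigan's dip test calibrated by Monte-Carlo against
  uniform samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._dip import dip_statistic

__all__ = [
    "VarianceProfile",
    "DipResult",
    "variance_profile",
    "dip_statistic",
    "dip_null_table",
    "dip_test",
]


@dataclass
class VarianceProfile:
    """Replicate variance per gradient level with a smoothed trend.

    Variances are unbiased sample variances of ``mortality_pct`` across
    replicate tanks at each level (percent-squared units).  The smooth is a
    tricube-weighted local-linear fit (lowess) evaluated on ``grid``, which
    spans the observed levels only.
    """

    levels: np.ndarray
    variances: np.ndarray
    grid: np.ndarray
    smoothed: np.ndarray
    span: float

    def to_dict(self) -> dict:
        return {
            "levels": self.levels.tolist(),
            "variances": self.variances.tolist(),
            "grid": self.grid.tolist(),
            "smoothed": self.smoothed.tolist(),
            "span": float(self.span),
        }


def variance_profile(observations: pd.DataFrame, span: float = 0.75,
                     grid_size: int = 50) -> VarianceProfile:
    """Variance-along-gradient profile for one salinity treatment.

    ``observations`` is a tidy tank table restricted to a single salinity
    treatment; levels with fewer than two replicates are dropped with a
    warning.  ``span`` is the lowess fraction; it is floored so that each
    local window covers at least 3 levels.
    """
    if observations["salinity"].nunique() > 1:
        raise ValueError("variance_profile expects a single salinity treatment")
    groups = observations.groupby("nutrient_g")["mortality_pct"]
    counts = groups.size()
    thin = counts[counts < 2]
    if len(thin):
        import warnings
        warnings.warn(
            f"dropping level(s) with < 2 replicates: {list(thin.index)}",
            stacklevel=2)
    var = groups.var(ddof=1).dropna()
    var = var[counts >= 2]
    levels = var.index.to_numpy(dtype=float)
    if levels.size < 2:
        raise ValueError("need at least 2 levels with >= 2 replicates")
    v = var.to_numpy(dtype=float)
    span = max(float(span), min(1.0, 3.0 / levels.size))
    grid = np.linspace(levels.min(), levels.max(), grid_size)
    smoothed = lowess(v, levels, frac=span, it=0, xvals=grid)
    return VarianceProfile(levels=levels, variances=v, grid=grid,
                           smoothed=np.asarray(smoothed), span=span)


@dataclass
class DipResult:
    """Hartigan dip test outcome."""

    statistic: float
    pvalue: float
    n: int
    n_boot: int
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DipResult(statistic={self.statistic:.5f}, "
                f"pvalue={self.pvalue:.4g}, n={self.n}, n_boot={self.n_boot})")


def dip_null_table(n: int, n_boot: int = 999, seed=None) -> np.ndarray:
    """Monte-Carlo null dips: Uniform(0,1) samples of size n.

    The uniform is the standard calibration null for the dip test (the
    least favourable unimodal distribution); the table can be shared across
    many tests of the same sample size.
    """
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.uniform(size=n))
                     for _ in range(n_boot)])


def dip_test(sample, n_boot: int = 999, seed=None,
             null_dips: np.ndarray | None = None) -> DipResult:
    """Monte-Carlo dip test for multimodality.

    p = (1 + #{D_b >= D_obs}) / (B + 1) over B uniform null samples of the
    same size; significant values indicate more than one mode.  Pass
    ``null_dips`` (from :func:`dip_null_table`) to reuse a null table.
    """
    x = np.asarray(sample, dtype=float).ravel()
    d = dip_statistic(x)
    if null_dips is None:
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        null_dips = dip_null_table(x.size, n_boot, seed)
    else:
        null_dips = np.asarray(null_dips, dtype=float)
        n_boot = null_dips.size
    p = (1.0 + np.sum(null_dips >= d)) / (n_boot + 1.0)
    return DipResult(statistic=float(d), pvalue=float(p), n=x.size,
                     n_boot=int(n_boot),
                     seed=None if seed is None else int(seed))
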