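"""Posterior-draw summaries shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def kde_mode(draws: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a Gaussian kernel density (Silverman bandwidth) evaluated
    on a regular grid over the draw range — the "most likely" value of a
    posterior sample. Degenerate (constant) samples return the constant.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    lo, hi = draws.min(), draws.max()
    if hi - lo < 1e-12:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def equal_tailed_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval from empirical quantiles."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
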