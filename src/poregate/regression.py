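"""Ordinary least-squares line fits shared by the geometry, hydration and
gating modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LinearModel:
    """A fitted straight line y = intercept + slope * x.

    ``r_squared`` is the coefficient of determination of the OLS fit (in
    [0, 1] for a fit with intercept); ``residual_sd`` is sqrt(SSE / (n - 2)).
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_line(x, y, min_points: int = 3) -> LinearModel:
    """Fit y = a + b*x by ordinary least squares.

    Raises ``ValueError`` for fewer than ``min_points`` points or degenerate
    (zero-variance) x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("x has zero variance; slope is undefined")
    if np.ptp(y) == 0.0:
        # constant response: the horizontal line fits perfectly
        return LinearModel(0.0, float(y[0]), 1.0, int(x.size), 0.0)
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(x.size - 2, 1)
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
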