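"""Robust locally weighted scatterplot smoothing (LOWESS).

Cleveland-style smoother used for exploratory trajectory plots: at each
evaluation point the q = ceil(f*n) nearest neighbours (ties included)
receive tricube weights W(u) = (1 - |u|^3)^3 scaled by the distance to
the farthest neighbour, a degree-d polynomial is fitted by weighted
least squares, and the smoothed value is the local prediction.  Robust
iterations re-weight points by the bisquare function of their residuals,
B(e) = (1 - (e/6m)^2)^2 for |e| < 6m with m the median absolute
residual, which pulls the influence of gross outliers to zero.

Defaults follow the exploratory analysis settings used throughout this
pipeline: window fraction f = 0.8, local degree d = 1, two robustness
iterations.  Inference is deliberately absent here (no confidence
bands); rate testing belongs to the mixed-model module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import PdmorphError

__all__ = ["LowessConfig", "LowessCurve", "lowess_fit", "annual_rate_readout"]


class DegenerateInputError(PdmorphError):
    pass


@dataclass(frozen=True)
class LowessConfig:
    f: float = 0.8
    degree: int = 1
    robust_iters: int = 2
    eval_points: tuple | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise PdmorphError("window fraction f must lie in (0, 1]")
        if self.degree not in (0, 1, 2):
            raise PdmorphError("local polynomial degree must be 0, 1 or 2")
        if self.robust_iters < 0:
            raise PdmorphError("robust_iters must be >= 0")


@dataclass
class LowessCurve:
    x: np.ndarray
    fitted: np.ndarray
    robustness_weights: np.ndarray  # per observed data point, in [0, 1]


def _local_fit(x, y, w, x0, degree):
    """Weighted polynomial fit centred at x0; returns prediction at x0."""
    pos = w > 0
    n_distinct = len(np.unique(x[pos]))
    d = min(degree, max(n_distinct - 1, 0))
    dx = x - x0
    X = np.vander(dx, d + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef[0]


def lowess_fit(x, y, config: LowessConfig = LowessConfig()) -> LowessCurve:
    """Smooth y over x; deterministic.

    Evaluation is at the observed x (sorted) unless ``config.eval_points``
    supplies a grid.  Robustness weights are always computed against fits
    at the observed points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PdmorphError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < max(3, config.degree + 2):
        raise PdmorphError(f"need at least {max(3, config.degree + 2)} points")
    if not np.all(np.isfinite(x)):
        raise PdmorphError("x must be finite")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all x identical: nothing to smooth over")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    q = math.ceil(config.f * n)

    def kernel_weights(x0):
        d = np.abs(xs - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h == 0:
            # replicated x at the window: uniform weights over replicates
            w = (d == 0).astype(float)
        else:
            u = d / h
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
        return w

    delta = np.ones(n)
    fitted_obs = np.empty(n)
    for it in range(config.robust_iters + 1):
        for i, x0 in enumerate(xs):
            w = kernel_weights(x0) * delta
            if not np.any(w > 0):
                w = kernel_weights(x0)
            fitted_obs[i] = _local_fit(xs, ys, w, x0, config.degree)
        if it == config.robust_iters:
            break
        resid = ys - fitted_obs
        m = np.median(np.abs(resid))
        if m <= 0:
            break  # perfect fit; nothing to down-weight
        u = resid / (6.0 * m)
        delta = np.clip(1.0 - u**2, 0.0, None) ** 2

    if config.eval_points is None:
        return LowessCurve(x=xs, fitted=fitted_obs, robustness_weights=delta)

    grid = np.asarray(config.eval_points, dtype=float)
    fitted = np.array(
        [_local_fit(xs, ys, kernel_weights(g) * delta, g, config.degree) for g in grid]
    )
    return LowessCurve(x=grid, fitted=fitted, robustness_weights=delta)


def annual_rate_readout(curve: LowessCurve, x0: float, window: float = 1.0):
    """Central-difference slope of the smoothed curve at x0.

    Returns ``(rate, percent_per_year)`` where the percentage is the
    rate relative to the smoothed level at x0.  ``x0 +/- window/2`` must
    lie inside the curve's support.
    """
    lo, hi = x0 - window / 2.0, x0 + window / 2.0
    if lo < curve.x.min() - 1e-12 or hi > curve.x.max() + 1e-12:
        raise PdmorphError(
            f"readout window [{lo:.3g}, {hi:.3g}] outside curve support "
            f"[{curve.x.min():.3g}, {curve.x.max():.3g}]"
        )
    f_lo = np.interp(lo, curve.x, curve.fitted)
    f_hi = np.interp(hi, curve.x, curve.fitted)
    level = np.interp(x0, curve.x, curve.fitted)
    rate = (f_hi - f_lo) / window
    if level == 0:
        raise PdmorphError("smoothed level at x0 is zero; percentage undefined")
    return float(rate), float(rate / level * 100.0)
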