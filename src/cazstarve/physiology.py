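"""Growth-rate and biomass-decay estimation from batch-culture curves.

The specific growth rate is defined as d(ln x)/dt and estimated by
least-squares regression of ln(biomass) on time.  ``best_loglinear`` window
selection scans contiguous windows of at least four points whose biomass
exceeds a noise floor and keeps the *longest* window whose fit reaches a
minimum r-squared, tie-broken by higher r-squared — preferring long windows
keeps single stray points from shrinking the fit and biasing the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import GrowthCurve

__all__ = ["GrowthFit", "fit_mu_max", "fit_decay"]

#: Biomass below this fraction of the curve maximum is excluded from window
#: scanning (measurement noise dominates the log scale there).
NOISE_FLOOR_FRACTION = 0.05

#: Minimum r-squared a candidate log-linear window must reach.
R2_MIN = 0.995

MIN_POINTS = 4


@dataclass(frozen=True)
class GrowthFit:
    mu_max: float  # 1/h
    window: tuple[float, float]  # (t_start, t_end), hours
    r_squared: float
    x_end: float  # g/kg at window end
    n_points: int


def _loglinear(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of ln(x) ~ t; r^2 = 1 for an exact fit."""
    y = np.log(x)
    res = stats.linregress(t, y)
    pred = res.intercept + res.slope * t
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 or sse < 1e-24 else 1.0 - sse / sst
    return float(res.slope), float(res.intercept), r2


def fit_mu_max(
    curve: GrowthCurve,
    window_selection: str = "best_loglinear",
    window: tuple[float, float] | None = None,
    r2_min: float = R2_MIN,
) -> GrowthFit:
    """Maximum specific growth rate from a biomass curve.

    ``window_selection='fixed'`` fits within the given ``window`` (hours);
    ``'best_loglinear'`` scans contiguous windows as described in the module
    docstring.  Non-positive biomass points are excluded; fewer than four
    usable points is an error.
    """
    t = np.asarray(curve.times_h, dtype=float)
    x = np.asarray(curve.biomass, dtype=float)
    keep = x > 0
    t, x = t[keep], x[keep]
    if window_selection == "fixed":
        if window is None:
            raise ValueError("fixed window selection requires a window")
        sel = (t >= window[0]) & (t <= window[1])
        t, x = t[sel], x[sel]
        if len(t) < MIN_POINTS:
            raise ValueError("fewer than 4 usable points in window")
        slope, _, r2 = _loglinear(t, x)
        return GrowthFit(slope, (float(t[0]), float(t[-1])), r2, float(x[-1]), len(t))
    if window_selection != "best_loglinear":
        raise ValueError(f"unsupported window selection {window_selection!r}")

    floor = NOISE_FLOOR_FRACTION * x.max()
    usable = x > floor
    t, x = t[usable], x[usable]
    # mu_max lives in the growth phase: scan only up to the biomass peak
    # (fall back to the whole curve when that leaves too few points, e.g. a
    # constant series whose "peak" is its first sample).
    i_peak = int(np.argmax(x))
    if i_peak + 1 >= MIN_POINTS:
        t, x = t[: i_peak + 1], x[: i_peak + 1]
    n = len(t)
    if n < MIN_POINTS:
        raise ValueError("fewer than 4 usable points above the noise floor")
    best: tuple[int, float, GrowthFit] | None = None  # (length, r2, fit)
    for i in range(n - MIN_POINTS + 1):
        for j in range(i + MIN_POINTS, n + 1):
            slope, _, r2 = _loglinear(t[i:j], x[i:j])
            if r2 < r2_min:
                continue
            key = (j - i, r2)
            if best is None or key > (best[0], best[1]):
                fit = GrowthFit(
                    slope, (float(t[i]), float(t[j - 1])), r2, float(x[j - 1]), j - i
                )
                best = (j - i, r2, fit)
    if best is None:
        raise ValueError(f"no window of >= {MIN_POINTS} points reaches r^2 {r2_min}")
    return best[2]


def fit_decay(curve: GrowthCurve, window: tuple[float, float]) -> float:
    """Slope of ln(biomass) over a starvation window (negative for decay)."""
    if window[0] < 0:
        raise ValueError("decay windows lie in the starvation phase (t >= 0)")
    t = np.asarray(curve.times_h, dtype=float)
    x = np.asarray(curve.biomass, dtype=float)
    sel = (t >= window[0]) & (t <= window[1]) & (x > 0)
    if sel.sum() < MIN_POINTS:
        raise ValueError("fewer than 4 usable points in decay window")
    slope, _, _ = _loglinear(t[sel], x[sel])
    return slope
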