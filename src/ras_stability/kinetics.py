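"""Protein half-life estimation from cycloheximide-chase series.

After translation shutoff, first-order decay gives
``y(t) = y(0) * exp(-k t)``; band intensities are normalized to a
loading control and to the t = 0 lane, the log intensities are fitted
by ordinary least squares, and ``t_half = ln 2 / k``.  Series with no
measurable decay inside the chase window (k <= 0) are censored rather
than assigned a fitted value.  Replicate series are fitted jointly by
stacking points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simdata import ChaseSeries

__all__ = ["HalfLifeFit", "normalize_lanes", "fit_halflife", "fit_series", "stability_ratio"]

LN2 = float(np.log(2.0))


@dataclass
class HalfLifeFit:
    """Fitted first-order decay; ``censored`` marks series stable
    within the chase window, with ``window`` the last timepoint (the
    half-life is then reported as > window)."""

    k: float
    t_half: float
    se_t_half: float
    r_squared: float
    censored: bool
    window: float
    label: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.censored:
            return f"{self.label or 'series'}: t1/2 > {self.window:g} h (no decay in window)"
        return (
            f"{self.label or 'series'}: t1/2 = {self.t_half:.2f} h "
            f"(SE {self.se_t_half:.2f}, R^2 {self.r_squared:.3f})"
        )


def normalize_lanes(series: ChaseSeries) -> np.ndarray:
    """Loading-control and t=0 normalization:
    ``y_t = (target_t / loading_t) / (target_0 / loading_0)``."""
    t = np.asarray(series.timepoints, dtype=float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing and start at 0")
    target = np.asarray(series.target, dtype=float)
    loading = np.asarray(series.loading, dtype=float)
    bad = np.flatnonzero((target <= 0) | (loading <= 0))
    if bad.size:
        raise ValueError(f"nonpositive intensity at timepoint(s) {t[bad]}")
    ratio = target / loading
    return ratio / ratio[0]


def fit_halflife(timepoints, y, label: str = "") -> HalfLifeFit:
    """OLS of ln y on t; k = -slope, t_half = ln2/k, SE by the delta
    method.  Requires >= 3 points and positive normalized intensities."""
    t = np.asarray(timepoints, dtype=float)
    yy = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 timepoints")
    if np.any(yy <= 0):
        raise ValueError("normalized intensities must be positive")
    res = stats.linregress(t, np.log(yy))
    k = -res.slope
    r2 = float(res.rvalue**2)
    window = float(t.max())
    if k <= 0:
        return HalfLifeFit(
            k=k, t_half=np.inf, se_t_half=np.nan, r_squared=r2, censored=True,
            window=window, label=label,
        )
    t_half = LN2 / k
    se_t_half = LN2 / k**2 * float(res.stderr)
    return HalfLifeFit(
        k=k, t_half=t_half, se_t_half=se_t_half, r_squared=r2, censored=False,
        window=window, label=label,
    )


def fit_series(series: Sequence[ChaseSeries], label: str = "") -> HalfLifeFit:
    """Joint fit of replicate chase series: each series is normalized
    on its own t=0 lane, then all (t, ln y) points are stacked into one
    regression."""
    if not series:
        raise ValueError("no series given")
    ts, ys = [], []
    for s in series:
        ts.append(np.asarray(s.timepoints, dtype=float))
        ys.append(normalize_lanes(s))
    return fit_halflife(np.concatenate(ts), np.concatenate(ys), label=label or series[0].label)


def stability_ratio(
    group_a: Sequence[HalfLifeFit],
    group_b: Sequence[HalfLifeFit],
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fold difference in mean half-life between two groups with a
    percentile bootstrap CI over series resampling.

    Censored fits enter as lower bounds at their chase window (so the
    ratio is conservative); each group needs >= 1 uncensored fit.
    """

    def values(fits: Sequence[HalfLifeFit], name: str) -> np.ndarray:
        if not any(not f.censored for f in fits):
            raise ValueError(f"group {name} has no uncensored fits")
        return np.array([f.window if f.censored else f.t_half for f in fits], dtype=float)

    a = values(group_a, "a")
    b = values(group_b, "b")
    if b.mean() <= 0:
        raise ValueError("group b mean half-life undefined")
    ratio = float(a.mean() / b.mean())

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True)
        rb = rng.choice(b, size=b.size, replace=True)
        boots[i] = ra.mean() / rb.mean()
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ratio, (float(lo), float(hi))
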