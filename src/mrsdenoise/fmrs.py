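"""Functional-MRS temporal analysis.

Per-TR metabolite estimates become time series aligned with the stimulation
paradigm (t = 0 at stimulation onset, baseline at negative times).  The
standard processing chain is: moving-window smoothing (default window 16
TRs), normalization to the grand mean, then a tie-corrected Kendall rank
correlation between the metabolite course and the interpolated pain ratings
restricted to times after pain onset (default 12 min).

Statistical note: smoothing with a width-w boxcar makes neighboring points
strongly dependent, so the usual tau-b normal approximation (which assumes
independent observations) is badly anti-conservative on smoothed series.
:func:`post_onset_correlation` therefore inflates Var(S) by the closed-form
variance-inflation factor implied by the known boxcar window (triangular lag
correlation, rho_k = 1 - k/w) before computing the p-value.  The raw
:func:`kendall_tau` keeps the classical independent-sample p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .simulate import RatingTrace

__all__ = [
    "FunctionalSeries",
    "moving_average",
    "normalize_to_mean",
    "kendall_tau",
    "post_onset_correlation",
    "group_average",
]


@dataclass
class FunctionalSeries:
    """One metabolite's per-TR estimates for one subject.

    ``times`` are seconds from stimulation onset (baseline period is
    negative).  ``meta`` carries processing provenance, e.g. the smoothing
    window applied, which downstream inference uses to correct p-values.
    """

    times: np.ndarray
    values: np.ndarray
    metabolite: str = ""
    subject: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def moving_average(series: FunctionalSeries, window: int = 16) -> FunctionalSeries:
    """Centered moving mean; edge windows shrink symmetrically.

    Interior points average exactly ``window`` samples ((w-1)//2 left,
    w//2 right of center); near the edges the half-width shrinks to what is
    available on the shorter side so the window stays centered.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = series.values
    n = len(v)
    left, right = (window - 1) // 2, window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n):
        if i - left < 0 or i + right > n - 1:
            h = min(i, n - 1 - i)
            lo, hi = i - h, i + h
        else:
            lo, hi = i - left, i + right
        out[i] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    meta = dict(series.meta)
    meta["smoothing_window"] = window
    return replace(series, values=out, meta=meta)


def normalize_to_mean(series: FunctionalSeries) -> FunctionalSeries:
    """Divide by the grand mean over all time points (result has mean 1)."""
    mean = series.values.mean()
    if mean == 0:
        raise ValueError("cannot normalize a zero-mean series")
    return replace(series, values=series.values / mean)


def _kendall_counts(x: np.ndarray, y: np.ndarray):
    """Concordant/discordant and tie bookkeeping via full pair enumeration."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    prod = dx[iu] * dy[iu]
    C = int(np.sum(prod > 0))
    D = int(np.sum(prod < 0))
    tx = int(np.sum(dx[iu] == 0))
    ty = int(np.sum(dy[iu] == 0))
    txy = int(np.sum((dx[iu] == 0) & (dy[iu] == 0)))
    return C, D, tx, ty, txy


def _tie_groups(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _var_s(n: int, x: np.ndarray, y: np.ndarray) -> float:
    """Exact null variance of S = C - D under ties (Kendall's formula)."""
    tx = _tie_groups(x)
    ty = _tie_groups(y)

    def f0(t):
        return np.sum(t * (t - 1) * (2 * t + 5))

    def f1(t):
        return np.sum(t * (t - 1) * (t - 2))

    def f2(t):
        return np.sum(t * (t - 1))

    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - f0(tx) - f0(ty)) / 18.0
    if n > 2:
        var += f1(tx) * f1(ty) / (9.0 * n * (n - 1) * (n - 2))
    var += f2(tx) * f2(ty) / (2.0 * n * (n - 1))
    return float(var)


def kendall_tau(x, y, variance_inflation: float = 1.0) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided normal-approximation p.

    tau_b = (C - D) / sqrt((n0 - t_x)(n0 - t_y)) with n0 = n(n-1)/2 and
    t_x, t_y the tied-pair counts.  The p-value uses the exact null
    variance of S under ties, optionally inflated by
    ``variance_inflation`` to account for serial dependence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined: all values tied in one argument")
    C, D, tx, ty, _ = _kendall_counts(x, y)
    n0 = n * (n - 1) // 2
    tau = (C - D) / np.sqrt((n0 - tx) * (n0 - ty))
    var_s = _var_s(n, x, y) * max(variance_inflation, 1.0)
    z = (C - D) / np.sqrt(var_s)
    p = 2.0 * norm.sf(abs(z))
    return float(tau), float(p)


def _boxcar_vif(n: int, window: int) -> float:
    """Variance-inflation factor of S for boxcar-smoothed iid noise.

    A width-w moving average of white noise has lag correlation
    rho_k = 1 - k/w for k < w.  Var(S) is inflated approximately by the
    Hamed-Rao weighting of those known correlations.
    """
    if window <= 1 or n <= 3:
        return 1.0
    k = np.arange(1, min(window, n - 1))
    rho = 1.0 - k / window
    w = (n - k) * (n - k - 1) * (n - k - 2)
    cf = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * np.sum(w * rho)
    return float(max(cf, 1.0))


def post_onset_correlation(
    series: FunctionalSeries,
    ratings: RatingTrace,
    t_min: float = 12.0,
) -> tuple[float, float]:
    """Kendall correlation between a metabolite course and pain ratings
    after onset.

    Ratings are linearly interpolated onto the series' time grid; both are
    restricted to times > ``t_min`` minutes.  If the series was produced by
    :func:`moving_average` (recorded in ``meta['smoothing_window']``) the
    p-value is corrected for the serial dependence the smoother introduced.
    """
    t_cut = t_min * 60.0
    mask = series.times > t_cut
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points after the onset threshold")
    t = series.times[mask]
    if t.min() < ratings.times.min() - 1e-9 or t.max() > ratings.times.max() + 1e-9:
        # tolerate partial overlap but require some support
        inside = (t >= ratings.times.min()) & (t <= ratings.times.max())
        if inside.sum() < 3:
            raise ValueError("no overlapping time support after onset")
        t = t[inside]
        vals = series.values[mask][inside]
    else:
        vals = series.values[mask]
    interp = np.interp(t, ratings.times, ratings.nrs)
    window = int(series.meta.get("smoothing_window", 1))
    vif = _boxcar_vif(len(t), window)
    return kendall_tau(vals, interp, variance_inflation=vif)


def group_average(
    series_list: list[FunctionalSeries],
    exclude: list[str] | None = None,
) -> FunctionalSeries:
    """Mean time course across included subjects (common time grid required)."""
    exclude = set(exclude or [])
    kept = [s for s in series_list if s.subject not in exclude]
    if not kept:
        raise ValueError("all subjects excluded")
    t0 = kept[0].times
    for s in kept[1:]:
        if len(s.times) != len(t0) or not np.allclose(s.times, t0):
            raise ValueError("all series must share a common time grid")
    values = np.mean([s.values for s in kept], axis=0)
    meta = {"n_subjects": len(kept), "excluded": sorted(exclude)}
    return FunctionalSeries(
        times=t0.copy(), values=values,
        metabolite=kept[0].metabolite, subject="group", meta=meta,
    )
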