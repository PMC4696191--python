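"""Culture phenotype statistics: autoaggregation and generation time.

Autoaggregation compares culture optical density after vigorous mixing (A1)
with the settled upper phase (A2): percentage = 100 * (1 - A2/A1). The
generation (doubling) time comes from a least-squares fit of log2(CFU/ml)
against time over the exponential phase. Both come with seeded simulators
so the estimators can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AggregationMeasurement",
    "GrowthCurve",
    "autoaggregation_pct",
    "generation_time_h",
    "simulate_growth_curve",
    "simulate_aggregation",
]


@dataclass(frozen=True)
class AggregationMeasurement:
    """OD600 after mixing (A1) and of the settled upper phase (A2)."""

    a1: float
    a2: float

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("A1 must be positive")
        if self.a2 < 0:
            raise ValueError("A2 must be nonnegative")


@dataclass(frozen=True)
class GrowthCurve:
    """CFU/ml over time (colonies x dilution factor x 10)."""

    times_h: tuple[float, ...]
    cfu_per_ml: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.cfu_per_ml, dtype=float)
        if len(t) != len(c):
            raise ValueError("times and CFU values differ in length")
        if len(t) < 3:
            raise ValueError("need >=3 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(c > 0):
            raise ValueError("CFU values must be positive")


def autoaggregation_pct(m: AggregationMeasurement) -> float:
    """100 * (1 - A2/A1); negative if the upper phase thickened."""
    return 100.0 * (1.0 - m.a2 / m.a1)


def generation_time_h(
    curve: GrowthCurve, window: tuple[float, float] | str | None = None
) -> tuple[float, float]:
    """Doubling time and r-squared from a log2-linear fit.

    ``window`` restricts the fit: a (t_lo, t_hi) pair keeps points inside
    that time range; "auto" picks the contiguous run of >=4 points with the
    highest r-squared (longer runs win ties). A nonpositive fitted slope
    raises, since no doubling time is defined without exponential growth.
    """
    t = np.asarray(curve.times_h, dtype=float)
    y = np.log2(np.asarray(curve.cfu_per_ml, dtype=float))

    def fit(ti, yi):
        slope, intercept = np.polyfit(ti, yi, 1)
        resid = yi - (slope * ti + intercept)
        ss_tot = float(np.sum((yi - yi.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return slope, r2

    if isinstance(window, tuple):
        keep = (t >= window[0]) & (t <= window[1])
        if keep.sum() < 3:
            raise ValueError("fewer than 3 points in the requested window")
        t, y = t[keep], y[keep]
        slope, r2 = fit(t, y)
    elif window == "auto":
        best = None
        n = len(t)
        for i in range(n - 3):
            for j in range(i + 4, n + 1):
                slope, r2 = fit(t[i:j], y[i:j])
                key = (round(r2, 12), j - i)
                if best is None or key > best[0]:
                    best = (key, slope, r2)
        _, slope, r2 = best
    elif window is None:
        slope, r2 = fit(t, y)
    else:
        raise ValueError(f"unrecognized window spec {window!r}")
    if slope <= 0:
        raise ValueError("no exponential growth detected (nonpositive slope)")
    return 1.0 / slope, r2


def simulate_growth_curve(
    n0: float,
    doubling_time_h: float,
    duration_h: float = 9.0,
    step_h: float = 0.5,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential growth sampled every ``step_h`` with lognormal noise.

    CFU(t) = n0 * 2^(t / doubling_time_h) * eps, where eps is lognormal with
    unit mean and coefficient of variation ``noise_cv``.
    """
    if min(n0, doubling_time_h, duration_h, step_h) <= 0:
        raise ValueError("all simulator parameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + step_h / 2, step_h)
    cfu = n0 * 2.0 ** (t / doubling_time_h)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        cfu = cfu * rng.lognormal(-(sigma**2) / 2, sigma, size=len(t))
    return GrowthCurve(times_h=tuple(t), cfu_per_ml=tuple(cfu))


def simulate_aggregation(
    true_fraction: float, a1: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> AggregationMeasurement:
    """Settled-phase OD A2 = a1*(1 - fraction) + Gaussian noise, floored at 0."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if a1 <= 0:
        raise ValueError("a1 must be positive")
    rng = np.random.default_rng(seed)
    a2 = a1 * (1.0 - true_fraction)
    if noise_sd > 0:
        a2 += rng.normal(0.0, noise_sd)
    return AggregationMeasurement(a1=a1, a2=max(0.0, a2))
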