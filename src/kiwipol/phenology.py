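"""Bloom phenology for a dioecious orchard.

Flower buds open at a Gaussian rate centred on a peak day, and each open
flower closes after a fixed, sex-specific lifespan.  Because the opening
rate is Gaussian, the cumulative number of opened flowers has a closed
form in the standard normal CDF, and the number of currently open flowers
is a difference of two CDF evaluations.  Integration starts at t = 0 with
all buds closed, so the total that ever opens is
``buds * (1 - Phi(-peak/spread))`` — slightly below the bud count, the
mass of the Gaussian tail before day 0.

Conventions: time is measured in days from the start of bloom; "day d"
means the half-open interval [d, d+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "FlowerParams",
    "BloomTrajectory",
    "cumulative_opened",
    "open_count",
    "daily_female_closing",
    "bloom_trajectory",
    "bloom_overlap",
]


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class FlowerParams:
    """Bud counts, bloom timing and flower lifespans for both sexes.

    Attributes
    ----------
    buds_male, buds_female
        Total flower buds per hectare (B_m, B_f).
    peak_male, peak_female
        Day of peak opening rate (t_m, t_f).
    spread_male, spread_female
        Standard deviation of the Gaussian opening-rate curve in days
        (sigma_m, sigma_f).
    lifespan_male, lifespan_female
        Days an open flower stays open (tau_m, tau_f).
    """

    buds_male: float = 600_000.0
    buds_female: float = 600_000.0
    peak_male: float = 6.0
    peak_female: float = 6.0
    spread_male: float = 2.5
    spread_female: float = 2.0
    lifespan_male: float = 4.0
    lifespan_female: float = 5.0

    def __post_init__(self) -> None:
        for name in ("buds_male", "buds_female", "peak_male", "peak_female"):
            v = _check_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("spread_male", "spread_female",
                     "lifespan_male", "lifespan_female"):
            v = _check_finite(name, getattr(self, name))
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def male(self) -> tuple[float, float, float, float]:
        """(buds, peak, spread, lifespan) for male flowers."""
        return (self.buds_male, self.peak_male,
                self.spread_male, self.lifespan_male)

    @property
    def female(self) -> tuple[float, float, float, float]:
        return (self.buds_female, self.peak_female,
                self.spread_female, self.lifespan_female)


@dataclass(frozen=True)
class BloomTrajectory:
    """Open and cumulative flower counts sampled on a uniform time grid."""

    times: np.ndarray
    open_male: np.ndarray
    open_female: np.ndarray
    cum_male: np.ndarray
    cum_female: np.ndarray
    daily_female_closing: dict[int, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "m": self.open_male,
                "f": self.open_female,
                "M": self.cum_male,
                "F": self.cum_female,
            }
        )


def cumulative_opened(t, buds: float, peak: float, spread: float):
    """Cumulative flowers opened by time ``t`` (scalar or array).

    The Gaussian opening rate integrated from 0 to t:
    ``buds * (Phi((t - peak)/spread) - Phi((0 - peak)/spread))``.
    Arguments below 0 are treated as 0 (nothing had opened).
    """
    buds = _check_finite("buds", buds)
    peak = _check_finite("peak", peak)
    spread = _check_finite("spread", spread)
    if buds < 0 or peak < 0:
        raise ValueError("buds and peak must be >= 0")
    if spread <= 0:
        raise ValueError("spread must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = buds * (ndtr((t_arr - peak) / spread) - ndtr(-peak / spread))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def open_count(t, buds: float, peak: float, spread: float, lifespan: float):
    """Currently open flowers at ``t``: opened minus closed.

    Equals ``M(t) - M(t - lifespan)`` once ``t`` exceeds the lifespan and
    plain ``M(t)`` before that; always within [0, buds].
    """
    lifespan = _check_finite("lifespan", lifespan)
    if lifespan <= 0:
        raise ValueError("lifespan must be > 0")
    t_arr = np.asarray(t, dtype=float)
    opened = cumulative_opened(t_arr, buds, peak, spread)
    closed = cumulative_opened(np.maximum(t_arr - lifespan, 0.0),
                               buds, peak, spread)
    out = np.maximum(np.asarray(opened) - np.asarray(closed), 0.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def daily_female_closing(day: int, params: FlowerParams) -> float:
    """Female flowers closing during day ``day`` (interval [day, day+1)).

    A flower closing in that window opened one female lifespan earlier, so
    the count is a difference of cumulative openings shifted by tau_f.
    Summed over all days this recovers the total number that ever opened.
    """
    day = int(day)
    if day < 0:
        raise ValueError("day must be >= 0")
    buds, peak, spread, tau = params.female
    hi = max(day + 1 - tau, 0.0)
    lo = max(day - tau, 0.0)
    if hi <= 0.0 or buds == 0:
        return 0.0
    return cumulative_opened(hi, buds, peak, spread) - cumulative_opened(
        lo, buds, peak, spread
    )


def bloom_trajectory(params: FlowerParams, horizon: float,
                     grid_step: float = 0.01) -> BloomTrajectory:
    """Sample open/cumulative counts on a uniform grid over [0, horizon]."""
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    n = int(np.floor(horizon / grid_step)) + 1
    times = np.arange(n) * grid_step
    bm, pm, sm, lm = params.male
    bf, pf, sf, lf = params.female
    cum_m = cumulative_opened(times, bm, pm, sm)
    cum_f = cumulative_opened(times, bf, pf, sf)
    dfc = {
        d: daily_female_closing(d, params) for d in range(int(np.floor(horizon)))
    }
    return BloomTrajectory(
        times=times,
        open_male=open_count(times, bm, pm, sm, lm),
        open_female=open_count(times, bf, pf, sf, lf),
        cum_male=cum_m,
        cum_female=cum_f,
        daily_female_closing=dfc,
    )


def bloom_overlap(params: FlowerParams, grid_step: float = 0.01,
                  horizon: float | None = None):
    """Diagnostic overlap of the two bloom curves.

    Returns ``(times, min(m, f), integral)`` where the integral (trapezoid
    rule) measures flower-days during which both sexes are open — the
    window in which cross-pollination is possible at all.
    """
    if horizon is None:
        horizon = (max(params.peak_male, params.peak_female)
                   + 4.0 * max(params.spread_male, params.spread_female)
                   + max(params.lifespan_male, params.lifespan_female) + 1.0)
    traj = bloom_trajectory(params, horizon, grid_step)
    overlap = np.minimum(traj.open_male, traj.open_female)
    integral = float(np.trapezoid(overlap, traj.times))
    return traj.times, overlap, integral
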