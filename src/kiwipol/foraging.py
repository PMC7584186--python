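"""Pollinator foraging: visitation rate, movement preference, compartments.

The pollinator population is structured by pollen load: high, medium and
low loads (acquired on a male flower and run down by successive female
visits) plus a no-load class.  A male-flower visit refills a bee to the
high-load class regardless of its current state; each female-flower visit
steps it down one class.  Visits are delivered at a Holling type II rate
in the total number of open flowers, and the choice of flower sex follows
a preference-weighted share rule: a bee on a sex-s flower stays on sex s
with probability (share of sex s)**preference, so preference exponent 1
means indifference and exponents near 0 mean the bee almost never
switches sex.

Total pollinators are conserved exactly: each movement term appears once
as an inflow and once as an outflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "PollinatorParams",
    "PollinatorState",
    "visitation_rate",
    "stay_probability",
    "state_derivative",
    "deposit_visit_rates",
]

#: Open-flower count below which per-flower ratios are treated as empty.
FLOWER_GUARD = 1e-6


@dataclass(frozen=True)
class PollinatorParams:
    """Foraging behaviour and stocking density.

    Attributes
    ----------
    search_rate
        Holling encounter coefficient alpha, 1/(day * flower).  The value
        folds in the ~4 h of active pollen foraging per day.
    handling_time
        Time spent per flower visit, beta, in days of active foraging;
        caps the visitation rate at 1/beta.
    pref_male, pref_female
        Preference exponents delta (stay on male) and epsilon (stay on
        female), in [0, 1]; 1 = no preference, -> 0 = never switch sex.
    density
        Pollinators per 1000 female buds (rho).
    """

    search_rate: float = 480.0
    handling_time: float = 0.0011
    pref_male: float = 0.0634
    pref_female: float = 0.0725
    density: float = 6.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.search_rate) and self.search_rate > 0):
            raise ValueError("search_rate must be finite and > 0")
        if not (np.isfinite(self.handling_time) and self.handling_time >= 0):
            raise ValueError("handling_time must be finite and >= 0")
        for name in ("pref_male", "pref_female"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (np.isfinite(self.density) and self.density >= 0):
            raise ValueError("density must be finite and >= 0")


class PollinatorState(NamedTuple):
    """Pollinator counts by pollen load (P_m1, P_m2, P_m3, P_f)."""

    high_load: float
    mid_load: float
    low_load: float
    no_load: float

    @property
    def total(self) -> float:
        return self.high_load + self.mid_load + self.low_load + self.no_load


def visitation_rate(open_male: float, open_female: float,
                    params: PollinatorParams) -> float:
    """Per-bee flower visitation rate (1/day), Holling type II.

    ``alpha * x / (1 + alpha * beta * x)`` with x the total open flowers;
    zero with no flowers open, saturating at 1/beta.
    """
    if open_male < 0 or open_female < 0:
        raise ValueError("open flower counts must be >= 0")
    x = open_male + open_female
    return params.search_rate * x / (1.0 + params.search_rate
                                     * params.handling_time * x)


def stay_probability(open_same: float, open_total: float,
                     pref: float) -> float:
    """Probability of the next visit staying on the current flower sex.

    ``(open_same / open_total) ** pref``.  With no flowers open there is
    no movement at all, so the convention stay = 1 is returned; the zero
    visitation rate makes the choice inconsequential.
    """
    if not 0.0 <= pref <= 1.0:
        raise ValueError("pref must be in [0, 1]")
    if open_total <= 0.0:
        return 1.0
    share = open_same / open_total
    if share < 0.0 or share > 1.0 + 1e-12:
        raise ValueError("open_same must lie in [0, open_total]")
    share = min(share, 1.0)
    if pref == 0.0:
        return 1.0
    return share ** pref


def _movement(open_male: float, open_female: float,
              params: PollinatorParams) -> tuple[float, float, float]:
    """(visit rate V, male->female switch prob, female stay prob)."""
    V = visitation_rate(open_male, open_female, params)
    total = open_male + open_female
    stay_m = stay_probability(open_male, total, params.pref_male)
    stay_f = stay_probability(open_female, total, params.pref_female)
    return V, 1.0 - stay_m, stay_f


def state_derivative(state: PollinatorState, open_male: float,
                     open_female: float,
                     params: PollinatorParams) -> PollinatorState:
    """Time derivative of the four pollen-load compartments.

    Any bee visiting a male flower re-enters the high-load class; female
    visits step high -> mid -> low -> none.  The four components sum to
    zero identically (conservation of bees).
    """
    p1, p2, p3, pf = state
    if any(not np.isfinite(v) for v in state):
        raise ValueError("state contains non-finite values")
    V, move_mf, stay_f = _movement(open_male, open_female, params)
    move_fm = 1.0 - stay_f
    d_high = V * (move_fm * (p2 + p3 + pf) - move_mf * p1)
    d_mid = V * (move_mf * p1 - move_fm * p2 - stay_f * p2)
    d_low = V * (stay_f * p2 - move_fm * p3 - stay_f * p3)
    d_none = V * (stay_f * p3 - move_fm * pf)
    return PollinatorState(d_high, d_mid, d_low, d_none)


def deposit_visit_rates(state: PollinatorState, open_male: float,
                        open_female: float,
                        params: PollinatorParams) -> tuple[float, float, float]:
    """Field-total rates of pollen-depositing female visits (visits/day).

    Type n is a female visit by a class-n bee: type 1 = high-load bees
    switching male -> female, types 2 and 3 = mid/low-load bees making a
    further female visit.  These are exactly the downward compartment
    fluxes of :func:`state_derivative`; no-load bees deposit nothing.
    """
    p1, p2, p3, _ = state
    V, move_mf, stay_f = _movement(open_male, open_female, params)
    return (V * move_mf * p1, V * stay_f * p2, V * stay_f * p3)
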