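"""Parameter-sweep experiments over the orchard model.

Each sweep point is an independent full :func:`~kiwipol.simulate.integrate`
call; the forward model is deterministic, so sweep outputs are exactly
reproducible.

A note on bee counts in bud-composition sweeps: the stocking density rho
is quoted per 1000 female buds.  When the female fraction of a fixed bud
total is varied, the bee population in the field is held at the *base*
scenario's count (rho x base B_f / 1000) rather than re-derived from each
point's female count ("reference" anchor).  Re-deriving per point
("per_point") makes the bee population collapse together with the female
share, which mixes two interventions — changing pruning and changing hive
stocking — into one axis; anchoring isolates the composition effect.
Both behaviours are available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .simulate import Scenario, SimulationResult, initial_pollinators, integrate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "sweep_female_fraction",
    "refine_female_fraction_optimum",
    "sweep_bee_density",
    "sweep_male_peak",
    "sweep_preference",
    "sweep_handling_time",
    "surface_female_by_density",
    "SECONDS_PER_FORAGING_DAY",
]

#: Active pollen-foraging time per day: 4 hours.  Handling times quoted in
#: seconds convert to model days of foraging with this factor, consistent
#: with the base parameterization (a 16 s visit ~ 0.0011 days).
SECONDS_PER_FORAGING_DAY = 4 * 3600


@dataclass(frozen=True)
class SweepSpec:
    """A named grid and a factory mapping each grid value to a Scenario."""

    name: str
    grid: np.ndarray
    factory: Callable[[float], Scenario]

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be nonempty")


@dataclass(frozen=True)
class SweepResult:
    """Yield and fruit set at every grid point of a 1-D sweep."""

    name: str
    grid: np.ndarray
    total_yield: np.ndarray
    fruit_set: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.total_yield)
                == len(self.fruit_set)):
            raise ValueError("grid and result lengths differ")

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.total_yield))

    @property
    def argmax_value(self) -> float:
        return float(self.grid[self.argmax])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            self.name: self.grid,
            "total_yield": self.total_yield,
            "fruit_set_percent": 100.0 * self.fruit_set,
        })

    def summary(self) -> dict:
        return {
            "sweep": self.name,
            "argmax": self.argmax_value,
            "max_yield": float(self.total_yield[self.argmax]),
            "fruit_set_at_max": float(self.fruit_set[self.argmax]),
        }


def run_sweep(spec: SweepSpec) -> SweepResult:
    yields, fsets = [], []
    for x in spec.grid:
        res: SimulationResult = integrate(spec.factory(float(x)))
        yields.append(res.total_yield)
        fsets.append(res.fruit_set)
    return SweepResult(spec.name, np.asarray(spec.grid, dtype=float),
                       np.asarray(yields), np.asarray(fsets))


def _female_fraction_scenario(base: Scenario, total_buds: float,
                              fraction: float, bee_anchor: str) -> Scenario:
    if not 0.0 < fraction < 1.0:
        raise ValueError("female fraction must be strictly inside (0, 1)")
    buds_f = fraction * total_buds
    flowers = replace(base.flowers, buds_female=buds_f,
                      buds_male=total_buds - buds_f)
    if bee_anchor == "reference":
        n_bees = initial_pollinators(base)
    elif bee_anchor == "per_point":
        n_bees = None
    else:
        raise ValueError("bee_anchor must be 'reference' or 'per_point'")
    return replace(base, flowers=flowers, n_pollinators=n_bees)


def sweep_female_fraction(fractions: Sequence[float], total_buds: float,
                          base: Scenario,
                          bee_anchor: str = "reference") -> SweepResult:
    """Vary the female share of a fixed bud total (composition sweep)."""
    spec = SweepSpec(
        "female_fraction", np.asarray(fractions, dtype=float),
        lambda x: _female_fraction_scenario(base, total_buds, x, bee_anchor))
    return run_sweep(spec)


def refine_female_fraction_optimum(
        base: Scenario, total_buds: float,
        coarse_step: float = 0.05, fine_step: float = 0.01,
        bee_anchor: str = "reference") -> tuple[SweepResult, SweepResult]:
    """Coarse composition sweep plus a fine re-sweep around its argmax.

    Returns ``(coarse, fine)``; the fine grid spans one coarse step either
    side of the coarse argmax at ``fine_step`` resolution.
    """
    coarse_grid = np.arange(coarse_step, 1.0 - coarse_step / 2, coarse_step)
    coarse = sweep_female_fraction(coarse_grid, total_buds, base, bee_anchor)
    center = coarse.argmax_value
    lo = max(center - coarse_step, fine_step)
    hi = min(center + coarse_step, 1.0 - fine_step)
    n = int(round((hi - lo) / fine_step))
    fine_grid = lo + fine_step * np.arange(n + 1)
    fine = sweep_female_fraction(fine_grid, total_buds, base, bee_anchor)
    return coarse, fine


def sweep_bee_density(densities: Sequence[float], base: Scenario) -> SweepResult:
    """Vary the stocking density rho (bees per 1000 female buds)."""
    densities = np.asarray(densities, dtype=float)
    if np.any(densities <= 0):
        raise ValueError("densities must be > 0")
    spec = SweepSpec(
        "bee_density", densities,
        lambda x: replace(base,
                          pollinators=replace(base.pollinators, density=x),
                          n_pollinators=None))
    return run_sweep(spec)


def sweep_male_peak(peaks: Sequence[float], base: Scenario) -> SweepResult:
    """Shift the male bloom peak t_m while the female peak stays put."""
    spec = SweepSpec(
        "male_peak", np.asarray(peaks, dtype=float),
        lambda x: replace(base, flowers=replace(base.flowers, peak_male=x)))
    return run_sweep(spec)


def sweep_preference(values: Sequence[float], base: Scenario,
                     which: str = "both") -> SweepResult:
    """Vary the stay-preference exponents delta/epsilon.

    ``which`` selects "male-pref" (delta), "female-pref" (epsilon) or
    "both".  Values near 0 are strong tendencies to remain on the current
    flower sex; 1 removes the preference entirely.
    """
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("preference values must lie in [0, 1]")
    if which not in ("male-pref", "female-pref", "both"):
        raise ValueError("which must be 'male-pref', 'female-pref' or 'both'")

    def factory(x: float) -> Scenario:
        pol = base.pollinators
        if which in ("male-pref", "both"):
            pol = replace(pol, pref_male=x)
        if which in ("female-pref", "both"):
            pol = replace(pol, pref_female=x)
        return replace(base, pollinators=pol)

    return run_sweep(SweepSpec(f"preference_{which}", values, factory))


def sweep_handling_time(handling_seconds: Sequence[float],
                        base: Scenario) -> SweepResult:
    """Vary the per-visit handling time, supplied in seconds.

    Seconds convert to days of active foraging via the 4 h foraging day
    (:data:`SECONDS_PER_FORAGING_DAY`).
    """
    secs = np.asarray(handling_seconds, dtype=float)
    if np.any(secs < 0):
        raise ValueError("handling times must be >= 0")
    spec = SweepSpec(
        "handling_seconds", secs,
        lambda x: replace(base, pollinators=replace(
            base.pollinators, handling_time=x / SECONDS_PER_FORAGING_DAY)))
    return run_sweep(spec)


def surface_female_by_density(fractions: Sequence[float],
                              densities: Sequence[float],
                              total_buds: float, base: Scenario,
                              bee_anchor: str = "reference") -> np.ndarray:
    """Yield matrix over (density, fraction): rows densities, cols fractions.

    Each row reuses the composition-sweep rule at that stocking density,
    so a row is pointwise identical to :func:`sweep_female_fraction` run
    at the same density.
    """
    fractions = np.asarray(fractions, dtype=float)
    densities = np.asarray(densities, dtype=float)
    out = np.empty((len(densities), len(fractions)))
    for i, rho in enumerate(densities):
        row_base = replace(base,
                           pollinators=replace(base.pollinators, density=rho),
                           n_pollinators=None)
        res = sweep_female_fraction(fractions, total_buds, row_base,
                                    bee_anchor)
        out[i] = res.total_yield
    return out
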