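"""Global sensitivity analysis: Latin hypercube sampling with PRCC.

Parameters are sampled with uniform marginals over their plausible
ranges using Latin hypercube sampling (one draw per equiprobable stratum
per parameter), the model is run at every sample, and the influence of
each parameter on total predicted yield is summarised by its partial
rank correlation coefficient (PRCC): the correlation between the ranks
of the parameter and the ranks of the output after removing the
rank-linear influence of every other parameter.  Significance follows
the usual transformation ``prcc * sqrt((n - 2 - k) / (1 - prcc**2))``
with ``k`` the number of covariates adjusted for, referred to Student's
t (a normal-reference p-value is reported alongside).

PRCC assumes a monotone parameter-output relationship, so a decile-bin
monotonicity diagnostic is provided; parameters flagged nonmonotone can
be re-analysed on truncated, monotone sub-ranges with a fresh design.

Bud-composition covariates: raw bud counts B_m and B_f can either be
sampled directly (``parameterization="raw"``, with PRCC optionally
reported for the derived covariates total buds and percent female), or
the design can sample total buds and the female percentage themselves
(``"derived"``), which lets the female share span its agronomically
interesting range 5-96% instead of the 25-75% reachable from independent
bud counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .simulate import Scenario, SimulationError, integrate

__all__ = [
    "ParameterRanges",
    "LHSDesign",
    "PRCCReport",
    "MonotonicityResult",
    "table2_ranges",
    "lhs_sample",
    "scenario_from_sample",
    "run_batch",
    "prcc",
    "monotonicity_check",
    "truncated_prcc",
]

_RAW_RANGES: tuple[tuple[str, float, float], ...] = (
    ("alpha", 120.0, 3600.0),
    ("beta", 0.00013, 0.0094),
    ("delta", 0.0, 1.0),
    ("epsilon", 0.0, 1.0),
    ("B_m", 300_000.0, 900_000.0),
    ("B_f", 300_000.0, 900_000.0),
    ("t_m", 2.0, 9.0),
    ("t_f", 2.0, 9.0),
    ("sigma_m", 0.5, 5.5),
    ("sigma_f", 1.0, 4.0),
    ("tau_m", 3.0, 5.0),
    ("tau_f", 3.0, 7.0),
    ("rho", 1.0, 20.0),
    ("p1", 0.25, 0.75),
    ("p2", 0.10, 0.65),
    ("p3", 0.0, 0.50),
)

_DERIVED_BUDS: tuple[tuple[str, float, float], ...] = (
    ("total_buds", 600_000.0, 1_800_000.0),
    ("pct_female", 0.05, 0.96),
)


@dataclass(frozen=True)
class ParameterRanges:
    """Ordered (name, low, high) triples defining the sampled hypercube."""

    items: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for name, lo, hi in self.items:
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: [{lo}, {hi}]")
            if name in seen:
                raise ValueError(f"duplicate parameter {name}")
            seen.add(name)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.items]

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[lo, hi] for _, lo, hi in self.items])

    def truncated(self, windows: dict[str, tuple[float, float]]
                  ) -> "ParameterRanges":
        """New ranges with some parameters restricted to sub-windows."""
        unknown = set(windows) - set(self.names)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        items = []
        for name, lo, hi in self.items:
            if name in windows:
                wlo, whi = windows[name]
                if not (lo <= wlo < whi <= hi):
                    raise ValueError(
                        f"window [{wlo}, {whi}] for {name} outside [{lo}, {hi}]")
                items.append((name, float(wlo), float(whi)))
            else:
                items.append((name, lo, hi))
        return ParameterRanges(tuple(items))


def table2_ranges(parameterization: str = "raw") -> ParameterRanges:
    """The default plausibility ranges for every model parameter.

    ``"raw"`` samples the bud counts B_m and B_f independently;
    ``"derived"`` replaces them with total buds and percent female.
    """
    if parameterization == "raw":
        return ParameterRanges(_RAW_RANGES)
    if parameterization == "derived":
        items = tuple(r for r in _RAW_RANGES if r[0] not in ("B_m", "B_f"))
        return ParameterRanges(_DERIVED_BUDS + items)
    raise ValueError("parameterization must be 'raw' or 'derived'")


@dataclass(frozen=True)
class LHSDesign:
    """A Latin hypercube sample over a set of parameter ranges."""

    ranges: ParameterRanges
    unit: np.ndarray      # (n, k) in [0, 1)
    samples: np.ndarray   # (n, k) scaled to the ranges
    seed: int

    @property
    def n(self) -> int:
        return self.unit.shape[0]

    @property
    def names(self) -> list[str]:
        return self.ranges.names

    def strata(self) -> np.ndarray:
        """Stratum index of every unit sample (LHS: a permutation per column)."""
        return np.floor(self.unit * self.n).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


def lhs_sample(ranges: ParameterRanges, n: int, seed: int) -> LHSDesign:
    """Stratified uniform sample: one draw in each of n equiprobable strata
    of every parameter's range."""
    k = len(ranges.items)
    if n < 2:
        raise ValueError("need at least 2 samples")
    sampler = qmc.LatinHypercube(d=k, seed=int(seed))
    unit = sampler.random(n=n)
    bounds = ranges.bounds
    samples = bounds[:, 0] + unit * (bounds[:, 1] - bounds[:, 0])
    return LHSDesign(ranges=ranges, unit=unit, samples=samples, seed=int(seed))


_SCENARIO_FIELDS = {
    "alpha": ("pollinators", "search_rate"),
    "beta": ("pollinators", "handling_time"),
    "delta": ("pollinators", "pref_male"),
    "epsilon": ("pollinators", "pref_female"),
    "rho": ("pollinators", "density"),
    "B_m": ("flowers", "buds_male"),
    "B_f": ("flowers", "buds_female"),
    "t_m": ("flowers", "peak_male"),
    "t_f": ("flowers", "peak_female"),
    "sigma_m": ("flowers", "spread_male"),
    "sigma_f": ("flowers", "spread_female"),
    "tau_m": ("flowers", "lifespan_male"),
    "tau_f": ("flowers", "lifespan_female"),
    "p1": ("fruitset", "p1"),
    "p2": ("fruitset", "p2"),
    "p3": ("fruitset", "p3"),
}


def scenario_from_sample(names: list[str], row: np.ndarray,
                         base: Scenario) -> Scenario:
    """Build a Scenario from one design row, overriding ``base``."""
    values = dict(zip(names, (float(v) for v in row)))
    if "total_buds" in values or "pct_female" in values:
        if not ("total_buds" in values and "pct_female" in values):
            raise KeyError("total_buds and pct_female must be sampled together")
        total = values.pop("total_buds")
        pct = values.pop("pct_female")
        values["B_f"] = pct * total
        values["B_m"] = (1.0 - pct) * total
    groups: dict[str, dict[str, float]] = {}
    for name, value in values.items():
        if name not in _SCENARIO_FIELDS:
            raise KeyError(f"unknown parameter {name}")
        group, fld = _SCENARIO_FIELDS[name]
        groups.setdefault(group, {})[fld] = value
    out = base
    if "flowers" in groups:
        out = replace(out, flowers=replace(out.flowers, **groups["flowers"]))
    if "pollinators" in groups:
        out = replace(out, pollinators=replace(out.pollinators,
                                               **groups["pollinators"]))
    if "fruitset" in groups:
        out = replace(out, fruitset=replace(out.fruitset, **groups["fruitset"]))
    return replace(out, n_pollinators=None, horizon=None)


def run_batch(design: LHSDesign, base: Scenario,
              max_failure_fraction: float = 0.01
              ) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Total predicted yield at every design row.

    Failed rows carry NaN in the output and are listed in the second
    return value; more than ``max_failure_fraction`` failures aborts.
    """
    yields = np.full(design.n, np.nan)
    failures: list[tuple[int, str]] = []
    for i in range(design.n):
        try:
            scen = scenario_from_sample(design.names, design.samples[i], base)
            yields[i] = integrate(scen).total_yield
        except (SimulationError, ValueError) as exc:
            failures.append((i, str(exc)))
    if len(failures) > max_failure_fraction * design.n:
        raise SimulationError(
            f"{len(failures)}/{design.n} batch rows failed; first: "
            f"{failures[0]}")
    return yields, failures


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def _partial_residual(target: np.ndarray, others: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(target)), others])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ coef


@dataclass(frozen=True)
class PRCCReport:
    """Per-parameter partial rank correlations with significance tests."""

    table: pd.DataFrame
    n: int
    k_adjusted: int
    alpha: float = 0.05
    truncation: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, parameter: str) -> float:
        return float(self.table.set_index("parameter").loc[parameter, "prcc"])

    def p_value(self, parameter: str) -> float:
        return float(self.table.set_index("parameter").loc[parameter, "p_t"])

    def is_significant(self, parameter: str) -> bool:
        return bool(self.table.set_index("parameter")
                    .loc[parameter, "significant"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def prcc(samples: np.ndarray, output: np.ndarray, names: list[str],
         alpha: float = 0.05,
         derive_bud_covariates: bool = False) -> PRCCReport:
    """Partial rank correlation of the output against each parameter.

    All columns and the output are rank-transformed (average ranks on
    ties); each parameter's PRCC is the Pearson correlation between the
    residuals of rank-linear regressions of that parameter and of the
    output on all remaining parameters.  Rows with a non-finite output
    (failed runs) are dropped.  With ``derive_bud_covariates`` the raw
    ``B_m``/``B_f`` columns are replaced by total buds and percent female
    before the analysis.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(output, dtype=float)
    names = list(names)
    if X.shape[0] != len(y):
        raise ValueError("samples and output lengths differ")
    if derive_bud_covariates:
        if "B_m" not in names or "B_f" not in names:
            raise KeyError("derive_bud_covariates requires B_m and B_f columns")
        im, if_ = names.index("B_m"), names.index("B_f")
        total = X[:, im] + X[:, if_]
        pct = X[:, if_] / total
        keep = [j for j in range(X.shape[1]) if j not in (im, if_)]
        X = np.column_stack([total, pct, X[:, keep]])
        names = ["total_buds", "pct_female"] + [names[j] for j in keep]
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("need more samples than parameters + 2")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant design column: rank degeneracy")
    R = _rank(X)
    ry = _rank(y)
    k_adj = k - 1
    df = n - 2 - k_adj
    rows = []
    for j in range(k):
        others = np.delete(R, j, axis=1)
        rx_res = _partial_residual(R[:, j], others)
        ry_res = _partial_residual(ry, others)
        denom = np.sqrt((rx_res ** 2).sum() * (ry_res ** 2).sum())
        if denom == 0:
            raise ValueError(f"rank degeneracy for parameter {names[j]}")
        r = float((rx_res * ry_res).sum() / denom)
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            stat = np.inf * np.sign(r)
            p_t = p_norm = 0.0
        else:
            stat = r * np.sqrt(df / (1.0 - r * r))
            p_t = 2.0 * stats.t.sf(abs(stat), df)
            p_norm = 2.0 * stats.norm.sf(abs(stat))
        rows.append({"parameter": names[j], "prcc": r, "stat": stat,
                     "p_t": p_t, "p_normal": p_norm,
                     "significant": p_t < alpha})
    table = pd.DataFrame(rows)
    return PRCCReport(table=table, n=n, k_adjusted=k_adj, alpha=alpha)


@dataclass(frozen=True)
class MonotonicityResult:
    """Decile-bin diagnostic of the parameter-output relationship."""

    monotone: bool
    split_points: tuple[float, ...]
    bin_edges: np.ndarray
    bin_means: np.ndarray
    smoothed: np.ndarray


def monotonicity_check(x: np.ndarray, y: np.ndarray,
                       n_bins: int = 10) -> MonotonicityResult:
    """Flag a nonmonotone parameter-output relationship.

    The parameter is cut into ``n_bins`` equal-count bins; bin means of
    the output are smoothed with a 3-point moving average (edge bins
    replicated), and successive differences of the smoothed curve whose
    magnitude exceeds twice their propagated standard error count as
    signed moves.  Both signs present => nonmonotone, with a split
    proposed at the boundary of the extremum bin (the edge where the
    monotone regime ends).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    ses = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = y[idx == b]
        if len(vals) == 0:
            raise ValueError("empty bin; not enough samples")
        means[b] = vals.mean()
        ses[b] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    # moving-average smoothing as an explicit weight matrix so the
    # standard error of each smoothed difference can be propagated exactly
    W = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        window = [max(i - 1, 0), i, min(i + 1, n_bins - 1)]
        for j in window:
            W[i, j] += 1.0 / 3.0
    smoothed = W @ means
    D = np.diff(W, axis=0)
    diffs = D @ means
    noise = 2.0 * np.sqrt((D ** 2) @ (ses ** 2))
    signs = np.sign(diffs) * (np.abs(diffs) > noise)
    signs = signs[signs != 0]
    monotone = not (np.any(signs > 0) and np.any(signs < 0))
    splits: tuple[float, ...] = ()
    if not monotone:
        if signs[0] > 0:          # rises then falls: peak
            ext = int(np.argmax(smoothed))
        else:                     # falls then rises: trough
            ext = int(np.argmin(smoothed))
        splits = (float(edges[min(ext + 1, n_bins)]),)
    return MonotonicityResult(monotone=monotone, split_points=splits,
                              bin_edges=edges, bin_means=means,
                              smoothed=smoothed)


def monotonicity_report(samples: np.ndarray, output: np.ndarray,
                        names: list[str],
                        n_bins: int = 10) -> dict[str, MonotonicityResult]:
    """Monotonicity diagnostics for every parameter of an LHS batch.

    In a global design the output variance at fixed x_j is dominated by
    the other sampled parameters, which would mask all but the largest
    curvature.  Mirroring the adjustment PRCC makes, the linear influence
    of the other parameters is regressed out of the output first and the
    bin diagnostic applied to the residual against x_j.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(output, dtype=float)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    report = {}
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        resid = _partial_residual(y, others)
        report[name] = monotonicity_check(X[:, j], resid, n_bins=n_bins)
    return report


def truncated_prcc(base: Scenario, ranges: ParameterRanges,
                   windows: dict[str, tuple[float, float]],
                   n: int, seed: int,
                   alpha: float = 0.05) -> PRCCReport:
    """Re-run the LHS/PRCC pipeline on truncated parameter ranges.

    A fresh hypercube (same seed, so truncating to the full original
    range reproduces the full-range analysis exactly) is drawn inside
    the truncated ranges, the batch is re-run, and PRCC recomputed.
    """
    truncated = ranges.truncated(windows)
    design = lhs_sample(truncated, n, seed)
    yields, _ = run_batch(design, base)
    report = prcc(design.samples, yields, design.names, alpha=alpha)
    return PRCCReport(table=report.table, n=report.n,
                      k_adjusted=report.k_adjusted, alpha=alpha,
                      truncation={k: (float(v[0]), float(v[1]))
                                  for k, v in windows.items()})
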