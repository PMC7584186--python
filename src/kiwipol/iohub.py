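"""Configuration, canonical scenario fixtures, and result serialization.

Configs are flat YAML key-value documents using the field-standard
parameter names (alpha, beta, delta, epsilon, B_m, B_f, t_m, t_f,
sigma_m, sigma_f, tau_m, tau_f, rho, p1, p2, p3) plus run controls.  An
empty document is the base orchard: a 1 ha block with 600,000 buds of
each sex peaking on day 6, 6 bees per 1000 female buds, and the measured
foraging and per-visit fruit-set parameters.

Values loaded from a file are checked against each parameter's plausible
range and rejected outside it unless ``allow_out_of_range`` is set;
scenarios built programmatically (e.g. by sweeps) are only subject to
hard validity constraints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from .experiments import (
    SECONDS_PER_FORAGING_DAY,
    SweepSpec,
    _female_fraction_scenario,
)
from .foraging import PollinatorParams
from .phenology import FlowerParams
from .simulate import FruitSetParams, Scenario

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "scenario_to_dict",
    "fixtures",
    "FIXTURE_NAMES",
    "write_summary_json",
]

log = logging.getLogger("kiwipol")


class ConfigError(ValueError):
    """Bad key, unreadable document or out-of-range value in a config."""


_PARAM_KEYS = {
    "alpha": ("pollinators", "search_rate", 120.0, 3600.0),
    "beta": ("pollinators", "handling_time", 0.00013, 0.0094),
    "delta": ("pollinators", "pref_male", 0.0, 1.0),
    "epsilon": ("pollinators", "pref_female", 0.0, 1.0),
    "rho": ("pollinators", "density", 0.0, 20.0),
    "B_m": ("flowers", "buds_male", 0.0, 5_000_000.0),
    "B_f": ("flowers", "buds_female", 0.0, 5_000_000.0),
    "t_m": ("flowers", "peak_male", 0.0, 30.0),
    "t_f": ("flowers", "peak_female", 0.0, 30.0),
    "sigma_m": ("flowers", "spread_male", 0.1, 10.0),
    "sigma_f": ("flowers", "spread_female", 0.1, 10.0),
    "tau_m": ("flowers", "lifespan_male", 1.0, 10.0),
    "tau_f": ("flowers", "lifespan_female", 1.0, 10.0),
    "p1": ("fruitset", "p1", 0.0, 1.0),
    "p2": ("fruitset", "p2", 0.0, 1.0),
    "p3": ("fruitset", "p3", 0.0, 1.0),
}

_CONTROL_KEYS = {"horizon", "grid_step", "rtol", "atol", "rho_basis",
                 "cohort_convention", "n_pollinators", "beta_seconds",
                 "seed"}


def load_config(source: str | Path | dict | None = None,
                allow_out_of_range: bool = False,
                **overrides: float) -> Scenario:
    """Build a validated Scenario from a YAML file, dict and/or overrides.

    ``beta_seconds`` is accepted as a convenience alternative to ``beta``
    (converted with the 4 h foraging day; both values are logged).  Any
    key deviating from the base value is logged at INFO level.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            doc = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    elif isinstance(source, dict):
        doc = dict(source)
    elif source is None:
        doc = {}
    else:
        raise ConfigError(f"unsupported config source: {type(source)!r}")
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    doc.update(overrides)

    unknown = set(doc) - set(_PARAM_KEYS) - _CONTROL_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "beta_seconds" in doc:
        if "beta" in doc:
            raise ConfigError("give beta or beta_seconds, not both")
        secs = float(doc.pop("beta_seconds"))
        doc["beta"] = secs / SECONDS_PER_FORAGING_DAY
        log.info("beta_seconds=%g s -> beta=%g days", secs, doc["beta"])
    doc.pop("seed", None)   # recorded by callers that use randomness

    groups: dict[str, dict[str, float]] = {}
    for key, raw in list(doc.items()):
        if key not in _PARAM_KEYS:
            continue
        group, fld, lo, hi = _PARAM_KEYS[key]
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{key}: not a number ({raw!r})") from exc
        if not np.isfinite(value):
            raise ConfigError(f"{key}: non-finite value")
        if not allow_out_of_range and not lo <= value <= hi:
            raise ConfigError(
                f"{key}={value} outside plausible range [{lo}, {hi}] "
                "(pass allow_out_of_range to accept)")
        groups.setdefault(group, {})[fld] = value
        doc.pop(key)

    base = Scenario()
    try:
        flowers = replace(base.flowers, **groups.get("flowers", {}))
        pollinators = replace(base.pollinators, **groups.get("pollinators", {}))
        fruitset = replace(base.fruitset, **groups.get("fruitset", {}))
        controls = {k: doc[k] for k in doc}
        scenario = replace(base, flowers=flowers, pollinators=pollinators,
                           fruitset=fruitset, **controls)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc

    for group, fields in groups.items():
        defaults = getattr(base, group)
        for fld, value in fields.items():
            if value != getattr(defaults, fld):
                log.info("config: %s.%s = %g (base %g)", group, fld, value,
                         getattr(defaults, fld))
    return scenario


def scenario_to_dict(scenario: Scenario) -> dict:
    """Flat config-dialect dict (inverse of :func:`load_config`)."""
    out: dict[str, float | str | None] = {}
    for key, (group, fld, _, _) in _PARAM_KEYS.items():
        out[key] = getattr(getattr(scenario, group), fld)
    out.update({
        "horizon": scenario.horizon,
        "grid_step": scenario.grid_step,
        "rtol": scenario.rtol,
        "atol": scenario.atol,
        "rho_basis": scenario.rho_basis,
        "cohort_convention": scenario.cohort_convention,
        "n_pollinators": scenario.n_pollinators,
    })
    return out


def dump_config(scenario: Scenario, path: str | Path | None = None) -> str:
    """Serialize a Scenario to YAML; round-trips through load_config."""
    text = yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


FIXTURE_NAMES = ("baseline", "fig5", "fig6", "fig7", "fig8a", "fig8b", "fig9")


def fixtures(name: str):
    """Canonical study scenarios and sweep grids.

    ``baseline``
        The base 1 ha orchard (Scenario).
    ``fig5``
        Composition sweep: female fraction 0.05-0.95 (step 0.05) of a
        fixed 1.2 M bud total.
    ``fig6``
        Male peak day 3-9 with the female peak fixed at day 6.
    ``fig7``
        Stocking density 1-20 bees per 1000 female buds.
    ``fig8a``
        Both preference exponents 0-1, step 0.02.
    ``fig8b``
        Handling time 5-120 s, step 5 s.
    ``fig9``
        The (female fraction x density) grids for the yield surface.
    """
    base = Scenario()
    if name == "baseline":
        return base
    if name == "fig5":
        return SweepSpec(
            "female_fraction", np.round(np.arange(0.05, 0.951, 0.05), 10),
            lambda x: _female_fraction_scenario(base, 1_200_000.0, x,
                                                "reference"))
    if name == "fig6":
        return SweepSpec(
            "male_peak", np.arange(3.0, 10.0),
            lambda x: replace(base,
                              flowers=replace(base.flowers, peak_male=x)))
    if name == "fig7":
        return SweepSpec(
            "bee_density", np.arange(1.0, 21.0),
            lambda x: replace(base, pollinators=replace(base.pollinators,
                                                        density=x)))
    if name == "fig8a":
        return SweepSpec(
            "preference", np.round(np.arange(0.0, 1.001, 0.02), 10),
            lambda x: replace(base, pollinators=replace(
                base.pollinators, pref_male=x, pref_female=x)))
    if name == "fig8b":
        return SweepSpec(
            "handling_seconds", np.arange(5.0, 121.0, 5.0),
            lambda x: replace(base, pollinators=replace(
                base.pollinators,
                handling_time=x / SECONDS_PER_FORAGING_DAY)))
    if name == "fig9":
        return (np.round(np.arange(0.05, 0.951, 0.05), 10),
                np.arange(1.0, 21.0))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def write_summary_json(summary: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default)
                          + "\n")
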