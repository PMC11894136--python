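"""Scenario projection of future emissions under lake expansion and
ice-phenology change.

The projection model is deliberately simple and explicit: regional
emissions scale linearly with the thermokarst-lake area of each vegetation
class (flux density held at its baseline value), and optionally with the
period durations.  Two modes:

``static_ice``
    Each per-class component scales with ``area(year)/area(baseline)``.

``dynamic_ice``
    Additionally, ice-free components scale with
    ``n_ice_free(year)/n_ice_free(baseline)`` and ice-melting components
    with ``n_ice_covered(year)/n_ice_covered(baseline)``; the ice-covered
    duration follows a linear trend (default -0.2 d/yr, the observed
    plateau lake-ice decline) and every day lost from ice cover is added
    to the open-water season.

Relative uncertainty of the baseline components is carried through
multiplicatively.  Area trajectories are inputs (e.g. from a lake
susceptibility model); this module does not produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import PeriodCalendar

__all__ = ["ScenarioConfig", "EmissionTrajectory", "project_emissions", "percent_change"]


@dataclass
class ScenarioConfig:
    """One emission-projection scenario.

    ``baseline_components``: DataFrame indexed by vegetation class with
    columns ``ice_free`` and ``ice_melting`` (Gg C yr^-1), optionally
    ``ice_free_sd`` / ``ice_melting_sd``.
    ``area_by_year``: DataFrame indexed by year, one column per vegetation
    class, areas in km^2; must include ``baseline_year``.
    """

    label: str
    baseline_year: int
    baseline_components: pd.DataFrame
    area_by_year: pd.DataFrame
    calendar: PeriodCalendar = field(default_factory=PeriodCalendar)
    ice_covered_trend: float = -0.2  # days per year
    mode: str = "static_ice"

    def __post_init__(self) -> None:
        if self.mode not in ("static_ice", "dynamic_ice"):
            raise ValueError("mode must be 'static_ice' or 'dynamic_ice'")
        if abs(self.ice_covered_trend) >= 2:
            raise ValueError("implausible ice-covered trend (|trend| >= 2 d/yr)")
        missing = set(self.baseline_components.index) - set(self.area_by_year.columns)
        if missing:
            raise ValueError(f"area trajectory missing vegetation classes: {sorted(missing)}")
        if self.baseline_year not in self.area_by_year.index:
            raise ValueError("area trajectory must include the baseline year")
        if (self.area_by_year.to_numpy(float) < 0).any():
            raise ValueError("areas must be >= 0")


@dataclass
class EmissionTrajectory:
    """Projected per-year emissions (Gg C yr^-1) with uncertainty.

    ``table`` columns: ice_free, ice_melting, annual (+ _sd columns when
    baseline uncertainties were given), indexed by year.  Annual additivity
    (annual = ice_free + ice_melting) holds every year by construction.
    """

    label: str
    mode: str
    table: pd.DataFrame


def _duration_factors(cfg: ScenarioConfig, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ice_free_factor, ice_melting_factor) per year for dynamic_ice."""
    cal = cfg.calendar
    dt = years - cfg.baseline_year
    n_cov = np.maximum(cal.n_ice_covered + cfg.ice_covered_trend * dt, 0.0)
    n_free = cal.n_ice_free + (cal.n_ice_covered - n_cov)
    return n_free / cal.n_ice_free, n_cov / cal.n_ice_covered


def project_emissions(cfg: ScenarioConfig) -> EmissionTrajectory:
    """Project the baseline budget along the scenario's area trajectory."""
    years = np.asarray(sorted(cfg.area_by_year.index), dtype=int)
    base_area = cfg.area_by_year.loc[cfg.baseline_year]
    classes = list(cfg.baseline_components.index)
    for veg in classes:
        if base_area[veg] <= 0:
            raise ValueError(f"baseline area for class {veg!r} must be > 0")

    if cfg.mode == "dynamic_ice":
        free_fac, melt_fac = _duration_factors(cfg, years)
    else:
        free_fac = melt_fac = np.ones_like(years, dtype=float)

    has_sd = {"ice_free_sd", "ice_melting_sd"} <= set(cfg.baseline_components.columns)

    rows = []
    for i, year in enumerate(years):
        ratio = cfg.area_by_year.loc[year, classes] / base_area[classes]
        ice_free = float((cfg.baseline_components["ice_free"] * ratio).sum()) * free_fac[i]
        ice_melt = float((cfg.baseline_components["ice_melting"] * ratio).sum()) * melt_fac[i]
        row = {
            "year": int(year),
            "ice_free": ice_free,
            "ice_melting": ice_melt,
            "annual": ice_free + ice_melt,
        }
        if has_sd:
            # relative uncertainty carried through multiplicatively,
            # class contributions combined in quadrature
            free_var = float(((cfg.baseline_components["ice_free_sd"] * ratio) ** 2).sum())
            melt_var = float(((cfg.baseline_components["ice_melting_sd"] * ratio) ** 2).sum())
            row["ice_free_sd"] = np.sqrt(free_var) * free_fac[i]
            row["ice_melting_sd"] = np.sqrt(melt_var) * melt_fac[i]
            row["annual_sd"] = float(np.hypot(row["ice_free_sd"], row["ice_melting_sd"]))
        rows.append(row)

    table = pd.DataFrame(rows).set_index("year")
    return EmissionTrajectory(label=cfg.label, mode=cfg.mode, table=table)


def percent_change(value_t, value_0):
    """Percent change of ``value_t`` relative to a positive baseline."""
    v0 = np.asarray(value_0, dtype=float)
    if np.any(v0 <= 0):
        raise ValueError("baseline value must be > 0")
    out = 100.0 * (np.asarray(value_t, dtype=float) - v0) / v0
    return float(out) if out.ndim == 0 else out
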