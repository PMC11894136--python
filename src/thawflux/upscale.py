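"""Monte-Carlo regional upscaling of lake fluxes and CO2-equivalent
conversion.

Per vegetation class, one lake's component fluxes (g CH4 m^-2 yr^-1) are
drawn with replacement per iteration and multiplied by the total
thermokarst-lake area of that class; emissions are reported in Gg C yr^-1
(mass of carbon, hence the 12/16.04 conversion).  Sampling is
lake-coherent: one lake index is drawn per class and iteration and all four
components come from that lake, so the per-iteration annual total is
exactly the sum of its components.

Uncertainty is reported two ways: the standard deviation of the iteration
totals (the Monte-Carlo spread, the primary figure), and a standard error
of the flux pool (SD of lake fluxes / sqrt(number of lakes)) propagated
through the area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import VEGETATION_CLASSES

__all__ = [
    "GwpConfig",
    "RegionalEstimate",
    "monte_carlo_upscale",
    "aggregate_components",
    "co2_equivalent",
    "FLUX_COMPONENTS",
]

#: Component columns expected in the lake-flux table, in budget order.
FLUX_COMPONENTS = ("f_diffusion", "f_ebullition", "f_water_storage", "f_ice_bubble")

_G_CH4_TO_GG_C = 12.0 / 16.04 / 1.0e9  # g CH4 -> Gg C
_KM2_TO_M2 = 1.0e6


@dataclass(frozen=True)
class GwpConfig:
    """CO2-equivalence of methane: GWP100 on a mass-of-CH4 basis.

    Emissions here are carbon masses, so the conversion is
    ``Gg C * (16.04/12) * gwp100``.  Default GWP100 = 27 (fossil-free CH4,
    current assessment-report value); 27.2 and 28 are common alternatives.
    """

    gwp100: float = 27.0
    mass_ratio: float = 16.04 / 12.0

    def __post_init__(self) -> None:
        if self.gwp100 <= 0 or self.mass_ratio <= 0:
            raise ValueError("gwp100 and mass_ratio must be > 0")


@dataclass
class RegionalEstimate:
    """Regional emission estimate by vegetation class and flux component.

    ``per_class``: DataFrame indexed by vegetation with one mean/sd/se
    column triple per component plus the class total (all Gg C yr^-1).
    ``proportions``: share of the grand total per class and per component.
    """

    per_class: pd.DataFrame
    total_mean: float
    total_sd: float
    total_se: float
    proportions_by_class: dict[str, float]
    proportions_by_component: dict[str, float]
    co2_eq_mean: float
    co2_eq_sd: float
    n_iterations: int
    seed: int | None
    metadata: dict = field(default_factory=dict)


def monte_carlo_upscale(
    lake_fluxes: pd.DataFrame,
    areas_km2: Mapping[str, float],
    n_iter: int = 1000,
    seed: int | None = None,
    gwp: GwpConfig = GwpConfig(),
) -> RegionalEstimate:
    """Upscale per-lake flux components to regional emissions (Gg C yr^-1).

    Parameters
    ----------
    lake_fluxes
        One row per lake with ``vegetation`` and the ``FLUX_COMPONENTS``
        columns in g CH4 m^-2 yr^-1.
    areas_km2
        Total thermokarst-lake area per vegetation class (km^2).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be > 0")
    rng = np.random.default_rng(seed)
    classes = [v for v in VEGETATION_CLASSES if v in areas_km2]
    missing = set(areas_km2) - set(VEGETATION_CLASSES)
    if missing:
        raise ValueError(f"unknown vegetation classes in area table: {sorted(missing)}")

    comp_list = list(FLUX_COMPONENTS)
    per_class_rows = []
    # iteration-level totals per class, Gg C: (n_iter, n_class, n_comp)
    class_samples = {}
    pool_sizes = {}
    for veg in classes:
        pool = lake_fluxes.loc[lake_fluxes["vegetation"] == veg, comp_list].to_numpy(float)
        if pool.size == 0:
            raise ValueError(f"empty flux pool for vegetation class {veg!r}")
        pool_sizes[veg] = len(pool)
        area_m2 = float(areas_km2[veg]) * _KM2_TO_M2
        idx = rng.integers(0, len(pool), size=n_iter)
        draws = pool[idx]  # (n_iter, n_comp), g CH4 m^-2 yr^-1
        class_samples[veg] = draws * area_m2 * _G_CH4_TO_GG_C

    for veg in classes:
        samples = class_samples[veg]
        pool = lake_fluxes.loc[lake_fluxes["vegetation"] == veg, comp_list].to_numpy(float)
        area_m2 = float(areas_km2[veg]) * _KM2_TO_M2
        row = {"vegetation": veg}
        for j, comp in enumerate(comp_list):
            row[f"{comp}_mean"] = samples[:, j].mean()
            row[f"{comp}_sd"] = samples[:, j].std(ddof=1) if n_iter > 1 else 0.0
            row[f"{comp}_se"] = (
                pool[:, j].std(ddof=1) / np.sqrt(len(pool)) * area_m2 * _G_CH4_TO_GG_C
                if len(pool) > 1
                else 0.0
            )
        totals = samples.sum(axis=1)
        row["total_mean"] = totals.mean()
        row["total_sd"] = totals.std(ddof=1) if n_iter > 1 else 0.0
        annual_pool = pool.sum(axis=1)
        row["total_se"] = (
            annual_pool.std(ddof=1) / np.sqrt(len(pool)) * area_m2 * _G_CH4_TO_GG_C
            if len(pool) > 1
            else 0.0
        )
        per_class_rows.append(row)

    per_class = pd.DataFrame(per_class_rows).set_index("vegetation")

    grand_samples = np.sum([class_samples[v].sum(axis=1) for v in classes], axis=0)
    total_mean = float(grand_samples.mean())
    total_sd = float(grand_samples.std(ddof=1)) if n_iter > 1 else 0.0
    total_se = float(np.sqrt(np.sum(per_class["total_se"] ** 2)))

    props_class = {v: float(per_class.loc[v, "total_mean"] / total_mean) for v in classes}
    props_comp = {
        comp: float(per_class[f"{comp}_mean"].sum() / total_mean) for comp in comp_list
    }

    co2_mean = co2_equivalent(total_mean, gwp)
    co2_sd = co2_equivalent(total_sd, gwp)

    return RegionalEstimate(
        per_class=per_class,
        total_mean=total_mean,
        total_sd=total_sd,
        total_se=total_se,
        proportions_by_class=props_class,
        proportions_by_component=props_comp,
        co2_eq_mean=co2_mean,
        co2_eq_sd=co2_sd,
        n_iterations=n_iter,
        seed=seed,
        metadata={"pool_sizes": pool_sizes, "areas_km2": dict(areas_km2)},
    )


def aggregate_components(per_class_components: pd.DataFrame) -> dict:
    """Budget-table aggregation of a class-by-component emission table.

    ``per_class_components``: rows indexed by vegetation class, columns are
    flux components, values in Gg C yr^-1.  Returns row totals (per class),
    column totals (per component), the grand total, and the proportion of
    the grand total per class and per component.
    """
    table = per_class_components.astype(float)
    if (table.to_numpy() < 0).any():
        raise ValueError("component emissions must be >= 0")
    row_totals = table.sum(axis=1)
    col_totals = table.sum(axis=0)
    grand = float(table.to_numpy().sum())
    if grand > 0:
        class_props = (row_totals / grand).to_dict()
        comp_props = (col_totals / grand).to_dict()
    else:
        class_props = {k: 0.0 for k in row_totals.index}
        comp_props = {k: 0.0 for k in col_totals.index}
    return {
        "row_totals": row_totals.to_dict(),
        "column_totals": col_totals.to_dict(),
        "grand_total": grand,
        "proportions_by_class": class_props,
        "proportions_by_component": comp_props,
    }


def co2_equivalent(total_gg_c, cfg: GwpConfig = GwpConfig()):
    """Convert a carbon-mass CH4 emission (Gg C) to Gg CO2-equivalent."""
    total = np.asarray(total_gg_c, dtype=float)
    if np.any(total < 0):
        raise ValueError("emission must be >= 0")
    out = total * cfg.mass_ratio * cfg.gwp100
    return float(out) if out.ndim == 0 else out
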