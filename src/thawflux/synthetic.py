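"""Synthetic survey generator with the statistical structure the budget
pipeline assumes.

The generator emulates a plateau-wide point survey of thermokarst lakes:

* right-skewed (lognormal) dissolved CH4 concentrations spanning several
  orders of magnitude, with the ice-covered pooled median (2.61 umol/L)
  well above the ice-free one (0.88 umol/L);
* a vegetation gradient of concentration medians
  ASM > AM > AS > AD (swamp meadow wettest, desert driest), with class
  medians placed geometrically symmetric around the pooled median so equal
  class sizes reproduce the pooled median by construction;
* positive cross-period correlation of lake levels on the log scale
  (lakes that are CH4-rich under ice are CH4-rich in open water);
* lake areas 373-648,966 m^2, log-uniform, so most lakes are small;
* carbon isotope pairs whose delta-13C-CH4 centres near -57.9 permil and
  whose implied fractionation factor straddles the 1.040/1.055 pathway
  thresholds;
* meteorological forcing (wind at 2 m, water and air temperature,
  ~0.6 atm plateau pressure).

Concentrations are generated as in-situ dissolved values and then inverted
through the headspace mass balance into syringe measurements, so reading
the written survey through the full concentration pipeline recovers the
generated values to machine precision.

``generate_known_truth`` produces degenerate (constant-concentration)
surveys whose implied regional budget is computable in closed form; it is
the parameter-recovery harness for the end-to-end pipeline.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import gas_transfer, headspace, icefree, icemelt
from .headspace import GasConstants, MOLAR_VOLUME_STP, bunsen_solubility
from .survey import LAKE_COLUMNS, SURVEY_COLUMNS, ObservationSet, PeriodCalendar, Period, VEGETATION_CLASSES
from .upscale import _G_CH4_TO_GG_C, _KM2_TO_M2

__all__ = ["SurveyConfig", "generate_survey", "generate_known_truth", "default_area_table"]


def default_area_table() -> dict[str, float]:
    """Per-class thermokarst-lake areas (km^2) summing to the plateau-wide
    2825 km^2 inventory, split with the meadow class dominant."""
    return {"ASM": 180.0, "AM": 2200.0, "AS": 350.0, "AD": 95.0}


def _class_multipliers() -> dict[str, float]:
    # Geometric symmetry around 1: pooled median of an equal-count mixture
    # of equal-spread lognormals equals the central median exactly.
    return {"ASM": 4.0, "AM": 1.8, "AS": 1.0 / 1.8, "AD": 1.0 / 4.0}


@dataclass
class SurveyConfig:
    """Parameters of the synthetic field campaign (defaults = the study
    conditions the pipeline is meant for)."""

    n_lakes_per_class: int = 50
    points_per_lake: tuple[int, int] = (3, 6)
    median_ice_covered: float = 2.61  # umol/L, pooled
    median_ice_free: float = 0.88  # umol/L, pooled
    class_multipliers: Mapping[str, float] = field(default_factory=_class_multipliers)
    # Within-class point-level spread (ln units), derived from the printed
    # pooled concentration ranges (0.03-280 umol/L over n=151 under ice,
    # 0.01-40 over n=353 open water) minus the between-class median spread.
    log_sd_ice_covered: float = 1.5
    log_sd_ice_free: float = 1.05
    point_log_sd: float = 0.3  # within-lake replicate spread
    cross_period_corr: float = 0.6  # lake levels, log scale
    endmelt_ratio: float = 0.35  # median end-melt / end-ice-covered conc
    endmelt_log_sd: float = 0.25
    endmelt_observed_frac: float = 0.6
    d13c_ch4_mean: float = -57.9
    d13c_ch4_sd: float = 8.0
    alpha_c_mean: float = 1.045
    alpha_c_sd: float = 0.012
    wind_median: float = 3.0  # m/s at 2 m
    wind_log_sd: float = 0.4
    wind_height_m: float = 2.0
    p_atm_mean: float = 0.60  # ~4500 m elevation
    p_atm_sd: float = 0.01
    v_w_l: float = 0.4
    v_h_l: float = 0.1
    area_range_m2: tuple[float, float] = (373.0, 648966.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lakes_per_class <= 0:
            raise ValueError("need at least one lake per class")
        lo, hi = self.points_per_lake
        if not (3 <= lo <= hi <= 6):
            raise ValueError("points per lake must lie in 3..6")
        if not -1 < self.cross_period_corr < 1:
            raise ValueError("correlation must be in (-1, 1)")
        if self.median_ice_covered <= 0 or self.median_ice_free <= 0:
            raise ValueError("medians must be positive")


# water temperatures (deg C) and air temperatures (K) per period
_T_WATER_RANGE = {
    Period.ICE_COVERED: (0.5, 3.0),
    Period.END_MELTING: (2.0, 6.0),
    Period.ICE_FREE: (5.0, 15.0),
}
_T_AIR_MEAN_SD = {
    Period.ICE_COVERED: (268.0, 4.0),
    Period.END_MELTING: (275.0, 3.0),
    Period.ICE_FREE: (283.0, 4.0),
}


def _headspace_ppm_for(c_w, t_air_k, t_water_c, p_atm, v_h, v_w, constants: GasConstants):
    """Invert the headspace mass balance: the syringe mixing ratio (ppm)
    that yields dissolved concentration ``c_w`` (umol/L)."""
    beta = bunsen_solubility(t_water_c)
    # c_w = P_m * 1e6 * (V_h/(R T_air V_w) + beta/V_stp)
    denom = v_h / (constants.R * t_air_k * v_w) + np.asarray(beta) / MOLAR_VOLUME_STP
    p_m = np.asarray(c_w) * 1.0e-6 / denom
    return p_m / (np.asarray(p_atm) * 1.0e-6)


def _sample_date(rng: np.random.Generator, period: Period) -> _dt.date:
    if period is Period.ICE_COVERED:
        start, span = _dt.date(2023, 3, 1), 55
    elif period is Period.END_MELTING:
        start, span = _dt.date(2023, 5, 1), 9
    else:
        start, span = _dt.date(2022, 6, 1), 120
    return start + _dt.timedelta(days=int(rng.integers(0, span)))


def _met_for(rng: np.random.Generator, period: Period, n: int, cfg: SurveyConfig):
    lo, hi = _T_WATER_RANGE[period]
    t_water = rng.uniform(lo, hi, size=n)
    mu, sd = _T_AIR_MEAN_SD[period]
    t_air = rng.normal(mu, sd, size=n)
    wind = cfg.wind_median * np.exp(rng.normal(0.0, cfg.wind_log_sd, size=n))
    p_atm = np.clip(rng.normal(cfg.p_atm_mean, cfg.p_atm_sd, size=n), 0.5, 0.7)
    return t_water, t_air, wind, p_atm


def generate_survey(
    cfg: SurveyConfig | None = None,
    constants: GasConstants = GasConstants(),
) -> ObservationSet:
    """Generate a reproducible synthetic survey (seeded from ``cfg.seed``)."""
    cfg = cfg or SurveyConfig()
    rng = np.random.default_rng(cfg.seed)

    lake_sd_cov = np.sqrt(max(cfg.log_sd_ice_covered**2 - cfg.point_log_sd**2, 1e-12))
    lake_sd_free = np.sqrt(max(cfg.log_sd_ice_free**2 - cfg.point_log_sd**2, 1e-12))
    cov = np.array(
        [
            [lake_sd_cov**2, cfg.cross_period_corr * lake_sd_cov * lake_sd_free],
            [cfg.cross_period_corr * lake_sd_cov * lake_sd_free, lake_sd_free**2],
        ]
    )

    lake_rows, point_rows = [], []
    lo_a, hi_a = cfg.area_range_m2
    for veg in VEGETATION_CLASSES:
        mult = cfg.class_multipliers[veg]
        mu = np.log([cfg.median_ice_covered * mult, cfg.median_ice_free * mult])
        for i in range(cfg.n_lakes_per_class):
            lake_id = f"{veg}-{i + 1:03d}"
            area = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a)))
            lake_rows.append(
                {
                    "lake_id": lake_id,
                    "vegetation": veg,
                    "area_m2": float(area),
                    "elevation_m": float(rng.uniform(4210, 5127)),
                }
            )
            level_cov, level_free = np.exp(rng.multivariate_normal(mu, cov))
            level_melt = (
                cfg.endmelt_ratio
                * level_cov
                * np.exp(rng.normal(0.0, cfg.endmelt_log_sd))
            )
            has_endmelt = rng.random() < cfg.endmelt_observed_frac
            periods = [
                (Period.ICE_COVERED, level_cov, True),
                (Period.ICE_FREE, level_free, False),
            ]
            if has_endmelt:
                periods.append((Period.END_MELTING, level_melt, False))
            for period, level, with_iso in periods:
                n_pts = int(rng.integers(cfg.points_per_lake[0], cfg.points_per_lake[1] + 1))
                c_w = level * np.exp(rng.normal(0.0, cfg.point_log_sd, size=n_pts))
                t_water, t_air, wind, p_atm = _met_for(rng, period, n_pts, cfg)
                ppm = _headspace_ppm_for(
                    c_w, t_air, t_water, p_atm, cfg.v_h_l, cfg.v_w_l, constants
                )
                date = _sample_date(rng, period)
                if with_iso:
                    d_ch4 = np.clip(
                        rng.normal(cfg.d13c_ch4_mean, cfg.d13c_ch4_sd, size=n_pts), -95.0, -25.0
                    )
                    alpha = np.clip(
                        rng.normal(cfg.alpha_c_mean, cfg.alpha_c_sd, size=n_pts), 1.0, 1.10
                    )
                    d_co2 = alpha * (d_ch4 + 1000.0) - 1000.0
                else:
                    d_ch4 = d_co2 = np.full(n_pts, np.nan)
                for j in range(n_pts):
                    point_rows.append(
                        {
                            "lake_id": lake_id,
                            "vegetation": veg,
                            "date": date,
                            "period": period.value,
                            "headspace_ch4_ppm": float(ppm[j]),
                            "v_h_l": cfg.v_h_l,
                            "v_w_l": cfg.v_w_l,
                            "t_air_k": float(t_air[j]),
                            "t_water_c": float(t_water[j]),
                            "p_atm": float(p_atm[j]),
                            "wind_speed_ms": float(wind[j]),
                            "wind_height_m": cfg.wind_height_m,
                            "d13c_ch4": float(d_ch4[j]) if np.isfinite(d_ch4[j]) else np.nan,
                            "d13c_co2": float(d_co2[j]) if np.isfinite(d_co2[j]) else np.nan,
                        }
                    )

    points = pd.DataFrame(point_rows, columns=list(SURVEY_COLUMNS))
    lakes = pd.DataFrame(lake_rows, columns=list(LAKE_COLUMNS))
    return ObservationSet(
        points=points, lakes=lakes, metadata={"generator": "synthetic", "seed": cfg.seed}
    )


# ---------------------------------------------------------------------------
# known-truth harness


def generate_known_truth(
    concentrations: Mapping[str, Mapping[str, float]] | None = None,
    areas_km2: Mapping[str, float] | None = None,
    n_lakes_per_class: int = 10,
    noise_log_sd: float = 0.0,
    seed: int = 0,
    calendar: PeriodCalendar | None = None,
    partition: icemelt.StoragePartitionParams | None = None,
    transfer: gas_transfer.GasTransferParams | None = None,
    constants: GasConstants = GasConstants(),
) -> tuple[ObservationSet, dict]:
    """Survey with an analytically known regional budget.

    Concentrations and met forcing are constant per class (met: 1.5 degC /
    270 K / 2 m/s / 0.6 atm under ice; 10 degC / 283 K / 3 m/s open water),
    so the per-class flux densities follow from the closed-form flux
    equations and the regional truth is ``sum_class density * area``.
    Multiplicative lognormal noise with mean 1 (``noise_log_sd`` > 0)
    perturbs point concentrations without biasing their expectation.

    Returns the survey and a truth record with per-class component flux
    densities (g CH4 m^-2 yr^-1) and regional emissions (Gg C yr^-1).
    """
    calendar = calendar or PeriodCalendar()
    partition = partition or icemelt.StoragePartitionParams()
    transfer = transfer or gas_transfer.GasTransferParams()
    areas_km2 = dict(areas_km2 or default_area_table())
    if concentrations is None:
        mult = _class_multipliers()
        concentrations = {
            veg: {
                "ice_covered": 2.61 * mult[veg],
                "ice_free": 0.88 * mult[veg],
                "end_melting": 0.35 * 2.61 * mult[veg],
            }
            for veg in VEGETATION_CLASSES
        }
    rng = np.random.default_rng(seed)

    met = {
        Period.ICE_COVERED: dict(t_water=1.5, t_air=270.0, wind=2.0, p_atm=0.6),
        Period.END_MELTING: dict(t_water=3.0, t_air=274.0, wind=2.0, p_atm=0.6),
        Period.ICE_FREE: dict(t_water=10.0, t_air=283.0, wind=3.0, p_atm=0.6),
    }
    v_h, v_w, z = 0.1, 0.4, 2.0

    lake_rows, point_rows = [], []
    truth_classes = {}
    total_gg = 0.0
    components_gg = {c: 0.0 for c in ("f_diffusion", "f_ebullition", "f_water_storage", "f_ice_bubble")}
    for veg, conc in concentrations.items():
        # closed-form per-class flux density
        m_eb = partition.m_for(veg)
        k = {
            p: gas_transfer.transfer_velocity_from_met(met[p]["t_water"], met[p]["wind"], z, transfer).k
            for p in met
        }
        c_eq = {
            p: headspace.equilibrium_concentration(met[p]["t_water"], met[p]["p_atm"], constants=constants)
            for p in met
        }
        f_diff = icefree.diffusion_flux(
            k[Period.ICE_FREE], conc["ice_free"], c_eq[Period.ICE_FREE], calendar.n_ice_free
        )
        f_eb = icefree.ebullition_flux(f_diff, m_eb)
        f_ws = icemelt.water_storage_flux(
            k[Period.ICE_COVERED],
            k[Period.END_MELTING],
            conc["ice_covered"],
            conc["end_melting"],
            c_eq[Period.ICE_COVERED],
            c_eq[Period.END_MELTING],
            calendar.melt_window_high,
            calendar.melt_window_low,
        )
        f_ib = icemelt.bubble_partition_factor(m_eb, partition) * f_ws
        density = dict(
            f_diffusion=f_diff, f_ebullition=f_eb, f_water_storage=f_ws, f_ice_bubble=f_ib
        )
        area_gg = areas_km2[veg] * _KM2_TO_M2 * _G_CH4_TO_GG_C
        class_total = sum(density.values()) * area_gg
        truth_classes[veg] = {
            "density": density,
            "emission_gg_c": {c: v * area_gg for c, v in density.items()},
            "total_gg_c": class_total,
        }
        total_gg += class_total
        for c, v in density.items():
            components_gg[c] += v * area_gg

        # survey points: constant concentration (times unbiased noise)
        area_m2 = areas_km2[veg] * _KM2_TO_M2 / n_lakes_per_class  # equal lakes
        for i in range(n_lakes_per_class):
            lake_id = f"{veg}-T{i + 1:02d}"
            lake_rows.append(
                {"lake_id": lake_id, "vegetation": veg, "area_m2": area_m2, "elevation_m": 4500.0}
            )
            for period, key in (
                (Period.ICE_COVERED, "ice_covered"),
                (Period.ICE_FREE, "ice_free"),
                (Period.END_MELTING, "end_melting"),
            ):
                m = met[period]
                for _ in range(3):
                    noise = (
                        np.exp(rng.normal(0.0, noise_log_sd) - noise_log_sd**2 / 2.0)
                        if noise_log_sd > 0
                        else 1.0
                    )
                    c_w = conc[key] * noise
                    ppm = _headspace_ppm_for(
                        c_w, m["t_air"], m["t_water"], m["p_atm"], v_h, v_w, constants
                    )
                    point_rows.append(
                        {
                            "lake_id": lake_id,
                            "vegetation": veg,
                            "date": _sample_date(rng, period),
                            "period": period.value,
                            "headspace_ch4_ppm": float(ppm),
                            "v_h_l": v_h,
                            "v_w_l": v_w,
                            "t_air_k": m["t_air"],
                            "t_water_c": m["t_water"],
                            "p_atm": m["p_atm"],
                            "wind_speed_ms": m["wind"],
                            "wind_height_m": z,
                            "d13c_ch4": np.nan,
                            "d13c_co2": np.nan,
                        }
                    )

    obs = ObservationSet(
        points=pd.DataFrame(point_rows, columns=list(SURVEY_COLUMNS)),
        lakes=pd.DataFrame(lake_rows, columns=list(LAKE_COLUMNS)),
        metadata={"generator": "known-truth", "seed": seed, "noise_log_sd": noise_log_sd},
    )
    truth = {
        "per_class": truth_classes,
        "components_gg_c": components_gg,
        "total_gg_c": total_gg,
        "areas_km2": areas_km2,
    }
    return obs, truth
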