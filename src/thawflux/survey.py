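"""Survey input/output and the shared domain vocabulary.

The field campaign this package models is a point survey of thermokarst
lakes: at each sampling point a headspace-equilibrated gas sample is taken
together with water temperature and meteorological forcing, and every lake
carries a vegetation-class label (alpine swamp meadow, meadow, steppe or
desert) and a surface area.  This module defines the validated in-memory
containers for those records and reads/writes them as plain UTF-8 CSV in
long format (one row per sampling point; the observation period is a
column, because the same lake is visited in several periods).

Missing optional fields (carbon isotopes, elevation) are empty cells, never
sentinel numbers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VEGETATION_CLASSES",
    "Period",
    "PointObservation",
    "LakeRecord",
    "ObservationSet",
    "ValidationIssue",
    "ValidationReport",
    "PeriodCalendar",
    "read_survey",
    "write_survey",
    "read_area_table",
    "write_area_table",
    "validate_periods",
]

#: The four vegetation classes of the alpine permafrost landscape, ordered
#: by decreasing sediment organic carbon (swamp meadow, meadow, steppe,
#: desert).
VEGETATION_CLASSES: tuple[str, ...] = ("ASM", "AM", "AS", "AD")


class Period(str, Enum):
    """Observation period of a sampling point."""

    ICE_COVERED = "ice_covered"
    ICE_FREE = "ice_free"
    END_MELTING = "end_melting"


#: Column order of the survey CSV.  Units are part of the schema:
#: volumes in litres, T_air in kelvin, T_water in deg C, pressure in atm,
#: wind speed in m/s at ``wind_height_m`` metres, isotopes in permil.
SURVEY_COLUMNS = (
    "lake_id",
    "vegetation",
    "date",
    "period",
    "headspace_ch4_ppm",
    "v_h_l",
    "v_w_l",
    "t_air_k",
    "t_water_c",
    "p_atm",
    "wind_speed_ms",
    "wind_height_m",
    "d13c_ch4",
    "d13c_co2",
)

LAKE_COLUMNS = ("lake_id", "vegetation", "area_m2", "elevation_m")

#: Plausibility window for lake areas (m^2); the observed lakes span
#: 373 to 648,966 m^2, the window is deliberately wider.
DEFAULT_AREA_WINDOW = (10.0, 1.0e7)


@dataclass(frozen=True)
class PointObservation:
    """One headspace sampling point.

    ``headspace_ch4_ppm`` is the CH4 mixing ratio measured in the syringe
    headspace after equilibration; the partial pressure entering the gas-law
    step is ``headspace_ch4_ppm * 1e-6 * p_atm``.
    """

    lake_id: str
    vegetation: str
    date: _dt.date
    period: Period
    headspace_ch4_ppm: float
    v_h_l: float
    v_w_l: float
    t_air_k: float
    t_water_c: float
    p_atm: float
    wind_speed_ms: float
    wind_height_m: float
    d13c_ch4: float | None = None
    d13c_co2: float | None = None


@dataclass(frozen=True)
class LakeRecord:
    lake_id: str
    vegetation: str
    area_m2: float
    elevation_m: float | None = None


@dataclass(frozen=True)
class ValidationIssue:
    row: int  # 1-based data-row number (header excluded)
    field: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    n_parsed: int = 0
    n_accepted: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_parsed - self.n_accepted

    def __bool__(self) -> bool:  # truthy when clean
        return not self.issues


@dataclass
class ObservationSet:
    """Validated survey: per-point observations plus per-lake records.

    Points and lakes are held as DataFrames (columns ``SURVEY_COLUMNS`` and
    ``LAKE_COLUMNS``); every ``lake_id`` in ``points`` must resolve to a row
    of ``lakes``.
    """

    points: pd.DataFrame
    lakes: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    report: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        missing = set(self.points["lake_id"]) - set(self.lakes["lake_id"])
        if missing:
            raise ValueError(f"observations reference unknown lakes: {sorted(missing)}")

    def lake_areas_m2(self) -> pd.Series:
        return self.lakes.set_index("lake_id")["area_m2"]

    def to_point_records(self) -> list[PointObservation]:
        out = []
        for row in self.points.itertuples(index=False):
            out.append(
                PointObservation(
                    lake_id=row.lake_id,
                    vegetation=row.vegetation,
                    date=row.date,
                    period=Period(row.period),
                    headspace_ch4_ppm=row.headspace_ch4_ppm,
                    v_h_l=row.v_h_l,
                    v_w_l=row.v_w_l,
                    t_air_k=row.t_air_k,
                    t_water_c=row.t_water_c,
                    p_atm=row.p_atm,
                    wind_speed_ms=row.wind_speed_ms,
                    wind_height_m=row.wind_height_m,
                    d13c_ch4=None if pd.isna(row.d13c_ch4) else row.d13c_ch4,
                    d13c_co2=None if pd.isna(row.d13c_co2) else row.d13c_co2,
                )
            )
        return out


@dataclass(frozen=True)
class PeriodCalendar:
    """Period durations and the month -> period mapping.

    Defaults: the ice-free season lasts 200 days (May-October) and the
    ice-covered season 146 days (about 40% of the year, November-April);
    the melt transition is modelled as a 14-day high-emission window at
    the end of ice cover plus a 14-day low-emission window at the start
    of the open-water season.
    """

    n_ice_free: float = 200.0
    n_ice_covered: float = 146.0
    melt_window_high: float = 14.0
    melt_window_low: float = 14.0
    ice_covered_months: frozenset[int] = frozenset({11, 12, 1, 2, 3, 4})
    ice_free_months: frozenset[int] = frozenset({5, 6, 7, 8, 9, 10})
    end_melting_months: frozenset[int] = frozenset({4, 5})

    def __post_init__(self) -> None:
        if self.n_ice_free <= 0 or self.n_ice_covered <= 0:
            raise ValueError("period durations must be positive")
        if self.n_ice_free + self.n_ice_covered > 366:
            raise ValueError("ice-free + ice-covered duration exceeds a year")
        if self.melt_window_high <= 0 or self.melt_window_low <= 0:
            raise ValueError("melt windows must be positive")

    def months_for(self, period: Period | str) -> frozenset[int]:
        period = Period(period)
        return {
            Period.ICE_COVERED: self.ice_covered_months,
            Period.ICE_FREE: self.ice_free_months,
            Period.END_MELTING: self.end_melting_months,
        }[period]


# ---------------------------------------------------------------------------
# row validation


def _check_point_row(row: pd.Series, area_window=DEFAULT_AREA_WINDOW) -> list[tuple[str, str]]:
    """Return (field, message) problems for one parsed survey row."""
    problems: list[tuple[str, str]] = []
    if row["vegetation"] not in VEGETATION_CLASSES:
        problems.append(("vegetation", f"unknown class {row['vegetation']!r}"))
    try:
        Period(row["period"])
    except ValueError:
        problems.append(("period", f"unknown period {row['period']!r}"))
    numeric_rules = [
        ("headspace_ch4_ppm", lambda v: v >= 0, "must be >= 0"),
        ("v_h_l", lambda v: v > 0, "must be > 0"),
        ("v_w_l", lambda v: v > 0, "must be > 0"),
        ("t_air_k", lambda v: v > 0, "must be > 0 K"),
        ("p_atm", lambda v: 0 < v <= 1.2, "must be in (0, 1.2] atm"),
        ("wind_speed_ms", lambda v: v >= 0, "must be >= 0"),
        ("wind_height_m", lambda v: v > 0, "must be > 0"),
        ("t_water_c", lambda v: -2.0 <= v <= 45.0, "implausible water temperature"),
    ]
    for name, ok, msg in numeric_rules:
        v = row[name]
        if pd.isna(v):
            problems.append((name, "missing value"))
        elif not ok(float(v)):
            problems.append((name, msg))
    for iso in ("d13c_ch4", "d13c_co2"):
        v = row[iso]
        if not pd.isna(v) and float(v) <= -1000.0:
            problems.append((iso, "delta value must exceed -1000 permil"))
    return problems


def read_survey(
    survey_path: str | Path,
    lakes_path: str | Path,
    *,
    on_invalid: str = "partial",
    area_window: tuple[float, float] = DEFAULT_AREA_WINDOW,
) -> ObservationSet:
    """Read and validate a survey CSV plus its lake-attribute CSV.

    Parameters
    ----------
    on_invalid
        ``"partial"`` keeps valid rows and records the rejected ones in the
        returned :class:`ValidationReport` (rows are reported with their
        1-based data-row number, never silently dropped); ``"strict"``
        raises on the first invalid row.
    """
    if on_invalid not in ("partial", "strict"):
        raise ValueError("on_invalid must be 'partial' or 'strict'")
    survey_path, lakes_path = Path(survey_path), Path(lakes_path)

    points = pd.read_csv(survey_path, dtype={"lake_id": str})
    missing_cols = set(SURVEY_COLUMNS) - set(points.columns)
    if missing_cols:
        raise ValueError(f"survey file missing mandatory columns: {sorted(missing_cols)}")
    points["date"] = pd.to_datetime(points["date"]).dt.date

    report = ValidationReport(n_parsed=len(points))
    keep = np.ones(len(points), dtype=bool)
    for i, (_, row) in enumerate(points.iterrows()):
        problems = _check_point_row(row)
        if problems:
            keep[i] = False
            for fld, msg in problems:
                report.issues.append(ValidationIssue(row=i + 1, field=fld, message=msg))
            if on_invalid == "strict":
                raise ValueError(
                    f"{survey_path.name} row {i + 1}: " + "; ".join(f"{f}: {m}" for f, m in problems)
                )
    points = points.loc[keep].reset_index(drop=True)
    report.n_accepted = len(points)

    lakes = pd.read_csv(lakes_path, dtype={"lake_id": str})
    missing_cols = {"lake_id", "vegetation", "area_m2"} - set(lakes.columns)
    if missing_cols:
        raise ValueError(f"lake file missing mandatory columns: {sorted(missing_cols)}")
    if "elevation_m" not in lakes.columns:
        lakes["elevation_m"] = np.nan
    lo, hi = area_window
    bad_area = ~lakes["area_m2"].between(lo, hi)
    if bad_area.any():
        bad = lakes.loc[bad_area, "lake_id"].tolist()
        raise ValueError(f"lake areas outside plausibility window {area_window}: {bad}")

    return ObservationSet(
        points=points,
        lakes=lakes,
        metadata={"survey_path": str(survey_path), "lakes_path": str(lakes_path)},
        report=report,
    )


def write_survey(obs: ObservationSet, survey_path: str | Path, lakes_path: str | Path) -> None:
    """Write an ObservationSet back to the two CSV files (inverse of read)."""
    obs.points.loc[:, list(SURVEY_COLUMNS)].to_csv(survey_path, index=False)
    obs.lakes.loc[:, list(LAKE_COLUMNS)].to_csv(lakes_path, index=False)


def read_area_table(path: str | Path) -> dict[str, float]:
    """Read the per-vegetation thermokarst-lake area table (km^2)."""
    df = pd.read_csv(path)
    missing = {"vegetation", "area_km2"} - set(df.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    table = dict(zip(df["vegetation"], df["area_km2"].astype(float)))
    absent = set(VEGETATION_CLASSES) - set(table)
    if absent:
        raise ValueError(f"area table missing vegetation classes: {sorted(absent)}")
    if any(v < 0 for v in table.values()):
        raise ValueError("areas must be >= 0")
    return {k: table[k] for k in VEGETATION_CLASSES}


def write_area_table(areas: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"vegetation": list(areas.keys()), "area_km2": list(areas.values())}
    ).to_csv(path, index=False)


def validate_periods(
    obs: ObservationSet, calendar: PeriodCalendar | None = None
) -> list[ValidationIssue]:
    """Flag observations whose calendar date contradicts their period label.

    Reporting only: an ice-covered sample dated July is flagged, nothing is
    dropped.
    """
    calendar = calendar or PeriodCalendar()
    issues: list[ValidationIssue] = []
    for i, row in enumerate(obs.points.itertuples(index=False)):
        month = row.date.month
        if month not in calendar.months_for(row.period):
            issues.append(
                ValidationIssue(
                    row=i + 1,
                    field="period",
                    message=(
                        f"lake {row.lake_id}: month {month} inconsistent with "
                        f"period {row.period!r}"
                    ),
                )
            )
    return issues
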