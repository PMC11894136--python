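import datetime as dt

import pandas as pd
import pytest

from thawflux.survey import LAKE_COLUMNS, SURVEY_COLUMNS, ObservationSet


def make_point(**overrides) -> dict:
    """A valid survey row with sensible plateau defaults."""
    row = {
        "lake_id": "L1",
        "vegetation": "AM",
        "date": dt.date(2023, 3, 20),
        "period": "ice_covered",
        "headspace_ch4_ppm": 500.0,
        "v_h_l": 0.1,
        "v_w_l": 0.4,
        "t_air_k": 270.0,
        "t_water_c": 1.5,
        "p_atm": 0.6,
        "wind_speed_ms": 2.5,
        "wind_height_m": 2.0,
        "d13c_ch4": None,
        "d13c_co2": None,
    }
    row.update(overrides)
    return row


def make_obs(point_rows, lake_rows) -> ObservationSet:
    points = pd.DataFrame(point_rows, columns=list(SURVEY_COLUMNS))
    lakes = pd.DataFrame(lake_rows, columns=list(LAKE_COLUMNS))
    return ObservationSet(points=points, lakes=lakes)


@pytest.fixture
def small_obs() -> ObservationSet:
    """Two lakes, every period observed, one lake with isotopes."""
    rows = []
    for lake, veg in (("L1", "AM"), ("L2", "AS")):
        for period, date, t_w, t_a in (
            ("ice_covered", dt.date(2023, 3, 20), 1.5, 270.0),
            ("end_melting", dt.date(2023, 5, 3), 3.0, 275.0),
            ("ice_free", dt.date(2022, 7, 10), 10.0, 283.0),
        ):
            for _ in range(2):
                rows.append(
                    make_point(
                        lake_id=lake,
                        vegetation=veg,
                        period=period,
                        date=date,
                        t_water_c=t_w,
                        t_air_k=t_a,
                        d13c_ch4=-58.0 if (lake == "L1" and period == "ice_covered") else None,
                        d13c_co2=-14.0 if (lake == "L1" and period == "ice_covered") else None,
                    )
                )
    lakes = [
        {"lake_id": "L1", "vegetation": "AM", "area_m2": 5000.0, "elevation_m": 4500.0},
        {"lake_id": "L2", "vegetation": "AS", "area_m2": 120000.0, "elevation_m": 4700.0},
    ]
    return make_obs(rows, lakes)
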