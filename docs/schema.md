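# Input file schemas

All inputs are UTF-8 CSV with a header row. Missing optional values are
empty cells.

## Survey table (`survey.csv`)

Long format: one row per sampling point (a lake appears once per period and
point; replicate syringes are separate rows).

| column | type | units | notes |
|---|---|---|---|
| `lake_id` | string | | must resolve to a row of the lake table |
| `vegetation` | enum | | `ASM`, `AM`, `AS`, `AD` |
| `date` | ISO date | | sampling date |
| `period` | enum | | `ice_covered`, `ice_free`, `end_melting` |
| `headspace_ch4_ppm` | float ≥ 0 | ppm | CH4 mixing ratio in the equilibrated headspace |
| `v_h_l` | float > 0 | L | headspace volume |
| `v_w_l` | float > 0 | L | water volume |
| `t_air_k` | float > 0 | K | air temperature |
| `t_water_c` | float | °C | water temperature (−2 to 45 accepted) |
| `p_atm` | float in (0, 1.2] | atm | ambient pressure |
| `wind_speed_ms` | float ≥ 0 | m s⁻¹ | wind at `wind_height_m` |
| `wind_height_m` | float > 0 | m | anemometer height |
| `d13c_ch4` | float, optional | ‰ | must be > −1000 |
| `d13c_co2` | float, optional | ‰ | must be > −1000 |

## Lake table (`lakes.csv`)

| column | type | units |
|---|---|---|
| `lake_id` | string | |
| `vegetation` | enum | |
| `area_m2` | float | m², plausibility window 10–10⁷ |
| `elevation_m` | float, optional | m |

## Vegetation area table (`areas.csv`)

| column | type | units |
|---|---|---|
| `vegetation` | enum | all four classes required |
| `area_km2` | float ≥ 0 | km² total thermokarst-lake area of the class |

## Run config (`config.yaml`)

Keys: `survey`, `lakes`, `areas` (paths relative to the config file),
`out_dir`, `seed`, `n_iterations`, and optional blocks `calendar`,
`partition`, `transfer`, `constants`, `gwp`, `scenario`
(see `thawflux.pipeline.RunConfig`). A scenario block carries `label`,
`baseline_year`, `mode` (`static_ice`/`dynamic_ice`), `ice_covered_trend`
(d yr⁻¹) and `area_by_year: {year: {class: km2}}`.
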