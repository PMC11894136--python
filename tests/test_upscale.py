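"""Monte-Carlo regional upscaling, budget aggregation, CO2-equivalence."""

import numpy as np
import pandas as pd
import pytest

from thawflux.upscale import (
    FLUX_COMPONENTS,
    GwpConfig,
    aggregate_components,
    co2_equivalent,
    monte_carlo_upscale,
)

# Published plateau budget (Gg C / yr) by vegetation class and component;
# used as a frozen aggregation input.
BUDGET_TABLE = pd.DataFrame(
    {
        "f_diffusion": [1.13, 5.22, 0.85, 0.13],
        "f_ebullition": [3.96, 37.52, 4.80, 0.64],
        "f_water_storage": [1.29, 6.08, 0.52, 0.03],
        "f_ice_bubble": [0.48, 2.59, 0.21, 0.01],
    },
    index=["ASM", "AM", "AS", "AD"],
)


def _lake_pool(rng, n, scale=1.0):
    rows = []
    for veg in ("ASM", "AM", "AS", "AD"):
        for i in range(n):
            f_d = scale * rng.lognormal(0.5, 1.0)
            rows.append(
                {
                    "lake_id": f"{veg}-{i}",
                    "vegetation": veg,
                    "f_diffusion": f_d,
                    "f_ebullition": 5.4 * f_d,
                    "f_water_storage": 0.3 * f_d,
                    "f_ice_bubble": 0.12 * f_d,
                }
            )
    return pd.DataFrame(rows)


AREAS = {"ASM": 180.0, "AM": 2200.0, "AS": 350.0, "AD": 95.0}


class TestMonteCarlo:
    def test_degenerate_pool_is_exact_with_zero_spread(self):
        rows = [
            {"lake_id": f"{veg}-1", "vegetation": veg, **{c: 2.0 for c in FLUX_COMPONENTS}}
            for veg in AREAS
        ]
        est = monte_carlo_upscale(pd.DataFrame(rows), AREAS, n_iter=100, seed=0)
        expected = sum(8.0 * a * 1e6 * 12.0 / 16.04 / 1e9 for a in AREAS.values())
        assert est.total_mean == pytest.approx(expected, rel=1e-12)
        assert est.total_sd == pytest.approx(0.0, abs=1e-9)

    def test_seed_determinism(self):
        pool = _lake_pool(np.random.default_rng(1), 30)
        a = monte_carlo_upscale(pool, AREAS, n_iter=500, seed=42)
        b = monte_carlo_upscale(pool, AREAS, n_iter=500, seed=42)
        c = monte_carlo_upscale(pool, AREAS, n_iter=500, seed=43)
        pd.testing.assert_frame_equal(a.per_class, b.per_class)
        assert a.total_mean == b.total_mean
        assert a.total_mean != c.total_mean

    def test_lognormal_pool_mean_recovery(self):
        """Per-class MC mean within 3 SE of pool mean x area at 1000 draws."""
        pool = _lake_pool(np.random.default_rng(2), 200)
        est = monte_carlo_upscale(pool, AREAS, n_iter=1000, seed=3)
        for veg, area in AREAS.items():
            sub = pool[pool["vegetation"] == veg]
            annual = sub[list(FLUX_COMPONENTS)].sum(axis=1)
            target = annual.mean() * area * 1e6 * 12.0 / 16.04 / 1e9
            mc_se = est.per_class.loc[veg, "total_sd"] / np.sqrt(1000)
            assert abs(est.per_class.loc[veg, "total_mean"] - target) < 3 * mc_se

    def test_convergence_to_pool_mean_at_1e4(self):
        """MC mean within 1% of pool mean x area at 10^4 iterations."""
        pool = _lake_pool(np.random.default_rng(4), 100)
        est = monte_carlo_upscale(pool, AREAS, n_iter=10_000, seed=5)
        annual = pool[list(FLUX_COMPONENTS)].sum(axis=1)
        target = sum(
            pool.loc[pool["vegetation"] == veg, list(FLUX_COMPONENTS)].sum(axis=1).mean()
            * area * 1e6 * 12.0 / 16.04 / 1e9
            for veg, area in AREAS.items()
        )
        assert est.total_mean == pytest.approx(target, rel=0.01)

    def test_invariant_under_pool_duplication(self):
        """Duplicating every lake leaves the estimate distribution unchanged
        (same expected value; checked via the exact per-class pool means)."""
        pool = _lake_pool(np.random.default_rng(6), 50)
        doubled = pd.concat([pool, pool], ignore_index=True)
        a = monte_carlo_upscale(pool, AREAS, n_iter=4000, seed=7)
        b = monte_carlo_upscale(doubled, AREAS, n_iter=4000, seed=7)
        assert b.total_mean == pytest.approx(a.total_mean, rel=0.1)

    def test_empty_class_pool_errors_with_name(self):
        pool = _lake_pool(np.random.default_rng(8), 5)
        pool = pool[pool["vegetation"] != "AD"]
        with pytest.raises(ValueError, match="AD"):
            monte_carlo_upscale(pool, AREAS, n_iter=10, seed=0)

    def test_proportions_sum_to_one(self):
        pool = _lake_pool(np.random.default_rng(9), 20)
        est = monte_carlo_upscale(pool, AREAS, n_iter=500, seed=1)
        assert sum(est.proportions_by_class.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(est.proportions_by_component.values()) == pytest.approx(1.0, abs=1e-9)


class TestAggregation:
    def test_published_budget_rows_and_totals(self):
        agg = aggregate_components(BUDGET_TABLE)
        assert agg["row_totals"]["ASM"] == pytest.approx(6.85, abs=0.02)
        assert agg["grand_total"] == pytest.approx(65.45, abs=0.02)
        melt = (
            agg["column_totals"]["f_water_storage"] + agg["column_totals"]["f_ice_bubble"]
        )
        assert melt == pytest.approx(11.2, abs=0.05)

    def test_permutation_invariance(self):
        a = aggregate_components(BUDGET_TABLE)
        b = aggregate_components(BUDGET_TABLE.iloc[::-1])
        assert a["grand_total"] == pytest.approx(b["grand_total"])
        assert a["column_totals"] == pytest.approx(b["column_totals"])

    def test_all_zero_table(self):
        agg = aggregate_components(BUDGET_TABLE * 0.0)
        assert agg["grand_total"] == 0.0
        assert all(v == 0.0 for v in agg["row_totals"].values())

    def test_negative_rejected(self):
        bad = BUDGET_TABLE.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            aggregate_components(bad)


class TestCo2Equivalent:
    def test_published_value(self):
        # 65.45 Gg C * (16.04/12) * 27
        assert co2_equivalent(65.45) == pytest.approx(2362.1, abs=0.1)

    def test_zero_and_linearity(self):
        assert co2_equivalent(0.0) == 0.0
        assert co2_equivalent(20.0) == pytest.approx(2 * co2_equivalent(10.0))

    def test_alternative_gwp(self):
        assert co2_equivalent(10.0, GwpConfig(gwp100=28.0)) == pytest.approx(
            10.0 * 16.04 / 12.0 * 28.0
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            co2_equivalent(-1.0)
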