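"""Under-ice storage fluxes: water storage, bubble partition, interpolation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thawflux.icemelt import (
    MeltConcentrations,
    StoragePartitionParams,
    bubble_partition_factor,
    ice_melting_total,
    interpolate_endmelt,
    water_storage_flux,
)


def partition_oracle(m, ox=0.5, redis=0.8, trap=0.2):
    """Brute-force composition of the storage model: bubbling production
    from the ebullition proportion, oxidation of the dissolved store,
    re-dissolution/entrapment split of the bubble store."""
    s_diff = 1.0
    s_eb = m * s_diff / (1.0 - m)
    s_water = ox * (s_diff + redis * s_eb)
    s_bubble = trap * s_eb
    return s_bubble / s_water


class TestWaterStorageFlux:
    def test_zero_at_saturation(self):
        assert water_storage_flux(3.0, 3.0, 0.5, 0.2, 0.5, 0.2) == 0.0

    def test_unit_factor_hand_calculation(self):
        # high 30.1 mg/m2/d, low 10.1 mg/m2/d, each over 14 days
        f = water_storage_flux(3.0, 3.0, 2.606, 0.876, 0.0, 0.0)
        assert f == pytest.approx(0.563, abs=0.001)

    def test_linearity_in_gradients(self):
        base = water_storage_flux(3.0, 3.0, 2.606, 0.876, 0.0, 0.0)
        doubled = water_storage_flux(3.0, 3.0, 5.212, 1.752, 0.0, 0.0)
        assert doubled == pytest.approx(2 * base)

    def test_missing_endmelt_concentration_rejected(self):
        with pytest.raises(ValueError):
            water_storage_flux(3.0, 3.0, 2.6, np.nan, 0.0, 0.0)


class TestBubblePartition:
    def test_zero_proportion(self):
        assert bubble_partition_factor(0.0) == 0.0

    def test_closed_form_matches_composition_to_1e12(self):
        for m in np.arange(0.0, 0.991, 0.01):
            closed = bubble_partition_factor(m)
            assert closed == pytest.approx(2 * m / (5 - m), abs=1e-12)
            assert closed == pytest.approx(partition_oracle(m), abs=1e-12)

    def test_printed_melt_release_split(self):
        """At the plateau-wide M = 0.844 the melt release splits 28.9%
        bubbles / 71.1% water storage."""
        f = bubble_partition_factor(0.844)
        assert f == pytest.approx(0.4062, abs=2e-4)
        assert 100 * f / (1 + f) == pytest.approx(28.9, abs=0.05)

    def test_bubble_share_monotone_with_limits(self):
        m = np.linspace(0.0, 0.999, 200)
        share = bubble_partition_factor(m) / (1 + bubble_partition_factor(m))
        assert np.all(np.diff(share) > 0)
        assert share[0] == 0.0
        assert share[-1] < 1.0 / 3.0 + 1e-3  # limit 1/3 at M -> 1

    def test_generalized_fractions(self):
        params = StoragePartitionParams(
            oxidation_fraction=0.4, redissolution_fraction=0.7, entrapment_fraction=0.3
        )
        for m in (0.1, 0.5, 0.9):
            assert bubble_partition_factor(m, params) == pytest.approx(
                partition_oracle(m, 0.4, 0.7, 0.3), abs=1e-12
            )

    def test_zero_entrapment_zeroes_bubble_flux(self):
        params = StoragePartitionParams(
            redissolution_fraction=1.0, entrapment_fraction=0.0
        )
        assert bubble_partition_factor(0.844, params) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bubble_partition_factor(1.0)
        with pytest.raises(ValueError):
            StoragePartitionParams(redissolution_fraction=0.5, entrapment_fraction=0.2)


def test_ice_melting_total_is_sum():
    # the plateau median melt release: 0.8 water storage + 0.3 ice bubble
    assert ice_melting_total(0.8, 0.3) == pytest.approx(1.1)
    assert ice_melting_total(0.0, 0.0) == 0.0
    assert ice_melting_total(1.6, 0.6) == pytest.approx(2 * ice_melting_total(0.8, 0.3))


class TestEndMeltInterpolation:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["lake_id", "vegetation", "c_w_ice_covered", "c_w_end_melting"]
        )

    def test_exact_fit_recovery(self):
        rows = [(f"L{i}", "AM", x, 0.3 * x) for i, x in enumerate([1.0, 2.0, 5.0])]
        rows.append(("LX", "AM", 10.0, np.nan))
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert out["LX"].interpolated
        assert out["LX"].c_w_end_melting == pytest.approx(3.0)

    def test_measured_value_returned_unchanged(self):
        rows = [(f"L{i}", "AM", x, 0.3 * x) for i, x in enumerate([1.0, 2.0, 5.0])]
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert not out["L0"].interpolated
        assert out["L0"].c_w_end_melting == pytest.approx(0.3)

    def test_prediction_floored_at_zero(self):
        rows = [(f"L{i}", "AM", x, max(0.5 * x - 1.0, 0.0)) for i, x in enumerate([2.0, 4.0, 6.0])]
        rows.append(("LX", "AM", 0.1, np.nan))
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert out["LX"].c_w_end_melting >= 0.0

    def test_ratio_fallback_for_sparse_class(self):
        rows = [
            ("L1", "AD", 4.0, 1.0),  # single pair -> ratio estimator 0.25
            ("LX", "AD", 8.0, np.nan),
        ]
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert out["LX"].c_w_end_melting == pytest.approx(2.0)
        assert "ratio" in out["LX"].fit_note

    def test_pooled_fallback_when_class_has_no_pairs(self):
        rows = [(f"L{i}", "AM", x, 0.4 * x) for i, x in enumerate([1.0, 3.0, 6.0])]
        rows.append(("LX", "AD", 5.0, np.nan))
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert out["LX"].interpolated
        assert out["LX"].c_w_end_melting == pytest.approx(2.0, rel=1e-6)

    def test_no_training_pairs_at_all_errors(self):
        rows = [("L1", "AM", 2.0, np.nan)]
        with pytest.raises(ValueError):
            interpolate_endmelt(self._table(rows))

    def test_slope_recovery_on_noisy_pairs(self):
        """OLS slope lands within 3 SE of the generating slope."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 20.0, size=40)
        y = 0.35 * x + rng.normal(0.0, 0.5, size=40)
        rows = [(f"L{i}", "AM", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        rows.append(("LX", "AM", 10.0, np.nan))
        fit = stats.linregress(x, y)
        out = {m.lake_id: m for m in interpolate_endmelt(self._table(rows))}
        assert abs(fit.slope - 0.35) < 3 * fit.stderr
        assert out["LX"].c_w_end_melting == pytest.approx(
            max(fit.slope * 10.0 + fit.intercept, 0.0)
        )
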