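"""Biome overrides, pixel stocks, lognormal CVs, aggregation and residual classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olsenp.conversion import build_default_registry
from olsenp.rasters import Raster
from olsenp.stocks import (
    BiomeOverrideRule, DEFAULT_BIOME_RULES, StockGrid, aggregate_stocks,
    biome_override, lognormal_cv, mehlich_stock_to_olsen, pixel_stock,
    residual_classes,
)


def _grid(data, labels=None, cellsize=1.0):
    r = Raster(np.asarray(data, dtype=float), 0.0, 0.0, cellsize)
    if labels:
        r.labels = labels
    return r


class TestBiomeOverride:
    def _setup(self):
        conc = _grid([[10.0, 20.0], [30.0, 40.0]])
        biome = _grid([[0, 0], [1, 1]], labels={0: "deserts", 1: "croplands"})
        return conc, biome

    def test_desert_pixels_fixed_at_two(self):
        conc, biome = self._setup()
        out = biome_override(conc, biome, DEFAULT_BIOME_RULES)
        assert (out.data[0] == 2.0).all()        # deserts overridden
        assert (out.data[1] == conc.data[1]).all()  # croplands untouched

    def test_idempotent(self):
        conc, biome = self._setup()
        once = biome_override(conc, biome, DEFAULT_BIOME_RULES)
        twice = biome_override(once, biome, DEFAULT_BIOME_RULES)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_development_gating(self):
        conc = _grid([[10.0, 10.0]])
        biome = _grid([[0, 0]],
                      labels={0: "flooded_grasslands_savannas_mangroves"})
        dev = _grid([[1, 0]], labels={0: "underdeveloped", 1: "developed"})
        out = biome_override(conc, biome, DEFAULT_BIOME_RULES, development=dev)
        assert out.data[0, 0] == 5.4       # developed pixel overridden
        assert out.data[0, 1] == 10.0      # underdeveloped untouched

    def test_range_rule_endpoints(self):
        conc = _grid([[10.0, 10.0]])
        biome = _grid([[0, 0]], labels={0: "alpine"})
        slope = _grid([[0.0, 30.0]])
        elev = _grid([[0.0, 4000.0]])
        rule = BiomeOverrideRule("alpine", value_range=(1.0, 3.0))
        out = biome_override(conc, biome, [rule], slope=slope, elevation=elev)
        assert out.data[0, 0] == pytest.approx(3.0)  # gentle & low
        assert out.data[0, 1] == pytest.approx(1.0)  # steep & high

    def test_range_rule_without_terrain_uses_midpoint(self):
        conc = _grid([[10.0]])
        biome = _grid([[0]], labels={0: "alpine"})
        rule = BiomeOverrideRule("alpine", value_range=(1.0, 3.0))
        with pytest.warns(UserWarning, match="midpoint"):
            out = biome_override(conc, biome, [rule])
        assert out.data[0, 0] == pytest.approx(2.0)


class TestPixelStock:
    def test_worked_example(self):
        # 26 mg/kg x 1300 kg/m3 x 0.2 m x 1 km2 = 6760 kg = 0.00676 kt
        assert pixel_stock(26.0, 1300.0, 0.2, 1e6) == pytest.approx(0.00676)

    def test_zero_concentration(self):
        assert pixel_stock(0.0, 1300.0, 0.2, 1e6) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 100), st.floats(100, 2000), st.floats(1, 3))
    def test_multilinear(self, conc, bd, k):
        base = pixel_stock(conc, bd, 0.2, 1e6)
        assert pixel_stock(conc, bd, 0.2, k * 1e6) == pytest.approx(k * base)
        assert pixel_stock(k * conc, bd, 0.2, 1e6) == pytest.approx(k * base)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pixel_stock(-1.0, 1300.0)


class TestLognormalCV:
    def test_closed_form_values(self):
        assert lognormal_cv(0.0) == 0.0
        assert lognormal_cv(1.0) == pytest.approx(np.sqrt(np.e - 1))

    def test_small_s_limit(self):
        assert lognormal_cv(0.01) == pytest.approx(0.01, rel=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.001, 3.0), st.floats(0.001, 0.5))
    def test_strictly_increasing(self, s, ds):
        assert lognormal_cv(s + ds) > lognormal_cv(s)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lognormal_cv(-0.1)


class TestAggregation:
    def _stock_grid(self):
        conc = _grid([[10.0, 20.0], [30.0, 40.0]], cellsize=0.025)
        bd = conc.copy_with(np.full((2, 2), 1300.0))
        country = conc.copy_with(np.array([[0.0, 1.0], [0.0, 2.0]]))
        country.labels = {0: "a", 1: "b", 2: "c"}
        return StockGrid(concentration=conc, bulk_density=bd, country=country,
                         continent_of={"a": "west", "b": "east", "c": "east"})

    def test_two_pixels_additive(self):
        grid = self._stock_grid()
        table = aggregate_stocks(grid)
        a = table.loc[table.region == "a", "stock_kt"].iloc[0]
        stock = grid.stock_kt
        assert a == pytest.approx(stock[0, 0] + stock[1, 0])

    def test_country_continent_global_conservation(self):
        table = aggregate_stocks(self._stock_grid())
        countries = table.loc[table.level == "country", "stock_kt"].sum()
        continents = table.loc[table.level == "continent", "stock_kt"].sum()
        glob = table.loc[table.level == "global", "stock_kt"].iloc[0]
        assert countries == pytest.approx(continents)
        assert continents == pytest.approx(glob)

    def test_unassigned_country_bucketed_not_dropped(self):
        grid = self._stock_grid()
        grid.continent_of.pop("c")
        table = aggregate_stocks(grid)
        assert "unassigned" in set(table.loc[table.level == "continent",
                                             "region"])
        glob = table.loc[table.level == "global", "stock_kt"].iloc[0]
        assert glob == pytest.approx(grid.stock_kt.sum())

    def test_masked_pixels_contribute_zero(self):
        grid = self._stock_grid()
        grid.concentration.data[0, 0] = np.nan
        stock = grid.stock_kt
        assert stock[0, 0] == 0.0


class TestResidualClasses:
    @pytest.mark.parametrize("obs,pred,label", [
        (10.0, 11.0, "5.1-10"),   # 10 % difference
        (10.0, 14.0, ">25"),      # 40 %
        (100.0, 101.0, "0-2"),    # 1 %
        (100.0, 104.0, "2.1-5"),
        (100.0, 120.0, "10.1-25"),
    ])
    def test_binning(self, obs, pred, label):
        table = residual_classes([obs], [pred])
        assert table.loc[table["count"] == 1, "class"].iloc[0] == label

    def test_perfect_predictions_all_first_class(self):
        o = np.linspace(1, 50, 20)
        table = residual_classes(o, o)
        assert table.loc[table["class"] == "0-2", "share_pct"].iloc[0] == 100.0

    def test_shares_sum_to_hundred(self, rng):
        o = rng.uniform(1, 100, 500)
        p = o * rng.uniform(0.5, 1.5, 500)
        table = residual_classes(o, p)
        assert table["share_pct"].sum() == pytest.approx(100.0)
        assert table["count"].sum() == 500

    def test_zero_observation_goes_to_top_class(self):
        with pytest.warns(UserWarning, match="zero observations"):
            table = residual_classes([0.0, 10.0], [1.0, 10.0])
        assert table.loc[table["class"] == ">25", "count"].iloc[0] == 1


class TestMehlichStockConversion:
    def _grid(self, conc_values, calc=None):
        conc = _grid(conc_values, cellsize=0.025)
        bd = conc.copy_with(np.full_like(conc.data, 1300.0))
        country = conc.copy_with(np.zeros_like(conc.data))
        country.labels = {0: "a"}
        grid = StockGrid(concentration=conc, bulk_density=bd, country=country)
        mask = None if calc is None else conc.copy_with(np.asarray(calc, float))
        return grid, mask

    def test_non_calcareous_pixel(self):
        grid, mask = self._grid([[20.0]], calc=[[0.0]])
        out = mehlich_stock_to_olsen(grid, build_default_registry(), mask)
        assert out.concentration.data[0, 0] == pytest.approx(0.47 * 20 + 2.4)

    def test_calcareous_pixel(self):
        grid, mask = self._grid([[20.0]], calc=[[1.0]])
        out = mehlich_stock_to_olsen(grid, build_default_registry(), mask)
        assert out.concentration.data[0, 0] == pytest.approx(0.41 * 20 + 1.1)

    def test_zero_concentration_becomes_intercept(self):
        grid, mask = self._grid([[0.0]], calc=[[0.0]])
        out = mehlich_stock_to_olsen(grid, build_default_registry(), mask)
        assert out.concentration.data[0, 0] == pytest.approx(2.4)

    def test_missing_mask_warns_and_treats_non_calcareous(self):
        grid, _ = self._grid([[20.0]])
        with pytest.warns(UserWarning, match="non-calcareous"):
            out = mehlich_stock_to_olsen(grid, build_default_registry())
        assert out.concentration.data[0, 0] == pytest.approx(11.8)

    def test_stock_rescales_with_concentration(self):
        grid, mask = self._grid([[20.0]], calc=[[0.0]])
        out = mehlich_stock_to_olsen(grid, build_default_registry(), mask)
        ratio = out.stock_kt[0, 0] / grid.stock_kt[0, 0]
        assert ratio == pytest.approx(11.8 / 20.0)
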