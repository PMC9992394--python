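"""Biome overrides, per-pixel phosphorus stocks, CVs and regional totals.

A predicted concentration grid is turned into an areal stock grid by
multiplying each pixel's concentration (mg P per kg soil) by bulk density
(kg per m^3), topsoil thickness (0.2 m) and pixel area (m^2):

    stock_kt = conc * 1e-6 * bulk_density * depth * area / 1e6

Data-poor, largely unproductive biomes are overridden with literature
constants before the stock calculation: deserts 2.0 mg/kg; developed flooded
grasslands/savannas and mangroves 5.4; tropical/subtropical dry broadleaf
forests 3.5; underdeveloped montane grasslands/shrublands 3.1; and a
slope/elevation-graded band from 3 (gentle, low) down to 1 (steep, high)
mg/kg where a range rule applies.

Per-pixel uncertainty is a lognormal coefficient of variation
cv = sqrt(exp(s_ln^2) - 1) from the log-scale prediction SD; regional
uncertainty is reported as mean pixel CV x regional total (a documented
reporting convention).  Aggregation is exactly additive: country totals sum
to continent totals sum to the global total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rasters import Raster
from .records import Method, SoilClass

__all__ = [
    "BiomeOverrideRule", "DEFAULT_BIOME_RULES", "biome_override",
    "pixel_stock", "lognormal_cv", "StockGrid", "aggregate_stocks",
    "residual_classes", "mehlich_stock_to_olsen", "regions_from_geojson",
]

TOPSOIL_DEPTH_M = 0.2

#: mg/kg -> kg/kg, then kg -> kt
_MG_PER_KG = 1e-6
_KG_PER_KT = 1e6


@dataclass(frozen=True)
class BiomeOverrideRule:
    """Replacement concentration for one data-poor biome.

    Either a ``constant`` (mg/kg) or a slope/elevation-graded ``value_range``
    (lo, hi): the replacement decreases linearly from ``hi`` at the gentlest,
    lowest pixels to ``lo`` at the steepest, highest ones, with slope and
    elevation normalized over configurable bounds.  ``development`` restricts
    the rule to 'developed' or 'underdeveloped' pixels when set.
    """

    biome: str
    constant: Optional[float] = None
    value_range: Optional[tuple] = None
    development: Optional[str] = None
    slope_bounds: tuple = (0.0, 30.0)       # %
    elevation_bounds: tuple = (0.0, 4000.0)  # m

    def __post_init__(self):
        if (self.constant is None) == (self.value_range is None):
            raise ValueError("rule needs exactly one of constant / value_range")
        if self.constant is not None and self.constant <= 0:
            raise ValueError("constant must be positive")
        if self.value_range is not None and self.value_range[0] > self.value_range[1]:
            raise ValueError("value_range must be (lo, hi) with lo <= hi")


DEFAULT_BIOME_RULES = (
    BiomeOverrideRule("deserts", constant=2.0),
    BiomeOverrideRule("flooded_grasslands_savannas_mangroves", constant=5.4,
                      development="developed"),
    BiomeOverrideRule("tropical_dry_broadleaf_forests", constant=3.5),
    BiomeOverrideRule("montane_grasslands_shrublands", constant=3.1,
                      development="underdeveloped"),
)


def biome_override(
    conc: Raster,
    biome: Raster,
    rules: Sequence[BiomeOverrideRule] = DEFAULT_BIOME_RULES,
    slope: Optional[Raster] = None,
    elevation: Optional[Raster] = None,
    development: Optional[Raster] = None,
) -> Raster:
    """Replace modelled concentrations in listed biomes; other pixels unchanged.

    Idempotent: re-applying the same rules changes nothing.  Range rules with
    missing slope/elevation fall back to the range midpoint.
    """
    out = conc.data.copy()
    inv_labels = {v: k for k, v in biome.labels.items()}
    dev_labels = {} if development is None else development.labels
    for rule in rules:
        if rule.biome not in inv_labels:
            continue
        mask = biome.data == inv_labels[rule.biome]
        if rule.development is not None:
            if development is None:
                continue
            dev_inv = {v: k for k, v in dev_labels.items()}
            if rule.development not in dev_inv:
                continue
            mask &= development.data == dev_inv[rule.development]
        if not mask.any():
            continue
        if rule.constant is not None:
            out[mask] = rule.constant
        else:
            lo, hi = rule.value_range
            mid = 0.5 * (lo + hi)
            if slope is None or elevation is None:
                import warnings
                warnings.warn("range rule without slope/elevation rasters; "
                              "using midpoint", stacklevel=2)
                out[mask] = mid
            else:
                s0, s1 = rule.slope_bounds
                e0, e1 = rule.elevation_bounds
                ns = np.clip((slope.data - s0) / (s1 - s0), 0, 1)
                ne = np.clip((elevation.data - e0) / (e1 - e0), 0, 1)
                grade = 0.5 * (ns + ne)
                vals = hi - (hi - lo) * grade
                bad = ~np.isfinite(vals)
                vals = np.where(bad, mid, vals)
                out[mask] = vals[mask]
    return conc.copy_with(out)


def pixel_stock(concentration, bulk_density, depth: float = TOPSOIL_DEPTH_M,
                area=1e6):
    """Stock in kilotonnes: conc(mg/kg) x bd(kg/m^3) x depth(m) x area(m^2).

    Multilinear in all four arguments; accepts scalars or aligned arrays.
    """
    c = np.asarray(concentration, dtype=float)
    b = np.asarray(bulk_density, dtype=float)
    if np.any(c[np.isfinite(c)] < 0) or np.any(b[np.isfinite(b)] < 0) \
            or depth < 0 or np.any(np.asarray(area) < 0):
        raise ValueError("stock inputs must be non-negative")
    out = c * _MG_PER_KG * b * depth * np.asarray(area, dtype=float) / _KG_PER_KT
    return float(out) if out.ndim == 0 else out


def lognormal_cv(s_ln):
    """CV of a lognormal variable from its log-scale SD: sqrt(exp(s^2) - 1).

    Tends to s_ln itself for small s_ln.
    """
    s = np.asarray(s_ln, dtype=float)
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("log-scale SD must be non-negative")
    out = np.sqrt(np.expm1(s ** 2))
    return float(out) if out.ndim == 0 else out


@dataclass
class StockGrid:
    """Aligned per-pixel stock layers with region labels for aggregation."""

    concentration: Raster           # mg/kg
    bulk_density: Raster            # kg/m^3
    country: Raster                 # categorical
    depth_m: float = TOPSOIL_DEPTH_M
    continent_of: dict = field(default_factory=dict)  # country -> continent
    cv: Optional[Raster] = None

    def __post_init__(self):
        for r in (self.bulk_density, self.country):
            if not self.concentration.same_grid(r):
                raise ValueError("stock grid layers are not aligned")

    @property
    def stock_kt(self) -> np.ndarray:
        conc = np.nan_to_num(self.concentration.data, nan=0.0)
        bd = np.nan_to_num(self.bulk_density.data, nan=0.0)
        masked = ~np.isfinite(self.concentration.data)
        out = pixel_stock(conc, bd, self.depth_m,
                          self.concentration.cell_area_m2())
        out[masked] = 0.0
        return out

    def stock_raster(self) -> Raster:
        return self.concentration.copy_with(self.stock_kt)


def aggregate_stocks(grid: StockGrid) -> pd.DataFrame:
    """Country, continent and global stock totals with CV-scaled uncertainty.

    Returns one row per country, per continent and one 'global' row, with
    area (km^2), stock (kt) and uncertainty (mean pixel CV x total, kt).
    Pixels with a country label missing from the continent map fall into an
    'unassigned' continent bucket; totals are exactly additive by
    construction and never drop pixels silently.
    """
    stock = grid.stock_kt
    area_km2 = grid.concentration.cell_area_m2() / 1e6
    land = np.isfinite(grid.country.data)
    cv = grid.cv.data if grid.cv is not None else np.zeros_like(stock)

    rows = []
    country_totals: dict[str, dict] = {}
    codes = np.unique(grid.country.data[land])
    for code in codes:
        name = grid.country.labels.get(int(code), str(int(code)))
        m = grid.country.data == code
        tot = float(stock[m].sum())
        mean_cv = float(np.nanmean(cv[m])) if m.any() else 0.0
        country_totals[name] = {
            "region": name, "level": "country",
            "parent": grid.continent_of.get(name, "unassigned"),
            "area_km2": float(area_km2[m].sum()),
            "stock_kt": tot,
            "uncertainty_kt": mean_cv * tot,
            "mean_cv": mean_cv,
        }
    rows.extend(country_totals.values())

    by_cont: dict[str, list] = {}
    for rec in country_totals.values():
        by_cont.setdefault(rec["parent"], []).append(rec)
    for cont, recs in sorted(by_cont.items()):
        tot = sum(r["stock_kt"] for r in recs)
        area = sum(r["area_km2"] for r in recs)
        w = np.array([r["area_km2"] for r in recs])
        mean_cv = float(np.average([r["mean_cv"] for r in recs],
                                   weights=w if w.sum() else None))
        rows.append({"region": cont, "level": "continent", "parent": "global",
                     "area_km2": area, "stock_kt": tot,
                     "uncertainty_kt": mean_cv * tot, "mean_cv": mean_cv})
    conts = [r for r in rows if r["level"] == "continent"]
    tot = sum(r["stock_kt"] for r in conts)
    area = sum(r["area_km2"] for r in conts)
    w = np.array([r["area_km2"] for r in conts])
    mean_cv = float(np.average([r["mean_cv"] for r in conts],
                               weights=w if len(w) and w.sum() else None)) \
        if conts else 0.0
    rows.append({"region": "global", "level": "global", "parent": "",
                 "area_km2": area, "stock_kt": tot,
                 "uncertainty_kt": mean_cv * tot, "mean_cv": mean_cv})
    return pd.DataFrame(rows)


RESIDUAL_CLASS_LABELS = ("0-2", "2.1-5", "5.1-10", "10.1-25", ">25")


def residual_classes(observed, predicted) -> pd.DataFrame:
    """Bin absolute percentage differences into the five reporting classes.

    The per-point difference is 100 * |predicted - observed| / observed,
    binned into [0,2], (2,5], (5,10], (10,25], (25,inf).  A zero observation
    makes the difference undefined and is classed '>25' with a warning.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size or o.size == 0:
        raise ValueError("need equal-length non-empty vectors")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(p - o) / o
    zero = (o == 0)
    if zero.any():
        import warnings
        warnings.warn(f"{int(zero.sum())} zero observations classed '>25%'",
                      stacklevel=2)
        pct[zero] = np.inf
    edges = [0, 2, 5, 10, 25, np.inf]
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0:
            counts.append(int(np.sum((pct >= 0) & (pct <= hi))))
        else:
            counts.append(int(np.sum((pct > lo) & (pct <= hi))))
    return pd.DataFrame({
        "class": RESIDUAL_CLASS_LABELS,
        "count": counts,
        "share_pct": [100.0 * c / o.size for c in counts],
    })


def mehlich_stock_to_olsen(
    grid: StockGrid,
    registry,
    calcareous_mask: Optional[Raster] = None,
) -> StockGrid:
    """Convert a Mehlich-3 stock grid to Olsen-equivalent stocks.

    The linear conversion has an intercept, so it must be applied to the
    per-pixel concentrations, not to stock totals.  ``calcareous_mask`` marks
    calcareous pixels (>0); without it all pixels are treated non-calcareous
    (with a warning).
    """
    if calcareous_mask is None:
        import warnings
        warnings.warn("no calcareous mask: treating all pixels as "
                      "non-calcareous", stacklevel=2)
        calc = np.zeros_like(grid.concentration.data, dtype=bool)
    else:
        calc = calcareous_mask.data > 0
    eq_nc = registry.resolve(Method.MEHLICH3, SoilClass.NON_CALCAREOUS)
    eq_ca = registry.resolve(Method.MEHLICH3, SoilClass.CALCAREOUS)
    conc = grid.concentration.data
    out = np.where(calc,
                   eq_ca.slope * conc + eq_ca.intercept,
                   eq_nc.slope * conc + eq_nc.intercept)
    out = np.maximum(out, 0.0)
    out[~np.isfinite(conc)] = np.nan
    return StockGrid(
        concentration=grid.concentration.copy_with(out),
        bulk_density=grid.bulk_density, country=grid.country,
        depth_m=grid.depth_m, continent_of=dict(grid.continent_of),
        cv=grid.cv)


def regions_from_geojson(path, template: Raster,
                         name_property: str = "name") -> Raster:
    """Rasterize GeoJSON region polygons onto a template grid.

    Each cell center is assigned to the polygon containing it (point in
    polygon via shapely); cells outside every polygon are nodata.
    """
    import json

    from shapely.geometry import Point, shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = [(f["properties"][name_property], shape(f["geometry"]))
             for f in feats]
    lon, lat = template.cell_centers()
    data = np.full(template.data.shape, np.nan)
    labels = {}
    for code, (name, poly) in enumerate(polys):
        labels[code] = name
        prepared = poly.buffer(0)
        for i in range(template.nrows):
            for j in range(template.ncols):
                if math.isnan(data[i, j]) and prepared.contains(
                        Point(lon[i, j], lat[i, j])):
                    data[i, j] = code
    out = template.copy_with(data)
    out.labels = labels
    return out
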