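"""Seeded generator of multi-source soil-sample tables and small rasters.

The generator emulates the statistical structure the pipeline assumes, not
any real geography: a small WGS84 grid (40x40 cells at 0.025 degrees by
default) split into vertical country bands and horizontal biome bands;
smooth abstract covariate fields (Gaussian-bump mixtures); a known additive
log-scale link from the covariates plus country offsets to true Olsen P; and
multiplicative lognormal noise with a stated sigma.

Records are dressed up the way real multi-source data arrive: a mix of test
methods (non-Olsen values are generated by inverting the published combined
conversion equations, so conversion recovery is testable), detection-limit
censoring, multi-depth profiles whose depth-weighted mean equals the site
truth, exact and coordinate duplicates, and planted contaminants (stannous
chloride assays, volumetric units, off-window years, off-land coordinates,
deep-only profiles) in exact configured counts.  A ground-truth manifest
records the generating parameters, every record's expected pipeline fate and
the true regional stock totals of the synthetic grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .conversion import build_default_registry
from .filters import substitute_detection_limit
from .rasters import Raster
from .records import Assay, Method, SoilClass, Unit
from .stocks import StockGrid, aggregate_stocks

__all__ = ["SyntheticConfig", "GroundTruthManifest", "generate_rasters",
           "generate_samples", "write_dataset"]

#: After-harmonization shares of each test method in the emulated database.
DEFAULT_METHOD_MIX = {
    "olsen": 0.568, "bray1": 0.374, "mehlich3": 0.047,
    "resin": 0.005, "kirsanov": 0.004, "abdpta": 0.002,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_sites_per_country: int = 250
    n_countries: int = 4
    n_biomes: int = 2
    grid_n: int = 40                     # cells per side
    cellsize: float = 0.025              # degrees
    origin: tuple = (10.0, 45.0)         # (xll, yll) degrees
    n_covariates: int = 3
    beta0: float = 2.6                   # log mg/kg intercept (mean ~26 mg/kg)
    amplitudes: tuple = (0.6, 0.4, 0.5)  # per-covariate effect sizes
    country_offset_scale: float = 0.3    # log-scale half-range of offsets
    sigma: float = 0.5                   # lognormal noise SD (log scale)
    method_mix: dict = field(default_factory=lambda: dict(DEFAULT_METHOD_MIX))
    detection_limit: float = 2.0         # mg/kg
    censored_fraction: float = 0.001
    multilayer_fraction: float = 0.30
    exact_duplicate_fraction: float = 0.005
    coord_duplicate_fraction: float = 0.005
    stannous_fraction: float = 0.0
    volumetric_fraction: float = 0.0
    off_window_fraction: float = 0.0
    off_land_fraction: float = 0.0
    deep_only_fraction: float = 0.0
    bulk_density: float = 1300.0         # kg/m^3, constant
    year_window: tuple = (2000, 2019)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        mix_sum = sum(self.method_mix.values())
        if abs(mix_sum - 1.0) > 1e-6:
            raise ValueError(f"method mix must sum to 1 (got {mix_sum})")
        for name in ("censored_fraction", "multilayer_fraction",
                     "exact_duplicate_fraction", "coord_duplicate_fraction",
                     "stannous_fraction", "volumetric_fraction",
                     "off_window_fraction", "off_land_fraction",
                     "deep_only_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.n_sites_per_country * self.n_countries

    @property
    def country_names(self):
        return [f"country_{i + 1}" for i in range(self.n_countries)]

    @property
    def biome_names(self):
        base = ["croplands", "grasslands", "deserts",
                "tropical_dry_broadleaf_forests",
                "montane_grasslands_shrublands"]
        return base[: self.n_biomes]


@dataclass
class GroundTruthManifest:
    """What the generator knows: link, truths, fates and stock totals."""

    config: SyntheticConfig
    country_offsets: dict
    covariate_stats: dict               # per-covariate (min, max) over grid
    sites: pd.DataFrame                 # site_id, truth columns, expected fate
    record_fates: pd.DataFrame          # record_id, site_id, expected fate
    true_stocks: pd.DataFrame           # aggregate_stocks of the mean field

    def expected_kept_ids(self):
        keep = self.record_fates["expected_fate"] == "kept"
        return set(self.record_fates.loc[keep, "record_id"])

    def save(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "country_offsets": self.country_offsets,
            "covariate_stats": self.covariate_stats,
            "sites": self.sites.to_dict(orient="list"),
            "record_fates": self.record_fates.to_dict(orient="list"),
            "true_stocks": self.true_stocks.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _bump_field(rng: np.random.Generator, lon, lat, n_bumps: int = 5):
    """Smooth random field: mixture of Gaussian bumps over the grid extent."""
    x0, x1 = lon.min(), lon.max()
    y0, y1 = lat.min(), lat.max()
    extent = max(x1 - x0, y1 - y0)
    out = np.zeros_like(lon)
    for _ in range(n_bumps):
        cx = rng.uniform(x0, x1)
        cy = rng.uniform(y0, y1)
        w = rng.uniform(-1, 1)
        s = rng.uniform(0.2, 0.5) * extent
        out += w * np.exp(-((lon - cx) ** 2 + (lat - cy) ** 2) / (2 * s ** 2))
    return out


def _link(cov_values, amplitudes, beta0):
    """Additive smooth link on the log scale."""
    f = beta0
    funcs = (lambda u: np.sin(1.5 * u),
             lambda u: u ** 2 - 0.5,
             lambda u: u)
    for j, u in enumerate(cov_values):
        f = f + amplitudes[j % len(amplitudes)] * funcs[j % 3](u)
    return f


def generate_rasters(config: SyntheticConfig) -> dict:
    """Covariate, bulk-density, land, country, biome and development rasters.

    All rasters share one grid.  Countries are vertical bands, biomes
    horizontal bands; 'land' is 1 everywhere except a nodata notch in the
    north-west corner (so off-land contamination has somewhere to fall).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.grid_n
    xll, yll = config.origin
    template = Raster(np.zeros((n, n)), xll, yll, config.cellsize)
    lon, lat = template.cell_centers()

    rasters = {}
    for j in range(config.n_covariates):
        field = _bump_field(rng, lon, lat)
        # standardize over the grid so the link's scale (and hence the
        # generated concentration distribution) is stable across seeds
        field = (field - field.mean()) / field.std()
        rasters[f"cov{j + 1}"] = template.copy_with(field)

    land = np.ones((n, n))
    notch = max(1, n // 10)
    land[:notch, :notch] = np.nan
    rasters["land"] = template.copy_with(land)

    country = np.zeros((n, n))
    band = n / config.n_countries
    for j in range(n):
        country[:, j] = min(int(j / band), config.n_countries - 1)
    r_country = template.copy_with(country)
    r_country.labels = dict(enumerate(config.country_names))
    rasters["country"] = r_country

    biome = np.zeros((n, n))
    band = n / config.n_biomes
    for i in range(n):
        biome[i, :] = min(int(i / band), config.n_biomes - 1)
    r_biome = template.copy_with(biome)
    r_biome.labels = dict(enumerate(config.biome_names))
    rasters["biome"] = r_biome

    dev = template.copy_with((country % 2 == 0).astype(float))
    dev.labels = {0: "underdeveloped", 1: "developed"}
    rasters["development"] = dev

    rasters["bulk_density"] = template.copy_with(
        np.full((n, n), config.bulk_density))
    return rasters


def _country_geojson(config: SyntheticConfig) -> dict:
    xll, yll = config.origin
    width = config.grid_n * config.cellsize
    band = width / config.n_countries
    feats = []
    for i, name in enumerate(config.country_names):
        x0 = xll + i * band
        x1 = xll + (i + 1) * band
        y1 = yll + width
        feats.append({
            "type": "Feature", "properties": {"name": name},
            "geometry": {"type": "Polygon", "coordinates": [[
                [x0, yll], [x1, yll], [x1, y1], [x0, y1], [x0, yll]]]},
        })
    return {"type": "FeatureCollection", "features": feats}


def _continent_of(config: SyntheticConfig) -> dict:
    half = (config.n_countries + 1) // 2
    return {name: ("continent_A" if i < half else "continent_B")
            for i, name in enumerate(config.country_names)}


def _exact_counts(n: int, fractions: dict, rng) -> list:
    """Deterministic allocation of n items to categories matching fractions."""
    names = sorted(fractions)
    counts = {k: int(np.floor(fractions[k] * n)) for k in names}
    remainder = n - sum(counts.values())
    frac_part = sorted(names, key=lambda k: -(fractions[k] * n - counts[k]))
    for k in frac_part[:remainder]:
        counts[k] += 1
    items = [k for k in names for _ in range(counts[k])]
    rng.shuffle(items)
    return items


def generate_sites(
    config: SyntheticConfig,
    rasters: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Site truths only: placement, covariates, link values and noisy Olsen.

    Returns (site table, country offsets, link grid).  The site table carries
    the covariate values at each site's cell (columns ``cov1..covK``), the
    noiseless log-scale mean, and the realized observation — everything a
    model-recovery experiment needs without dressing records up as raw
    multi-source data.
    """
    if rasters is None:
        rasters = generate_rasters(config)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    country_r = rasters["country"]
    biome_r = rasters["biome"]
    lon2d, lat2d = country_r.cell_centers()
    offsets = {
        name: float(rng.uniform(-config.country_offset_scale,
                                config.country_offset_scale))
        for name in config.country_names}

    cov_grids = [rasters[f"cov{j + 1}"].data for j in range(config.n_covariates)]
    link_grid = _link(cov_grids, config.amplitudes, config.beta0)
    for code, name in country_r.labels.items():
        link_grid = link_grid + np.where(country_r.data == code,
                                         offsets[name], 0.0)
    # off-land cells carry no samples and no stock
    link_grid = np.where(np.isfinite(rasters["land"].data), link_grid, np.nan)

    land_ok = np.isfinite(rasters["land"].data)
    rows, cols, countries = [], [], []
    for code, name in country_r.labels.items():
        cells = np.argwhere((country_r.data == code) & land_ok)
        pick = cells[rng.integers(0, len(cells), config.n_sites_per_country)]
        rows.extend(pick[:, 0].tolist())
        cols.extend(pick[:, 1].tolist())
        countries.extend([name] * len(pick))
    rows = np.array(rows)
    cols = np.array(cols)
    m = len(rows)
    jitter = rng.uniform(-0.35, 0.35, (m, 2)) * config.cellsize
    site_df = pd.DataFrame({
        "site_id": [f"site{i:05d}" for i in range(m)],
        "country": countries,
        "row": rows, "col": cols,
        "longitude": lon2d[rows, cols] + jitter[:, 0],
        "latitude": lat2d[rows, cols] + jitter[:, 1],
        "year": rng.integers(config.year_window[0],
                             config.year_window[1] + 1, m),
        "biome": [biome_r.labels[int(b)] for b in biome_r.data[rows, cols]],
        "true_log_mean": link_grid[rows, cols],
    })
    for j, c in enumerate(cov_grids):
        site_df[f"cov{j + 1}"] = c[rows, cols]
    eps = rng.normal(0.0, config.sigma, m)
    site_df["observed_olsen"] = np.exp(site_df["true_log_mean"] + eps)
    site_df["true_olsen_median"] = np.exp(site_df["true_log_mean"])
    return site_df, offsets, link_grid


def generate_samples(
    config: SyntheticConfig,
    rasters: Optional[dict] = None,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Generate the raw multi-source sample table plus its ground truth.

    Records are generated so that, absent noise and contamination, the full
    pipeline reproduces each site's true Olsen value exactly: non-Olsen
    methods invert the published combined equations, depth profiles average
    back to the site value, coordinate duplicates mean back to it.
    """
    if rasters is None:
        rasters = generate_rasters(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    registry = build_default_registry()
    country_r = rasters["country"]
    site_df, offsets, link_grid = generate_sites(config, rasters, rng)
    cov_grids = [rasters[f"cov{j + 1}"].data for j in range(config.n_covariates)]

    n = len(site_df)
    methods = _exact_counts(n, config.method_mix, rng)

    n_censored = int(round(config.censored_fraction * n))
    n_multi = int(round(config.multilayer_fraction * n))
    flags = np.array(["single"] * n, dtype=object)
    flags[rng.choice(n, n_multi, replace=False)] = "multi"
    censored_idx = set(rng.choice(n, n_censored, replace=False).tolist())

    records = []
    fates = []
    expected_vals = np.empty(n)
    rec_no = 0

    def new_id():
        nonlocal rec_no
        rec_no += 1
        return f"rec{rec_no:06d}"

    def base_record(site, method, value, depth=(0.0, 20.0), **over):
        d = {
            "source_id": over.pop("source_id", "synth_main"),
            "sample_id": new_id(),
            "longitude": site["longitude"], "latitude": site["latitude"],
            "year": site["year"],
            "depth_top": depth[0], "depth_bottom": depth[1],
            "method": method, "assay": Assay.MOLYBDENUM_BLUE.value,
            "value": value, "unit": Unit.MASS.value,
            "below_detection": False, "pH": np.nan,
            "soil_class": SoilClass.UNKNOWN.value,
            "country": site["country"], "province": "",
            "land_use": site["biome"],
        }
        d.update(over)
        return d

    for k, site in enumerate(site_df.to_dict(orient="records")):
        olsen = float(site["observed_olsen"])
        method = methods[k]
        expected = olsen

        if k in censored_idx:
            # the source reports half the detection limit for censored values
            half = config.detection_limit / 2.0
            rec = base_record(site, Method.OLSEN.value, half,
                              below_detection=True)
            records.append(rec)
            fates.append({"record_id": rec["sample_id"],
                          "site_id": site["site_id"], "expected_fate": "kept"})
            expected_vals[k] = half
            continue

        # route through a non-Olsen test where the inverse stays positive
        eq = None
        ph = np.nan
        soil_class = SoilClass.UNKNOWN.value
        if method != "olsen":
            if method in ("bray1", "kirsanov"):
                ph = float(rng.uniform(4.5, 6.9))
                eq = registry.resolve(Method.BRAY1, SoilClass.NON_CALCAREOUS)
            elif method == "abdpta":
                eq = registry.resolve(Method.ABDPTA, SoilClass.ANY)
            else:
                soil_class = (SoilClass.CALCAREOUS.value if rng.random() < 0.5
                              else SoilClass.NON_CALCAREOUS.value)
                ph = float(rng.uniform(7.6, 8.2)
                           if soil_class == SoilClass.CALCAREOUS.value
                           else rng.uniform(5.0, 6.9))
                eq = registry.resolve(Method(method), SoilClass(soil_class))
            # the deepest synthetic layer carries 0.7x the site value; its
            # inverse must stay positive too
            if 0.7 * olsen <= eq.intercept + 0.1:
                method, eq = "olsen", None  # inverse would go negative
                ph, soil_class = np.nan, SoilClass.UNKNOWN.value

        def value_for(conc):
            return conc if eq is None else eq.invert(conc)

        def after_pipeline(raw):
            # what the filter + conversion stages will make of a raw value:
            # half-limit substitution below the default detection limit,
            # then the conversion equation where one applies
            sub = substitute_detection_limit(raw, config.detection_limit)
            return sub if eq is None else eq.apply(sub)

        if flags[k] == "multi":
            # two layers whose 0.75/0.25 overlap-weighted mean is the truth
            d = 0.1 * olsen
            c_top, c_deep = olsen + d, olsen - 3 * d
            for depth, conc in (((0.0, 15.0), c_top), ((15.0, 25.0), c_deep)):
                rec = base_record(site, method, value_for(conc), depth=depth,
                                  pH=ph, soil_class=soil_class)
                records.append(rec)
                fates.append({"record_id": rec["sample_id"],
                              "site_id": site["site_id"],
                              "expected_fate": "kept"})
            expected = (0.75 * after_pipeline(value_for(c_top))
                        + 0.25 * after_pipeline(value_for(c_deep)))
        else:
            rec = base_record(site, method, value_for(olsen),
                              pH=ph, soil_class=soil_class)
            records.append(rec)
            fates.append({"record_id": rec["sample_id"],
                          "site_id": site["site_id"], "expected_fate": "kept"})
            expected = after_pipeline(value_for(olsen))
        expected_vals[k] = expected

    site_df["expected_olsen_0_20"] = expected_vals
    df = pd.DataFrame(records)

    # ---- duplicates -------------------------------------------------------
    # duplicate pairs are perturbed by +/-5%, which must not cross the
    # detection limit or the planted mean would shift under substitution
    single_idx = df.index[(df["depth_top"] == 0) & (df["depth_bottom"] == 20)
                          & (df["method"] == "olsen")
                          & ~df["below_detection"]
                          & (df["value"] >= config.detection_limit / 0.95)
                          ].to_numpy()
    n_exact = min(int(round(config.exact_duplicate_fraction * n)),
                  len(single_idx))
    n_coord = min(int(round(config.coord_duplicate_fraction * n)),
                  max(0, len(single_idx) - n_exact))
    dup_pick = rng.choice(single_idx, n_exact + n_coord, replace=False)
    extra = []
    for i in dup_pick[:n_exact]:
        rec = df.loc[i].to_dict()
        rec["sample_id"] = new_id()
        extra.append(rec)
        fates.append({"record_id": rec["sample_id"],
                      "site_id": "", "expected_fate": "kept"})
    for i in dup_pick[n_exact:n_exact + n_coord]:
        # a pair (v - d, v + d) replacing the original keeps the site mean
        rec = df.loc[i].to_dict()
        d = 0.05 * rec["value"]
        df.loc[i, "value"] = rec["value"] - d
        rec = df.loc[i].to_dict()
        rec["sample_id"] = new_id()
        rec["value"] = rec["value"] + 2 * d
        extra.append(rec)
        fates.append({"record_id": rec["sample_id"],
                      "site_id": "", "expected_fate": "kept"})
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)

    # ---- planted contaminants --------------------------------------------
    xll, yll = config.origin
    width = config.grid_n * config.cellsize

    def random_site():
        return site_df.iloc[int(rng.integers(0, len(site_df)))].to_dict()

    contaminants = [
        ("stannous_fraction", "method",
         dict(assay=Assay.STANNOUS_CHLORIDE.value)),
        ("volumetric_fraction", "unit", dict(unit=Unit.VOLUMETRIC.value)),
        ("off_window_fraction", "year", dict(year=1993)),
        ("off_land_fraction", "land_mask", {}),
    ]
    bad = []
    for frac_name, reason, overrides in contaminants:
        k = int(round(getattr(config, frac_name) * n))
        for _ in range(k):
            site = random_site()
            rec = base_record(site, Method.OLSEN.value,
                              float(site["observed_olsen"]),
                              source_id="synth_contam")
            rec.update(overrides)
            if reason == "land_mask":
                # inside the nodata notch in the north-west corner
                rec["longitude"] = xll + 0.5 * config.cellsize
                rec["latitude"] = yll + width - 0.5 * config.cellsize
            bad.append(rec)
            fates.append({"record_id": rec["sample_id"], "site_id": "",
                          "expected_fate": f"discarded:{reason}"})
    k_deep = int(round(config.deep_only_fraction * n))
    for _ in range(k_deep):
        site = random_site()
        rec = base_record(site, Method.OLSEN.value,
                          float(site["observed_olsen"]),
                          depth=(25.0, 40.0), source_id="synth_deep",
                          longitude=site["longitude"] + 0.001)
        bad.append(rec)
        fates.append({"record_id": rec["sample_id"], "site_id": "",
                      "expected_fate": "discarded:depth"})
    if bad:
        df = pd.concat([df, pd.DataFrame(bad)], ignore_index=True)

    # ---- true stocks over the grid ---------------------------------------
    # the pipeline's smearing-corrected predictions target the conditional
    # MEAN concentration exp(link + sigma^2/2), so that is the stock truth
    mean_field = np.exp(link_grid + config.sigma ** 2 / 2.0)
    grid = StockGrid(
        concentration=country_r.copy_with(mean_field),
        bulk_density=rasters["bulk_density"],
        country=country_r,
        continent_of=_continent_of(config))
    true_stocks = aggregate_stocks(grid)

    manifest = GroundTruthManifest(
        config=config,
        country_offsets=offsets,
        covariate_stats={
            f"cov{j + 1}": (float(np.nanmin(c)), float(np.nanmax(c)))
            for j, c in enumerate(cov_grids)},
        sites=site_df,
        record_fates=pd.DataFrame(fates),
        true_stocks=true_stocks,
    )
    # stable shuffle of the output table so sources are interleaved
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    return df, manifest


def write_dataset(outdir, config: SyntheticConfig) -> dict:
    """Materialize a dataset on disk in the dialects the pipeline consumes.

    Writes samples.csv, one .asc per raster (with .labels.csv sidecars for
    categorical layers), countries.geojson and manifest.json; returns the
    path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rasters = generate_rasters(config)
    samples, manifest = generate_samples(config, rasters)
    paths = {"samples": outdir / "samples.csv"}
    samples.to_csv(paths["samples"], index=False)
    for name, r in rasters.items():
        p = outdir / f"{name}.asc"
        r.write_ascii(p)
        paths[name] = p
    paths["regions"] = outdir / "countries.geojson"
    with open(paths["regions"], "w") as fh:
        json.dump(_country_geojson(config), fh)
    paths["manifest"] = outdir / "manifest.json"
    manifest.save(paths["manifest"])
    return paths
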