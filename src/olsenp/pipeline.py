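"""End-to-end orchestration: filter -> convert -> harmonize -> model -> stocks.

This module chains the stage functions with their default configurations so
that a whole dataset (real or synthetic) can be processed in one call; each
stage remains individually usable and the intermediate tables are returned
for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .conversion import ConversionRegistry, build_default_registry
from .depth import harmonize_table, outlier_summary
from .filters import FilterConfig, FilterReport, apply_filters
from .model import OlsenPModel, OlsenPResults, extract_predictors
from .rasters import Raster
from .stocks import (StockGrid, aggregate_stocks, biome_override,
                     lognormal_cv, DEFAULT_BIOME_RULES)

__all__ = ["PipelineResult", "run_pipeline", "harmonize_dataset"]


@dataclass
class PipelineResult:
    filtered: pd.DataFrame
    filter_report: FilterReport
    converted: pd.DataFrame
    harmonized: pd.DataFrame
    outliers: object
    fit: Optional[OlsenPResults] = None
    concentration: Optional[Raster] = None
    stocks: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)


def harmonize_dataset(
    samples: pd.DataFrame,
    filter_config: Optional[FilterConfig] = None,
    registry: Optional[ConversionRegistry] = None,
    manifest=None,
):
    """Run the filtering, conversion and depth-standardization stages.

    Returns (harmonized table, filtered table, report, converted table).
    """
    filter_config = filter_config or FilterConfig()
    registry = registry or build_default_registry()
    filtered, report = apply_filters(samples, filter_config, manifest=manifest)
    kept = filtered.loc[filtered["filter_status"] == "kept"]
    converted = registry.convert_table(kept)
    harmonized = harmonize_table(converted, value_col="olsen_p")
    return harmonized, filtered, report, converted


def run_pipeline(
    samples: pd.DataFrame,
    rasters: Optional[dict] = None,
    covariates: tuple = (),
    filter_config: Optional[FilterConfig] = None,
    registry: Optional[ConversionRegistry] = None,
    fit_model: bool = True,
    split: Optional[float] = None,
    seed: int = 0,
    model_kwargs: Optional[dict] = None,
    compute_stocks: bool = True,
    biome_rules=DEFAULT_BIOME_RULES,
    continent_of: Optional[dict] = None,
) -> PipelineResult:
    """Process a raw sample table to harmonized values, a fitted model
    and (given rasters) a concentration grid with stock totals.

    ``covariates`` names the raster layers used as smooth model terms; when
    empty, all ``cov*`` layers are used.  ``split=None`` fits the production
    model on all data (metrics then describe the training fit).
    """
    harmonized, filtered, report, converted = harmonize_dataset(
        samples, filter_config, registry)
    out = PipelineResult(
        filtered=filtered, filter_report=report, converted=converted,
        harmonized=harmonized,
        outliers=outlier_summary(harmonized["olsen_p_0_20"])
        if len(harmonized) >= 4 else None,
    )
    if not fit_model or rasters is None:
        return out

    covariates = tuple(covariates) or tuple(
        sorted(k for k in rasters if k.startswith("cov")))
    cov_rasters = {k: rasters[k] for k in covariates}
    table = extract_predictors(harmonized, cov_rasters)
    model = OlsenPModel(
        table, response_col="olsen_p_0_20",
        smooth_terms=list(covariates), factor_terms=["country"],
        **(model_kwargs or {}))
    fit = model.fit(split=split, seed=seed)
    out.fit = fit

    if not compute_stocks:
        return out
    if "country" in rasters:
        # per-cell country labels feed the factor term
        conc = fit.predict_grid({**cov_rasters, "country": rasters["country"]})
    else:
        conc = fit.predict_grid(dict(cov_rasters), extra={"country": "other"})
    if "land" in rasters:
        conc = conc.copy_with(
            np.where(np.isfinite(rasters["land"].data), conc.data, np.nan))
    if "biome" in rasters and biome_rules:
        conc = biome_override(
            conc, rasters["biome"], biome_rules,
            slope=rasters.get("slope"), elevation=rasters.get("elevation"),
            development=rasters.get("development"))
    out.concentration = conc

    cv = lognormal_cv(fit.residual_sd)
    grid = StockGrid(
        concentration=conc,
        bulk_density=rasters["bulk_density"],
        country=rasters["country"],
        continent_of=continent_of or {},
        cv=conc.copy_with(np.full_like(conc.data, cv)),
    )
    out.stocks = aggregate_stocks(grid)
    out.extras["stock_grid"] = grid
    return out
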