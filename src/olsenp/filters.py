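"""Method/unit/detection-limit and space/time screens for raw sample tables.

Two screening stages run before any conversion:

* the method screen drops stannous-chloride colorimetry (not comparable with
  molybdenum-blue or ion-chromatography determinations) and volumetric
  (mg L^-1) results, and substitutes half the detection limit for censored
  values;
* the geotemporal screen drops records without usable coordinates, records
  falling off land (aquatic systems, glaciers, permanent snowpack), records
  outside the accepted sampling window (2000-2019 by default, with per-source
  exemptions for areas of unchanged land use), and — for the Chinese national
  survey source — records from the listed eastern provinces or sampled before
  1995.

Every decision is tallied in a :class:`FilterReport` so that kept + discarded
always reconstructs the input count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rasters import Raster
from .records import Assay, Unit

__all__ = [
    "FilterConfig", "FilterReport", "screen_method",
    "infer_detection_limit", "substitute_detection_limit",
    "filter_geotemporal", "apply_filters",
]

#: Eastern Chinese provinces excluded from the second national survey source.
CHINA_EXCLUDED_PROVINCES = (
    "Anhui", "Fujian", "Guangdong", "Guangxi", "Hainan", "Hebei",
    "Jiangsu", "Jiangxi", "Shandong", "Sichuan", "Tianjin",
)


@dataclass
class FilterConfig:
    detection_limit_default: float = 2.0          # mg/kg
    year_window: tuple[int, int] = (2000, 2019)
    exempt_sources: frozenset = frozenset()
    china_sources: frozenset = frozenset({"CTSDB"})
    excluded_provinces: tuple = CHINA_EXCLUDED_PROVINCES
    china_min_year: int = 1995
    land_mask: Optional[Raster] = None            # >0 / 1 = land
    treat_zero_zero_as_missing: bool = True
    at_limit_censored: bool = False               # also substitute values == limit
    detection_repeat_threshold: int = 10

    def __post_init__(self):
        if self.detection_limit_default <= 0:
            raise ValueError("detection limit must be positive")
        if self.year_window[0] > self.year_window[1]:
            raise ValueError("year_window start must be <= end")


@dataclass
class FilterReport:
    """Audit trail: one counter per discard reason, conserving the input count."""

    input_n: int = 0
    kept_n: int = 0
    discarded: dict = field(default_factory=dict)

    def discard(self, reason: str, n: int = 1) -> None:
        self.discarded[reason] = self.discarded.get(reason, 0) + n

    def keep(self, n: int = 1) -> None:
        self.kept_n += n

    @property
    def discarded_n(self) -> int:
        return sum(self.discarded.values())

    def check(self) -> None:
        if self.kept_n + self.discarded_n != self.input_n:
            raise AssertionError(
                f"filter bookkeeping broken: {self.kept_n} kept + "
                f"{self.discarded_n} discarded != {self.input_n} input")

    def to_dict(self) -> dict:
        return {"input_n": self.input_n, "kept_n": self.kept_n,
                "discarded_n": self.discarded_n,
                "discarded": dict(self.discarded)}


def screen_method(assay, unit, value=None):
    """(keep: bool, reason or None) for the analytical-method screen."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False, "malformed"
    try:
        assay = Assay(assay)
        unit = Unit(unit)
    except ValueError:
        return False, "malformed"
    if assay is Assay.STANNOUS_CHLORIDE:
        return False, "method"
    if unit is Unit.VOLUMETRIC:
        return False, "unit"
    return True, None


def infer_detection_limit(
    values: Sequence[float], repeat_threshold: int = 10
) -> Optional[float]:
    """Detect an unreported censoring floor from repeated low values.

    A source that substituted half its detection limit leaves a single low
    concentration repeated many times.  Returns the smallest value repeated at
    least ``repeat_threshold`` times that sits in the lowest decile of the
    source's values, or None.  The implied detection limit is twice the
    returned value (the repeated value being the half-limit substitution).
    """
    if repeat_threshold < 2:
        raise ValueError("repeat_threshold must be >= 2")
    values = np.asarray([v for v in values if v is not None and not math.isnan(v)],
                        dtype=float)
    if values.size == 0 or np.ptp(values) == 0:
        return None
    q10 = float(np.quantile(values, 0.1))
    uniq, counts = np.unique(values, return_counts=True)
    candidates = uniq[(counts >= repeat_threshold) & (uniq <= q10)]
    return float(candidates.min()) if candidates.size else None


def substitute_detection_limit(
    value: float, limit: float,
    below_detection: bool = False, at_limit: bool = False,
) -> float:
    """Half-limit substitution for censored values.

    Values flagged below detection, or numerically below the limit (at or
    below, with ``at_limit=True``), become limit/2; all others pass through.
    Idempotent and never value-increasing for values >= limit/2.
    """
    if limit <= 0:
        raise ValueError("detection limit must be positive")
    if value < 0:
        raise ValueError(f"invalid concentration {value}")
    if below_detection or value < limit or (at_limit and value == limit):
        return limit / 2.0
    return value


def filter_geotemporal(
    longitude, latitude, year, source_id, province, config: FilterConfig
):
    """(keep: bool, reason or None) for the space/time screen."""
    if longitude is None or latitude is None \
            or (isinstance(longitude, float) and math.isnan(longitude)) \
            or (isinstance(latitude, float) and math.isnan(latitude)):
        return False, "georeference"
    if not (-180 <= longitude <= 180 and -90 <= latitude <= 90):
        return False, "georeference"
    if config.treat_zero_zero_as_missing and longitude == 0 and latitude == 0:
        return False, "georeference"
    if config.land_mask is not None:
        v = config.land_mask.sample(longitude, latitude)
        if math.isnan(v) or v <= 0:
            return False, "land_mask"
    if source_id in config.china_sources:
        if province in config.excluded_provinces:
            return False, "province"
        if year < config.china_min_year:
            return False, "year"
        return True, None
    lo, hi = config.year_window
    if not (lo <= year <= hi) and source_id not in config.exempt_sources:
        return False, "year"
    return True, None


def apply_filters(
    df: pd.DataFrame, config: FilterConfig, manifest=None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run both screens plus detection-limit substitution over a sample table.

    Returns the full table with ``filter_status`` ('kept'/'discarded') and
    ``filter_reason`` columns, and the conservation-checked report.  Censored
    substitution uses a per-source limit inferred from repeated low values
    when the source does not report one, else the configured default.
    """
    if manifest is not None and getattr(manifest, "exempt_sources", None):
        from dataclasses import replace
        config = replace(config, exempt_sources=frozenset(
            set(config.exempt_sources) | set(manifest.exempt_sources)))
    report = FilterReport(input_n=len(df))
    status = np.full(len(df), "kept", dtype=object)
    reason = np.full(len(df), "", dtype=object)

    values = df["value"].to_numpy(dtype=float, copy=True)

    for i, row in enumerate(df.itertuples(index=False)):
        keep, why = screen_method(row.assay, row.unit, row.value)
        if keep:
            keep, why = filter_geotemporal(
                row.longitude, row.latitude, int(row.year),
                row.source_id, getattr(row, "province", None), config)
        if not keep:
            status[i] = "discarded"
            reason[i] = why
            report.discard(why)
        else:
            report.keep()

    # per-source detection limits on the surviving records
    kept_mask = status == "kept"
    known_limits = getattr(manifest, "detection_limits", {}) if manifest else {}
    for source, sub in df.loc[kept_mask].groupby("source_id", sort=False):
        if source in known_limits:
            limit = known_limits[source]
        else:
            inferred = infer_detection_limit(
                sub["value"].tolist(), config.detection_repeat_threshold)
            limit = 2 * inferred if inferred is not None else config.detection_limit_default
        for i in sub.index:
            pos = df.index.get_loc(i)
            values[pos] = substitute_detection_limit(
                values[pos], limit,
                below_detection=bool(df.at[i, "below_detection"])
                if "below_detection" in df.columns else False,
                at_limit=config.at_limit_censored)

    out = df.copy()
    out["value"] = values
    out["filter_status"] = status
    out["filter_reason"] = reason
    report.check()
    return out, report
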