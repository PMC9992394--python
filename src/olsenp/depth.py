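"""Standardization of multi-depth profiles to a single 0-20 cm value.

Sites sampled at several depth intervals are averaged to the top 20 cm using
each layer's overlap with the 0-20 cm window, optionally weighted by layer
bulk density: a 15-25 cm sample influences the 0-20 cm mean by a quarter
under equal bulk density, and layers wholly below 20 cm drop out.  Multiple
records at the same coordinates and date collapse to one (exact duplicates
removed, distinct values averaged).  Outliers are summarized with Tukey
fences (quartiles +/- 1.5 IQR) but never removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileLayer", "OutlierSummary", "overlap_weight", "harmonize_profile",
    "dedupe", "outlier_summary", "harmonize_table",
]

TARGET_TOP = 0.0
TARGET_BOTTOM = 20.0

#: Decimal places for coordinate matching (~1 m at the equator).
SITE_KEY_DECIMALS = 5


@dataclass(frozen=True)
class ProfileLayer:
    depth_top: float       # cm
    depth_bottom: float    # cm
    olsen_p: float         # mg/kg
    bulk_density: Optional[float] = None  # kg/m3; None = equal across layers

    def __post_init__(self):
        if not (self.depth_bottom > self.depth_top >= 0):
            raise ValueError(
                f"invalid layer [{self.depth_top}, {self.depth_bottom}]")
        if self.olsen_p < 0:
            raise ValueError("olsen_p must be non-negative")
        if self.bulk_density is not None and self.bulk_density <= 0:
            raise ValueError("bulk density must be positive")


def overlap_weight(
    layer: ProfileLayer,
    target_top: float = TARGET_TOP,
    target_bottom: float = TARGET_BOTTOM,
) -> float:
    """Fraction of the target window covered by the layer, x bulk density.

    A 15-25 cm layer in a 0-20 cm window gets 5/20 = 0.25 under equal bulk
    density; a layer entirely below the window gets 0 (excluded).
    """
    overlap = max(0.0, min(layer.depth_bottom, target_bottom)
                  - max(layer.depth_top, target_top))
    w = overlap / (target_bottom - target_top)
    if layer.bulk_density is not None:
        w *= layer.bulk_density
    return w


class ProfileBelowWindowError(ValueError):
    """All layers lie below the target window; the site carries no 0-20 cm value."""


def harmonize_profile(
    layers: Sequence[ProfileLayer],
    target_top: float = TARGET_TOP,
    target_bottom: float = TARGET_BOTTOM,
    min_coverage: float = 0.0,
) -> float:
    """Overlap-and-bulk-density weighted 0-20 cm mean concentration.

    Weights are renormalized over the contributing layers, so a profile that
    only covers part of the window is taken as representative of it (no
    extrapolation is attempted).  ``min_coverage`` (fraction of the window)
    enables a strict mode that rejects poorly covering profiles.
    """
    if not layers:
        raise ValueError("no layers")
    w = np.array([overlap_weight(l, target_top, target_bottom) for l in layers])
    c = np.array([l.olsen_p for l in layers])
    if w.sum() <= 0:
        raise ProfileBelowWindowError("below 20 cm only")
    if min_coverage > 0:
        covered = sum(
            max(0.0, min(l.depth_bottom, target_bottom) - max(l.depth_top, target_top))
            for l in layers) / (target_bottom - target_top)
        if covered < min_coverage:
            raise ProfileBelowWindowError(
                f"profile covers {covered:.0%} of the window (< {min_coverage:.0%})")
    return float(np.sum(w * c) / np.sum(w))


def _site_key(df: pd.DataFrame) -> pd.Series:
    lon = df["longitude"].round(SITE_KEY_DECIMALS)
    lat = df["latitude"].round(SITE_KEY_DECIMALS)
    year = df["year"] if "year" in df.columns else 0
    return (lon.astype(str) + "|" + lat.astype(str) + "|" + pd.Series(year, index=df.index).astype(str))


def dedupe(df: pd.DataFrame, value_col: str = "olsen_p_0_20") -> pd.DataFrame:
    """Collapse duplicate site x date rows.

    Exact duplicates (same site key and value) reduce to one row; distinct
    values at one site key are replaced by their arithmetic mean.  Adds
    ``n_duplicates_merged``.  Idempotent.
    """
    if df.empty:
        out = df.copy()
        out["n_duplicates_merged"] = pd.Series(dtype=int)
        return out
    key = _site_key(df)
    grouped = df.assign(_key=key).groupby("_key", sort=False)
    rows = []
    for _, g in grouped:
        first = g.iloc[0].copy()
        first[value_col] = g[value_col].mean()
        prior = int(g["n_duplicates_merged"].sum()) \
            if "n_duplicates_merged" in g.columns else 0
        first["n_duplicates_merged"] = prior + len(g) - 1
        rows.append(first)
    out = pd.DataFrame(rows).drop(columns="_key").reset_index(drop=True)
    out["n_duplicates_merged"] = out["n_duplicates_merged"].astype(int)
    return out


@dataclass(frozen=True)
class OutlierSummary:
    q25: float
    q50: float
    q75: float
    iqr: float
    lower_fence: float
    upper_fence: float
    minor_count: int
    major_count: int
    pct_major: float
    n: int


def outlier_summary(values: Sequence[float]) -> OutlierSummary:
    """Tukey box-plot summary: quartiles, 1.5 IQR fences, outlier counts.

    Quartiles use linear interpolation between order statistics.  Minor
    outliers lie strictly between the 75th percentile and the upper fence;
    major outliers exceed the upper fence.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("insufficient data: need >= 4 values")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    minor = int(np.sum((v > q75) & (v < hi)))
    major = int(np.sum(v > hi))
    return OutlierSummary(
        q25=float(q25), q50=float(q50), q75=float(q75), iqr=float(iqr),
        lower_fence=float(lo), upper_fence=float(hi),
        minor_count=minor, major_count=major,
        pct_major=100.0 * major / v.size, n=int(v.size))


def harmonize_table(
    df: pd.DataFrame,
    value_col: str = "olsen_p",
    bulk_density_col: Optional[str] = None,
    min_coverage: float = 0.0,
) -> pd.DataFrame:
    """Full depth standardization of a converted sample table.

    Groups rows by site key (rounded coordinates + year), combines depth
    layers into one 0-20 cm value, drops sites sampled only below 20 cm, and
    merges duplicates.  Returns one row per site x date with
    ``olsen_p_0_20``, ``n_layers_used`` and ``n_duplicates_merged``.
    """
    work = df.loc[df[value_col].notna()].copy()
    rows = []
    for _, g in work.assign(_key=_site_key(work)).groupby("_key", sort=False):
        n_raw = len(g)
        # exact repeats of a layer (same interval, same value) would otherwise
        # double-weight it in the profile mean
        g = g.drop_duplicates(subset=["depth_top", "depth_bottom", value_col])
        n_intervals = g[["depth_top", "depth_bottom"]].drop_duplicates().shape[0]
        layers = []
        for r in g.itertuples(index=False):
            bd = getattr(r, bulk_density_col, None) if bulk_density_col else None
            try:
                layers.append(ProfileLayer(
                    float(r.depth_top), float(r.depth_bottom),
                    float(getattr(r, value_col)),
                    None if bd is None or pd.isna(bd) else float(bd)))
            except ValueError:
                continue  # malformed layer: skip, conserved in filter report upstream
        if not layers:
            continue
        try:
            value = harmonize_profile(layers, min_coverage=min_coverage)
        except ProfileBelowWindowError:
            continue
        first = g.iloc[0]
        rows.append({
            "source_id": first.get("source_id", ""),
            "longitude": round(float(first["longitude"]), SITE_KEY_DECIMALS),
            "latitude": round(float(first["latitude"]), SITE_KEY_DECIMALS),
            "year": int(first["year"]) if "year" in g.columns else 0,
            "country": first.get("country", ""),
            "olsen_p_0_20": value,
            "n_layers_used": sum(
                1 for l in layers if overlap_weight(l) > 0),
            "n_duplicates_merged": n_raw - n_intervals,
            "converted_from": first.get("converted_from", ""),
        })
    return pd.DataFrame(rows)
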