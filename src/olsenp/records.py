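"""Canonical sample schema for multi-source soil phosphorus data.

Every ingested source is mapped onto one flat table whose columns mirror
:class:`SoilSampleRecord`.  Optional columns may be absent in input CSVs and
are filled with NA / defaults on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class Method(str, enum.Enum):
    """Soil phosphorus extraction test."""

    OLSEN = "olsen"
    BRAY1 = "bray1"
    MEHLICH3 = "mehlich3"
    RESIN = "resin"
    KIRSANOV = "kirsanov"
    ABDPTA = "abdpta"


class Assay(str, enum.Enum):
    """Phosphorus determination chemistry applied to the extract."""

    MOLYBDENUM_BLUE = "molybdenum_blue"
    ION_CHROMATOGRAPHY = "ion_chromatography"
    STANNOUS_CHLORIDE = "stannous_chloride"
    UNKNOWN = "unknown"


class Unit(str, enum.Enum):
    MASS = "mass"          # mg P per kg soil
    VOLUMETRIC = "volumetric"  # mg P per L; not convertible, excluded


class SoilClass(str, enum.Enum):
    CALCAREOUS = "calcareous"
    NON_CALCAREOUS = "non_calcareous"
    UNKNOWN = "unknown"
    ANY = "any"


@dataclass
class SoilSampleRecord:
    """One raw soil-test phosphorus measurement.

    Concentrations are mg P kg^-1 soil for ``unit='mass'``; depths are cm
    below the surface with ``depth_bottom > depth_top >= 0``.
    """

    source_id: str
    sample_id: str
    longitude: float
    latitude: float
    year: int
    depth_top: float
    depth_bottom: float
    method: Method
    assay: Assay
    value: float
    unit: Unit = Unit.MASS
    below_detection: bool = False
    pH: Optional[float] = None
    soil_class: SoilClass = SoilClass.UNKNOWN
    country: str = ""
    province: Optional[str] = None
    land_use: Optional[str] = None

    def validate(self) -> None:
        if not (self.depth_bottom > self.depth_top >= 0):
            raise ValueError(
                f"invalid depth interval [{self.depth_top}, {self.depth_bottom}]"
            )
        if self.value is not None and not np.isnan(self.value) and self.value < 0:
            raise ValueError(f"invalid concentration {self.value}")
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError(
                f"coordinates out of range ({self.longitude}, {self.latitude})"
            )


#: Columns of the canonical sample table, in write order.
SAMPLE_COLUMNS = [
    "source_id", "sample_id", "longitude", "latitude", "year",
    "depth_top", "depth_bottom", "method", "assay", "value", "unit",
    "below_detection", "pH", "soil_class", "country", "province", "land_use",
]

_DEFAULTS = {
    "assay": Assay.UNKNOWN.value,
    "unit": Unit.MASS.value,
    "below_detection": False,
    "pH": np.nan,
    "soil_class": SoilClass.UNKNOWN.value,
    "country": "",
    "province": "",
    "land_use": "",
}


def read_samples(path) -> pd.DataFrame:
    """Read a canonical sample CSV, filling absent optional columns."""
    df = pd.read_csv(path)
    missing = [c for c in ("source_id", "longitude", "latitude", "year",
                           "depth_top", "depth_bottom", "method", "value")
               if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing required columns: {missing}")
    for col, default in _DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    if "sample_id" not in df.columns:
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
    df["below_detection"] = df["below_detection"].fillna(False).astype(bool)
    return df[SAMPLE_COLUMNS + [c for c in df.columns if c not in SAMPLE_COLUMNS]]


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class SourceManifest:
    """Per-source metadata: time-window exemptions and known detection limits."""

    exempt_sources: set = field(default_factory=set)
    detection_limits: dict = field(default_factory=dict)  # source_id -> mg/kg

    @classmethod
    def from_csv(cls, path) -> "SourceManifest":
        df = pd.read_csv(path)
        exempt = set(df.loc[df.get("exempt", pd.Series(False, index=df.index))
                            .fillna(False).astype(bool), "source_id"])
        limits = {
            r.source_id: float(r.detection_limit)
            for r in df.itertuples()
            if "detection_limit" in df.columns and pd.notna(r.detection_limit)
        }
        return cls(exempt_sources=exempt, detection_limits=limits)
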