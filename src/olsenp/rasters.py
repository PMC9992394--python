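"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Grids are cell-center registered in WGS84 decimal degrees.  Row 0 of ``data``
is the NORTHERN-most row, matching the ASCII-grid convention.  This container
covers everything the pipeline needs from a raster: nearest-cell sampling at
point coordinates, alignment checks, and round-tripping through a text format
that any GIS can read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    data: np.ndarray            # 2D, row 0 = north
    xll: float                  # x of the lower-left cell *corner* (deg)
    yll: float                  # y of the lower-left cell corner (deg)
    cellsize: float             # deg
    nodata: float = -9999.0
    labels: dict = field(default_factory=dict)  # int code -> label (categorical)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self):
        """(xmin, ymin, xmax, ymax) outer edges."""
        return (self.xll, self.yll,
                self.xll + self.ncols * self.cellsize,
                self.yll + self.nrows * self.cellsize)

    def same_grid(self, other: "Raster") -> bool:
        return (self.data.shape == other.data.shape
                and math.isclose(self.xll, other.xll, abs_tol=1e-9)
                and math.isclose(self.yll, other.yll, abs_tol=1e-9)
                and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12))

    def index_of(self, lon: float, lat: float):
        """(row, col) of the cell containing the point; None if off-grid."""
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmin <= lon < xmax and ymin < lat <= ymax):
            # tolerate points exactly on the east/south outer edge
            if not (math.isclose(lon, xmax) or math.isclose(lat, ymin)):
                return None
        col = min(int((lon - xmin) / self.cellsize), self.ncols - 1)
        row = min(int((ymax - lat) / self.cellsize), self.nrows - 1)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            return None
        return row, col

    def sample(self, lon: float, lat: float) -> float:
        """Nearest-cell (containing-cell) value; NaN off grid or at nodata."""
        idx = self.index_of(lon, lat)
        if idx is None:
            return float("nan")
        v = self.data[idx]
        return float("nan") if v == self.nodata else float(v)

    def cell_centers(self):
        """(lon2d, lat2d) arrays of cell-center coordinates."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def cell_area_m2(self) -> np.ndarray:
        """Per-cell area on the WGS84 sphere (cos-latitude approximation)."""
        r_earth = 6_371_000.0
        deg = math.pi / 180.0
        _, lat = self.cell_centers()
        return (self.cellsize * deg * r_earth) ** 2 * np.cos(lat * deg)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.xll, self.yll,
                      self.cellsize, self.nodata, dict(self.labels))

    # ---- text I/O ---------------------------------------------------------

    def write_ascii(self, path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll!r}\n"
            f"yllcorner {self.yll!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        body = np.where(np.isnan(self.data), self.nodata, self.data)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")
        if self.labels:
            lab = path.with_suffix(".labels.csv")
            with open(lab, "w") as fh:
                fh.write("code,label\n")
                for code, label in sorted(self.labels.items()):
                    fh.write(f"{code},{label}\n")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        path = Path(path)
        header = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        labels = {}
        lab = path.with_suffix(".labels.csv")
        if lab.exists():
            import csv
            with open(lab) as fh:
                for row in csv.DictReader(fh):
                    labels[int(row["code"])] = row["label"]
        r = cls(data, header["xllcorner"], header["yllcorner"],
                header["cellsize"], nodata, labels)
        if r.nrows != int(header["nrows"]) or r.ncols != int(header["ncols"]):
            raise ValueError(f"grid shape does not match header in {path}")
        return r
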