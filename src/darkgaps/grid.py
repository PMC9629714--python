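"""Regular lon/lat grids and rasters.

All rasters in the package share one convention: cells are half-open
``[west, west + dx) x [south, south + dx)`` squares in WGS84 degrees, row 0
at the south, column 0 at the west.  Missing cells are NaN.  Rasters are
written as ESRI ASCII grids (plain text, north-up, ``NODATA_value``), which
any GIS stack reads directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


class GridError(ValueError):
    """Raised for inconsistent grid geometry or out-of-extent lookups."""


class OutsideExtentError(GridError):
    """A queried point falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    west, south, east, north:
        Extent in degrees; ``west < east``, ``south < north``.
    cell_size_deg:
        Square cell size in degrees.  Must divide both extent spans exactly
        (to within 1e-9 of a whole number of cells).
    """

    west: float
    south: float
    east: float
    north: float
    cell_size_deg: float

    def __post_init__(self) -> None:
        if not (self.west < self.east and self.south < self.north):
            raise GridError("empty extent: need west < east and south < north")
        if self.cell_size_deg <= 0:
            raise GridError("cell_size_deg must be positive")
        for span, name in ((self.east - self.west, "lon"),
                           (self.north - self.south, "lat")):
            n = span / self.cell_size_deg
            if abs(n - round(n)) > 1e-9:
                raise GridError(
                    f"cell_size_deg {self.cell_size_deg} does not divide the "
                    f"{name} span {span} into a whole number of cells")

    @property
    def ncols(self) -> int:
        return int(round((self.east - self.west) / self.cell_size_deg))

    @property
    def nrows(self) -> int:
        return int(round((self.north - self.south) / self.cell_size_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.west) & (lon < self.east)
                & (lat >= self.south) & (lat < self.north))

    def cell_index(self, lon, lat):
        """Row/column of the half-open cell containing each point.

        Points on a cell's west or south edge belong to that cell; points on
        the grid's east or north boundary are outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not np.all(self.contains(lon, lat)):
            bad_lon = lon[~self.contains(lon, lat)] if lon.ndim else lon
            raise OutsideExtentError(
                f"point(s) outside extent [{self.west},{self.east})x"
                f"[{self.south},{self.north}): e.g. lon={np.atleast_1d(bad_lon).ravel()[0]}")
        col = np.floor((lon - self.west) / self.cell_size_deg).astype(np.int64)
        row = np.floor((lat - self.south) / self.cell_size_deg).astype(np.int64)
        # guard against float round-off exactly at the boundary
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.west + (col + 0.5) * self.cell_size_deg
        lat = self.south + (row + 0.5) * self.cell_size_deg
        return lon, lat

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (nrows, ncols) of every cell center."""
        rows, cols = np.mgrid[0:self.nrows, 0:self.ncols]
        return self.cell_center(rows, cols)


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`; NaN marks missing cells."""

    spec: GridSpec
    values: np.ndarray
    layer: str = "values"
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}")

    def value_at(self, lon, lat):
        """Value of the containing cell (no resampling); NaN for missing."""
        row, col = self.spec.cell_index(lon, lat)
        return self.values[row, col]

    def same_geometry(self, other: "Raster") -> bool:
        return self.spec == other.spec

    def copy_with(self, values: np.ndarray, layer: str | None = None) -> "Raster":
        return Raster(self.spec, np.array(values, dtype=float),
                      layer=layer or self.layer, units=self.units)

    # ---- ESRI ASCII grid I/O -------------------------------------------

    def write_ascii(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        vals = np.where(np.isnan(self.values), NODATA, self.values)
        header = (f"ncols {self.spec.ncols}\n"
                  f"nrows {self.spec.nrows}\n"
                  f"xllcorner {self.spec.west!r}\n"
                  f"yllcorner {self.spec.south!r}\n"
                  f"cellsize {self.spec.cell_size_deg!r}\n"
                  f"NODATA_value {NODATA}\n")
        with open(path, "w") as fh:
            fh.write(header)
            # ESRI convention: first data row is the northernmost
            np.savetxt(fh, vals[::-1], fmt="%.10g")
        return path

    @classmethod
    def read_ascii(cls, path: str | Path, layer: str = "values") -> "Raster":
        path = Path(path)
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)[::-1]  # back to row 0 = south
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        cell = hdr["cellsize"]
        spec = GridSpec(west=hdr["xllcorner"], south=hdr["yllcorner"],
                        east=hdr["xllcorner"] + ncols * cell,
                        north=hdr["yllcorner"] + nrows * cell,
                        cell_size_deg=cell)
        vals = np.where(data == hdr.get("nodata_value", NODATA), np.nan, data)
        return cls(spec, vals, layer=layer)
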