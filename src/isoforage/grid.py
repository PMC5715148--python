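"""Regular lon/lat grids and rasters.

The study area is a regular geographic grid (square cells in degrees).
Rasters are stored north-up: row 0 holds the northernmost cell centers.
Cells can be masked out (land / off-shelf); masked cells carry NaN in
every raster defined on the grid.

Text I/O uses the ESRI ASCII grid format (``.asc``), which any GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

NODATA = -9999.0


@dataclass
class GridSpec:
    """Bounding box + cell size + ocean mask defining the study grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Bounding box in decimal degrees.
    cell_size
        Cell edge in degrees (> 0). The box extents must be whole
        multiples of the cell size.
    crs
        Identifier only; all math is geographic.
    mask
        Boolean array, shape ``(nrows, ncols)``; True = usable (ocean)
        cell. Defaults to all-True.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float
    crs: str = "EPSG:4326"
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        for lo, hi, name in (
            (self.lon_min, self.lon_max, "lon"),
            (self.lat_min, self.lat_max, "lat"),
        ):
            n = (hi - lo) / self.cell_size
            if hi <= lo or abs(n - round(n)) > 1e-8:
                raise ConfigurationError(
                    f"{name} extent must be a positive whole multiple of cell_size"
                )
        if self.mask is None:
            self.mask = np.ones((self.nrows, self.ncols), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.nrows, self.ncols):
                raise ConfigurationError(
                    f"mask shape {self.mask.shape} does not match grid "
                    f"({self.nrows}, {self.ncols})"
                )

    @property
    def ncols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def nrows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (row order)."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinates as two (nrows, ncols) arrays."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def contains(self, lon: float, lat: float) -> bool:
        return (self.lon_min <= lon <= self.lon_max) and (
            self.lat_min <= lat <= self.lat_max
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (point on the max edge
        snaps inward)."""
        if not self.contains(lon, lat):
            raise ConfigurationError(f"point ({lon}, {lat}) outside grid")
        col = min(int((lon - self.lon_min) / self.cell_size), self.ncols - 1)
        row = min(int((self.lat_max - lat) / self.cell_size), self.nrows - 1)
        return row, col

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            np.allclose(
                [self.lon_min, self.lon_max, self.lat_min, self.lat_max, self.cell_size],
                [other.lon_min, other.lon_max, other.lat_min, other.lat_max, other.cell_size],
            )
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`; masked cells are NaN."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        self.values = np.where(self.grid.mask, self.values, np.nan)

    def masked_values(self) -> np.ndarray:
        """Values at masked-in cells, flat array."""
        return self.values[self.grid.mask]

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, values)

    # -- text I/O ---------------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid (text, north-up)."""
        g = self.grid
        out = np.where(np.isnan(self.values), NODATA, self.values)
        header = (
            f"ncols {g.ncols}\nnrows {g.nrows}\n"
            f"xllcorner {g.lon_min}\nyllcorner {g.lat_min}\n"
            f"cellsize {g.cell_size}\nNODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @staticmethod
    def read_ascii(path: str | Path, crs: str = "EPSG:4326") -> "Raster":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh)
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        cs = hdr["cellsize"]
        values = values.reshape(nrows, ncols)
        nodata = hdr.get("nodata_value", NODATA)
        values = np.where(values == nodata, np.nan, values)
        grid = GridSpec(
            lon_min=hdr["xllcorner"],
            lon_max=hdr["xllcorner"] + ncols * cs,
            lat_min=hdr["yllcorner"],
            lat_max=hdr["yllcorner"] + nrows * cs,
            cell_size=cs,
            crs=crs,
            mask=~np.isnan(values),
        )
        return Raster(grid, values)


def great_circle_deg(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle separation between points, in degrees of arc.

    Haversine formula; inputs broadcast. Using arc degrees (rather than
    km) keeps variogram ranges on the same scale as the grid.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return np.degrees(2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def pairwise_great_circle_deg(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Full pairwise great-circle distance matrix in arc degrees."""
    return great_circle_deg(
        lons[:, None], lats[:, None], lons[None, :], lats[None, :]
    )
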