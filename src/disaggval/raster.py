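"""Single-band raster grids with a minimal geospatial transform.

A :class:`RasterLayer` is a north-up rectangular grid of floats with a
missing-value mask, an origin (top-left corner), a square cell size and a CRS
descriptor.  Two CRS families are supported: ``"planar_m"`` (coordinates in
metres, the default for synthetic scenes) and ``"geographic"`` (longitude /
latitude in degrees, with distances computed on a local equirectangular
metric).  GeoTIFF read/write goes through :mod:`tifffile` using the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

#: metres per degree of latitude (spherical approximation)
M_PER_DEG_LAT = 111_320.0


@dataclass
class RasterLayer:
    """A single-band raster with mask, transform and CRS descriptor.

    Parameters
    ----------
    values : ndarray
        2-d array of cell values, row 0 at the top (north).
    x_origin, y_origin : float
        Coordinates of the *top-left corner* of the grid.
    cell_size : float
        Square cell edge length, in CRS units (metres for ``planar_m``,
        degrees for ``geographic``).
    crs : str
        ``"planar_m"`` or ``"geographic"``.
    name : str
        Layer label used in output tables.
    mask : ndarray of bool, optional
        True where the cell is missing.  Defaults to all-valid.
    binary : bool
        Marks presence/absence layers (e.g. settlement masks) whose only
        meaningful zonal statistic is the mean.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "planar_m"
    name: str = "layer"
    mask: np.ndarray | None = field(default=None)
    binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-d array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs not in ("planar_m", "geographic"):
            raise ValueError(f"unknown crs {self.crs!r}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, same shape as values."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (x, y), or None when outside."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def center_distances_m(self, x: float, y: float) -> np.ndarray:
        """Distance in metres from (x, y) to every cell center.

        Planar CRS distances are Euclidean; geographic coordinates use a
        local equirectangular approximation centred on the query point,
        adequate for buffer radii of a few tens of km.
        """
        cx, cy = self.cell_centers()
        if self.crs == "geographic":
            dx = (cx - x) * M_PER_DEG_LAT * np.cos(np.deg2rad(y))
            dy = (cy - y) * M_PER_DEG_LAT
        else:
            dx = cx - x
            dy = cy - y
        return np.hypot(dx, dy)

    def contains(self, x: float, y: float) -> bool:
        return self.index_of(x, y) is not None


def write_geotiff(layer: RasterLayer, path, nodata: float = -9999.0, dtype=np.float32) -> None:
    """Write a layer as single-band GeoTIFF with geo tags.

    float32 by default; pass ``dtype=np.float64`` for lossless round trips.
    """
    data = layer.values.astype(dtype).copy()
    data[layer.mask] = nodata
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(layer.cell_size), float(layer.cell_size), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(layer.x_origin), float(layer.y_origin), 0.0)),
        (_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    desc = f"crs={layer.crs};name={layer.name};binary={int(layer.binary)}"
    try:
        tifffile.imwrite(str(path), data, extratags=extratags, description=desc)
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise OSError(f"failed to write raster to {path}: {exc}") from exc


def read_geotiff(path) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(float)
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tiepoint = page.tags[_MODEL_TIEPOINT].value
            nodata_tag = page.tags.get(_GDAL_NODATA)
            desc_tag = page.tags.get("ImageDescription")
    except OSError as exc:
        raise OSError(f"failed to read raster from {path}: {exc}") from exc
    crs, name, binary = "planar_m", "layer", False
    if desc_tag is not None:
        for part in str(desc_tag.value).split(";"):
            if part.startswith("crs="):
                crs = part[4:]
            elif part.startswith("name="):
                name = part[5:]
            elif part.startswith("binary="):
                binary = bool(int(part[7:]))
    mask = None
    if nodata_tag is not None:
        nodata = float(nodata_tag.value)
        mask = data == nodata
        data = np.where(mask, np.nan, data)
    return RasterLayer(
        values=data,
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        cell_size=float(scale[0]),
        crs=crs,
        name=name,
        mask=mask,
        binary=binary,
    )
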