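"""Lightweight georeferenced raster container and GeoTIFF/CSV I/O.

Rasters live on an axis-aligned grid in scene (map) coordinates: the origin
``(x0, y0)`` is the top-left corner of the top-left pixel, x grows to the
right and y grows downward, and pixels are square with side ``gsd`` metres.
Values are stored band-major as ``(n_bands, n_rows, n_cols)`` float arrays
with a sentinel nodata value (default -9999).

GeoTIFF round-tripping is implemented with :mod:`tifffile` using the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA); band names
travel in a JSON ImageDescription.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid (origin, pixel size, shape)."""

    x0: float
    y0: float
    gsd: float
    n_rows: int
    n_cols: int

    def cell_center(self, row, col):
        """Map coordinates of pixel centers (vectorized over row/col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.gsd
        y = self.y0 + (np.asarray(row) + 0.5) * self.gsd
        return x, y

    def cell_of(self, x, y):
        """Row/col indices of the cells containing points (x, y); half-open cells."""
        col = np.floor((np.asarray(x) - self.x0) / self.gsd).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.gsd).astype(int)
        return row, col


@dataclass
class Raster:
    """Multi-band raster: ``data`` has shape (n_bands, n_rows, n_cols)."""

    data: np.ndarray
    bands: tuple
    x0: float = 0.0
    y0: float = 0.0
    gsd: float = 1.0
    nodata: float = NODATA

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("raster data must be 2-D or (band, row, col) 3-D")
        self.bands = tuple(self.bands)
        if len(self.bands) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.bands)} band names for {self.data.shape[0]} data bands"
            )
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")

    @property
    def n_rows(self):
        return self.data.shape[1]

    @property
    def n_cols(self):
        return self.data.shape[2]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.x0, self.y0, self.gsd, self.n_rows, self.n_cols)

    def band(self, name) -> np.ndarray:
        """2-D view of a named band."""
        try:
            return self.data[self.bands.index(name)]
        except ValueError:
            raise KeyError(f"band {name!r} not in {self.bands}") from None

    def valid_mask(self) -> np.ndarray:
        """Cells where every band is valid (not nodata, finite)."""
        return np.all(np.isfinite(self.data) & (self.data != self.nodata), axis=0)

    def with_data(self, data, bands=None) -> "Raster":
        return Raster(
            data,
            self.bands if bands is None else bands,
            self.x0,
            self.y0,
            self.gsd,
            self.nodata,
        )


def fvc_raster(values, grid: GridSpec = None, **kw) -> Raster:
    """Wrap a 2-D cover-fraction array as a single-band FVC raster."""
    if grid is not None:
        kw.setdefault("x0", grid.x0)
        kw.setdefault("y0", grid.y0)
        kw.setdefault("gsd", grid.gsd)
    return Raster(values, ("fvc",), **kw)


def write_geotiff(path, raster: Raster) -> None:
    desc = json.dumps({"bands": list(raster.bands)})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.gsd, raster.gsd, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.x0, raster.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    data = raster.data.astype(np.float32)
    kw = {}
    if data.shape[0] == 1:
        data = data[0]
    else:
        kw["planarconfig"] = "separate"
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
        **kw,
    )


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing georeferencing tags") from exc
        nodata = NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        bands = None
        desc = page.description
        if desc:
            try:
                bands = json.loads(desc).get("bands")
            except (json.JSONDecodeError, AttributeError):
                bands = None
    if data.ndim == 2:
        data = data[None]
    if bands is None:
        bands = [f"band{i + 1}" for i in range(data.shape[0])]
    return Raster(
        data,
        tuple(bands),
        x0=float(tie[3]),
        y0=float(tie[4]),
        gsd=float(scale[0]),
        nodata=nodata,
    )
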