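"""Georeferenced single-band raster grids (2-m benthic-cover maps).

A :class:`RasterGrid` carries a 2-D float array plus the minimal
georeferencing needed to round-trip a north-up GeoTIFF: origin, pixel
size, CRS string and nodata value.  I/O is implemented over ``tifffile``
writing the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA) so the files open in GIS tools; the CRS is carried in the
ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """Single-band north-up raster with simple affine georeferencing."""

    data: np.ndarray  # 2-D float array, row 0 = northernmost
    x_origin: float = 0.0  # west edge of pixel (0, 0)
    y_origin: float = 0.0  # north edge of pixel (0, 0)
    pixel_size: float = 2.0  # metres (square pixels)
    crs: str = "EPSG:32605"
    nodata: float = -9999.0
    band: str = "lcc_percent"  # semantic label of the band
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.crs:
            raise ValueError("CRS metadata is required")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        return ~np.isclose(self.data, self.nodata) & np.isfinite(self.data)

    def like(self, data: np.ndarray, band: str) -> "RasterGrid":
        """New grid with identical georeferencing but different values."""
        return RasterGrid(
            data=data,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            pixel_size=self.pixel_size,
            crs=self.crs,
            nodata=self.nodata,
            band=band,
            meta=dict(self.meta),
        )

    def valid_values(self) -> np.ndarray:
        return self.data[self.mask]


def write_geotiff(grid: RasterGrid, path: str | Path) -> None:
    description = json.dumps(
        {"crs": grid.crs, "band": grid.band, **grid.meta}, sort_keys=True
    )
    extratags = [
        (
            _TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (grid.pixel_size, grid.pixel_size, 0.0),
            True,
        ),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0),
            True,
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata), True),
    ]
    tifffile.imwrite(
        Path(path),
        grid.data,
        description=description,
        extratags=extratags,
    )


def read_geotiff(path: str | Path) -> RasterGrid:
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata = float(tags[_TAG_GDAL_NODATA].value)
        desc = tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: missing CRS metadata")
        info = json.loads(desc.value)
    meta = {k: v for k, v in info.items() if k not in ("crs", "band")}
    return RasterGrid(
        data=data,
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        crs=str(info["crs"]),
        nodata=nodata,
        band=str(info.get("band", "lcc_percent")),
        meta=meta,
    )
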