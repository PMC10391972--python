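"""Planar raster grids with a validity mask, plus Esri ASCII and GeoTIFF I/O.

All surface operations in this package share one raster convention: values
are stored row-major with row 0 at the top, the grid origin is the *top-left
cell corner*, and per-cell values are registered at cell centers.  Pairwise
operations between grids require identical shape, origin and cell size —
silent resampling is never attempted.

Coordinates are planar (synthetic-world units); there is no CRS handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RasterGrid", "GeometryError", "read_raster", "write_raster"]

_DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes (single-band, planar "geo" registration only)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GeometryError(ValueError):
    """Raised when two rasters that must share geometry do not."""


@dataclass
class RasterGrid:
    """A 2-D grid of values with an explicit validity mask.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top.  Values on invalid cells are
        ignored (and stored as NaN internally for safety).
    mask
        2-D boolean array, ``True`` where the cell holds a valid value.
    origin_x, origin_y
        Planar coordinates of the top-left corner of cell (0, 0).
    cell_size
        Edge length of a (square) cell, > 0.
    """

    values: np.ndarray
    mask: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite on valid cells")
        # normalize storage: invalid cells hold NaN
        self.values = np.where(self.mask, self.values, np.nan)

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "RasterGrid", *, check_mask: bool = False) -> bool:
        if self.shape != other.shape:
            return False
        if not (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        ):
            return False
        if check_mask and not np.array_equal(self.mask, other.mask):
            return False
        return True

    def require_same_geometry(self, other: "RasterGrid", *, check_mask: bool = False) -> None:
        if not self.same_geometry(other, check_mask=check_mask):
            raise GeometryError(
                f"raster geometry mismatch: {self.shape}@({self.origin_x},{self.origin_y},"
                f"{self.cell_size}) vs {other.shape}@({other.origin_x},{other.origin_y},"
                f"{other.cell_size})"
            )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays of the grid shape."""
        nrows, ncols = self.shape
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, (nrows, ncols)).copy(), np.broadcast_to(
            y[:, None], (nrows, ncols)
        ).copy()

    # -- convenience -------------------------------------------------------

    def copy_with(self, values: np.ndarray | None = None, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            values=self.values.copy() if values is None else values,
            mask=self.mask.copy() if mask is None else mask,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
        )

    def __eq__(self, other: object) -> bool:  # value/mask/geometry equality
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return (
            self.same_geometry(other, check_mask=True)
            and np.allclose(
                self.values[self.mask], other.values[other.mask], rtol=0, atol=0, equal_nan=True
            )
        )


# ---------------------------------------------------------------------------
# Esri ASCII grid
# ---------------------------------------------------------------------------

def _write_ascii(grid: RasterGrid, path: Path, nodata: float = _DEFAULT_NODATA) -> None:
    nrows, ncols = grid.shape
    # Esri headers use the lower-left corner
    yll = grid.origin_y - nrows * grid.cell_size
    out = np.where(grid.mask, grid.values, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(grid.origin_x)!r}\n"
        f"yllcorner {float(yll)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {float(nodata)!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out)
    path.write_text(header + body + "\n")


def _read_ascii(path: Path) -> RasterGrid:
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"Esri ASCII grid missing header field '{key}': {path}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    data = np.loadtxt(lines[i:], dtype=float).reshape(nrows, ncols)
    mask = data != nodata
    origin_y = header["yllcorner"] + nrows * header["cellsize"]
    return RasterGrid(
        values=data, mask=mask,
        origin_x=header["xllcorner"], origin_y=origin_y, cell_size=header["cellsize"],
    )


# ---------------------------------------------------------------------------
# Minimal single-band GeoTIFF (pixel scale + tiepoint + GDAL nodata tags)
# ---------------------------------------------------------------------------

def _write_geotiff(grid: RasterGrid, path: Path, nodata: float = _DEFAULT_NODATA) -> None:
    out = np.where(grid.mask, grid.values, nodata).astype(np.float64)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), True),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        if data.ndim != 2:
            raise ValueError(f"only single-band GeoTIFFs are supported: {path}")
        if scale is None or tiepoint is None:
            raise ValueError(f"GeoTIFF missing ModelPixelScale/ModelTiepoint tags: {path}")
        cell_size = float(scale.value[0])
        # tiepoint maps raster (0,0) to the top-left corner coordinate
        origin_x, origin_y = float(tiepoint.value[3]), float(tiepoint.value[4])
        nodata = float(nodata_tag.value) if nodata_tag is not None else _DEFAULT_NODATA
    mask = data != nodata
    return RasterGrid(values=data, mask=mask, origin_x=origin_x, origin_y=origin_y,
                      cell_size=cell_size)


def read_raster(path: str | Path) -> RasterGrid:
    """Read an Esri ASCII grid (``.asc``/``.txt``) or single-band GeoTIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_ascii(path)


def write_raster(grid: RasterGrid, path: str | Path, nodata: float = _DEFAULT_NODATA) -> None:
    """Write a grid as Esri ASCII (default) or GeoTIFF (``.tif``/``.tiff``).

    ``write_raster`` followed by :func:`read_raster` reproduces values, mask
    and geometry exactly (float64 round trip through ``repr`` for ASCII).
    """
    path = Path(path)
    if np.any(grid.values[grid.mask] == nodata):
        raise ValueError("a valid cell equals the nodata sentinel; choose another nodata")
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(grid, path, nodata)
    else:
        _write_ascii(grid, path, nodata)
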