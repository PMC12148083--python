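"""Gridded-raster data model and I/O.

A :class:`GridRaster` is a uniform-cell 2-D field in projected map
coordinates with kilometre units.  Storage follows the convention of the
formats it reads and writes: row 0 is the top (northernmost) row, and map
``y`` increases northward.  ``origin_xy`` is the map coordinate of the
*lower-left corner* of the grid, so the centre of cell ``(row, col)`` sits
at::

    x = origin_x + (col + 0.5) * cell_size_km
    y = origin_y + (n_rows - row - 0.5) * cell_size_km

Two formats are supported: ESRI ASCII grid (plain text) and single-band
float GeoTIFF (via :mod:`tifffile`, carrying the standard ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags).  All distances are planar Euclidean
in km; the package assumes already-projected square-cell rasters and does
no reprojection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import tifffile

__all__ = [
    "GridRaster",
    "CellCoord",
    "read_raster",
    "write_raster",
    "cell_to_xy",
    "xy_to_cell",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class CellCoord(NamedTuple):
    """Grid cell address: ``row`` counted from the top, ``col`` from the left."""

    row: int
    col: int

    def is_adjacent8(self, other: "CellCoord") -> bool:
        """True iff the two cells differ and are within one king-move."""
        dr, dc = abs(self.row - other.row), abs(self.col - other.col)
        return max(dr, dc) == 1


@dataclass
class GridRaster:
    """Uniform-cell raster with extent and nodata semantics.

    Parameters
    ----------
    values
        ``(n_rows, n_cols)`` float array, row 0 = north.
    cell_size_km
        Edge length of the square cells in km (nominally 1.0).
    origin_xy
        Map coordinate of the lower-left grid corner.
    nodata_value
        Sentinel marking undefined cells; every non-nodata value must be
        finite.
    """

    values: np.ndarray
    cell_size_km: float = 1.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.cell_size_km <= 0:
            raise ValueError(f"cell_size_km must be positive, got {self.cell_size_km}")
        ox, oy = self.origin_xy
        self.origin_xy = (float(ox), float(oy))
        valid = self.values != self.nodata_value
        if not np.isfinite(self.values[valid]).all():
            raise ValueError("non-nodata values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata_value

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def same_geometry(self, other: "GridRaster", rtol: float = 1e-9) -> bool:
        """True iff shape, cell size, and origin agree."""
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size_km, other.cell_size_km, rel_tol=rtol)
            and math.isclose(self.origin_xy[0], other.origin_xy[0], rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.origin_xy[1], other.origin_xy[1], rel_tol=rtol, abs_tol=1e-9)
        )

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        """New raster sharing this raster's geometry and nodata sentinel."""
        return GridRaster(
            np.asarray(values, dtype=np.float64),
            cell_size_km=self.cell_size_km,
            origin_xy=self.origin_xy,
            nodata_value=self.nodata_value,
        )

    def iter_cells(self) -> Iterator[CellCoord]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield CellCoord(r, c)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridRaster):
            return NotImplemented
        return (
            self.same_geometry(other)
            and self.nodata_value == other.nodata_value
            and np.array_equal(self.values, other.values)
        )


def cell_to_xy(r: GridRaster, c: CellCoord) -> tuple[float, float]:
    """Map coordinates of the centre of cell ``c``."""
    row, col = c
    if not r.in_bounds(row, col):
        raise IndexError(f"cell {c!r} out of bounds for {r.shape} raster")
    ox, oy = r.origin_xy
    x = ox + (col + 0.5) * r.cell_size_km
    y = oy + (r.n_rows - row - 0.5) * r.cell_size_km
    return (x, y)


def xy_to_cell(r: GridRaster, x: float, y: float) -> CellCoord:
    """Cell containing map point ``(x, y)``; inverse of :func:`cell_to_xy`."""
    ox, oy = r.origin_xy
    col = int(math.floor((x - ox) / r.cell_size_km))
    row = r.n_rows - 1 - int(math.floor((y - oy) / r.cell_size_km))
    if not r.in_bounds(row, col):
        raise IndexError(f"point ({x}, {y}) outside raster extent")
    return CellCoord(row, col)


def cells_to_xy(r: GridRaster, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`cell_to_xy` (no bounds check)."""
    ox, oy = r.origin_xy
    x = ox + (np.asarray(cols) + 0.5) * r.cell_size_km
    y = oy + (r.n_rows - np.asarray(rows) - 0.5) * r.cell_size_km
    return x, y


# ---------------------------------------------------------------------------
# I/O

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "ascii-grid"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".grd", ".txt"):
        return "ascii-grid"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r} of {path}")


def read_raster(path: str | Path, format: str | None = None) -> GridRaster:
    """Read a raster file into a :class:`GridRaster`.

    ``format`` is ``"geotiff"`` or ``"ascii-grid"``; when ``None`` it is
    inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "ascii-grid":
        return _read_ascii(path)
    return _read_geotiff(path)


def write_raster(r: GridRaster, path: str | Path, format: str | None = None) -> Path:
    """Write ``r`` so that :func:`read_raster` recovers it bit-exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ascii-grid":
        _write_ascii(r, path)
    else:
        _write_geotiff(r, path)
    return path


def _read_ascii(path: Path) -> GridRaster:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=np.float64))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid {path} missing header field {req!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.concatenate(rows).reshape(n_rows, n_cols)
    except ValueError as exc:
        raise ValueError(f"ASCII grid {path}: body does not match header shape") from exc
    return GridRaster(
        values,
        cell_size_km=header["cellsize"],
        origin_xy=(header["xllcorner"], header["yllcorner"]),
        nodata_value=header.get("nodata_value", DEFAULT_NODATA),
    )


def _write_ascii(r: GridRaster, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {r.n_cols}\n")
        fh.write(f"nrows {r.n_rows}\n")
        fh.write(f"xllcorner {r.origin_xy[0]!r}\n")
        fh.write(f"yllcorner {r.origin_xy[1]!r}\n")
        fh.write(f"cellsize {r.cell_size_km!r}\n")
        fh.write(f"NODATA_value {r.nodata_value!r}\n")
        for row in r.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> GridRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"GeoTIFF {path} is not single-band")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"GeoTIFF {path} lacks georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_MODEL_TIEPOINT].value
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ValueError(f"GeoTIFF {path} has non-square cells ({sx} x {sy})")
        # tiepoint maps raster (0, 0) to the map coordinate of the upper-left
        # corner; convert to the lower-left origin used internally
        x_ul, y_ul = tie[3], tie[4]
        n_rows = values.shape[0]
        origin = (x_ul, y_ul - n_rows * sy)
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    return GridRaster(
        np.asarray(values, dtype=np.float64),
        cell_size_km=float(sx),
        origin_xy=origin,
        nodata_value=nodata,
    )


def _write_geotiff(r: GridRaster, path: Path) -> None:
    cs = r.cell_size_km
    x_ul = r.origin_xy[0]
    y_ul = r.origin_xy[1] + r.n_rows * cs
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x_ul, y_ul, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(r.nodata_value)),
    ]
    tifffile.imwrite(path, r.values, extratags=extratags)
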