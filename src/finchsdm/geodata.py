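"""Raster data model, terrain derivatives, aggregation and file I/O.

Grid convention
---------------
``values`` is a 2-D array with row 0 at the *top* of the map (raster
standard).  ``origin = (x0, y0)`` is the lower-left corner of the grid in a
projected metric coordinate system.  The centre of cell ``(row, col)`` is::

    x = x0 + (col + 0.5) * cell_size
    y = y_top - (row + 0.5) * cell_size,   y_top = y0 + nrows * cell_size

Supported file formats are ESRI ASCII grid (``.asc``/``.agr``/``.grd``) and
GeoTIFF (``.tif``/``.tiff``, via :mod:`tifffile` with ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "EnvStack",
    "PREDICTOR_NAMES",
    "slope_aspect",
    "aggregate_mean",
    "read_raster",
    "write_raster",
    "read_points_csv",
    "FormatError",
]

logger = logging.getLogger(__name__)

#: Canonical names of the twelve environmental predictor layers.
PREDICTOR_NAMES: tuple[str, ...] = (
    "pine_height",
    "tree_cover",
    "altitude",
    "summer_rainfall",
    "slope",
    "radiation",
    "northness",
    "shrub_cover",
    "t_may",
    "westness",
    "shrub_height",
    "t_july",
)


class FormatError(ValueError):
    """Raised when a raster or point file violates the expected format."""


@dataclass
class RasterGrid:
    """Single-band regular grid with square cells in projected metres.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values, row 0 at the top.
    cell_size : float
        Cell edge length in metres; must be positive.
    origin : tuple of float
        ``(x0, y0)`` of the lower-left corner of the grid.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data.  Defaults to all-valid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"nodata_mask shape {self.nodata_mask.shape} does not match "
                f"values shape {self.values.shape}"
            )
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def y_top(self) -> float:
        return self.origin[1] + self.shape[0] * self.cell_size

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of the centre of cell ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.y_top - (row + 0.5) * self.cell_size
        return x, y

    def cell_at(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing projected point (x, y)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.y_top - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
        )


@dataclass
class EnvStack:
    """Named collection of co-registered predictor grids.

    All layers must share shape, cell size and origin.  The default
    constructor enforces exactly the twelve canonical predictor names;
    pass ``require_full=False`` to hold an arbitrary subset.
    """

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    require_full: bool = True

    def __post_init__(self) -> None:
        if self.require_full:
            missing = set(PREDICTOR_NAMES) - set(self.layers)
            extra = set(self.layers) - set(PREDICTOR_NAMES)
            if missing or extra:
                raise ValueError(
                    f"EnvStack requires exactly the 12 predictors; "
                    f"missing={sorted(missing)}, unexpected={sorted(extra)}"
                )
        grids = list(self.layers.values())
        if grids:
            ref = grids[0]
            for name, g in self.layers.items():
                if g.shape != ref.shape or g.cell_size != ref.cell_size or g.origin != ref.origin:
                    raise ValueError(f"layer {name!r} is not co-registered with the stack")

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"missing layer {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def cell_size(self) -> float:
        return next(iter(self.layers.values())).cell_size

    @property
    def grid(self) -> RasterGrid:
        """A reference grid sharing the stack's geometry."""
        return next(iter(self.layers.values()))

    def combined_nodata(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def feature_matrix(
        self, rows: np.ndarray, cols: np.ndarray, names: Iterable[str] = PREDICTOR_NAMES
    ) -> np.ndarray:
        """n x p feature matrix for the given cells, columns in ``names`` order."""
        return np.column_stack([self[n].values[rows, cols] for n in names])


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Slope (percent) and aspect components from a DEM by Horn's method.

    Horn's 8-neighbour finite differences (the GRASS r.slope.aspect
    default).  Aspect is the downslope-facing direction measured clockwise
    from geographic north; it is returned decomposed as
    ``northness = cos(aspect)`` and ``westness = -sin(aspect)``, both in
    [-1, 1].  Flat cells get northness = westness = 0.  The one-cell border
    is flagged nodata in all three outputs.
    """
    z = dem.values
    nrows, ncols = z.shape
    if nrows < 3 or ncols < 3:
        raise ValueError(f"slope_aspect requires a grid of at least 3x3 cells, got {z.shape}")
    cs = dem.cell_size

    # 8-neighbour windows of the interior: letters follow the compass layout
    #   a b c      (a north-west of e, rows increase southwards)
    #   d e f
    #   g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]

    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)     # eastward gradient
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cs)     # northward gradient

    grad = np.hypot(dz_dx, dz_dy)
    slope_pct = np.full(z.shape, np.nan)
    slope_pct[1:-1, 1:-1] = 100.0 * grad

    # downslope unit vector is -(dz_dx, dz_dy) in (east, north) components
    north = np.zeros_like(grad)
    west = np.zeros_like(grad)
    nz = grad > 0
    north[nz] = -dz_dy[nz] / grad[nz]
    west[nz] = dz_dx[nz] / grad[nz]

    northness = np.full(z.shape, np.nan)
    westness = np.full(z.shape, np.nan)
    northness[1:-1, 1:-1] = north
    westness[1:-1, 1:-1] = west

    border = np.ones(z.shape, dtype=bool)
    border[1:-1, 1:-1] = False
    mask = border | dem.nodata_mask
    # any window touching a nodata cell is itself nodata
    if dem.nodata_mask.any():
        bad = dem.nodata_mask
        touch = np.zeros((nrows - 2, ncols - 2), dtype=bool)
        for dr in (0, 1, 2):
            for dc in (0, 1, 2):
                touch |= bad[dr:dr + nrows - 2, dc:dc + ncols - 2]
        interior_mask = np.zeros(z.shape, dtype=bool)
        interior_mask[1:-1, 1:-1] = touch
        mask |= interior_mask

    for arr in (slope_pct, northness, westness):
        arr[mask] = np.nan

    mk = lambda v: RasterGrid(v, dem.cell_size, dem.origin, mask.copy())
    return mk(slope_pct), mk(northness), mk(westness)


def aggregate_mean(r: RasterGrid, factor: int) -> RasterGrid:
    """Aggregate by block means with an integer ``factor``.

    Output cell size is ``factor * r.cell_size``; each output cell is the
    mean of the non-nodata inputs in its block, nodata if the block is
    fully nodata.  Trailing rows/columns not filling a complete block are
    dropped (logged).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    nrows, ncols = r.shape
    nr, nc = nrows // factor, ncols // factor
    if nr == 0 or nc == 0:
        raise ValueError(f"grid {r.shape} too small to aggregate by factor {factor}")
    if nrows % factor or ncols % factor:
        logger.warning(
            "aggregate_mean: dropping %d trailing row(s) and %d trailing column(s)",
            nrows % factor, ncols % factor,
        )
    vals = r.values[: nr * factor, : nc * factor]
    mask = r.nodata_mask[: nr * factor, : nc * factor]

    blocks = vals.reshape(nr, factor, nc, factor)
    bmask = mask.reshape(nr, factor, nc, factor)
    valid = ~bmask
    counts = valid.sum(axis=(1, 3))
    sums = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    out = np.full((nr, nc), np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]

    # lower-left corner is preserved only when no trailing rows are dropped;
    # the retained block starts at the top-left, so shift y0 accordingly.
    y0 = r.y_top - nr * factor * r.cell_size
    return RasterGrid(out, factor * r.cell_size, (r.origin[0], y0), ~has)


# ---------------------------------------------------------------------------
# File I/O


def read_raster(path: str | Path) -> RasterGrid:
    """Read a raster from an ESRI ASCII grid or GeoTIFF file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_esri_ascii(path)


def write_raster(r: RasterGrid, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write a raster as ESRI ASCII grid or GeoTIFF, by file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        _write_geotiff(r, path, nodata_value)
    else:
        _write_esri_ascii(r, path, nodata_value)


_ASC_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def _read_esri_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASC_HEADER_KEYS:
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}: malformed header line {line.strip()!r}") from exc
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing required header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        values = np.loadtxt(data_lines).reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"{path}: data block does not match ncols/nrows") from exc
    mask = np.zeros(values.shape, dtype=bool)
    if "nodata_value" in header:
        mask = values == header["nodata_value"]
        values = np.where(mask, np.nan, values)
    return RasterGrid(values, header["cellsize"], (header["xllcorner"], header["yllcorner"]), mask)


def _write_esri_ascii(r: RasterGrid, path: Path, nodata_value: float) -> None:
    vals = np.where(r.nodata_mask, nodata_value, r.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {r.shape[1]}\n")
        fh.write(f"nrows {r.shape[0]}\n")
        fh.write(f"xllcorner {r.origin[0]!r}\n")
        fh.write(f"yllcorner {r.origin[1]!r}\n")
        fh.write(f"cellsize {r.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise FormatError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise FormatError(f"{path}: missing georeferencing tags (ModelPixelScale/ModelTiepoint)")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        if not math.isclose(scale[0], scale[1]):
            raise FormatError(f"{path}: non-square cells not supported (cellsize x={scale[0]}, y={scale[1]})")
        cell_size = float(scale[0])
        # tiepoint maps raster (i, j, k) -> model (x, y, z); we write (0, 0) -> (x0, y_top)
        x0 = float(tie[3])
        y_top = float(tie[4])
        nrows = values.shape[0]
        y0 = y_top - nrows * cell_size
        mask = np.zeros(values.shape, dtype=bool)
        if _TAG_GDAL_NODATA in tags:
            nd = float(tags[_TAG_GDAL_NODATA].value)
            mask = (values == nd) | np.isnan(values)
            values = np.where(mask, np.nan, values)
        return RasterGrid(values, cell_size, (x0, y0), mask)


def _write_geotiff(r: RasterGrid, path: Path, nodata_value: float) -> None:
    import tifffile

    vals = np.where(r.nodata_mask, nodata_value, r.values).astype(np.float64)
    cs = float(r.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, r.origin[0], r.y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata_value))),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_points_csv(path: str | Path, x_col: str = "x", y_col: str = "y") -> pd.DataFrame:
    """Read a point table (CSV with header) requiring numeric x/y columns."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"point file not found: {path}")
    df = pd.read_csv(path)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    return df


def write_points_csv(df: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def stack_from_dir(path: str | Path, names: Iterable[str] = PREDICTOR_NAMES) -> EnvStack:
    """Load an EnvStack from a directory of ``<name>.asc`` / ``<name>.tif`` files."""
    path = Path(path)
    layers: dict[str, RasterGrid] = {}
    for name in names:
        for ext in (".asc", ".tif", ".tiff", ".grd"):
            p = path / f"{name}{ext}"
            if p.exists():
                layers[name] = read_raster(p)
                break
        else:
            raise FormatError(f"no raster file found for layer {name!r} in {path}")
    return EnvStack(layers)


def stack_to_dir(stack: EnvStack, path: str | Path, fmt: str = "asc") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        write_raster(grid, path / f"{name}.{fmt}")
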