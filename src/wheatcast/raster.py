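"""Georeferenced grid/cube data model, GeoTIFF I/O, resampling and masking.

Coordinate convention (used everywhere in the package): pixel-center
coordinates, row 0 at the top of the grid, 0-based indices, half-open pixel
extents.  The center of pixel ``(row, col)`` sits at::

    x = origin_x + (col + 0.5) * pixel_width
    y = origin_y - (row + 0.5) * pixel_height

where ``(origin_x, origin_y)`` is the map coordinate of the grid's top-left
*corner*.  No reprojection is performed; grids interoperate only when their
``crs_tag`` strings are equal.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "RasterGrid",
    "RasterCube",
    "read_raster",
    "write_raster",
    "read_cube",
    "write_cube",
    "resample_bilinear",
    "mask_where",
]

_DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes used for georeferencing metadata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular, axis-aligned raster grid.

    ``origin_x``/``origin_y`` are the map coordinates of the top-left corner;
    ``pixel_width``/``pixel_height`` are positive map units per pixel (the
    grid extends rightward and downward from the origin).
    """

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float
    n_rows: int
    n_cols: int
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_centers[n_cols], y_centers[n_rows]) map coordinates."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_width
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_height
        return xs, ys

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open containment test for a map coordinate."""
        return (
            self.origin_x <= x < self.origin_x + self.n_cols * self.pixel_width
            and self.origin_y - self.n_rows * self.pixel_height < y <= self.origin_y
        )

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Index of the pixel whose (half-open) extent contains (x, y)."""
        if not self.contains_point(x, y):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        col = int(np.floor((x - self.origin_x) / self.pixel_width))
        row = int(np.floor((self.origin_y - y) / self.pixel_height))
        return min(row, self.n_rows - 1), min(col, self.n_cols - 1)


@dataclass
class RasterGrid:
    """A single georeferenced band: values plus a per-pixel validity mask."""

    spec: GridSpec
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.spec.shape or self.valid.shape != self.spec.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match spec {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values in valid cells")

    @classmethod
    def full(cls, spec: GridSpec, value: float, valid: bool = True) -> "RasterGrid":
        return cls(
            spec,
            np.full(spec.shape, value, dtype=np.float64),
            np.full(spec.shape, valid, dtype=bool),
        )

    @classmethod
    def from_values(cls, spec: GridSpec, values: np.ndarray) -> "RasterGrid":
        """Grid valid wherever ``values`` is finite."""
        values = np.asarray(values, dtype=np.float64)
        valid = np.isfinite(values)
        out = np.where(valid, values, 0.0)
        return cls(spec, out, valid)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.spec, self.values.copy(), self.valid.copy())

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        return np.where(self.valid, self.values, np.nan)


@dataclass
class RasterCube:
    """Time-stamped stack of grids sharing one GridSpec."""

    spec: GridSpec
    timestamps: list[_dt.date]
    layers: list[RasterGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.layers):
            raise ValueError("one layer per timestamp required")
        for t0, t1 in zip(self.timestamps, self.timestamps[1:]):
            if t1 <= t0:
                raise ValueError("timestamps must be strictly increasing")
        for layer in self.layers:
            if layer.spec != self.spec:
                raise ValueError("all layers must share the cube's GridSpec")

    def __len__(self) -> int:
        return len(self.layers)

    def values_array(self) -> np.ndarray:
        """(T, rows, cols) value stack."""
        return np.stack([g.values for g in self.layers]) if self.layers else np.empty((0,) + self.spec.shape)

    def valid_array(self) -> np.ndarray:
        return np.stack([g.valid for g in self.layers]) if self.layers else np.empty((0,) + self.spec.shape, bool)

    @classmethod
    def from_arrays(
        cls,
        spec: GridSpec,
        timestamps: Sequence[_dt.date],
        values: np.ndarray,
        valid: np.ndarray | None = None,
    ) -> "RasterCube":
        values = np.asarray(values, dtype=np.float64)
        if valid is None:
            valid = np.isfinite(values)
            values = np.where(valid, values, 0.0)
        layers = [RasterGrid(spec, values[i], np.asarray(valid[i], bool)) for i in range(values.shape[0])]
        return cls(spec, list(timestamps), layers)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(grid: RasterGrid, path: str | Path, nodata: float = _DEFAULT_NODATA) -> Path:
    """Write a grid as a single-band GeoTIFF with a declared nodata sentinel.

    Invalid cells are stored as ``nodata``; georeferencing goes into the
    standard ModelPixelScale/ModelTiepoint tags and the CRS tag string into
    GeoAsciiParams.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.where(grid.valid, grid.values, nodata).astype(np.float64)
    spec = grid.spec
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.pixel_width, spec.pixel_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GEO_ASCII, "s", 0, spec.crs_tag + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    single-band float GeoTIFF carrying pixel-scale/tiepoint tags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such raster: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"expected a single-band raster, got shape {data.shape}")
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"raster lacks a readable geotransform: {path}") from exc
        crs_tag = "local"
        if _TAG_GEO_ASCII in tags:
            crs_tag = str(tags[_TAG_GEO_ASCII].value).rstrip("|\x00")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).rstrip("\x00"))
    spec = GridSpec(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        pixel_width=float(scale[0]),
        pixel_height=float(scale[1]),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        crs_tag=crs_tag,
    )
    values = np.asarray(data, dtype=np.float64)
    valid = np.isfinite(values)
    if nodata is not None:
        valid &= values != nodata
    return RasterGrid(spec, np.where(valid, values, 0.0), valid)


def write_cube(cube: RasterCube, directory: str | Path) -> Path:
    """Persist a cube as a directory of date-stamped GeoTIFFs + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for ts, layer in zip(cube.timestamps, cube.layers):
        name = f"{ts.isoformat()}.tif"
        write_raster(layer, directory / name)
        names.append(name)
    (directory / "manifest.json").write_text(
        json.dumps({"timestamps": [t.isoformat() for t in cube.timestamps], "files": names}, indent=2)
    )
    return directory


def read_cube(directory: str | Path) -> RasterCube:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    timestamps = [_dt.date.fromisoformat(t) for t in manifest["timestamps"]]
    layers = [read_raster(directory / name) for name in manifest["files"]]
    if not layers:
        raise ValueError(f"empty cube directory: {directory}")
    return RasterCube(layers[0].spec, timestamps, layers)


# ---------------------------------------------------------------------------
# Resampling and masking


def resample_bilinear(src: RasterGrid, target: GridSpec) -> RasterGrid:
    """Bilinear resampling between pixel-center grids.

    Each target pixel center is interpolated from the four surrounding source
    pixel centers.  Validity is conservative: a target cell is invalid if any
    source neighbor that receives nonzero weight is invalid, and if the target
    center falls outside the hull of source pixel centers.  Gap repair is
    deliberately left to the reconstruction stage.
    """
    if src.spec.crs_tag != target.crs_tag:
        raise ValueError(f"crs mismatch: {src.spec.crs_tag!r} vs {target.crs_tag!r}")
    sxs, sys_ = src.spec.pixel_centers()
    txs, tys = target.pixel_centers()
    if txs[-1] < sxs[0] - src.spec.pixel_width or txs[0] > sxs[-1] + src.spec.pixel_width or (
        tys[0] < sys_[-1] - src.spec.pixel_height or tys[-1] > sys_[0] + src.spec.pixel_height
    ):
        raise ValueError("source and target extents are disjoint")

    # Fractional source indices of target centers.
    fx = (txs - src.spec.origin_x) / src.spec.pixel_width - 0.5
    fy = (src.spec.origin_y - tys) / src.spec.pixel_height - 0.5
    inside_x = (fx >= 0) & (fx <= src.spec.n_cols - 1)
    inside_y = (fy >= 0) & (fy <= src.spec.n_rows - 1)

    i0 = np.clip(np.floor(fy).astype(int), 0, max(src.spec.n_rows - 2, 0))
    j0 = np.clip(np.floor(fx).astype(int), 0, max(src.spec.n_cols - 2, 0))
    wy = (fy - i0)[:, None]
    wx = (fx - j0)[None, :]
    i0 = i0[:, None]
    j0 = j0[None, :]
    i1 = np.minimum(i0 + 1, src.spec.n_rows - 1)
    j1 = np.minimum(j0 + 1, src.spec.n_cols - 1)

    v = src.values
    out = (
        v[i0, j0] * (1 - wy) * (1 - wx)
        + v[i0, j1] * (1 - wy) * wx
        + v[i1, j0] * wy * (1 - wx)
        + v[i1, j1] * wy * wx
    )
    m = src.valid
    # A neighbor only constrains validity when its bilinear weight is nonzero.
    ok = (
        (m[i0, j0] | ((1 - wy) * (1 - wx) == 0))
        & (m[i0, j1] | ((1 - wy) * wx == 0))
        & (m[i1, j0] | (wy * (1 - wx) == 0))
        & (m[i1, j1] | (wy * wx == 0))
    )
    ok &= inside_y[:, None] & inside_x[None, :]
    return RasterGrid(target, np.where(ok, out, 0.0), ok)


def mask_where(grid: RasterGrid, mask: RasterGrid) -> RasterGrid:
    """Keep grid cells where ``mask`` is valid and nonzero."""
    if grid.spec != mask.spec:
        raise ValueError("grid and mask must share a GridSpec")
    keep = grid.valid & mask.valid & (mask.values != 0)
    return RasterGrid(grid.spec, np.where(keep, grid.values, 0.0), keep)
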