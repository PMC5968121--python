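"""Planar raster grids, aligned stacks and plain-text (ESRI ASCII Grid) I/O.

Conventions
-----------
* north-up arrays: row 0 is the northernmost row;
* ``origin`` is the (x, y) of the lower-left *corner* of the grid;
* points are binned to cells over half-open intervals ``[edge, edge + cell_size)``;
* ``mask`` is ``True`` where a cell holds valid data.

No coordinate reference systems are handled: the grid is purely planar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0

__all__ = [
    "RasterGrid",
    "RasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "resample_align",
]


@dataclass
class RasterGrid:
    """A single 2-D raster layer on a regular planar grid.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values. Stored as float; categorical layers must hold integer
        values on every valid cell.
    mask : ndarray of bool, same shape
        ``True`` marks a valid cell.
    origin : (float, float)
        x, y of the lower-left corner.
    cell_size : float
        Side length of a (square) cell, > 0.
    categorical : bool
        Whether the layer holds class identifiers rather than a continuum.
    """

    values: np.ndarray
    mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.categorical:
            valid = self.values[self.mask]
            if valid.size and not np.allclose(valid, np.round(valid)):
                raise ValueError("categorical layer holds non-integer values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def rowcol_to_xy(self, rows, cols):
        """Cell-centre coordinates of (row, col) indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x0, y0 = self.origin
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.nrows - rows - 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x, y):
        """Bin points into cells; half-open [edge, edge + cell_size)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((y - y0) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, rows, cols):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return (rows >= 0) & (rows < self.nrows) & (cols >= 0) & (cols < self.ncols)

    # -- values -------------------------------------------------------------

    def valid_values(self) -> np.ndarray:
        """1-D array of the values on valid cells (row-major order)."""
        return self.values[self.mask]

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(),
            self.mask.copy(),
            self.origin,
            self.cell_size,
            self.categorical,
        )

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
        )


class RasterStack:
    """An ordered, aligned collection of named :class:`RasterGrid` layers.

    All layers must share shape, origin and cell size. On construction the
    masks are intersected and every layer is given the shared mask, so the
    stack presents one common validity footprint.
    """

    def __init__(self, layers: dict[str, RasterGrid]):
        if not layers:
            raise ValueError("a RasterStack needs at least one layer")
        self._layers: dict[str, RasterGrid] = {}
        first = next(iter(layers.values()))
        mask = np.ones(first.shape, dtype=bool)
        for name, layer in layers.items():
            if not layer.same_grid(first):
                raise ValueError(f"layer {name!r} is not aligned with the stack grid")
            mask &= layer.mask
        for name, layer in layers.items():
            g = layer.copy()
            g.mask = mask.copy()
            self._layers[name] = g
        self.mask = mask

    # -- mapping-like interface --------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n, g in self._layers.items() if not g.categorical]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, g in self._layers.items() if g.categorical]

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    @property
    def template(self) -> RasterGrid:
        """A masked copy of the first layer, handy as a geometry template."""
        return next(iter(self._layers.values()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.template.shape

    @property
    def cell_size(self) -> float:
        return self.template.cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return self.template.origin

    def valid_rowcol(self):
        """(rows, cols) arrays of all valid cells, row-major order."""
        rows, cols = np.nonzero(self.mask)
        return rows, cols

    def table(self, rows=None, cols=None):
        """Per-cell predictor table as a pandas DataFrame (one row per cell).

        Defaults to all valid cells in row-major order.
        """
        import pandas as pd

        if rows is None:
            rows, cols = self.valid_rowcol()
        data = {name: layer.values[rows, cols] for name, layer in self.items()}
        return pd.DataFrame(data)

    def subset(self, names) -> "RasterStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack({n: self._layers[n] for n in names})

    def with_layer(self, name: str, layer: RasterGrid) -> "RasterStack":
        """Return a new stack with ``name`` added or replaced."""
        layers = dict(self._layers)
        layers[name] = layer
        return RasterStack(layers)


# ---------------------------------------------------------------------------
# ESRI ASCII Grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path, categorical: bool = False) -> RasterGrid:
    """Read an ESRI ASCII Grid (``.asc``) file.

    NODATA cells become masked. ``categorical=True`` on a file holding
    non-integer values is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    header_keys = {
        "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
        "cellsize", "nodata_value",
    }
    with open(path) as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in header_keys:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                fh.seek(pos)
                break
        try:
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"unreadable raster data in {path}: {exc}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path} is not an ESRI ASCII grid (missing {key})")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    if "xllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"])
    elif "xllcenter" in header:
        origin = (header["xllcenter"] - cell / 2, header["yllcenter"] - cell / 2)
    else:
        origin = (0.0, 0.0)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    mask = ~np.isclose(data, nodata) & np.isfinite(data)
    if categorical:
        valid = data[mask]
        if valid.size and not np.allclose(valid, np.round(valid)):
            raise ValueError(
                f"{path}: categorical layer requested but file holds non-integer values"
            )
    return RasterGrid(data, mask, origin, cell, categorical)


def write_ascii_grid(grid: RasterGrid, path, nodata: float = NODATA_DEFAULT) -> None:
    """Write a :class:`RasterGrid` as an ESRI ASCII Grid text file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = np.where(grid.mask, grid.values, nodata)
    fmt = "%d" if grid.categorical else "%.10g"
    if grid.categorical:
        out = np.round(out).astype(int)
        nodata = int(nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, out, fmt=fmt)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _block_majority(block_vals: np.ndarray, block_mask: np.ndarray) -> float:
    vals = block_vals[block_mask]
    if vals.size == 0:
        return np.nan
    uniq, counts = np.unique(vals, return_counts=True)
    # ties broken by the smallest class id (np.unique sorts ascending)
    return uniq[np.argmax(counts)]


def _aggregate(grid: RasterGrid, factor: int) -> RasterGrid:
    nr = -(-grid.nrows // factor) * factor
    nc = -(-grid.ncols // factor) * factor
    vals = np.full((nr, nc), np.nan)
    mask = np.zeros((nr, nc), dtype=bool)
    vals[: grid.nrows, : grid.ncols] = grid.values
    mask[: grid.nrows, : grid.ncols] = grid.mask
    br, bc = nr // factor, nc // factor
    v4 = vals.reshape(br, factor, bc, factor)
    m4 = mask.reshape(br, factor, bc, factor)
    out_mask = m4.any(axis=(1, 3))
    if grid.categorical:
        out = np.full((br, bc), np.nan)
        for i in range(br):
            for j in range(bc):
                out[i, j] = _block_majority(v4[i, :, j, :], m4[i, :, j, :])
    else:
        s = np.where(m4, v4, 0.0).sum(axis=(1, 3))
        cnt = m4.sum(axis=(1, 3))
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    # pad rows hang off the northern edge in array terms appended at the
    # bottom, i.e. the southern edge: keep the origin fixed in y by shifting
    y0 = grid.origin[1] - (nr - grid.nrows) * grid.cell_size
    return RasterGrid(
        out, out_mask, (grid.origin[0], y0), grid.cell_size * factor, grid.categorical
    )


def _disaggregate(grid: RasterGrid, factor: int) -> RasterGrid:
    vals = np.kron(grid.values, np.ones((factor, factor)))
    mask = np.kron(grid.mask, np.ones((factor, factor), dtype=bool))
    return RasterGrid(vals, mask, grid.origin, grid.cell_size / factor, grid.categorical)


def resample_align(stack: RasterStack, target_cell_size: float) -> RasterStack:
    """Resample every layer of a stack to ``target_cell_size``.

    Continuous layers aggregate by block mean over valid cells, categorical
    layers by block majority (ties to the smallest class id); disaggregation
    replicates cells. The target size must be an integer multiple or divisor
    of the source cell size.
    """
    src = stack.cell_size
    if np.isclose(target_cell_size, src):
        return RasterStack({n: g.copy() for n, g in stack.items()})
    if target_cell_size > src:
        factor = target_cell_size / src
        if not np.isclose(factor, round(factor)):
            raise ValueError(
                f"target cell size {target_cell_size} is not an integer multiple "
                f"of source cell size {src}"
            )
        return RasterStack({n: _aggregate(g, round(factor)) for n, g in stack.items()})
    factor = src / target_cell_size
    if not np.isclose(factor, round(factor)):
        raise ValueError(
            f"source cell size {src} is not an integer multiple of target "
            f"cell size {target_cell_size}"
        )
    return RasterStack({n: _disaggregate(g, round(factor)) for n, g in stack.items()})
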