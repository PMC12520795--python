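"""Planar analysis grid and named raster stacks.

All spatial data in this package live on a single shared lattice: a regular
grid of square cells in a projected CRS (meters), addressed ``(row, col)``,
0-based, row-major, with row 0 at the bottom (y increases with row index).
Cells are half-open intervals ``[low, high)`` in both axes, so every point
belongs to exactly one cell. Region membership (e.g. invasive vs. native
range) is a per-cell label.

Layers are 2-D float arrays with ``NaN`` marking no-data; the stack keeps a
provenance tag per layer (climatic, topographic, anthropogenic, vegetation,
effort). The effort layer is special throughout the pipeline: it is never
centered or scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

NO_REGION = ""

LAYER_TAGS = ("climatic", "topographic", "anthropogenic", "vegetation", "effort")
EFFORT_TAG = "effort"


@dataclass(frozen=True)
class Grid:
    """A regular planar lattice of square cells.

    Parameters
    ----------
    n_rows, n_cols:
        Lattice shape.
    cell_size_m:
        Side length of a cell in meters (> 0).
    origin:
        ``(x, y)`` of the lower-left corner of cell (0, 0), in projected meters.
    region_mask:
        Per-cell region label (``""`` = no region), shape ``(n_rows, n_cols)``.
    """

    n_rows: int
    n_cols: int
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError(f"cell_size_m must be positive, got {self.cell_size_m}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.region_mask is not None:
            mask = np.asarray(self.region_mask, dtype=object)
            if mask.shape != self.shape:
                raise ValueError(
                    f"region_mask shape {mask.shape} != grid shape {self.shape}"
                )
            object.__setattr__(self, "region_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def regions(self) -> list[str]:
        """Distinct non-empty region labels, sorted."""
        if self.region_mask is None:
            return []
        labels = {str(v) for v in self.region_mask.ravel()} - {NO_REGION}
        return sorted(labels)

    # ------------------------------------------------------------------
    # coordinate <-> cell conversions
    # ------------------------------------------------------------------
    def point_to_cell(self, x, y):
        """Map points to (row, col); half-open cells [low, high).

        Points outside the lattice get row/col outside [0, n_rows/n_cols);
        callers decide whether that is an error or a filter condition.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size_m).astype(np.int64)
        row = np.floor((y - self.origin[1]) / self.cell_size_m).astype(np.int64)
        return row, col

    def contains(self, x, y):
        """Boolean mask: does each point fall inside the lattice extent?"""
        row, col = self.point_to_cell(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        """(x, y) of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size_m
        y = self.origin[1] + (row + 0.5) * self.cell_size_m
        return x, y

    def cell_bounds(self, row, col):
        """(xmin, ymin, xmax, ymax) of cells."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        s = self.cell_size_m
        return (
            self.origin[0] + col * s,
            self.origin[1] + row * s,
            self.origin[0] + (col + 1) * s,
            self.origin[1] + (row + 1) * s,
        )

    def region_cells_mask(self, region: str) -> np.ndarray:
        if self.region_mask is None:
            raise ValueError("grid has no region mask")
        return np.asarray(self.region_mask == region)


def split_region_mask(n_rows: int, n_cols: int, labels: tuple[str, str] = ("invasive", "native"),
                      fraction: float = 0.7) -> np.ndarray:
    """Simple two-region mask: left `fraction` of columns is labels[0]."""
    mask = np.full((n_rows, n_cols), labels[1], dtype=object)
    cut = int(round(fraction * n_cols))
    mask[:, :cut] = labels[0]
    return mask


@dataclass
class RasterStack:
    """Named, NA-aware layers sharing one grid.

    ``layers`` maps name -> 2-D float array (NaN = no data); ``tags`` maps
    name -> provenance tag. ``standardization`` records (mean, sd) per layer
    once :func:`invasdm.predictors.standardize` has run, so projection can
    reuse the training constants.
    """

    grid: Grid
    layers: dict[str, np.ndarray]
    tags: dict[str, str] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    effort_mean_nonzero: float | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            self.layers[name] = arr
        for name in self.layers:
            self.tags.setdefault(name, "climatic")
        unknown = set(self.tags) - set(self.layers)
        if unknown:
            raise ValueError(f"tags for unknown layers: {sorted(unknown)}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def effort_name(self) -> str | None:
        for name, tag in self.tags.items():
            if tag == EFFORT_TAG:
                return name
        return None

    def predictor_names(self, include_effort: bool = True) -> list[str]:
        """Layer names in insertion order, optionally without the effort layer."""
        eff = self.effort_name
        return [n for n in self.layers if include_effort or n != eff]

    def valid_mask(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Cells where every requested layer is non-NA."""
        names = list(names) if names is not None else self.layer_names
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            mask &= np.isfinite(self.layers[n])
        return mask

    def values_at(self, rows, cols, names: Iterable[str] | None = None) -> np.ndarray:
        """Matrix of layer values at cells, shape (n_points, n_layers)."""
        names = list(names) if names is not None else self.layer_names
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def copy(self) -> "RasterStack":
        return RasterStack(
            grid=self.grid,
            layers={n: a.copy() for n, a in self.layers.items()},
            tags=dict(self.tags),
            standardization=dict(self.standardization),
            effort_mean_nonzero=self.effort_mean_nonzero,
        )

    def subset(self, names: Iterable[str]) -> "RasterStack":
        names = list(names)
        missing = set(names) - set(self.layers)
        if missing:
            raise KeyError(f"unknown layers: {sorted(missing)}")
        return RasterStack(
            grid=self.grid,
            layers={n: self.layers[n] for n in names},
            tags={n: self.tags[n] for n in names},
            standardization={n: self.standardization[n] for n in names if n in self.standardization},
            effort_mean_nonzero=self.effort_mean_nonzero,
        )


# ----------------------------------------------------------------------
# text raster I/O (ESRI ASCII grid)
# ----------------------------------------------------------------------
_NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: Grid) -> None:
    """Write one layer as an ESRI ASCII grid (.asc), NaN as nodata.

    The format stores rows top-down, so the bottom-up array is flipped on
    write and on read.
    """
    values = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1].copy()
    body[body == header["nodata_value"]] = np.nan
    grid = Grid(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    return body, grid


def write_stack(directory: str | Path, stack: RasterStack) -> None:
    """Write every layer as .asc plus a plain-text manifest of names/tags."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for name in stack.layer_names:
        write_ascii_grid(directory / f"{name}.asc", stack.layers[name], stack.grid)
        lines.append(f"{name}\t{stack.tags[name]}")
    (directory / "manifest.tsv").write_text("\n".join(lines) + "\n")
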