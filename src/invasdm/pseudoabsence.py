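"""Replicated pseudo-absence sampling under two exclusion geometries.

Presence-only data need background ("pseudo-absence", PA) points. Sets are
drawn at a 1:1 ratio with presences per region, under one of two exclusion
modes reflecting the positional precision of the region's records:

* **cell exclusion** — every cell containing a presence is ineligible but
  its neighbors remain viable (appropriate when positional errors are below
  the cell size);
* **buffer exclusion** — a disc of radius equal to each record's coordinate
  uncertainty is drawn around its reported location, and every cell whose
  rectangle intersects any disc is ineligible (appropriate when errors span
  multiple cells, so the true location could be in any of them).

Disc-rectangle intersection is exact: the distance from the disc center to
the rectangle is computed by clamping the center into the rectangle — no
polygon discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid, RasterStack
from .occurrences import PresenceCells

CELL_EXCLUSION = "cell"
BUFFER_EXCLUSION = "buffer"


@dataclass
class PASet:
    """One seeded replicate of pseudo-absence cells."""

    set_id: int
    seed: int
    cells: pd.DataFrame  # columns: row, col, region


def _valid_region_mask(grid: Grid, stack: RasterStack, region: str) -> np.ndarray:
    """Region cells where every predictor layer has data."""
    return grid.region_cells_mask(region) & stack.valid_mask()


def eligible_cells_cellexcl(
    presences: PresenceCells, grid: Grid, stack: RasterStack, region: str
) -> np.ndarray:
    """Eligibility mask under cell exclusion: valid region cells minus presence cells."""
    mask = _valid_region_mask(grid, stack, region)
    sub = presences.cells[presences.cells["region"] == region]
    mask = mask.copy()
    if len(sub):
        mask[sub["row"].to_numpy(dtype=int), sub["col"].to_numpy(dtype=int)] = False
    if not mask.any():
        raise ValueError(f"no eligible pseudo-absence cells in region {region!r}")
    return mask


def disc_excluded_cells(grid: Grid, x, y, radius_m) -> np.ndarray:
    """Cells whose rectangle intersects any disc (center (x, y), radius CU).

    Exact nearest-point test: clamp the disc center into each candidate
    rectangle and compare the distance to the radius (closed inequality, so
    tangent cells are excluded too). A zero radius excludes only the cell
    containing the point.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    radius = np.broadcast_to(np.asarray(radius_m, dtype=float), x.shape)
    if np.any(~np.isfinite(radius)) or np.any(radius < 0):
        raise ValueError("positional-uncertainty radii must be finite and >= 0")
    excluded = np.zeros(grid.shape, dtype=bool)
    s = grid.cell_size_m
    for xi, yi, ri in zip(x, y, radius):
        r0, c0 = grid.point_to_cell(xi - ri, yi - ri)
        r1, c1 = grid.point_to_cell(xi + ri, yi + ri)
        # widen by one cell: closed rectangles tangent to the disc at exactly
        # the radius can sit just outside the half-open bounding cells
        r0 = max(int(r0) - 1, 0)
        c0 = max(int(c0) - 1, 0)
        r1 = min(int(r1) + 1, grid.n_rows - 1)
        c1 = min(int(c1) + 1, grid.n_cols - 1)
        if r1 < r0 or c1 < c0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        xmin = grid.origin[0] + cols * s
        ymin = grid.origin[1] + rows * s
        nearest_x = np.clip(xi, xmin, xmin + s)  # (n_cols,)
        nearest_y = np.clip(yi, ymin, ymin + s)  # (n_rows,)
        d2 = (nearest_x[None, :] - xi) ** 2 + (nearest_y[:, None] - yi) ** 2
        block = d2 <= ri**2
        excluded[r0 : r1 + 1, c0 : c1 + 1] |= block
    return excluded


def eligible_cells_bufferexcl(
    records: pd.DataFrame, grid: Grid, stack: RasterStack, region: str
) -> np.ndarray:
    """Eligibility mask under buffer exclusion.

    ``records`` must carry finite coordinates and coordinate_uncertainty_m.
    """
    cu = records["coordinate_uncertainty_m"].to_numpy(dtype=float)
    if np.any(~np.isfinite(cu)) or np.any(cu < 0):
        raise ValueError("buffer exclusion requires finite non-negative CU for every record")
    mask = _valid_region_mask(grid, stack, region)
    excl = disc_excluded_cells(
        grid,
        records["longitude"].to_numpy(dtype=float),
        records["latitude"].to_numpy(dtype=float),
        cu,
    )
    mask = mask & ~excl
    if not mask.any():
        raise ValueError(f"no eligible pseudo-absence cells in region {region!r}")
    return mask


def draw_pa_sets(
    eligible: dict[str, np.ndarray],
    n_per_region: dict[str, int],
    n_sets: int = 10,
    base_seed: int = 0,
) -> list[PASet]:
    """Draw ``n_sets`` independent PA sets, each under its own seed.

    Within a set, cells are drawn uniformly without replacement per region;
    across sets, draws are independent (a cell may recur in several sets).
    Set ``k`` (1-based) uses seed ``base_seed + k``.
    """
    for region, n in n_per_region.items():
        pool = int(eligible[region].sum())
        if n > pool:
            raise ValueError(
                f"region {region!r}: requested {n} pseudo-absences but only {pool} eligible cells"
            )
    sets = []
    for k in range(1, n_sets + 1):
        seed = base_seed + k
        rng = np.random.default_rng(seed)
        frames = []
        for region in sorted(n_per_region):
            rows, cols = np.nonzero(eligible[region])
            pick = rng.choice(rows.size, size=n_per_region[region], replace=False)
            frames.append(
                pd.DataFrame({"row": rows[pick], "col": cols[pick], "region": region})
            )
        cells = pd.concat(frames, ignore_index=True)
        sets.append(PASet(set_id=k, seed=seed, cells=cells))
    return sets


def pa_sets_to_frame(sets: list[PASet], grid: Grid) -> pd.DataFrame:
    """Flatten PA sets to one table (set_id, row, col, region, x, y) for audit."""
    frames = []
    for s in sets:
        df = s.cells.copy()
        df.insert(0, "set_id", s.set_id)
        x, y = grid.cell_center(df["row"].to_numpy(), df["col"].to_numpy())
        df["x"] = x
        df["y"] = y
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
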