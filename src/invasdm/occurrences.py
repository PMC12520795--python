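"""Occurrence cleaning, region-specific uncertainty filtering and per-cell thinning.

Raw community-science and museum occurrence tables arrive with wildly
heterogeneous positional precision. The preparation pipeline runs in a fixed
order — validity/terrestrial cleaning, then coordinate-uncertainty (CU)
filtering with a per-region threshold, then thinning to at most one presence
per grid cell — producing the presence set every later stage consumes.

Occurrence tables are pandas DataFrames with columns ``longitude, latitude,
coordinate_uncertainty_m, event_date, basis_of_record, region`` (projected
meters in the synthetic setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, RasterStack

logger = logging.getLogger(__name__)


@dataclass
class PresenceCells:
    """One retained presence per occupied grid cell."""

    grid: Grid
    cells: pd.DataFrame  # columns: row, col, region

    def __post_init__(self) -> None:
        dup = self.cells.duplicated(subset=["row", "col"])
        if dup.any():
            raise ValueError("duplicate presence cells")

    def count(self, region: str | None = None) -> int:
        if region is None:
            return len(self.cells)
        return int((self.cells["region"] == region).sum())

    @property
    def regions(self) -> list[str]:
        return sorted(self.cells["region"].unique())


def basic_clean(
    records: pd.DataFrame,
    grid: Grid,
    stack: RasterStack,
    rejected: list | None = None,
) -> pd.DataFrame:
    """Drop invalid and non-terrestrial records.

    Removes records with non-finite coordinates, records outside the grid
    extent, and records falling in cells where *all* predictor layers are NA
    (water / no-data — the minimal terrestrial-validity screen). Survivor
    order is preserved. ``rejected``, if given, collects (index, reason)
    tuples for audit output.
    """
    if records.empty:
        return records.copy()
    x = records["longitude"].to_numpy(dtype=float)
    y = records["latitude"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    inside = np.zeros(len(records), dtype=bool)
    inside[finite] = grid.contains(x[finite], y[finite])

    # a cell is "terrestrial" if at least one predictor layer has data there
    any_data = np.zeros(grid.shape, dtype=bool)
    for name in stack.layer_names:
        any_data |= np.isfinite(stack.layers[name])

    keep = np.zeros(len(records), dtype=bool)
    rows = np.zeros(len(records), dtype=int)
    cols = np.zeros(len(records), dtype=int)
    r, c = grid.point_to_cell(np.where(finite, x, 0.0), np.where(finite, y, 0.0))
    rows, cols = r, c
    ok = finite & inside
    keep[ok] = any_data[rows[ok], cols[ok]]

    if rejected is not None:
        for i in np.flatnonzero(~keep):
            if not finite[i]:
                reason = "non_finite_coordinates"
            elif not inside[i]:
                reason = "outside_grid"
            else:
                reason = "non_terrestrial_cell"
            rejected.append((records.index[i], reason))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("basic_clean: dropped %d of %d records", dropped, len(records))
    return records.loc[keep].copy()


def filter_uncertainty(
    records: pd.DataFrame,
    max_cu_m: dict[str, float],
    keep_missing_cu: bool = False,
) -> pd.DataFrame:
    """Apply per-region coordinate-uncertainty thresholds.

    A record survives iff its CU is <= the threshold configured for its
    region (strictly greater is excluded). Records with missing CU are
    excluded by default — the thresholds are defined on CU and silently
    keeping unmeasured records would leak imprecise locations — with the
    count logged; set ``keep_missing_cu=True`` to retain them.
    """
    for region, thr in max_cu_m.items():
        if thr <= 0:
            raise ValueError(f"threshold for region {region!r} must be positive")
    regions = records["region"].unique()
    missing_thr = [r for r in regions if r not in max_cu_m]
    if missing_thr:
        raise KeyError(f"no CU threshold configured for regions: {missing_thr}")
    if records.empty:
        return records.copy()

    cu = records["coordinate_uncertainty_m"].to_numpy(dtype=float)
    thr = records["region"].map(max_cu_m).to_numpy(dtype=float)
    has_cu = np.isfinite(cu)
    keep = np.where(has_cu, cu <= thr, keep_missing_cu)
    n_missing = int((~has_cu).sum())
    if n_missing:
        logger.info(
            "filter_uncertainty: %d records with missing CU %s",
            n_missing,
            "retained" if keep_missing_cu else "excluded",
        )
    return records.loc[keep].copy()


def thin_to_cells(records: pd.DataFrame, grid: Grid) -> PresenceCells:
    """Keep one presence per occupied grid cell (first record in input order)."""
    if records.empty:
        return PresenceCells(grid=grid, cells=pd.DataFrame(columns=["row", "col", "region"]))
    x = records["longitude"].to_numpy(dtype=float)
    y = records["latitude"].to_numpy(dtype=float)
    rows, cols = grid.point_to_cell(x, y)
    df = pd.DataFrame(
        {"row": rows, "col": cols, "region": records["region"].to_numpy()},
        index=records.index,
    )
    thinned = df.drop_duplicates(subset=["row", "col"], keep="first").reset_index(drop=True)
    return PresenceCells(grid=grid, cells=thinned)


def prepare_presences(
    records: pd.DataFrame,
    grid: Grid,
    stack: RasterStack,
    max_cu_m: dict[str, float],
    keep_missing_cu: bool = False,
) -> PresenceCells:
    """The fixed pipeline: clean -> CU filter -> thin."""
    cleaned = basic_clean(records, grid, stack)
    filtered = filter_uncertainty(cleaned, max_cu_m, keep_missing_cu=keep_missing_cu)
    return thin_to_cells(filtered, grid)
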