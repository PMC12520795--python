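"""Suitability projection, independent-validation aggregation and habitat overlap.

Projection maps the selected ensemble over the predictor stack. In
``standardized`` effort mode, the sampling-effort layer is replaced by a
single constant — the mean of the non-zero effort values from training — so
the map reflects environmental suitability with observer bias held
constant; in ``observed`` mode the effort layer enters as-is.

Independent survey data are aggregated to one labeled point per grid cell
with precedence to presences, and habitat overlap with focal (e.g.
threatened invertebrate) species is scored as the mean +/- SE of suitability
at the cells holding their thinned occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid, RasterStack

logger = logging.getLogger(__name__)

EFFORT_OBSERVED = "observed"
EFFORT_STANDARDIZED = "standardized"


@dataclass
class SuitabilityMap:
    grid: Grid
    values: np.ndarray  # per-cell scores in [0,1], NaN where predictors missing
    ensemble_id: str
    effort_mode: str
    effort_constant: float | None
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def at_cells(self, rows, cols) -> np.ndarray:
        return self.values[np.asarray(rows), np.asarray(cols)]


def project_map(
    ensemble,
    stack: RasterStack,
    effort_mode: str = EFFORT_STANDARDIZED,
    effort_constant: float | None = None,
) -> SuitabilityMap:
    """Project a fitted model/ensemble onto a stack.

    The stack must already be standardized with the training constants.
    In standardized mode every effort cell (sampled or not) is set to
    ``effort_constant``, defaulting to the stack's recorded mean non-zero
    effort value.
    """
    if effort_mode not in (EFFORT_OBSERVED, EFFORT_STANDARDIZED):
        raise ValueError(f"unknown effort mode {effort_mode!r}")
    effort_name = stack.effort_name
    if effort_name is None:
        raise ValueError("stack has no effort layer")
    work = stack
    const = None
    if effort_mode == EFFORT_STANDARDIZED:
        const = effort_constant if effort_constant is not None else stack.effort_mean_nonzero
        if const is None:
            raise ValueError(
                "standardized effort mode needs an effort constant "
                "(none recorded on the stack and none supplied)"
            )
        work = stack.copy()
        eff = work.layers[effort_name]
        work.layers[effort_name] = np.where(np.isfinite(eff), float(const), np.nan)
    values = ensemble.predict_stack(work)
    return SuitabilityMap(
        grid=stack.grid,
        values=values,
        ensemble_id=getattr(ensemble, "ensemble_id", getattr(ensemble, "algorithm_id", "model")),
        effort_mode=effort_mode,
        effort_constant=None if const is None else float(const),
        standardization=dict(stack.standardization),
    )


def aggregate_independent(points: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Aggregate labeled survey points to one per cell, presences taking precedence.

    ``points`` needs columns x, y, label (1 = presence, 0 = absence).
    Returns one row per occupied cell with columns row, col, label.
    """
    labels = points["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    if not np.all(grid.contains(x, y)):
        raise ValueError("survey points must fall inside the grid")
    rows, cols = grid.point_to_cell(x, y)
    df = pd.DataFrame({"row": rows, "col": cols, "label": labels})
    agg = df.groupby(["row", "col"], as_index=False)["label"].max()
    return agg


@dataclass
class OverlapSummary:
    species: str
    n_cells: int
    mean_suitability: float
    standard_error: float
    n_dropped_na: int


def overlap_summary(map_: SuitabilityMap, occurrences: pd.DataFrame, species: str) -> OverlapSummary:
    """Mean +/- SE suitability at the thinned occurrence cells of one species.

    ``occurrences`` needs columns x, y. Points are thinned to one per cell
    before extraction; occurrences falling in NA map cells are dropped with
    the count reported.
    """
    x = occurrences["x"].to_numpy(dtype=float)
    y = occurrences["y"].to_numpy(dtype=float)
    inside = map_.grid.contains(x, y)
    rows, cols = map_.grid.point_to_cell(x[inside], y[inside])
    cells = pd.DataFrame({"row": rows, "col": cols}).drop_duplicates()
    vals = map_.at_cells(cells["row"].to_numpy(), cells["col"].to_numpy())
    ok = np.isfinite(vals)
    n_dropped = int((~ok).sum() + (~inside).sum())
    vals = vals[ok]
    if vals.size == 0:
        raise ValueError(f"all occurrences of {species!r} fall in NA map cells")
    if n_dropped:
        logger.info("overlap_summary(%s): dropped %d occurrences in NA cells", species, n_dropped)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return OverlapSummary(
        species=species,
        n_cells=int(vals.size),
        mean_suitability=mean,
        standard_error=se,
        n_dropped_na=n_dropped,
    )
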