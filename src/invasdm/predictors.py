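"""Sampling-effort layer, collinearity pruning and standardization.

The effort layer absorbs observer bias: each cell gets the natural log of
the number of community-science observations it contains, with two special
values — 0 for unsampled cells and 0.33 for single-observation cells — so
that low-effort cells are not compressed onto the unsampled value
(ln 1 = 0). The effort layer is a predictor like any other at fit time but
is never centered or scaled, and its mean non-zero value is recorded for
use as the constant effort at projection time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EFFORT_TAG, Grid, RasterStack

logger = logging.getLogger(__name__)

SINGLE_OBSERVATION_EFFORT = 0.33


@dataclass
class EffortLayer:
    grid: Grid
    values: np.ndarray
    mean_nonzero: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("effort values must be non-negative")


def effort_value(n_obs) -> np.ndarray:
    """Per-cell effort from observation counts: 0, 0.33, or ln(n)."""
    n = np.asarray(n_obs, dtype=float)
    return np.where(n == 0, 0.0, np.where(n == 1, SINGLE_OBSERVATION_EFFORT, np.log(np.maximum(n, 2))))


def build_effort(x, y, grid: Grid) -> EffortLayer:
    """Rasterize observation points into the log-count effort surface.

    Points outside the grid raise: the effort surface must be built on the
    same spatial framework as every other layer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size and not np.all(grid.contains(x, y)):
        raise ValueError("effort observation points must fall inside the grid")
    counts = np.zeros(grid.shape, dtype=np.int64)
    if x.size:
        rows, cols = grid.point_to_cell(x, y)
        np.add.at(counts, (rows, cols), 1)
    values = effort_value(counts)
    nonzero = values[values > 0]
    mean_nonzero = float(nonzero.mean()) if nonzero.size else 0.0
    return EffortLayer(grid=grid, values=values, mean_nonzero=mean_nonzero)


def attach_effort(stack: RasterStack, effort: EffortLayer, name: str = "effort") -> RasterStack:
    """Return a stack with the effort layer appended (tagged, never scaled)."""
    out = stack.copy()
    out.layers[name] = effort.values.copy()
    out.tags[name] = EFFORT_TAG
    out.effort_mean_nonzero = effort.mean_nonzero
    return out


# ----------------------------------------------------------------------
# collinearity pruning
# ----------------------------------------------------------------------
@dataclass
class CollinearityReport:
    kept: list[str]
    dropped: list[dict]  # {"layer", "abs_r", "partner"}
    threshold: float

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold, "kept": self.kept, "dropped": self.dropped}


def prune_collinear(stack: RasterStack, threshold: float = 0.7) -> tuple[RasterStack, CollinearityReport]:
    """Greedily drop layers until no pairwise |Pearson r| exceeds the threshold.

    Correlations are computed over cells where all compared layers are
    non-NA. At each step, among the layers involved in a still-violating
    pair, the one with the largest mean |r| against the other kept layers is
    dropped (ties broken alphabetically). The effort layer is exempt.
    """
    effort = stack.effort_name
    names = [n for n in stack.layer_names if n != effort]
    if len(names) < 2:
        raise ValueError("need at least two non-effort layers to prune")
    complete = stack.valid_mask(names)
    data = np.column_stack([stack.layers[n][complete] for n in names])
    sds = data.std(axis=0)
    zero_var = [n for n, s in zip(names, sds) if s == 0 or not np.isfinite(s)]
    if zero_var:
        raise ValueError(f"zero-variance layer(s), correlation undefined: {zero_var}")
    corr = np.abs(np.corrcoef(data, rowvar=False))
    np.fill_diagonal(corr, 0.0)

    kept_idx = list(range(len(names)))
    dropped: list[dict] = []
    while True:
        sub = corr[np.ix_(kept_idx, kept_idx)]
        viol_i, viol_j = np.nonzero(np.triu(sub, 1) > threshold)
        if viol_i.size == 0:
            break
        candidates = sorted({kept_idx[i] for i in np.concatenate([viol_i, viol_j])})
        mean_abs = {
            i: corr[i, [j for j in kept_idx if j != i]].mean() for i in candidates
        }
        # largest mean |r| first; alphabetical on ties
        best = max(mean_abs.values())
        tied = sorted(names[i] for i in candidates if mean_abs[i] == best)
        victim = names.index(tied[0])
        # record the strongest partner of the victim among the survivors
        kept_only = [j for j in kept_idx if j != victim]
        partner = max(kept_only, key=lambda j: corr[victim, j])
        dropped.append(
            {"layer": names[victim], "abs_r": float(corr[victim, partner]), "partner": names[partner]}
        )
        kept_idx.remove(victim)

    kept = [names[i] for i in kept_idx]
    report = CollinearityReport(kept=kept, dropped=dropped, threshold=threshold)
    keep_names = kept + ([effort] if effort else [])
    keep_names = [n for n in stack.layer_names if n in keep_names]  # original order
    return stack.subset(keep_names), report


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------
def standardize(stack: RasterStack) -> RasterStack:
    """Center and scale every non-effort layer to mean 0 / sd 1 over non-NA cells.

    Means and sds are pooled across regions (one model spans both) and are
    recorded on the returned stack so projection reuses the training
    constants rather than re-deriving them on a new extent.
    """
    out = stack.copy()
    effort = stack.effort_name
    for name in stack.layer_names:
        if name == effort:
            continue
        vals = out.layers[name]
        finite = np.isfinite(vals)
        mu = float(vals[finite].mean())
        sd = float(vals[finite].std())
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance layer {name!r} cannot be standardized")
        out.layers[name] = (vals - mu) / sd
        # compose with any previous standardization so constants always map
        # RAW values to the current scale
        if name in stack.standardization:
            mu0, sd0 = stack.standardization[name]
            out.standardization[name] = (mu0 + mu * sd0, sd0 * sd)
        else:
            out.standardization[name] = (mu, sd)
    return out


def apply_standardization(stack: RasterStack, constants: dict[str, tuple[float, float]]) -> RasterStack:
    """Standardize a (projection) stack with frozen training constants."""
    out = stack.copy()
    effort = stack.effort_name
    for name, (mu, sd) in constants.items():
        if name == effort or name not in out.layers:
            continue
        out.layers[name] = (out.layers[name] - mu) / sd
        out.standardization[name] = (mu, sd)
    return out
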