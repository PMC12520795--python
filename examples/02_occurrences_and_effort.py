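"""Clean, filter and thin occurrences; build the sampling-effort layer.

Shows the fixed preparation order (validity clean -> per-region coordinate-
uncertainty filter -> one presence per cell) and the log-count effort rule
(0 for empty cells, 0.33 for one observation, ln n for n >= 2).
"""

import numpy as np

from invasdm import (
    Grid,
    INVASIVE_CU,
    build_effort,
    define_truth,
    filter_uncertainty,
    basic_clean,
    sample_occurrences,
    simulate_predictors,
    thin_to_cells,
)
from invasdm.grid import split_region_mask

mask = split_region_mask(40, 40, labels=("invasive", "native"), fraction=0.6)
grid = Grid(40, 40, 1000.0, region_mask=mask)
stack = simulate_predictors(grid, 4, seed=5, na_fraction=0.03)
truth = define_truth(stack, {"L1": 1.5}, intercept=0.0)

rng = np.random.default_rng(6)
xs, ys = rng.uniform(0, 40_000, 5000), rng.uniform(0, 40_000, 5000)
effort = build_effort(xs, ys, grid)
counts = {0: float((effort.values == 0).sum()), 1: float((effort.values == 0.33).sum())}
print(f"effort: {counts[0]:.0f} empty cells (value 0), {counts[1]:.0f} single-obs cells "
      f"(value 0.33), mean non-zero value {effort.mean_nonzero:.3f}")
print("  (the mean non-zero value is reused as the constant effort at projection time)")

occ = sample_occurrences(truth, effort.values, 400, "invasive", INVASIVE_CU, seed=7)
clean = basic_clean(occ, grid, stack)
kept = filter_uncertainty(clean, {"invasive": 1000.0, "native": 15000.0})
presences = thin_to_cells(kept, grid)
print(f"records: {len(occ)} raw -> {len(clean)} clean -> {len(kept)} within CU threshold "
      f"-> {presences.count()} presence cells (one per grid cell)")
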