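import numpy as np
import pandas as pd
import pytest

from invasdm import Grid, RasterStack, aggregate_independent, overlap_summary, project_map
from invasdm.projection import EFFORT_OBSERVED, EFFORT_STANDARDIZED, SuitabilityMap


class _LinearModel:
    """Toy score function: sigmoid of a weighted sum of named layers."""

    def __init__(self, weights):
        self.weights = weights
        self.feature_names = list(weights)

    def predict_stack(self, stack):
        eta = np.zeros(stack.grid.shape)
        for name, w in self.weights.items():
            eta = eta + w * stack.layers[name]
        return 1.0 / (1.0 + np.exp(-eta))


@pytest.fixture
def proj_stack():
    grid = Grid(6, 6, 100.0)
    rng = np.random.default_rng(0)
    env = rng.standard_normal(grid.shape)
    env[4, 4] = np.nan
    effort = np.abs(rng.standard_normal(grid.shape))
    effort[0, :3] = 0.0
    st = RasterStack(grid=grid, layers={"env": env, "effort": effort},
                     tags={"env": "climatic", "effort": "effort"})
    st.effort_mean_nonzero = float(effort[effort > 0].mean())
    return st


class TestProjectMap:
    def test_standardized_mode_uses_mean_nonzero_constant(self, proj_stack):
        model = _LinearModel({"env": 0.5, "effort": 1.0})
        smap = project_map(model, proj_stack, EFFORT_STANDARDIZED)
        mu = proj_stack.effort_mean_nonzero
        expected = 1 / (1 + np.exp(-(0.5 * proj_stack.layers["env"] + 1.0 * mu)))
        finite = np.isfinite(expected)
        np.testing.assert_allclose(smap.values[finite], expected[finite])
        assert smap.effort_constant == pytest.approx(mu)

    def test_na_cells_propagate(self, proj_stack):
        model = _LinearModel({"env": 1.0, "effort": 0.0})
        smap = project_map(model, proj_stack, EFFORT_STANDARDIZED)
        assert np.isnan(smap.values[4, 4])

    def test_effort_ablation_makes_modes_identical(self, proj_stack):
        """With a zero effort coefficient, observed and standardized maps agree."""
        model = _LinearModel({"env": 1.2, "effort": 0.0})
        a = project_map(model, proj_stack, EFFORT_OBSERVED)
        b = project_map(model, proj_stack, EFFORT_STANDARDIZED)
        finite = np.isfinite(a.values)
        np.testing.assert_allclose(a.values[finite], b.values[finite])

    def test_standardized_map_constant_in_observed_effort(self, proj_stack):
        model = _LinearModel({"env": 0.7, "effort": 0.9})
        base = project_map(model, proj_stack, EFFORT_STANDARDIZED, effort_constant=1.16)
        perturbed = proj_stack.copy()
        perturbed.layers["effort"] = perturbed.layers["effort"] * 3.0 + 0.5
        after = project_map(model, perturbed, EFFORT_STANDARDIZED, effort_constant=1.16)
        finite = np.isfinite(base.values)
        np.testing.assert_allclose(after.values[finite], base.values[finite])

    def test_missing_effort_layer_rejected(self):
        grid = Grid(3, 3, 1.0)
        st = RasterStack(grid=grid, layers={"env": np.zeros(grid.shape)})
        with pytest.raises(ValueError):
            project_map(_LinearModel({"env": 1.0}), st, EFFORT_STANDARDIZED)


class TestAggregateIndependent:
    def test_presence_takes_precedence_in_shared_cell(self):
        g = Grid(5, 5, 100.0)
        pts = pd.DataFrame({"x": [50.0, 60.0], "y": [50.0, 60.0], "label": [0, 1]})
        out = aggregate_independent(pts, g)
        assert len(out) == 1 and out.iloc[0]["label"] == 1

    def test_distinct_cells_identity(self):
        g = Grid(5, 5, 100.0)
        pts = pd.DataFrame({"x": [50.0, 150.0, 250.0], "y": [50.0] * 3, "label": [1, 0, 1]})
        out = aggregate_independent(pts, g)
        assert len(out) == 3
        assert out["label"].tolist() == [1, 0, 1]

    def test_matches_brute_force_grouping(self):
        g = Grid(8, 8, 10.0)
        rng = np.random.default_rng(1)
        pts = pd.DataFrame({
            "x": rng.uniform(0, 80, 60),
            "y": rng.uniform(0, 80, 60),
            "label": rng.integers(0, 2, 60),
        })
        out = aggregate_independent(pts, g)
        oracle = {}
        for _, p in pts.iterrows():
            key = (int(p["y"] // 10), int(p["x"] // 10))
            oracle[key] = max(oracle.get(key, 0), int(p["label"]))
        got = {(int(r["row"]), int(r["col"])): int(r["label"]) for _, r in out.iterrows()}
        assert got == oracle
        assert len(out) <= len(pts)

    def test_non_binary_labels_rejected(self):
        g = Grid(3, 3, 1.0)
        pts = pd.DataFrame({"x": [0.5], "y": [0.5], "label": [2]})
        with pytest.raises(ValueError):
            aggregate_independent(pts, g)


class TestOverlapSummary:
    def _map(self):
        g = Grid(4, 4, 100.0)
        vals = np.full(g.shape, np.nan)
        vals[0, 0], vals[0, 1], vals[1, 1] = 0.4, 0.6, 0.9
        return SuitabilityMap(grid=g, values=vals, ensemble_id="t",
                              effort_mode="standardized", effort_constant=1.0)

    def test_single_cell_mean_and_zero_se(self):
        m = self._map()
        occ = pd.DataFrame({"x": [50.0, 60.0, 70.0], "y": [50.0, 60.0, 70.0]})
        out = overlap_summary(m, occ, "snail")
        assert out.n_cells == 1
        assert out.mean_suitability == pytest.approx(0.4)
        assert out.standard_error == 0.0

    def test_two_cell_arithmetic(self):
        m = self._map()
        occ = pd.DataFrame({"x": [50.0, 150.0], "y": [50.0, 50.0]})
        out = overlap_summary(m, occ, "beetle")
        assert out.mean_suitability == pytest.approx(0.5)
        assert out.standard_error == pytest.approx(0.1)

    def test_thin_then_extract_equals_extract_then_dedup(self):
        m = self._map()
        rng = np.random.default_rng(2)
        occ = pd.DataFrame({"x": rng.uniform(0, 200, 40), "y": rng.uniform(0, 200, 40)})
        out = overlap_summary(m, occ, "sp")
        rows, cols = m.grid.point_to_cell(occ["x"].to_numpy(), occ["y"].to_numpy())
        vals = m.values[rows, cols]
        dedup = pd.DataFrame({"r": rows, "c": cols, "v": vals}).drop_duplicates(["r", "c"])
        direct = dedup["v"].dropna()
        assert out.n_cells == len(direct)
        assert out.mean_suitability == pytest.approx(direct.mean())

    def test_na_cells_dropped_with_count(self):
        m = self._map()
        occ = pd.DataFrame({"x": [50.0, 350.0], "y": [50.0, 350.0]})  # second in NA cell
        out = overlap_summary(m, occ, "sp")
        assert out.n_cells == 1 and out.n_dropped_na == 1

    def test_all_na_rejected(self):
        m = self._map()
        occ = pd.DataFrame({"x": [350.0], "y": [350.0]})
        with pytest.raises(ValueError):
            overlap_summary(m, occ, "sp")
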