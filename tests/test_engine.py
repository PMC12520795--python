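import numpy as np
import pandas as pd
import pytest

from invasdm import (
    Grid,
    RasterStack,
    assemble_frame,
    fit_model,
    optimal_tss,
    split_train_valid,
)
from invasdm.engine import CLASS_COLUMN, derive_fit_seed
from invasdm.occurrences import PresenceCells
from invasdm.pseudoabsence import PASet


@pytest.fixture
def frame_fixture():
    """A 12x12 two-region stack with 40+20 presences and a 1:1 PA set."""
    mask = np.full((12, 12), "native", dtype=object)
    mask[:, :8] = "invasive"
    grid = Grid(12, 12, 100.0, region_mask=mask)
    rng = np.random.default_rng(7)
    layers = {
        "a": rng.standard_normal(grid.shape),
        "b": rng.standard_normal(grid.shape),
        "effort": np.abs(rng.standard_normal(grid.shape)),
    }
    stack = RasterStack(grid=grid, layers=layers,
                        tags={"a": "climatic", "b": "climatic", "effort": "effort"})
    cells = [(r, c) for r in range(12) for c in range(12)]
    rng.shuffle(cells)
    pres, pa = [], []
    for r, c in cells:
        region = mask[r, c]
        want = 40 if region == "invasive" else 20
        if sum(1 for rr, cc in pres if mask[rr, cc] == region) < want:
            pres.append((r, c))
        elif sum(1 for rr, cc in pa if mask[rr, cc] == region) < want:
            pa.append((r, c))
    presences = PresenceCells(grid=grid, cells=pd.DataFrame(
        {"row": [r for r, _ in pres], "col": [c for _, c in pres],
         "region": [mask[r, c] for r, c in pres]}))
    pa_set = PASet(set_id=1, seed=0, cells=pd.DataFrame(
        {"row": [r for r, _ in pa], "col": [c for _, c in pa],
         "region": [mask[r, c] for r, c in pa]}))
    return presences, pa_set, stack


class TestAssembleFrame:
    def test_row_count_is_presences_plus_pas(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        frame = assemble_frame(presences, pa_set, stack)
        assert len(frame) == 120

    def test_one_to_one_per_region_and_class(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        frame = assemble_frame(presences, pa_set, stack)
        counts = frame.groupby(["region", CLASS_COLUMN]).size()
        assert counts.loc[("invasive", 1)] == counts.loc[("invasive", 0)] == 40
        assert counts.loc[("native", 1)] == counts.loc[("native", 0)] == 20

    def test_frames_differ_only_in_background_rows(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        other = PASet(set_id=2, seed=1, cells=pa_set.cells.iloc[::-1].reset_index(drop=True))
        f1 = assemble_frame(presences, pa_set, stack)
        f2 = assemble_frame(presences, other, stack)
        pd.testing.assert_frame_equal(
            f1[f1[CLASS_COLUMN] == 1].reset_index(drop=True),
            f2[f2[CLASS_COLUMN] == 1].reset_index(drop=True),
        )

    def test_na_predictors_rejected(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        stack.layers["a"][presences.cells.iloc[0]["row"], presences.cells.iloc[0]["col"]] = np.nan
        with pytest.raises(ValueError):
            assemble_frame(presences, pa_set, stack)


class TestSplitTrainValid:
    def test_seventy_thirty_per_stratum(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        frame = assemble_frame(presences, pa_set, stack)
        plans = split_train_valid(frame, train_frac=0.7, n_reps=10, base_seed=3)
        assert len(plans) == 10
        for plan in plans:
            assert len(plan.train_idx) + len(plan.valid_idx) == len(frame)
            assert set(plan.train_idx) & set(plan.valid_idx) == set()
            for (region, label), idx in frame.groupby(["region", CLASS_COLUMN]).indices.items():
                n_train = len(set(idx) & set(plan.train_idx))
                assert abs(n_train - 0.7 * len(idx)) <= 1

    def test_seeded_determinism(self, frame_fixture):
        presences, pa_set, stack = frame_fixture
        frame = assemble_frame(presences, pa_set, stack)
        a = split_train_valid(frame, n_reps=3, base_seed=5)
        b = split_train_valid(frame, n_reps=3, base_seed=5)
        for p, q in zip(a, b):
            assert np.array_equal(p.train_idx, q.train_idx)

    def test_tiny_stratum_rejected(self):
        frame = pd.DataFrame({"region": ["A", "A", "A"], CLASS_COLUMN: [1, 0, 0],
                              "x": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            split_train_valid(frame, n_reps=1)

    def test_design_cardinality(self, frame_fixture):
        """n_pa_sets x n_reps split plans: the constituent-model design size."""
        presences, pa_set, stack = frame_fixture
        frame = assemble_frame(presences, pa_set, stack)
        all_plans = [
            p
            for sid in range(1, 11)
            for p in split_train_valid(frame, n_reps=10, base_seed=sid, pa_set_id=sid)
        ]
        assert len(all_plans) == 100
        assert len({(p.pa_set_id, p.rep_id) for p in all_plans}) == 100


def _separable_frame(n=120):
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(2, 0.3, n // 2), rng.normal(-2, 0.3, n // 2)])
    return pd.DataFrame({
        "row": 0, "col": 0, "region": "invasive",
        CLASS_COLUMN: [1] * (n // 2) + [0] * (n // 2),
        "p1": x, "p2": rng.standard_normal(n),
    })


class TestFitAndPredict:
    @pytest.mark.parametrize("alg", ["rf", "gbm", "cta", "ann", "xgb", "maxent"])
    def test_separable_data_perfect_training_tss(self, alg):
        frame = _separable_frame()
        hp = {"n_estimators": 50} if alg in ("rf", "gbm", "xgb") else None
        model = fit_model(alg, frame, hyperparams=hp, seed=1)
        scores = model.predict_frame(frame)
        assert np.all((scores >= 0) & (scores <= 1))
        assert optimal_tss(frame[CLASS_COLUMN], scores).tss == 1.0

    def test_shuffled_labels_give_no_heldout_skill(self):
        """Permutation null: held-out TSS stays near zero over 10 seeds."""
        rng = np.random.default_rng(1)
        tss_vals = []
        for seed in range(10):
            frame = _separable_frame(200)
            frame[CLASS_COLUMN] = rng.permutation(frame[CLASS_COLUMN].to_numpy())
            train, test = frame.iloc[:140], frame.iloc[140:]
            if train[CLASS_COLUMN].nunique() < 2 or test[CLASS_COLUMN].nunique() < 2:
                continue
            model = fit_model("rf", train, hyperparams={"n_estimators": 100}, seed=seed)
            tss_vals.append(optimal_tss(test[CLASS_COLUMN], model.predict_frame(test)).tss)
        assert abs(np.median(tss_vals)) < 0.2

    def test_seeded_determinism(self):
        frame = _separable_frame()
        a = fit_model("rf", frame, hyperparams={"n_estimators": 50}, seed=9)
        b = fit_model("rf", frame, hyperparams={"n_estimators": 50}, seed=9)
        np.testing.assert_array_equal(a.predict_frame(frame), b.predict_frame(frame))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(KeyError):
            fit_model("sorcery", _separable_frame())

    def test_single_class_rejected(self):
        frame = _separable_frame()
        frame[CLASS_COLUMN] = 1
        with pytest.raises(ValueError):
            fit_model("rf", frame)

    def test_missing_predictor_column_rejected(self):
        frame = _separable_frame()
        model = fit_model("rf", frame, hyperparams={"n_estimators": 20}, seed=0)
        with pytest.raises(KeyError):
            model.predict_frame(frame.drop(columns=["p2"]))

    def test_stack_prediction_na_propagation_and_consistency(self):
        frame = _separable_frame()
        model = fit_model("rf", frame, hyperparams={"n_estimators": 30}, seed=2)
        grid = Grid(5, 5, 1.0)
        rng = np.random.default_rng(4)
        layers = {"p1": rng.standard_normal(grid.shape), "p2": rng.standard_normal(grid.shape)}
        layers["p1"][2, 2] = np.nan
        stack = RasterStack(grid=grid, layers=layers)
        smap = model.predict_stack(stack)
        assert np.isnan(smap[2, 2])
        # frame and stack paths agree on identical predictor vectors
        rows, cols = np.nonzero(stack.valid_mask())
        as_frame = pd.DataFrame({
            "p1": stack.layers["p1"][rows, cols],
            "p2": stack.layers["p2"][rows, cols],
        })
        np.testing.assert_array_equal(model.predict_frame(as_frame), smap[rows, cols])

    def test_fit_seed_derivation_distinct(self):
        seeds = {derive_fit_seed(0, alg, pa, rep)
                 for alg in ("rf", "gbm") for pa in range(1, 11) for rep in range(1, 11)}
        assert len(seeds) == 200
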