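import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from invasdm import (
    fit_beta_glmm,
    permutation_importance,
    region_contrasts,
    scale_importances,
)
from invasdm.importance import squeeze_unit_interval


class _ColumnModel:
    """A 'model' whose prediction is one predictor column (identity map)."""

    def __init__(self, column):
        self.column = column

    def predict_frame(self, frame):
        return frame[self.column].to_numpy(dtype=float)


class _SumModel:
    def predict_frame(self, frame):
        return frame["p1"].to_numpy(dtype=float)


class TestPermutationImportance:
    def test_unused_predictor_scores_zero(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"p1": rng.random(100), "p2": rng.random(100)})
        model = _ColumnModel("p1")
        assert permutation_importance(model, frame, "p2", seed=1) == 0.0

    def test_identity_model_importance_near_one(self):
        """Shuffling the only predictor decorrelates predictions entirely."""
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"p1": rng.random(10_000)})
        model = _ColumnModel("p1")
        imp = permutation_importance(model, frame, "p1", seed=2)
        assert imp == pytest.approx(1.0, abs=0.05)

    def test_constant_predictor_importance_exactly_zero(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"p1": rng.random(50), "flat": np.full(50, 3.0)})
        model = _SumModel()
        assert permutation_importance(model, frame, "flat", seed=0) == 0.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({"p1": rng.random(200), "p2": rng.random(200)})

        class Mix:
            def predict_frame(self, f):
                return 0.7 * f["p1"].to_numpy() + 0.3 * f["p2"].to_numpy()

        a = permutation_importance(Mix(), frame, "p2", seed=11)
        b = permutation_importance(Mix(), frame, "p2", seed=11)
        assert a == b

    def test_raw_importance_within_zero_two(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({"p1": rng.random(300)})

        class Anti:  # anti-correlated after shuffling is impossible beyond 2
            def predict_frame(self, f):
                return -f["p1"].to_numpy()

        imp = permutation_importance(Anti(), frame, "p1", seed=5)
        assert 0.0 <= imp <= 2.0


class TestScaleImportances:
    def _table(self, raws, runs=None, regions=None):
        n = len(raws)
        return pd.DataFrame({
            "run": runs or ["r1"] * n,
            "region": regions or ["A"] * n,
            "predictor": [f"p{i}" for i in range(n)],
            "raw_importance": raws,
        })

    def test_normalization(self):
        out = scale_importances(self._table([2.0, 1.0, 1.0]))
        np.testing.assert_allclose(out["scaled_importance"], [0.5, 0.25, 0.25])

    def test_already_normalized_unchanged(self):
        out = scale_importances(self._table([0.6, 0.4]))
        np.testing.assert_allclose(out["scaled_importance"], [0.6, 0.4])

    def test_all_zero_group_flagged(self):
        out = scale_importances(self._table([0.0, 0.0]))
        assert (out["scaled_importance"] == 0).all()
        assert out["all_zero_group"].all()

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            scale_importances(self._table([-0.1, 0.5]))

    def test_group_sums_to_one_property(self):
        rng = np.random.default_rng(5)
        rows = []
        for run in ["r1", "r2", "r3"]:
            for region in ["A", "B"]:
                for p in ["x", "y", "z"]:
                    rows.append({"run": run, "region": region, "predictor": p,
                                 "raw_importance": rng.random()})
        out = scale_importances(pd.DataFrame(rows))
        sums = out.groupby(["run", "region"])["scaled_importance"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def _simulate_table(rng, n_runs=50, shift_predictor=None, shift=0.0, sigma_b=0.3, phi=30.0):
    rows = []
    for run in range(n_runs):
        b = rng.normal(0, sigma_b)
        for region in ["invasive", "native"]:
            for j, p in enumerate(["p1", "p2", "p3"]):
                eta = -1.0 + 0.5 * j + b
                if region == "native" and p == shift_predictor:
                    eta += shift
                mu = expit(eta)
                y = rng.beta(mu * phi, (1 - mu) * phi)
                rows.append({"run": f"r{run:02d}", "region": region,
                             "predictor": p, "scaled_importance": y})
    return pd.DataFrame(rows)


def _betareg_nll_oracle(theta, y, cell_idx, n_cells):
    """Plain beta-regression likelihood for the generic-optimizer cross-check."""
    mu = expit(theta[:n_cells][cell_idx])
    phi = np.exp(theta[n_cells:][cell_idx])
    a, b = mu * phi, (1 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
    return -ll.sum()


class TestBetaGLMM:
    def test_all_half_outcomes_give_zero_logit_intercept(self):
        rows = [{"run": f"r{i}", "region": reg, "predictor": p, "scaled_importance": 0.5}
                for i in range(6) for reg in ["A", "B"] for p in ["x", "y"]]
        fit = fit_beta_glmm(pd.DataFrame(rows))
        assert np.all(np.abs(fit.beta) < 0.05)

    def test_matches_generic_optimizer_without_random_effect(self):
        """Coefficient recovery vs an independent optimizer fit of the same likelihood."""
        rng = np.random.default_rng(10)
        tab = _simulate_table(rng, n_runs=40, sigma_b=0.0)
        fit = fit_beta_glmm(tab, min_groups_for_random_effect=10_000)  # force fixed-effects
        assert not fit.has_random_effect

        regions = sorted(tab["region"].unique())
        predictors = sorted(tab["predictor"].unique())
        r_idx = tab["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
        p_idx = tab["predictor"].map({p: i for i, p in enumerate(predictors)}).to_numpy()
        cell_idx = r_idx * len(predictors) + p_idx
        y = squeeze_unit_interval(tab["scaled_importance"].to_numpy(), len(tab))
        n_cells = len(regions) * len(predictors)
        res = minimize(
            _betareg_nll_oracle, np.concatenate([np.zeros(n_cells), np.full(n_cells, np.log(5))]),
            args=(y, cell_idx, n_cells), method="BFGS",
        )
        np.testing.assert_allclose(fit.beta.ravel(), res.x[:n_cells], atol=1e-3)
        np.testing.assert_allclose(fit.gamma.ravel(), res.x[n_cells:], atol=1e-3)

    def test_shift_recovery_with_random_effect(self):
        rng = np.random.default_rng(11)
        tab = _simulate_table(rng, shift_predictor="p2", shift=1.0)
        fit = fit_beta_glmm(tab)
        assert fit.converged and fit.has_random_effect
        ctr = region_contrasts(fit, invasive_region="invasive").set_index("predictor")
        assert abs(ctr.loc["p2", "estimate"] - 1.0) <= 2 * ctr.loc["p2", "se"]
        assert ctr.loc["p2", "z"] > 2

    def test_symmetric_data_contrasts_near_zero(self):
        rng = np.random.default_rng(12)
        tab = _simulate_table(rng)
        ctr = region_contrasts(fit_beta_glmm(tab), invasive_region="invasive")
        assert np.all(np.abs(ctr["estimate"]) < 0.3)

    def test_relabeling_flips_contrast_signs(self):
        rng = np.random.default_rng(13)
        tab = _simulate_table(rng, shift_predictor="p1", shift=0.8)
        fit = fit_beta_glmm(tab)
        a = region_contrasts(fit, invasive_region="invasive")
        swapped = tab.assign(region=tab["region"].map({"invasive": "native", "native": "invasive"}))
        b = region_contrasts(fit_beta_glmm(swapped), invasive_region="invasive")
        np.testing.assert_allclose(a["estimate"], -b["estimate"], atol=0.02)
        np.testing.assert_allclose(np.abs(a["z"]), np.abs(b["z"]), rtol=0.05)

    def test_sign_convention_negative_means_invasive(self):
        rng = np.random.default_rng(14)
        # p1 more important in the INVASIVE region
        tab = _simulate_table(rng)
        inv = (tab["region"] == "invasive") & (tab["predictor"] == "p1")
        tab.loc[inv, "scaled_importance"] = np.clip(
            tab.loc[inv, "scaled_importance"] + 0.25, 0.01, 0.99
        )
        ctr = region_contrasts(fit_beta_glmm(tab), invasive_region="invasive")
        assert ctr.set_index("predictor").loc["p1", "estimate"] < 0

    def test_outcomes_outside_unit_interval_rejected(self):
        tab = _simulate_table(np.random.default_rng(15), n_runs=5)
        tab.loc[0, "scaled_importance"] = 1.5
        with pytest.raises(ValueError):
            fit_beta_glmm(tab)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(16)
        tab = _simulate_table(rng, shift_predictor="p3", shift=1.2)
        ctr = region_contrasts(fit_beta_glmm(tab), invasive_region="invasive", holm=True)
        assert (ctr["p_holm"] >= ctr["p"] - 1e-15).all()
        assert (ctr["p_holm"] <= 1.0).all()
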