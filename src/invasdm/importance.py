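"""Permutation variable importance and beta-regression mixed-model inference.

Importance of a predictor is measured by prediction perturbation: shuffle
the predictor's values, re-predict, and take ``1 - Pearson correlation``
between the reference and shuffled predictions, averaged over nine
shuffles. A predictor the model never uses scores exactly 0; a predictor
that fully determines the output scores near 1 (the raw scale is [0, 2]).
Raw importances are standardized to sum to one within each model run x
region, making them comparable across predictors and regions.

Regional differences in scaled importance are modeled with a beta
regression mixed model: the outcome follows a Beta distribution whose
logit mean and log precision are both linear in region, predictor and
their interaction, with a Gaussian random intercept per model run
(integrated by a Laplace approximation). Region contrasts are differences
of estimated marginal means on the logit-link scale, with delta-method
standard errors; the sign convention is fixed so that a negative contrast
means the predictor is more influential in the invasive range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit, polygamma

# ----------------------------------------------------------------------
# permutation importance
# ----------------------------------------------------------------------


def _safe_pearson(ref: np.ndarray, shuffled: np.ndarray) -> float:
    """Pearson r with the degenerate-case conventions of the importance score.

    A constant shuffled prediction vector means the shuffle had no effect
    worth measuring: its correlation is defined as 1 (importance 0).
    """
    if np.std(shuffled) == 0 or np.std(ref) == 0:
        return 1.0
    return float(np.corrcoef(ref, shuffled)[0, 1])


def permutation_importance(
    model,
    frame: pd.DataFrame,
    predictor: str,
    n_shuffles: int = 9,
    seed: int = 0,
    reference: np.ndarray | None = None,
) -> float:
    """Raw permutation importance of one predictor: mean over shuffles of (1 - r)."""
    if len(frame) < 3:
        raise ValueError("need at least 3 rows to estimate importance")
    if predictor not in frame.columns:
        raise KeyError(f"predictor {predictor!r} not in frame")
    ref = np.asarray(reference if reference is not None else model.predict_frame(frame), dtype=float)
    if np.std(ref) == 0:
        # nothing to perturb: every predictor is reported as 0 by the caller
        return 0.0
    rng = np.random.default_rng(seed)
    work = frame.copy()
    col = work[predictor].to_numpy().copy()
    total = 0.0
    for _ in range(n_shuffles):
        work[predictor] = rng.permutation(col)
        shuffled = np.asarray(model.predict_frame(work), dtype=float)
        total += 1.0 - _safe_pearson(ref, shuffled)
    return total / n_shuffles


def compute_importance_table(
    models: dict[str, object],
    frame: pd.DataFrame,
    valid_idx_by_run: dict[str, np.ndarray],
    predictors: list[str],
    n_shuffles: int = 9,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Raw importance per (run, region, predictor) on each run's validation rows.

    Region-wise importance is computed separately on the validation rows of
    each region, so a predictor can matter in one range and not the other.
    """
    records = []
    for run_id in sorted(models):
        model = models[run_id]
        sub = frame.iloc[valid_idx_by_run[run_id]]
        for region, rows in sub.groupby("region"):
            ref = np.asarray(model.predict_frame(rows), dtype=float)
            ref_constant = np.std(ref) == 0
            for j, pred in enumerate(predictors):
                seed = _mix_seed(base_seed, run_id, str(region), pred)
                raw = (
                    0.0
                    if ref_constant
                    else permutation_importance(
                        model, rows, pred, n_shuffles=n_shuffles, seed=seed, reference=ref
                    )
                )
                records.append(
                    {
                        "run": run_id,
                        "region": region,
                        "predictor": pred,
                        "raw_importance": raw,
                        "reference_constant": ref_constant,
                    }
                )
    return pd.DataFrame.from_records(records)


def _mix_seed(base_seed: int, *tokens: str) -> int:
    h = int(base_seed) % 2**32
    for token in tokens:
        for ch in token:
            h = (h * 31 + ord(ch)) % 2**32
    return h % (2**31 - 1)


def scale_importances(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw importances to sum to one within (run, region).

    All-zero groups pass through as zeros with ``all_zero_group`` flagged.
    """
    if (raw_table["raw_importance"] < 0).any():
        raise ValueError("raw importances must be non-negative")
    out = raw_table.copy()
    sums = out.groupby(["run", "region"])["raw_importance"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["scaled_importance"] = np.where(sums > 0, out["raw_importance"] / sums, 0.0)
    out["all_zero_group"] = sums == 0
    return out


# ----------------------------------------------------------------------
# beta regression mixed model
# ----------------------------------------------------------------------
@dataclass
class BetaRegFit:
    """A fitted beta GLMM over scaled importances.

    ``beta``/``gamma`` are (n_regions, n_predictors) cell-means coefficient
    matrices for the logit mean and log precision; ``cov`` is the observed
    covariance of the flattened parameter vector [beta, gamma, log_sigma].
    """

    regions: list[str]
    predictors: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    sigma: float
    random_effects: pd.Series | None
    loglik: float
    converged: bool
    cov: np.ndarray
    has_random_effect: bool
    n_squeeze: int
    boundary_squeezed: int


class _BetaGLMM:
    """Laplace-approximated beta GLMM with cell-means region x predictor design."""

    def __init__(self, y, cell_idx, group_idx, n_cells, n_groups, random_effect=True):
        self.y = y
        self.logit_y = np.log(y) - np.log1p(-y)
        self.cell_idx = cell_idx
        self.group_idx = group_idx
        self.n_cells = n_cells
        self.n_groups = n_groups
        self.random_effect = random_effect
        self._b = np.zeros(n_groups)  # warm start for the inner mode search

    # per-row log-likelihood and eta-derivatives at given linear predictors
    def _row_terms(self, eta, log_phi):
        mu = expit(eta)
        phi = np.exp(log_phi)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(self.y)
            + (b - 1.0) * np.log1p(-self.y)
        )
        dl_dmu = phi * (-digamma(a) + digamma(b) + self.logit_y)
        v = mu * (1.0 - mu)
        d1 = dl_dmu * v
        d2l_dmu2 = -(phi**2) * (polygamma(1, a) + polygamma(1, b))
        d2 = d2l_dmu2 * v**2 + dl_dmu * v * (1.0 - 2.0 * mu)
        return ll, d1, d2

    def _laplace(self, beta_cells, gamma_cells, sigma2):
        """Marginal log-likelihood via a vectorized per-group Newton mode search."""
        eta0 = beta_cells[self.cell_idx]
        log_phi = gamma_cells[self.cell_idx]
        b = self._b.copy()
        for _ in range(50):
            ll, d1, d2 = self._row_terms(eta0 + b[self.group_idx], log_phi)
            g = np.bincount(self.group_idx, weights=d1, minlength=self.n_groups) - b / sigma2
            h = np.bincount(self.group_idx, weights=d2, minlength=self.n_groups) - 1.0 / sigma2
            h = np.minimum(h, -1e-10)
            step = g / h
            # dampen long steps to keep the mode search stable
            step = np.clip(step, -2.0, 2.0)
            b = b - step
            if np.max(np.abs(g)) < 1e-9:
                break
        self._b = b
        ll, d1, d2 = self._row_terms(eta0 + b[self.group_idx], log_phi)
        h = np.bincount(self.group_idx, weights=d2, minlength=self.n_groups) - 1.0 / sigma2
        h = np.minimum(h, -1e-10)
        group_ll = np.bincount(self.group_idx, weights=ll, minlength=self.n_groups)
        lap = group_ll - b**2 / (2.0 * sigma2) - 0.5 * np.log(sigma2 * (-h))
        return float(lap.sum()), b

    def nll(self, theta):
        k = self.n_cells
        beta_cells = theta[:k]
        gamma_cells = theta[k : 2 * k]
        if self.random_effect:
            sigma2 = np.exp(2.0 * theta[2 * k])
            ll, _ = self._laplace(beta_cells, gamma_cells, sigma2)
        else:
            row_ll, _, _ = self._row_terms(
                beta_cells[self.cell_idx], gamma_cells[self.cell_idx]
            )
            ll = float(row_ll.sum())
        if not np.isfinite(ll):
            return 1e10
        return -ll


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink [0,1] outcomes strictly inside the beta support: (y(n-1)+0.5)/n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    return (y * (n - 1) + 0.5) / n


def fit_beta_glmm(
    table: pd.DataFrame,
    outcome: str = "scaled_importance",
    min_groups_for_random_effect: int = 5,
) -> BetaRegFit:
    """Fit the beta GLMM: logit mean and log precision ~ region * predictor.

    Boundary outcomes (exact 0/1, legal for scaled importances) are squeezed
    inside (0, 1) before fitting. The run-level random intercept is dropped
    when there are fewer than ``min_groups_for_random_effect`` runs (its
    variance is not identifiable from so few groups).
    """
    y_raw = table[outcome].to_numpy(dtype=float)
    if np.any(y_raw < 0) or np.any(y_raw > 1):
        raise ValueError("outcomes must lie in [0, 1]")
    regions = sorted(table["region"].unique())
    predictors = sorted(table["predictor"].unique())
    runs = sorted(table["run"].unique())
    if len(regions) < 2 or len(predictors) < 2 or len(runs) < 2:
        raise ValueError("need >= 2 regions, >= 2 predictors and >= 2 runs")

    n = len(table)
    boundary = int(((y_raw <= 0) | (y_raw >= 1)).sum())
    y = squeeze_unit_interval(y_raw, n)

    r_idx = table["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    p_idx = table["predictor"].map({p: i for i, p in enumerate(predictors)}).to_numpy()
    cell_idx = r_idx * len(predictors) + p_idx
    g_map = {g: i for i, g in enumerate(runs)}
    group_idx = table["run"].map(g_map).to_numpy()
    n_cells = len(regions) * len(predictors)

    use_re = len(runs) >= min_groups_for_random_effect
    model = _BetaGLMM(y, cell_idx, group_idx, n_cells, len(runs), random_effect=use_re)

    # start: logit of cell means; moderate precision; small RE sd
    cell_means = np.full(n_cells, 0.5)
    sums = np.bincount(cell_idx, weights=y, minlength=n_cells)
    counts = np.bincount(cell_idx, minlength=n_cells)
    nonempty = counts > 0
    cell_means[nonempty] = sums[nonempty] / counts[nonempty]
    beta0 = logit(np.clip(cell_means, 1e-4, 1 - 1e-4))
    theta0 = np.concatenate([beta0, np.full(n_cells, np.log(10.0))])
    if use_re:
        theta0 = np.concatenate([theta0, [np.log(0.1)]])

    res = minimize(
        model.nll,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    cov = _observed_covariance(model.nll, theta)

    beta = theta[:n_cells].reshape(len(regions), len(predictors))
    gamma = theta[n_cells : 2 * n_cells].reshape(len(regions), len(predictors))
    sigma = float(np.exp(theta[2 * n_cells])) if use_re else 0.0
    ranef = None
    if use_re:
        _, b = model._laplace(theta[:n_cells], theta[n_cells : 2 * n_cells], sigma**2)
        ranef = pd.Series(b, index=runs, name="random_intercept")
    return BetaRegFit(
        regions=regions,
        predictors=predictors,
        beta=beta,
        gamma=gamma,
        sigma=sigma,
        random_effects=ranef,
        loglik=-float(res.fun),
        converged=bool(res.success),
        cov=cov,
        has_random_effect=use_re,
        n_squeeze=n,
        boundary_squeezed=boundary,
    )


def _observed_covariance(nll, theta, rel_step: float = 1e-4) -> np.ndarray:
    """Covariance = inverse of a central-difference Hessian of the negative ll."""
    k = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    # gradient via central differences, differentiated again centrally
    def grad(t):
        g = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            g[i] = (nll(t + e) - nll(t - e)) / (2 * h[i])
        return g

    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        H[:, j] = (grad(theta + e) - grad(theta - e)) / (2 * h[j])
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov


# ----------------------------------------------------------------------
# region contrasts
# ----------------------------------------------------------------------
from scipy.stats import norm as _norm  # noqa: E402


@dataclass
class ContrastResult:
    predictor: str
    estimate: float
    se: float
    z: float
    p: float


def region_contrasts(
    fit: BetaRegFit,
    invasive_region: str | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-predictor region contrast of estimated marginal means (logit scale).

    Computed as EMM(native) - EMM(invasive), so a negative estimate means
    the predictor is more influential in the invasive range. Two-sided p
    from the normal reference; optional Holm adjustment.
    """
    if not fit.converged:
        raise ValueError("cannot form contrasts from a non-converged fit")
    if len(fit.regions) != 2:
        raise ValueError("region contrasts require exactly two regions")
    if invasive_region is None:
        invasive_region = fit.regions[0]
    if invasive_region not in fit.regions:
        raise KeyError(f"unknown region {invasive_region!r}")
    i_inv = fit.regions.index(invasive_region)
    i_nat = 1 - i_inv
    P = len(fit.predictors)
    rows = []
    for k, pred in enumerate(fit.predictors):
        j_nat = i_nat * P + k
        j_inv = i_inv * P + k
        est = fit.beta[i_nat, k] - fit.beta[i_inv, k]
        var = fit.cov[j_nat, j_nat] + fit.cov[j_inv, j_inv] - 2.0 * fit.cov[j_nat, j_inv]
        if var <= 0 or not np.isfinite(var):
            raise np.linalg.LinAlgError(
                f"singular covariance for contrast of predictor {pred!r}"
            )
        se = float(np.sqrt(var))
        z = est / se
        p = 2.0 * _norm.sf(abs(z))
        rows.append(ContrastResult(predictor=pred, estimate=float(est), se=se, z=float(z), p=float(p)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if holm:
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
    return df
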