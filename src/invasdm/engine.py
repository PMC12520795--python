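"""Model frames, repeated stratified splits and the algorithm registry.

Each pseudo-absence set joined to the presence cells yields one balanced
model frame (class 1 = presence, class 0 = pseudo-absence, 1:1 per region).
Frames are split 70/30, stratified by region x class, ten times with
distinct seeds — repeated random splits rather than disjoint folds, so the
full design is n_pa_sets x n_reps constituent fits per algorithm.

The registry exposes presence/background classifiers behind one contract: a
fitted model maps a predictor vector to a score in [0, 1], deterministically
for a given seed. Random Forest (RF), Gradient Boosting Machines (GBM),
Classification Tree Analysis (CTA) and Artificial Neural Networks (ANN) are
always available; Extreme Gradient Boosting (XGB) and a penalized-logistic
Maximum Entropy approximation (MAXENT) plug in behind the same contract.
Hyperparameter defaults are declared here and overridable per algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .grid import RasterStack
from .occurrences import PresenceCells
from .pseudoabsence import PASet

CLASS_COLUMN = "label"
META_COLUMNS = ["row", "col", "region", CLASS_COLUMN]


# ----------------------------------------------------------------------
# frames
# ----------------------------------------------------------------------
def assemble_frame(presences: PresenceCells, pa_set: PASet, stack: RasterStack) -> pd.DataFrame:
    """Join presence and pseudo-absence cells with predictor values.

    One row per cell; predictor vector = every stack layer (effort
    included) at the cell. Any NA predictor is an error — both presences and
    pseudo-absences are restricted to cells with complete data upstream.
    """
    names = stack.layer_names
    parts = []
    for cells, label in ((presences.cells, 1), (pa_set.cells, 0)):
        vals = stack.values_at(cells["row"].to_numpy(), cells["col"].to_numpy(), names)
        df = pd.DataFrame(vals, columns=names)
        df.insert(0, CLASS_COLUMN, label)
        df.insert(0, "region", cells["region"].to_numpy())
        df.insert(0, "col", cells["col"].to_numpy())
        df.insert(0, "row", cells["row"].to_numpy())
        parts.append(df)
    frame = pd.concat(parts, ignore_index=True)
    if frame[names].isna().any().any():
        bad = frame[names].isna().any(axis=1).sum()
        raise ValueError(f"{bad} frame rows have NA predictors")
    return frame


@dataclass
class SplitPlan:
    pa_set_id: int
    rep_id: int
    seed: int
    train_idx: np.ndarray
    valid_idx: np.ndarray


def split_train_valid(
    frame: pd.DataFrame,
    train_frac: float = 0.7,
    n_reps: int = 10,
    base_seed: int = 0,
    pa_set_id: int = 0,
) -> list[SplitPlan]:
    """Repeated stratified 70/30 splits.

    Stratification is by region x class; within every stratum the train
    fraction is ``train_frac`` to within one row. Rep ``r`` (1-based) uses
    seed ``base_seed + r``.
    """
    strata = frame.groupby(["region", CLASS_COLUMN], sort=True).indices
    for key, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {key} has fewer than 2 rows; cannot split")
    plans = []
    for r in range(1, n_reps + 1):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        train_parts, valid_parts = [], []
        for key in sorted(strata):
            idx = np.asarray(strata[key])
            perm = rng.permutation(idx)
            n_train = int(round(train_frac * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_parts.append(perm[:n_train])
            valid_parts.append(perm[n_train:])
        plans.append(
            SplitPlan(
                pa_set_id=pa_set_id,
                rep_id=r,
                seed=seed,
                train_idx=np.sort(np.concatenate(train_parts)),
                valid_idx=np.sort(np.concatenate(valid_parts)),
            )
        )
    return plans


# ----------------------------------------------------------------------
# algorithm registry
# ----------------------------------------------------------------------
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500, "max_features": "sqrt"},
    "gbm": {"n_estimators": 1000, "max_depth": 3, "learning_rate": 0.01},
    "cta": {"cv_folds": 5},  # cost-complexity pruned by internal CV
    "ann": {"hidden_units": 8, "weight_decay": 0.01, "max_iter": 2000},
    "xgb": {"n_estimators": 500, "max_depth": 4, "learning_rate": 0.05},
    "maxent": {"C": 1.0},  # penalized logistic approximation
}


def _extras(hp, *known):
    return {k: v for k, v in hp.items() if k not in known}


def _make_rf(hp, seed):
    return RandomForestClassifier(
        n_estimators=hp["n_estimators"],
        max_features=hp["max_features"],
        random_state=seed,
        n_jobs=1,
        **_extras(hp, "n_estimators", "max_features"),
    )


def _make_gbm(hp, seed):
    return GradientBoostingClassifier(
        n_estimators=hp["n_estimators"],
        max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"],
        random_state=seed,
        **_extras(hp, "n_estimators", "max_depth", "learning_rate"),
    )


class _PrunedTree:
    """Decision tree with cost-complexity pruning chosen by internal CV."""

    def __init__(self, hp, seed):
        self.hp = hp
        self.seed = seed
        self.tree_: DecisionTreeClassifier | None = None

    def fit(self, X, y):
        base = DecisionTreeClassifier(random_state=self.seed)
        path = base.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
        if len(alphas) > 12:  # thin the candidate list; CV cost is linear in it
            alphas = alphas[np.linspace(0, len(alphas) - 1, 12).astype(int)]
        best_alpha, best_score = 0.0, -np.inf
        folds = min(self.hp["cv_folds"], int(np.min(np.bincount(y.astype(int)))))
        for a in alphas:
            tree = DecisionTreeClassifier(random_state=self.seed, ccp_alpha=a)
            cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=self.seed)
            score = cross_val_score(tree, X, y, cv=cv, scoring="accuracy").mean()
            if score > best_score:
                best_alpha, best_score = a, score
        self.tree_ = DecisionTreeClassifier(random_state=self.seed, ccp_alpha=best_alpha)
        self.tree_.fit(X, y)
        return self

    def predict_proba(self, X):
        return self.tree_.predict_proba(X)

    @property
    def classes_(self):
        return self.tree_.classes_


def _make_cta(hp, seed):
    return _PrunedTree(hp, seed)


def _make_ann(hp, seed):
    return MLPClassifier(
        hidden_layer_sizes=(hp["hidden_units"],),
        alpha=hp["weight_decay"],
        max_iter=hp["max_iter"],
        random_state=seed,
        **_extras(hp, "hidden_units", "weight_decay", "max_iter"),
    )


def _make_xgb(hp, seed):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=hp["n_estimators"],
        max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"],
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **_extras(hp, "n_estimators", "max_depth", "learning_rate"),
    )


def _make_maxent(hp, seed):
    # background-contrasted penalized logistic regression; fidelity to the
    # original MaxEnt software is a non-goal
    return LogisticRegression(C=hp["C"], max_iter=5000, random_state=seed,
                              **_extras(hp, "C"))


ALGORITHM_REGISTRY: dict[str, Callable] = {
    "rf": _make_rf,
    "gbm": _make_gbm,
    "cta": _make_cta,
    "ann": _make_ann,
    "xgb": _make_xgb,
    "maxent": _make_maxent,
}


def derive_fit_seed(base_seed: int, algorithm_id: str, pa_set_id: int, rep_id: int) -> int:
    """Deterministic per-fit seed from (algorithm, pa_set, rep)."""
    h = int(base_seed) % 2**32
    for token in (algorithm_id, str(pa_set_id), str(rep_id)):
        for ch in token:
            h = (h * 31 + ord(ch)) % 2**32
    return h % (2**31 - 1)


@dataclass
class FittedModel:
    """A trained predictor-to-score function with its provenance."""

    algorithm_id: str
    pa_set_id: int
    rep_id: int
    feature_names: list[str]
    estimator: object
    seed: int

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in frame.columns]
        if missing:
            raise KeyError(f"frame missing predictor columns: {missing}")
        X = frame[self.feature_names].to_numpy(dtype=float)
        return self._score(X)

    def predict_stack(self, stack: RasterStack) -> np.ndarray:
        """Per-cell scores over a stack; NA cells propagate to NA."""
        missing = [c for c in self.feature_names if c not in stack.layers]
        if missing:
            raise KeyError(f"stack missing predictor layers: {missing}")
        valid = stack.valid_mask(self.feature_names)
        out = np.full(stack.grid.shape, np.nan)
        rows, cols = np.nonzero(valid)
        if rows.size:
            X = stack.values_at(rows, cols, self.feature_names)
            out[rows, cols] = self._score(X)
        return out

    def _score(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        cls = list(self.estimator.classes_)
        return proba[:, cls.index(1)]


def fit_model(
    algorithm_id: str,
    frame: pd.DataFrame,
    feature_names: list[str] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
    pa_set_id: int = 0,
    rep_id: int = 0,
) -> FittedModel:
    """Fit one registered algorithm on the given frame rows."""
    if algorithm_id not in ALGORITHM_REGISTRY:
        raise KeyError(
            f"unknown algorithm {algorithm_id!r}; registered: {sorted(ALGORITHM_REGISTRY)}"
        )
    if feature_names is None:
        feature_names = [c for c in frame.columns if c not in META_COLUMNS]
    y = frame[CLASS_COLUMN].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    hp = {**DEFAULT_HYPERPARAMS[algorithm_id], **(hyperparams or {})}
    est = ALGORITHM_REGISTRY[algorithm_id](hp, seed)
    X = frame[feature_names].to_numpy(dtype=float)
    est.fit(X, y)
    return FittedModel(
        algorithm_id=algorithm_id,
        pa_set_id=pa_set_id,
        rep_id=rep_id,
        feature_names=list(feature_names),
        estimator=est,
        seed=seed,
    )
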