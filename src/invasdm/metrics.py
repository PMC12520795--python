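"""Discrimination metrics: max-TSS, continuous Boyce index, confusion summaries.

The True Skill Statistic (TSS = sensitivity + specificity - 1) is maximized
over candidate thresholds; the continuous Boyce index is the Spearman rank
correlation between the predicted-to-expected presence ratio in overlapping
suitability windows and the window midpoint. Both are region-stratified
throughout the pipeline: the two ranges differ enormously in sample size and
environment, and pooled metrics would hide a failure in the smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class TSSResult:
    tss: float
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class EvalResult:
    """Region-stratified discrimination metrics for one model or ensemble."""

    model_id: str
    region: str
    tss: float
    threshold_at_max_tss: float
    boyce: float
    sensitivity: float
    specificity: float
    accuracy: float
    kappa: float
    balanced_accuracy: float
    n_presence: int
    n_background: int

    def to_dict(self) -> dict:
        return asdict(self)


def optimal_tss(obs, scores) -> TSSResult:
    """Maximize TSS over thresholds; positive prediction iff score >= threshold.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores plus {0, 1}; ties in max TSS break toward the larger threshold.
    """
    obs = np.asarray(obs)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = obs == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute TSS")

    uniq = np.unique(scores)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    candidates = np.unique(candidates)
    # sensitivity/specificity for all thresholds at once
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    tn = (~pred & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    tss = sens + spec - 1.0
    best = np.max(tss)
    idx = np.flatnonzero(tss == best)[-1]  # ties -> larger threshold
    return TSSResult(
        tss=float(tss[idx]),
        threshold=float(candidates[idx]),
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
    )


def boyce_index(
    presence_scores,
    background_scores,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> float:
    """Continuous Boyce index.

    Overlapping windows of width ``window_width`` x the combined score range
    slide across that range; each window's P/E ratio is the fraction of
    presence scores inside it divided by the fraction of background scores
    inside it. The index is the Spearman correlation between P/E and the
    window midpoint, skipping windows with zero background mass; consecutive
    duplicate P/E values are retained (rank averaging handles ties).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    w = window_width * (hi - lo)
    if w <= 0:
        raise ValueError("degenerate score range: all scores identical")
    lows = np.linspace(lo, hi - w, n_windows)
    mids = lows + w / 2.0
    pe = np.empty(n_windows)
    valid = np.zeros(n_windows, dtype=bool)
    for i, lw in enumerate(lows):
        # closed on the upper end for the last window so the max score counts
        hi_edge = lw + w
        if i == n_windows - 1:
            in_p = (p >= lw) & (p <= hi_edge)
            in_b = (b >= lw) & (b <= hi_edge)
        else:
            in_p = (p >= lw) & (p < hi_edge)
            in_b = (b >= lw) & (b < hi_edge)
        fb = in_b.mean()
        if fb > 0:
            pe[i] = in_p.mean() / fb
            valid[i] = True
    if valid.sum() < 2:
        raise ValueError("fewer than 2 windows with background mass")
    if np.all(pe[valid] == pe[valid][0]):
        return 0.0  # flat P/E curve: presences track background, no enrichment
    rho = spearmanr(pe[valid], mids[valid]).statistic
    return float(rho)


def confusion_summary(obs, scores, threshold: float) -> dict:
    """Standard 2x2 confusion metrics at a fixed threshold (positive iff >=)."""
    obs = np.asarray(obs)
    pred = np.asarray(scores, dtype=float) >= threshold
    pos = obs == 1
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    n = tp + fn + fp + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / n
    p_yes = ((tp + fn) / n) * ((tp + fp) / n)
    p_no = ((tn + fp) / n) * ((tn + fn) / n)
    pe = p_yes + p_no
    kappa = 0.0 if pe == 1.0 else (acc - pe) / (1.0 - pe)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "kappa": kappa,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def evaluate_scores(
    model_id: str,
    region: str,
    obs,
    scores,
    boyce_presence_scores=None,
    boyce_background_scores=None,
    strict_boyce: bool = True,
    **boyce_kwargs,
) -> EvalResult:
    """TSS + Boyce + confusion for one model x region.

    By default Boyce uses the same presence/background scores as TSS; a
    fixed presence set can be supplied separately (ensemble evaluation uses
    the fixed presence locations against the partition's background scores).
    With ``strict_boyce=False``, a degenerate Boyce (fewer than two windows
    with background mass, e.g. all background scored identically on a small
    validation split) is reported as NaN instead of raising, so replicate
    averaging can skip it.
    """
    obs = np.asarray(obs)
    scores = np.asarray(scores, dtype=float)
    t = optimal_tss(obs, scores)
    conf = confusion_summary(obs, scores, t.threshold)
    bp = boyce_presence_scores if boyce_presence_scores is not None else scores[obs == 1]
    bb = boyce_background_scores if boyce_background_scores is not None else scores[obs == 0]
    try:
        bi = boyce_index(bp, bb, **boyce_kwargs)
    except ValueError:
        if strict_boyce:
            raise
        bi = float("nan")
    return EvalResult(
        model_id=model_id,
        region=region,
        tss=t.tss,
        threshold_at_max_tss=t.threshold,
        boyce=bi,
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        accuracy=conf["accuracy"],
        kappa=conf["kappa"],
        balanced_accuracy=conf["balanced_accuracy"],
        n_presence=int((obs == 1).sum()),
        n_background=int((obs == 0).sum()),
    )


def select_best(eval_table: pd.DataFrame, regions: tuple[str, str] | None = None) -> str:
    """Pick the candidate with the highest joint mean of TSS and Boyce.

    ``eval_table`` needs columns model_id, region, tss, boyce with every
    candidate evaluated in both regions. Score = mean(TSS_A, TSS_B, BI_A,
    BI_B); ties break by higher mean TSS, then lexicographic id.
    """
    if regions is None:
        regions = tuple(sorted(eval_table["region"].unique()))
    scores = []
    for mid, sub in eval_table.groupby("model_id"):
        present = set(sub["region"])
        missing = set(regions) - present
        if missing:
            raise ValueError(f"candidate {mid!r} missing metrics for regions {sorted(missing)}")
        sub = sub[sub["region"].isin(regions)]
        joint = float(np.mean(np.concatenate([sub["tss"].to_numpy(), sub["boyce"].to_numpy()])))
        scores.append((joint, float(sub["tss"].mean()), str(mid)))
    # maximize joint, then mean TSS; minimize id lexicographically
    scores.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return scores[0][2]
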