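"""End-to-end pipeline: synthetic landscape -> ensembles -> maps and inference.

``run_pipeline`` executes the whole analysis from one :class:`RunConfig`:

1. simulate the landscape (autocorrelated predictors, logistic suitability
   truth, observer-activity surface) and effort-biased occurrences;
2. build the effort layer, clean/filter/thin occurrences to presence cells;
3. prune collinear predictors and standardize;
4. draw replicated pseudo-absence sets (cell exclusion in the invasive
   range, uncertainty-buffer exclusion in the native range);
5. fit the algorithm registry over PA sets x repeated stratified splits;
6. build per-algorithm and global ensembles, evaluate region-stratified
   TSS/Boyce per split, and select the best by joint mean;
7. permutation importance on the first PA set's validation partition,
   beta-GLMM region contrasts;
8. project standardized- and observed-effort suitability maps, aggregate a
   synthetic independent survey, and score focal-species overlap.

Every stage draws its seed from the global seed through a documented hash
(:func:`stage_seed`), so stages rerun identically in isolation. All tables
are written as CSV with a fixed float format, so identical configs produce
byte-identical outputs; stage counts and seeds go to a JSON-lines log.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensembles as ens
from . import metrics as met
from .config import RunConfig
from .engine import (
    CLASS_COLUMN,
    META_COLUMNS,
    assemble_frame,
    derive_fit_seed,
    fit_model,
    split_train_valid,
)
from .grid import Grid, RasterStack, split_region_mask, write_ascii_grid
from .importance import (
    compute_importance_table,
    fit_beta_glmm,
    region_contrasts,
    scale_importances,
)
from .occurrences import basic_clean, filter_uncertainty, thin_to_cells
from .predictors import attach_effort, build_effort, prune_collinear, standardize
from .projection import (
    EFFORT_OBSERVED,
    EFFORT_STANDARDIZED,
    aggregate_independent,
    overlap_summary,
    project_map,
)
from .pseudoabsence import (
    draw_pa_sets,
    eligible_cells_bufferexcl,
    eligible_cells_cellexcl,
    pa_sets_to_frame,
)
from .synth import (
    INVASIVE_CU,
    MixtureCU,
    UniformCU,
    define_truth,
    sample_occurrences,
    simulate_predictors,
)

_FLOAT_FMT = "%.10g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: a 31-bit multiplicative string hash."""
    h = int(global_seed) % 2**32
    for ch in stage:
        h = (h * 1000003 + ord(ch)) % 2**32
    return h % (2**31 - 1)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def stage(self, name: str, **fields) -> None:
        rec = {"stage": name, **fields}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written to disk)."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    log_path = out / "log.jsonl"
    log_path.write_text("")
    log = _RunLog(log_path)

    lc, tc, sc = config.landscape, config.truth, config.sampling
    inv, nat = lc.invasive_region, lc.native_region

    # ---------------- landscape ----------------
    mask = split_region_mask(lc.n_rows, lc.n_cols, labels=(inv, nat), fraction=lc.invasive_fraction)
    grid = Grid(lc.n_rows, lc.n_cols, lc.cell_size_m, region_mask=mask)
    target_corr = {tuple(lc.correlated_pair): lc.pair_correlation}
    stack = simulate_predictors(
        grid,
        n_layers=lc.n_predictors,
        smoothness=lc.smoothness,
        target_corr=target_corr,
        seed=stage_seed(config.seed, "predictors"),
        na_fraction=lc.na_fraction,
    )
    truth = define_truth(stack, tc.coefficients, tc.intercept)
    log.stage("landscape", n_cells=grid.n_cells, n_layers=lc.n_predictors,
              seed=stage_seed(config.seed, "predictors"))

    # observer activity: an extra smooth field concentrates effort spatially
    act = simulate_predictors(
        grid, n_layers=2, smoothness=lc.smoothness,
        seed=stage_seed(config.seed, "activity"), layer_names=["activity", "_spare"],
    ).layers["activity"]
    rng_eff = np.random.default_rng(stage_seed(config.seed, "effort_points"))
    valid = stack.valid_mask()
    w = np.where(valid, np.exp(sc.effort_concentration * act), 0.0)
    p = (w / w.sum()).ravel()
    cells = rng_eff.choice(grid.n_cells, size=sc.n_effort_observations, replace=True, p=p)
    rr, cc = np.unravel_index(cells, grid.shape)
    ex, ey = grid.cell_center(rr, cc)
    jit = rng_eff.uniform(-0.5, 0.5, size=(2, cells.size)) * grid.cell_size_m
    effort = build_effort(ex + jit[0], ey + jit[1], grid)
    stack = attach_effort(stack, effort)
    log.stage("effort", n_observations=sc.n_effort_observations,
              mean_nonzero=effort.mean_nonzero)

    # ---------------- occurrences ----------------
    native_cu = MixtureCU(
        components=(UniformCU(4.0, 1000.0), UniformCU(1000.0, sc.native_cu_tail_max_m)),
        weights=(0.5, 0.5),
    )
    occ_parts = []
    for region, n, cu_model in (
        (inv, sc.n_invasive, INVASIVE_CU),
        (nat, sc.n_native, native_cu),
    ):
        occ_parts.append(
            sample_occurrences(
                truth, effort.values, n_target=n, region=region, cu_model=cu_model,
                seed=stage_seed(config.seed, f"occurrences:{region}"),
            )
        )
    records = pd.concat(occ_parts, ignore_index=True)
    _write_csv(records, out / "occurrences.csv")

    rejected: list = []
    cleaned = basic_clean(records, grid, stack, rejected=rejected)
    filtered = filter_uncertainty(cleaned, config.cu.max_cu_m, keep_missing_cu=config.cu.keep_missing)
    presences = thin_to_cells(filtered, grid)
    if rejected:
        _write_csv(pd.DataFrame(rejected, columns=["record_index", "reason"]),
                   out / "rejected_records.csv")
    _write_csv(presences.cells, out / "presence_cells.csv")
    log.stage("occurrence_prep", n_raw=len(records), n_clean=len(cleaned),
              n_filtered=len(filtered), n_presence_cells=presences.count(),
              n_dropped_clean=len(records) - len(cleaned),
              n_dropped_cu=len(cleaned) - len(filtered))

    # ---------------- predictor stack ----------------
    stack, collin = prune_collinear(stack, threshold=0.7)
    stack = standardize(stack)
    (out / "collinearity.json").write_text(json.dumps(collin.to_json_dict(), indent=2))
    log.stage("predictor_stack", kept=collin.kept,
              dropped=[d["layer"] for d in collin.dropped])

    # ---------------- pseudo-absences ----------------
    eligible = {}
    for region in (inv, nat):
        if config.pa.mode[region] == "cell":
            eligible[region] = eligible_cells_cellexcl(presences, grid, stack, region)
        else:
            eligible[region] = eligible_cells_bufferexcl(
                filtered[filtered["region"] == region], grid, stack, region
            )
    n_per_region = {r: presences.count(r) for r in (inv, nat)}
    pa_sets = draw_pa_sets(
        eligible, n_per_region, n_sets=config.pa.n_sets,
        base_seed=stage_seed(config.seed, "pa"),
    )
    pa_frame = pa_sets_to_frame(pa_sets, grid)
    _write_csv(pa_frame, out / "pa_sets.csv")
    pa_totals = {r: int((pa_frame["region"] == r).sum()) for r in (inv, nat)}
    log.stage("pseudo_absence", n_sets=config.pa.n_sets, n_per_region=n_per_region,
              totals=pa_totals)

    # ---------------- fits ----------------
    feature_names = stack.layer_names
    frames = {s.set_id: assemble_frame(presences, s, stack) for s in pa_sets}
    splits = {
        s.set_id: split_train_valid(
            frames[s.set_id], train_frac=config.cv.train_frac, n_reps=config.cv.n_reps,
            base_seed=stage_seed(config.seed, f"split:{s.set_id}"), pa_set_id=s.set_id,
        )
        for s in pa_sets
    }
    models = {}
    member_rows = []
    for alg in config.algorithms:
        hp = config.hyperparams.get(alg)
        for s in pa_sets:
            frame = frames[s.set_id]
            for plan in splits[s.set_id]:
                seed = derive_fit_seed(config.seed, alg, s.set_id, plan.rep_id)
                model = fit_model(
                    alg, frame.iloc[plan.train_idx], feature_names=feature_names,
                    hyperparams=hp, seed=seed, pa_set_id=s.set_id, rep_id=plan.rep_id,
                )
                run_id = f"{alg}_pa{s.set_id}_rep{plan.rep_id}"
                models[run_id] = model
                # member-level region-stratified evaluation on its validation rows
                vrows = frame.iloc[plan.valid_idx]
                scores = model.predict_frame(vrows)
                for region, idx in vrows.groupby("region").indices.items():
                    ev = met.evaluate_scores(
                        run_id, str(region), vrows[CLASS_COLUMN].to_numpy()[idx], scores[idx],
                        window_width=config.metrics.boyce_window,
                        n_windows=config.metrics.boyce_windows,
                        strict_boyce=False,
                    )
                    member_rows.append({**ev.to_dict(), "algorithm": alg,
                                        "pa_set": s.set_id, "rep": plan.rep_id})
    member_eval = pd.DataFrame(member_rows)
    _write_csv(member_eval, out / "eval_members.csv")
    log.stage("fits", n_models=len(models),
              design=f"{len(config.algorithms)} algorithms x {config.pa.n_sets} PA sets x {config.cv.n_reps} reps")

    # ---------------- ensembles ----------------
    candidates: dict[str, ens.EnsembleModel] = {}
    for alg in config.algorithms:
        members = [models[k] for k in sorted(models) if k.startswith(f"{alg}_pa")]
        candidates[alg.upper()] = ens.algorithm_ensemble(alg.upper(), members)
    all_ids = sorted(models)
    all_members = [models[k] for k in all_ids]
    pooled = member_eval.groupby("model_id").agg(
        tss=("tss", "mean"), thr=("threshold_at_max_tss", "mean")
    )
    member_tss = [float(pooled.loc[k, "tss"]) for k in all_ids]
    member_thr = [float(pooled.loc[k, "thr"]) for k in all_ids]
    for scheme in config.ensemble_schemes:
        candidates[scheme] = ens.global_ensemble(
            scheme, all_members, scheme,
            thresholds=member_thr if scheme == "EMca" else None,
            member_tss=member_tss if scheme == "EMwmean" else None,
        )

    # per-split evaluation of every candidate, averaged across splits
    ens_rows = []
    for cid, cand in candidates.items():
        per_split = []
        for s in pa_sets:
            frame = frames[s.set_id]
            for plan in splits[s.set_id]:
                vrows = frame.iloc[plan.valid_idx]
                scores = cand.predict_frame(vrows)
                for region, idx in vrows.groupby("region").indices.items():
                    ev = met.evaluate_scores(
                        cid, str(region), vrows[CLASS_COLUMN].to_numpy()[idx], scores[idx],
                        window_width=config.metrics.boyce_window,
                        n_windows=config.metrics.boyce_windows,
                        strict_boyce=False,
                    )
                    per_split.append(ev.to_dict())
        df = pd.DataFrame(per_split)
        agg = df.groupby(["model_id", "region"], as_index=False).mean(numeric_only=True)
        ens_rows.append(agg)
    ens_eval = pd.concat(ens_rows, ignore_index=True)
    _write_csv(ens_eval, out / "eval_ensembles.csv")
    best_id = met.select_best(ens_eval, regions=(inv, nat))
    best = candidates[best_id]
    log.stage("ensembles", candidates=sorted(candidates), best=best_id)

    # ---------------- importance & inference ----------------
    best_members = (
        [k for k in all_ids if k.startswith(f"{best_id.lower()}_pa")]
        if best_id.upper() in (a.upper() for a in config.algorithms)
        else all_ids
    )
    pred_names = [c for c in feature_names]
    first_frame = frames[pa_sets[0].set_id]
    first_valid = splits[pa_sets[0].set_id][0].valid_idx
    imp_raw = compute_importance_table(
        {k: models[k] for k in best_members},
        first_frame,
        {k: first_valid for k in best_members},
        predictors=pred_names,
        n_shuffles=config.importance.n_shuffles,
        base_seed=stage_seed(config.seed, "importance"),
    )
    imp = scale_importances(imp_raw)
    _write_csv(imp, out / "importance.csv")
    contrasts = None
    if len(best_members) >= 2:
        fit = fit_beta_glmm(imp)
        contrasts = region_contrasts(fit, invasive_region=inv)
        _write_csv(contrasts, out / "contrasts.csv")
        (out / "betareg_fit.json").write_text(json.dumps({
            "regions": fit.regions, "predictors": fit.predictors,
            "beta": fit.beta.tolist(), "gamma": fit.gamma.tolist(),
            "sigma": fit.sigma, "loglik": fit.loglik, "converged": fit.converged,
            "has_random_effect": fit.has_random_effect,
            "boundary_squeezed": fit.boundary_squeezed,
        }, indent=2))
    log.stage("importance", n_runs=len(best_members), n_predictors=len(pred_names))

    # ---------------- projection ----------------
    std_map = project_map(best, stack, effort_mode=EFFORT_STANDARDIZED)
    obs_map = project_map(best, stack, effort_mode=EFFORT_OBSERVED)
    write_ascii_grid(out / "maps" / "suitability_standardized_effort.asc", std_map.values, grid)
    write_ascii_grid(out / "maps" / "suitability_observed_effort.asc", obs_map.values, grid)
    log.stage("projection", effort_constant=std_map.effort_constant, best=best_id)

    # ---------------- independent validation ----------------
    rng_iv = np.random.default_rng(stage_seed(config.seed, "survey"))
    inv_valid = grid.region_cells_mask(inv) & stack.valid_mask()
    vr, vc = np.nonzero(inv_valid)
    pick = rng_iv.choice(vr.size, size=min(config.overlap.n_survey_points, vr.size), replace=False)
    sx, sy = grid.cell_center(vr[pick], vc[pick])
    p_true = truth.suitability[vr[pick], vc[pick]]
    labels = rng_iv.binomial(1, np.where(np.isfinite(p_true), p_true, 0.0))
    survey = pd.DataFrame({"x": sx, "y": sy, "label": labels})
    agg = aggregate_independent(survey, grid)
    indep = None
    vals = std_map.at_cells(agg["row"].to_numpy(), agg["col"].to_numpy())
    ok = np.isfinite(vals)
    lab = agg["label"].to_numpy()[ok]
    if len(np.unique(lab)) == 2:
        ev = met.evaluate_scores(
            "independent", inv, lab, vals[ok],
            window_width=config.metrics.boyce_window, n_windows=config.metrics.boyce_windows,
        )
        indep = ev.to_dict()
        _write_csv(pd.DataFrame([indep]), out / "independent_eval.csv")
    log.stage("independent", n_points=len(agg), n_presence=int(lab.sum()))

    # ---------------- focal-species overlap ----------------
    rng_ov = np.random.default_rng(stage_seed(config.seed, "overlap"))
    overlaps = []
    suit = np.where(np.isfinite(truth.suitability) & inv_valid, truth.suitability, 0.0)
    p_focal = (suit**2 / (suit**2).sum()).ravel()  # focal species hug high-suitability cells
    for species, n_pts in config.overlap.species.items():
        cells_f = rng_ov.choice(grid.n_cells, size=n_pts, replace=True, p=p_focal)
        fr, fc = np.unravel_index(cells_f, grid.shape)
        fx, fy = grid.cell_center(fr, fc)
        occ = pd.DataFrame({"x": fx, "y": fy})
        overlaps.append(overlap_summary(std_map, occ, species).__dict__)
    overlap_df = pd.DataFrame(overlaps)
    _write_csv(overlap_df, out / "overlap.csv")
    log.stage("overlap", species=list(config.overlap.species))

    manifest = {
        "config": config.to_dict(),
        "seeds": {s: stage_seed(config.seed, s) for s in
                  ["predictors", "activity", "effort_points", "pa", "importance",
                   "survey", "overlap"]},
        "n_presence_cells": {r: presences.count(r) for r in (inv, nat)},
        "pa_totals": pa_totals,
        "n_constituent_models": len(models),
        "design_cardinality": {
            "algorithms": len(config.algorithms),
            "pa_sets": config.pa.n_sets,
            "reps": config.cv.n_reps,
            "per_algorithm": config.pa.n_sets * config.cv.n_reps,
        },
        "best_ensemble": best_id,
        "effort_mean_nonzero": effort.mean_nonzero,
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return manifest
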