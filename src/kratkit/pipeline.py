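"""Stage orchestration: simulate -> features -> train -> annotate ->
budget -> model, each stage reading/writing the tidy CSV formats so any
stage can also be run standalone from the CLI.
"""

from __future__ import annotations

import logging
import pickle
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import budgets as budgets_mod
from . import classify, ephemeris, features, io, mixed, synth
from .core import BEHAVIOR_NAMES

logger = logging.getLogger(__name__)


def _start_time(cfg: io.PipelineConfig) -> datetime:
    d = pd.to_datetime(cfg.start_date).date()
    return datetime(d.year, d.month, d.day, cfg.start_hour_utc, tzinfo=timezone.utc)


def simulate_study(cfg: io.PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Simulate deployments and nightly covariates; write the raw-data tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    site = cfg.site()
    rng = np.random.default_rng(seed)
    start = _start_time(cfg)
    duration_h = (
        cfg.deployment_hours
        if cfg.deployment_hours is not None
        else 24.0 * cfg.n_nights
    )
    sexes = ["f" if i % 3 != 2 else "m" for i in range(cfg.n_individuals)]
    meta: dict = {"seed": seed, "individuals": {}, "site": {
        "latitude": cfg.latitude, "longitude": cfg.longitude, "timezone": cfg.timezone}}
    for i in range(cfg.n_individuals):
        dep_id = f"kr{i:02d}"
        dep = synth.simulate_deployment(
            dep_id,
            start,
            duration_h,
            site,
            fs=cfg.fs,
            seed=rng,
            sex=sexes[i],
        )
        io.write_accel_csv(dep.trace, out / f"{dep_id}_accel.csv")
        io.write_annotations_csv(
            synth.schedule_to_annotations(dep_id, dep.schedule),
            out / f"{dep_id}_annotations.csv",
        )
        meta["individuals"][dep_id] = {"sex": dep.sex, "n_bouts": len(dep.schedule)}
    cov, cov_meta = synth.simulate_covariates(
        cfg.n_nights + 1, pd.to_datetime(cfg.start_date).date(), site, seed=rng
    )
    io.write_weather_csv(cov, out / "covariates.csv")
    meta.update(cov_meta)
    day_occ = synth.default_profile().occupancy
    meta["true_occupancy"] = {
        ph.value: {b.value: occ for b, occ in day_occ(ph).items()}
        for ph in ephemeris.LightPhase
    }
    synth.write_ground_truth(out / "ground_truth.json", meta)
    return meta


def stage_features(cfg: io.PipelineConfig, data_dir, out_dir) -> dict[float, Path]:
    """Window features (labeled where annotations exist) per window size."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    accel_files = sorted(data_dir.glob("*_accel.csv"))
    if not accel_files:
        raise io.ValidationError(f"no *_accel.csv files in {data_dir}")
    written = {}
    for w in cfg.window_sizes:
        parts = []
        for f in accel_files:
            dep_id = f.name.replace("_accel.csv", "")
            ann_path = data_dir / f"{dep_id}_annotations.csv"
            ann = io.read_annotations(ann_path, dep_id) if ann_path.exists() else None
            for trace in io.read_accel_csv(f, cfg.fs, dep_id):
                parts.append(
                    features.feature_table(
                        trace, w, annotations=ann, label_slack_s=cfg.label_slack_s
                    )
                )
        table = pd.concat(parts, ignore_index=True)
        path = out / f"features_w{w:g}.csv"
        table.to_csv(path, index=False, float_format="%.17g")
        written[float(w)] = path
    return written


def stage_train(cfg: io.PipelineConfig, features_dir, out_dir) -> classify.SelectionResult:
    """Model selection over the configured grid; persist leaderboard + bundle."""
    features_dir, out = Path(features_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {}
    for w in cfg.window_sizes:
        path = features_dir / f"features_w{w:g}.csv"
        tables[float(w)] = pd.read_csv(path, keep_default_na=False)
    result = classify.model_selection(
        tables,
        algorithms=[classify.Algorithm(a) for a in cfg.algorithms],
        feature_sets=cfg.feature_sets,
        seed=cfg.seed,
        train_fraction=cfg.train_fraction,
    )
    result.leaderboard.to_csv(out / "leaderboard.csv", index=False, float_format="%.17g")
    bundle = {
        "spec": {
            "algorithm": result.best.spec.algorithm.value,
            "feature_set": result.best.spec.feature_set,
            "window_s": result.best.spec.window_s,
            "seed": result.best.spec.seed,
        },
        "feature_names": list(features.FEATURE_SETS[result.best.spec.feature_set]),
        "estimator": result.best._estimator,
        "report_row": result.best.to_row(),
    }
    with open(out / "model_bundle.pkl", "wb") as fh:
        pickle.dump(bundle, fh)
    return result


def load_bundle(path) -> classify.ModelReport:
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    spec = classify.ModelSpec(
        algorithm=classify.Algorithm(bundle["spec"]["algorithm"]),
        feature_set=bundle["spec"]["feature_set"],
        window_s=bundle["spec"]["window_s"],
        seed=bundle["spec"]["seed"],
    )
    row = bundle["report_row"]
    cm = np.array(
        [
            [row[f"n_{bt}_as_{bp}"] for bp in BEHAVIOR_NAMES]
            for bt in BEHAVIOR_NAMES
        ]
    )
    report = classify.ModelReport(spec=spec, confusion=cm, train_sizes={}, test_sizes={})
    report._estimator = bundle["estimator"]
    return report


def stage_annotate(cfg: io.PipelineConfig, data_dir, model_path, out_path) -> pd.DataFrame:
    """Predict behavior for every window of every deployment."""
    report = load_bundle(model_path)
    parts = []
    for f in sorted(Path(data_dir).glob("*_accel.csv")):
        dep_id = f.name.replace("_accel.csv", "")
        for trace in io.read_accel_csv(f, cfg.fs, dep_id):
            parts.append(classify.annotate_deployment(trace, report))
    pred = pd.concat(parts, ignore_index=True)
    pred.to_csv(out_path, index=False)
    return pred


def stage_budget(
    cfg: io.PipelineConfig, predictions_path, covariates_path, out_dir,
    ground_truth_path=None,
) -> dict[str, pd.DataFrame]:
    """Diel annotation, phase/night budgets, and the model-ready table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    site = cfg.site()
    pred = pd.read_csv(predictions_path)
    ann = budgets_mod.annotate_windows(pred, site)
    phase_budget = budgets_mod.compute_budgets(ann, ("individual", "night", "phase"))
    night_budget = budgets_mod.compute_budgets(ann, ("individual", "night"))
    cov = pd.read_csv(covariates_path)
    sex_map = None
    if ground_truth_path and Path(ground_truth_path).exists():
        gt = synth.read_ground_truth(ground_truth_path)
        sex_map = {k: v["sex"] for k, v in gt.get("individuals", {}).items()}
    model_ready = budgets_mod.attach_covariates(
        night_budget,
        cov,
        sex_by_individual=sex_map,
        moon_analysis=cfg.moon_analysis,
        exclude_precipitation=cfg.exclude_precipitation,
    ).rename(columns={"deployment_id": "individual"})
    phase_budget.to_csv(out / "budgets_phase.csv", index=False, float_format="%.17g")
    night_budget.to_csv(out / "budgets_night.csv", index=False, float_format="%.17g")
    model_ready.to_csv(out / "model_ready.csv", index=False, float_format="%.17g")
    return {
        "phase": phase_budget,
        "night": night_budget,
        "model_ready": model_ready,
    }


def stage_model(cfg: io.PipelineConfig, model_ready_path, out_dir) -> pd.DataFrame:
    """Per-behavior family selection, VIF screening, Wald tests, R2c."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(model_ready_path)
    results_rows, aic_rows, vif_rows = [], [], []
    for behavior in BEHAVIOR_NAMES:
        sub = table[table["behavior"] == behavior].reset_index(drop=True)
        if sub.empty:
            continue
        import patsy

        _, X = patsy.dmatrices(cfg.model_formula, sub, return_type="dataframe")
        pred_cols = X.drop(columns=["Intercept"], errors="ignore")
        if pred_cols.shape[1] >= 2:
            vif = mixed.compute_vif(pred_cols)
            vif["behavior"] = behavior
            vif_rows.append(vif)
        sel = mixed.select_family(
            cfg.model_formula,
            sub,
            groups=("individual", "night"),
            weights=cfg.model_weights if cfg.model_weights in sub.columns else None,
        )
        fit = sel.best
        at = sel.aic_table.copy()
        at["behavior"] = behavior
        aic_rows.append(at)
        wald = fit.wald_test_terms().set_index("term")
        r2c = fit.conditional_r2()
        for name in fit.params.index:
            term = _term_of(fit, name)
            results_rows.append(
                {
                    "behavior": behavior,
                    "term": name,
                    "estimate": fit.params[name],
                    "se": fit.bse[name],
                    "chi2": wald.loc[term, "chi2"] if term in wald.index else np.nan,
                    "df": wald.loc[term, "df"] if term in wald.index else np.nan,
                    "p": wald.loc[term, "p"] if term in wald.index else np.nan,
                    "family": fit.family,
                    "r2_conditional": r2c,
                    "converged": fit.converged,
                }
            )
    results = pd.DataFrame(results_rows)
    results.to_csv(out / "model_results.csv", index=False, float_format="%.17g")
    pd.concat(aic_rows, ignore_index=True).to_csv(
        out / "aic_table.csv", index=False, float_format="%.17g"
    )
    if vif_rows:
        pd.concat(vif_rows, ignore_index=True).to_csv(
            out / "vif_table.csv", index=False, float_format="%.17g"
        )
    return results


def _term_of(fit: mixed.MixedGLMResults, coef_name: str) -> str:
    di = fit.model.design_info
    if di is None:
        return coef_name
    for term_name, sl in di.term_name_slices.items():
        if coef_name in di.column_names[sl]:
            return term_name
    return coef_name


def run_all(cfg: io.PipelineConfig, out_dir, seed: int | None = None) -> Path:
    """Full chain into ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.seed = seed
    raw = out / "raw"
    simulate_study(cfg, raw)
    feat = out / "features"
    stage_features(cfg, raw, feat)
    train = out / "train"
    stage_train(cfg, feat, train)
    pred_path = out / "predictions.csv"
    stage_annotate(cfg, raw, train / "model_bundle.pkl", pred_path)
    bud = out / "budgets"
    stage_budget(
        cfg, pred_path, raw / "covariates.csv", bud,
        ground_truth_path=raw / "ground_truth.json",
    )
    stage_model(cfg, bud / "model_ready.csv", out / "models")
    cfg.to_yaml(out / "config.yaml")
    manifest = out / "manifest.json"
    inputs = sorted(str(p) for p in raw.glob("*.csv"))
    outputs = [
        str(p)
        for p in [
            train / "leaderboard.csv",
            pred_path,
            bud / "budgets_phase.csv",
            bud / "budgets_night.csv",
            bud / "model_ready.csv",
            out / "models" / "model_results.csv",
        ]
    ]
    io.write_manifest(manifest, cfg, inputs, outputs, base=out)
    return manifest
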