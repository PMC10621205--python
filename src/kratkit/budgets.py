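"""Activity budgets: proportions of time per behavior by diel grouping.

Each classified window is assigned to the light phase containing its
midpoint (windows may straddle phase boundaries; the midpoint rule is
deterministic and unbiased).  Budgets are computed per grouping cell as
window counts and proportions; proportions within one cell sum to one.
Budgets are kept at the (individual, night, phase) grain and modeled with
group sizes as weights, preserving the random-effect structure that the
downstream mixed models assume.
"""

from __future__ import annotations

import logging
from datetime import timezone

import numpy as np
import pandas as pd

from . import ephemeris
from .core import BEHAVIOR_NAMES, LightPhase, SUN_DOWN_PHASES

logger = logging.getLogger(__name__)

_GROUP_COLS = {
    "individual": "deployment_id",
    "night": "night",
    "phase": "light_phase",
    "moon_intensity": "moon_intensity",
    "moon_up": "moon_up",
}


def annotate_windows(
    predictions: pd.DataFrame, site: ephemeris.SiteContext
) -> pd.DataFrame:
    """Attach diel/moon annotation (at the window midpoint) to predictions.

    ``predictions`` needs columns deployment_id, start, end, behavior (the
    output of whole-deployment annotation).
    """
    pred = predictions.copy()
    start = pd.to_datetime(pred["start"])
    end = pd.to_datetime(pred["end"])
    mid = start + (end - start) / 2
    ann = ephemeris.annotate_times(site, mid)
    pred["light_phase"] = ann["light_phase"].to_numpy()
    pred["moon_illumination"] = ann["moon_illumination"].to_numpy()
    pred["moon_intensity"] = ann["moon_intensity"].to_numpy()
    pred["moon_up"] = ann["moon_up"].to_numpy()
    pred["night"] = ann["night"].to_numpy()
    return pred


def compute_budgets(
    annotated: pd.DataFrame, grouping: tuple[str, ...] = ("individual", "night", "phase")
) -> pd.DataFrame:
    """Window counts and proportions per behavior for each grouping cell.

    ``grouping`` is a subset of {individual, night, phase, moon_intensity,
    moon_up}.  Every behavior appears in every non-empty cell (with zero
    count where unobserved) so proportions within a cell always sum to 1.
    """
    bad = [g for g in grouping if g not in _GROUP_COLS]
    if bad:
        raise ValueError(f"unknown grouping keys: {bad}")
    if annotated.empty:
        raise ValueError("no classified windows to aggregate")
    missing = annotated["light_phase"].isna()
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} windows lack a diel annotation (span mismatch)"
        )
    cols = [_GROUP_COLS[g] for g in grouping]
    counts = (
        annotated.groupby(cols + ["behavior"], sort=True, observed=True)
        .size()
        .rename("n_windows")
        .reset_index()
    )
    # complete the behavior index within each cell
    full = (
        counts.set_index(cols + ["behavior"])["n_windows"]
        .unstack("behavior", fill_value=0)
        .reindex(columns=list(BEHAVIOR_NAMES), fill_value=0)
        .stack()
        .rename("n_windows")
        .reset_index()
    )
    totals = full.groupby(cols, sort=True)["n_windows"].transform("sum")
    full["n_total"] = totals
    full["proportion"] = full["n_windows"] / totals
    return full


def attach_covariates(
    budget: pd.DataFrame,
    covariates: pd.DataFrame,
    sex_by_individual: dict[str, str] | None = None,
    moon_analysis: bool = False,
    exclude_precipitation: bool = False,
) -> pd.DataFrame:
    """Join nightly covariates (moon, weather, sex) onto a budget table.

    With ``moon_analysis`` set, rows are restricted to the phases where the
    sun is below the horizon (dusk, evening twilight, night, morning
    twilight, dawn), which is the domain of the moonlight models.  With
    ``exclude_precipitation`` set, nights with precipitation rate > 0 are
    dropped (cloud-cover proxy) and the drop is logged.
    """
    out = budget.copy()
    cov = covariates.copy()
    cov["night"] = pd.to_datetime(cov["night"]).dt.date
    out["night"] = pd.to_datetime(out["night"]).dt.date

    have = set(cov["night"])
    need = set(out["night"])
    missing = sorted(need - have)
    if missing:
        raise ValueError(
            "nights missing from covariate table: "
            + ", ".join(d.isoformat() for d in missing)
        )

    if exclude_precipitation and "precip_mmh" in cov.columns:
        wet = cov.loc[cov["precip_mmh"] > 0, "night"]
        n_before = len(out)
        out = out[~out["night"].isin(set(wet))]
        logger.info(
            "attach_covariates: dropped %d rows on %d precipitation nights",
            n_before - len(out),
            wet.nunique(),
        )
        cov = cov[cov["precip_mmh"] <= 0]

    out = out.merge(cov, on="night", how="left", validate="many_to_one")
    if sex_by_individual is not None and "deployment_id" in out.columns:
        out["sex"] = out["deployment_id"].map(sex_by_individual)

    if moon_analysis:
        if "light_phase" not in out.columns:
            raise ValueError("moon analysis needs a phase grouping in the budget")
        keep = {p.value for p in SUN_DOWN_PHASES}
        out = out[out["light_phase"].isin(keep)]
    return out.reset_index(drop=True)


def durations(budget: pd.DataFrame, window_s: float) -> pd.Series:
    """Cell durations in seconds: n_windows * window_s, exactly."""
    return budget["n_windows"] * float(window_s)
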