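"""Repeatability, stability and digestion-timecourse analyses.

Repeatability follows the classic two-stage CV scheme from replicated
measurements over multiple days:

* intra-assay (within-day) CV — the mean over days of the CV computed within
  each day;
* inter-assay (between-day) CV — the CV of the per-day mean ratios.

Stability compares replicate ratios measured after each storage/handling
condition against a fresh control, reporting the condition CV and the
absolute percent difference of means; a peptide is called stable under a
condition when both stay within the configured bounds.

The digestion timecourse normalizes mean ratios to the maximum timepoint and
locates the earliest plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, ValidationError
from .io import AnalysisConfig
from .quant import cv

logger = logging.getLogger("immunomrm")

PRECISION_COLUMNS = ["peptide_id", "spike_level", "intra_cv", "inter_cv",
                     "n_days", "n_reps_per_day"]

STABILITY_COLUMNS = ["peptide_id", "condition", "cv_percent", "pct_diff",
                     "stable_flag"]


@dataclass
class TimecourseProfile:
    """Digestion recovery profile of one peptide, normalized to its maximum."""

    peptide_id: str
    timepoints_h: list
    normalized_ratios: list
    plateau_time_h: float


def _usable_days(values_by_day: dict) -> dict:
    out = {}
    for day, vals in values_by_day.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            logger.warning("day %s has %d replicate(s); excluded", day, arr.size)
            continue
        out[day] = arr
    if len(out) < 2:
        raise InsufficientReplicatesError(
            "need at least 2 days with >= 2 replicates each")
    return out


def intra_day_cv(values_by_day: dict) -> float:
    """Mean over days of the within-day replicate CV, in percent."""
    usable = _usable_days(values_by_day)
    return float(np.mean([cv(v) for v in usable.values()]))


def inter_day_cv(values_by_day: dict) -> float:
    """CV of the per-day mean ratios, in percent."""
    out = {}
    for day, vals in values_by_day.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            continue
        out[day] = arr
    if len(out) < 2:
        raise InsufficientReplicatesError("need at least 2 days")
    means = [v.mean() for v in out.values()]
    return cv(means)


def repeatability_summary(quants: pd.DataFrame, design: pd.DataFrame,
                          cfg: AnalysisConfig | None = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-peptide, per-spike-level intra- and inter-day CVs plus panel medians.

    Ratios come from the quantification table (config orientation); the
    endogenous level, when present in the design, uses the light:heavy ratio
    of the unspiked-light signal exactly like any other level.
    """
    cfg = cfg or AnalysisConfig()
    rep = design[design["role"] == "repeatability"]
    if rep.empty:
        raise ValidationError("design contains no repeatability samples")
    merged = quants.merge(rep[["sample_id", "spike_level", "day"]],
                          on="sample_id")
    merged = merged.dropna(subset=["ratio"])
    rows = []
    for (peptide_id, level), grp in merged.groupby(
            ["peptide_id", "spike_level"], sort=True):
        by_day = {day: sub["ratio"].to_numpy()
                  for day, sub in grp.groupby("day")}
        try:
            intra = intra_day_cv(by_day)
            inter = inter_day_cv(by_day)
        except InsufficientReplicatesError:
            logger.warning("repeatability: %s level %s skipped "
                           "(insufficient days/replicates)", peptide_id, level)
            continue
        n_reps = int(round(np.mean([len(v) for v in by_day.values()])))
        rows.append(dict(peptide_id=peptide_id, spike_level=level,
                         intra_cv=intra, inter_cv=inter,
                         n_days=len(by_day), n_reps_per_day=n_reps))
    table = pd.DataFrame(rows, columns=PRECISION_COLUMNS)
    summary = {}
    for level, grp in table.groupby("spike_level"):
        summary[level] = {
            "median_intra_cv": float(grp["intra_cv"].median()),
            "median_inter_cv": float(grp["inter_cv"].median()),
            "range_intra_cv": (float(grp["intra_cv"].min()),
                               float(grp["intra_cv"].max())),
            "range_inter_cv": (float(grp["inter_cv"].min()),
                               float(grp["inter_cv"].max())),
        }
    logger.info("repeatability_summary: %d peptide-levels [cfg %s]",
                len(table), cfg.digest())
    return table, summary


def stability_assess(control, treated: dict,
                     cfg: AnalysisConfig | None = None,
                     peptide_id: str = "") -> pd.DataFrame:
    """Assess one peptide's stability under each handling condition.

    ``control`` holds fresh replicate ratios; ``treated`` maps condition name
    to its replicate ratios.  Per condition: the replicate CV and
    ``pct_diff = 100 * |mean(treated) - mean(control)| / mean(control)``;
    stable iff CV <= stability_cv_max and pct_diff <= stability_diff_max.
    """
    cfg = cfg or AnalysisConfig()
    ctrl = np.asarray(control, dtype=float)
    if ctrl.size < 2:
        raise InsufficientReplicatesError("control arm needs >= 2 replicates")
    ctrl_mean = ctrl.mean()
    if ctrl_mean <= 0:
        raise ValidationError("control mean must be positive")
    rows = []
    for condition, vals in treated.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise InsufficientReplicatesError(
                f"condition {condition!r} needs >= 2 replicates")
        c = cv(arr)
        pct = 100.0 * abs(arr.mean() - ctrl_mean) / ctrl_mean
        stable = (c <= 100.0 * cfg.stability_cv_max
                  and pct <= 100.0 * cfg.stability_diff_max)
        rows.append(dict(peptide_id=peptide_id, condition=condition,
                         cv_percent=c, pct_diff=pct, stable_flag=stable))
    return pd.DataFrame(rows, columns=STABILITY_COLUMNS)


def stability_summary(quants: pd.DataFrame, design: pd.DataFrame,
                      cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Design-driven stability assessment over all peptides."""
    cfg = cfg or AnalysisConfig()
    stab = design[design["role"] == "stability"]
    if stab.empty:
        raise ValidationError("design contains no stability samples")
    merged = quants.merge(stab[["sample_id", "condition"]], on="sample_id")
    merged = merged.dropna(subset=["ratio"])
    frames = []
    for peptide_id, grp in merged.groupby("peptide_id", sort=True):
        ctrl = grp.loc[grp["condition"] == "fresh", "ratio"].to_numpy()
        treated = {cond: sub["ratio"].to_numpy()
                   for cond, sub in grp.groupby("condition") if cond != "fresh"}
        if ctrl.size < 2 or not treated:
            logger.warning("stability: %s skipped (missing arms)", peptide_id)
            continue
        frames.append(stability_assess(ctrl, treated, cfg, peptide_id))
    if not frames:
        raise ValidationError("no peptide had both control and treated arms")
    return pd.concat(frames, ignore_index=True)


def digestion_timecourse(ratios_by_timepoint: dict,
                         cfg: AnalysisConfig | None = None,
                         peptide_id: str = "") -> TimecourseProfile:
    """Normalize a digestion timecourse and locate the recovery plateau.

    Mean ratios are normalized to the maximum timepoint.  The plateau is the
    earliest timepoint whose normalized mean is at least
    ``(1 - plateau_tolerance)`` times every later timepoint's mean.
    """
    cfg = cfg or AnalysisConfig()
    if len(ratios_by_timepoint) < 3:
        raise ValidationError("need at least 3 timepoints")
    times = sorted(ratios_by_timepoint)
    means = np.array([np.mean(np.asarray(ratios_by_timepoint[t], dtype=float))
                      for t in times])
    if not (means > 0).any():
        raise ValidationError("all-zero timecourse signal")
    norm = means / means.max()
    plateau = times[-1]
    for i, t in enumerate(times):
        later = norm[i + 1:]
        if later.size == 0 or (norm[i] >= (1 - cfg.plateau_tolerance) * later).all():
            plateau = t
            break
    return TimecourseProfile(peptide_id=peptide_id, timepoints_h=list(times),
                             normalized_ratios=[float(v) for v in norm],
                             plateau_time_h=float(plateau))


def timecourse_summary(quants: pd.DataFrame, design: pd.DataFrame,
                       cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Design-driven timecourse profiles for all peptides."""
    cfg = cfg or AnalysisConfig()
    tc = design[design["role"] == "timecourse"]
    if tc.empty:
        raise ValidationError("design contains no timecourse samples")
    merged = quants.merge(tc[["sample_id", "timepoint_h"]], on="sample_id")
    merged = merged.dropna(subset=["ratio"])
    rows = []
    for peptide_id, grp in merged.groupby("peptide_id", sort=True):
        by_t = {float(t): sub["ratio"].to_numpy()
                for t, sub in grp.groupby("timepoint_h")}
        prof = digestion_timecourse(by_t, cfg, peptide_id)
        for t, v in zip(prof.timepoints_h, prof.normalized_ratios):
            rows.append(dict(peptide_id=peptide_id, timepoint_h=t,
                             normalized_ratio=v,
                             plateau_time_h=prof.plateau_time_h))
    return pd.DataFrame(rows, columns=["peptide_id", "timepoint_h",
                                       "normalized_ratio", "plateau_time_h"])
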