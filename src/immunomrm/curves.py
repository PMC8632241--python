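"""Calibration (response) curves and per-peptide figures of merit.

A response curve titrates the heavy internal standard into a constant
background with a constant light spike, so the heavy:light peak-area ratio
is proportional to the spiked concentration.  From replicate measurements at
each level the module derives:

* LLOQ — the lowest level whose replicate CV is below the threshold
  (default 20%), with every higher level also passing;
* the linear range — an ordinary least-squares fit of log10(mean ratio) on
  log10(concentration) over levels at or above the LLOQ, iteratively
  dropping the top level (saturation) until R^2 meets the threshold;
* ULOQ — the highest level retained by the linear fit (a minimum estimate
  when the top measured level is retained);
* dynamic range in orders of magnitude, log10(ULOQ / LLOQ).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import AnalysisConfig
from .quant import cv

logger = logging.getLogger("immunomrm")

LEVEL_COLUMNS = ["peptide_id", "nominal_conc", "n_replicates", "mean_ratio",
                 "cv_percent", "usable"]

FIT_COLUMNS = ["peptide_id", "lloq", "uloq", "slope", "intercept", "r2",
               "dynamic_range_orders", "status", "uloq_is_minimum",
               "n_levels_used"]


@dataclass
class CurveFit:
    """Figures of merit of one peptide's response curve."""

    peptide_id: str
    lloq: float = math.nan
    uloq: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    r2: float = math.nan
    dynamic_range_orders: float = math.nan
    status: str = "ok"          # ok | failed_linearity | no_lloq
    uloq_is_minimum: bool = False
    n_levels_used: int = 0


def _curve_ratio(row) -> float:
    """Heavy:light ratio for a curve sample (heavy is the titrated analyte)."""
    lt, ht = row["light_total"], row["heavy_total"]
    if not (lt and ht) or lt <= 0 or ht <= 0 or math.isnan(lt) or math.isnan(ht):
        return math.nan
    return ht / lt


def build_curve(quants: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Aggregate curve-sample quantifications into per-level summaries.

    Returns one row per peptide x nominal concentration with the replicate
    count, mean heavy:light ratio and CV, sorted by ascending concentration
    within peptide.  Blank levels (nominal 0) are reported with the mean
    ratio of whatever light-normalized signal is present but are marked
    unusable so they never enter the LLOQ search or the regression.  Levels
    with fewer than 3 replicates are kept but marked unusable with a warning.
    """
    roles = design[design["role"].isin(["curve_point", "blank"])]
    if roles.empty:
        raise ValidationError("design contains no curve_point samples")
    merged = quants.merge(
        roles[["sample_id", "role", "nominal_conc"]], on="sample_id")
    if merged.empty:
        raise ValidationError("no quantifications for curve samples")
    merged.loc[merged["role"] == "blank", "nominal_conc"] = 0.0
    merged["curve_ratio"] = merged.apply(_curve_ratio, axis=1)

    rows = []
    for (peptide_id, conc), grp in merged.groupby(
            ["peptide_id", "nominal_conc"], sort=True):
        ratios = grp["curve_ratio"].dropna().to_numpy()
        n = len(ratios)
        mean_ratio = float(ratios.mean()) if n else math.nan
        cv_pct = cv(ratios) if n >= 2 else math.nan
        usable = (conc > 0) and (n >= 3)
        if conc > 0 and n < 3:
            logger.warning("curve level %s @ %g has only %d replicates; "
                           "marked unusable", peptide_id, conc, n)
        rows.append(dict(peptide_id=peptide_id, nominal_conc=float(conc),
                         n_replicates=n, mean_ratio=mean_ratio,
                         cv_percent=cv_pct, usable=usable))
    levels = pd.DataFrame(rows, columns=LEVEL_COLUMNS)
    return levels.sort_values(["peptide_id", "nominal_conc"],
                              kind="mergesort").reset_index(drop=True)


def determine_lloq(levels: pd.DataFrame, cfg: AnalysisConfig | None = None) -> float:
    """Empirical LLOQ of one peptide's curve levels.

    The LLOQ is the lowest nonzero concentration whose replicate CV is
    strictly below ``cfg.cv_lloq_threshold`` *and* whose every higher level
    also passes; NaN when no level qualifies.  Requiring the full suffix to
    pass guards against an isolated low level passing by chance.
    """
    cfg = cfg or AnalysisConfig()
    thresh = 100.0 * cfg.cv_lloq_threshold
    use = levels[(levels["nominal_conc"] > 0) & levels["usable"]]
    use = use.sort_values("nominal_conc")
    if use.empty:
        return math.nan
    concs = use["nominal_conc"].to_numpy()
    cvs = use["cv_percent"].to_numpy()
    lloq = math.nan
    # walk from the top down; stop at the first failing level
    for conc, c in zip(concs[::-1], cvs[::-1]):
        if np.isnan(c) or c >= thresh:
            break
        lloq = conc
    naive = concs[cvs < thresh]
    if len(naive) and not math.isnan(lloq) and naive.min() < lloq:
        logger.info("determine_lloq: suffix rule raised LLOQ to %g "
                    "(naive lowest-passing level %g)", lloq, naive.min())
    return lloq


def fit_linear_range(levels: pd.DataFrame, lloq: float,
                     cfg: AnalysisConfig | None = None) -> CurveFit:
    """Log-log linear fit over levels at or above the LLOQ.

    Repeatedly drops the highest level while R^2 falls below
    ``cfg.linearity_r2_min`` (saturation trims from the top; the LLOQ rule
    already trimmed the bottom).  Fewer than 3 retained levels means the
    curve failed linearity.
    """
    cfg = cfg or AnalysisConfig()
    peptide_id = levels["peptide_id"].iloc[0] if len(levels) else ""
    if math.isnan(lloq):
        return CurveFit(peptide_id=peptide_id, status="no_lloq")
    use = levels[(levels["nominal_conc"] >= lloq) & levels["usable"]
                 & (levels["mean_ratio"] > 0)]
    use = use.sort_values("nominal_conc")
    top_level = use["nominal_conc"].max() if len(use) else math.nan
    concs = use["nominal_conc"].to_numpy()
    x = np.log10(concs)
    y = np.log10(use["mean_ratio"].to_numpy())
    while len(x) >= 3:
        res = stats.linregress(x, y)
        r2 = res.rvalue ** 2
        if r2 >= cfg.linearity_r2_min:
            uloq = float(concs[len(x) - 1])
            return CurveFit(
                peptide_id=peptide_id, lloq=float(lloq), uloq=uloq,
                slope=float(res.slope), intercept=float(res.intercept),
                r2=float(r2),
                dynamic_range_orders=dynamic_range_orders(lloq, uloq),
                status="ok", uloq_is_minimum=bool(uloq == top_level),
                n_levels_used=len(x))
        x, y = x[:-1], y[:-1]
    return CurveFit(peptide_id=peptide_id, lloq=float(lloq),
                    status="failed_linearity")


def dynamic_range_orders(lloq: float, uloq: float) -> float:
    """Linear dynamic range in orders of magnitude: log10(uloq / lloq)."""
    if not (lloq > 0 and uloq > 0):
        raise ValidationError("lloq and uloq must be positive")
    if uloq < lloq:
        raise ValidationError("uloq must be >= lloq")
    return math.log10(uloq / lloq)


def analyze_curves(quants: pd.DataFrame, design: pd.DataFrame,
                   cfg: AnalysisConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full response-curve analysis: per-level diagnostics and per-peptide fits."""
    cfg = cfg or AnalysisConfig()
    levels = build_curve(quants, design)
    fits = []
    for peptide_id, grp in levels.groupby("peptide_id", sort=True):
        lloq = determine_lloq(grp, cfg)
        fits.append(asdict(fit_linear_range(grp, lloq, cfg)))
    fits_df = pd.DataFrame(fits, columns=FIT_COLUMNS)
    logger.info("analyze_curves: %d peptides, %d ok [cfg %s]", len(fits_df),
                int((fits_df["status"] == "ok").sum()), cfg.digest())
    return fits_df, levels


def curve_figures_of_merit(fits: pd.DataFrame) -> dict:
    """Panel-level summary of per-peptide curve figures of merit."""
    if fits.empty:
        raise ValidationError("need at least one curve fit")
    ok = fits[fits["status"] == "ok"]
    summary = {
        "n_assays": int(len(fits)),
        "n_ok": int(len(ok)),
        "n_failed_linearity": int((fits["status"] == "failed_linearity").sum()),
        "n_no_lloq": int((fits["status"] == "no_lloq").sum()),
    }
    for col, name in [("lloq", "lloq"), ("uloq", "uloq"),
                      ("dynamic_range_orders", "dynamic_range"), ("r2", "r2")]:
        vals = ok[col].dropna()
        summary[f"median_{name}"] = float(vals.median()) if len(vals) else math.nan
        summary[f"min_{name}"] = float(vals.min()) if len(vals) else math.nan
        summary[f"max_{name}"] = float(vals.max()) if len(vals) else math.nan
    return summary
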