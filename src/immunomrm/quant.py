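"""Transition-level QC and peptide-level quantification.

The quantitative readout of an immuno-MRM assay is the ratio of the summed
transition intensities of the endogenous (light) peptide to those of the
spiked stable-isotope-labeled (heavy) internal standard.  Per-transition
total intensity is *peak area + background*.  Before summation, light and
heavy transitions are paired by transition id and checked for concordant
retention times and relative transition areas; transitions with detected
interference are excluded from both channels (paired exclusion).  The
endogenous concentration is inferred from the light:heavy ratio and the
known heavy spike.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, InsufficientReplicatesError,
                     ValidationError)
from .io import AnalysisConfig

logger = logging.getLogger("immunomrm")

QUANT_COLUMNS = [
    "sample_id", "peptide_id", "light_total", "heavy_total", "ratio",
    "log2_ratio", "est_conc", "n_transitions_used", "qc_flags",
]

QC_REPORT_COLUMNS = [
    "sample_id", "peptide_id", "transition_id", "rt_delta",
    "light_rel_area", "heavy_rel_area", "interference_flag", "retained",
    "light_rel_area_retained", "heavy_rel_area_retained",
]


def transition_intensity(peak_area: float, background: float) -> float:
    """Total intensity of one transition: peak area + background."""
    if peak_area < 0 or background < 0:
        raise ValidationError("peak_area and background must be >= 0")
    return peak_area + background


def peptide_ratio(light_total: float, heavy_total: float,
                  orientation: str = "light_over_heavy") -> float:
    """Peptide-level ratio of summed channel intensities.

    ``light_over_heavy`` (the panel/application convention) divides the
    endogenous signal by the internal standard; ``heavy_over_light`` (the
    response-curve convention, where the heavy standard is the titrated
    analyte) is its reciprocal.
    """
    if orientation == "light_over_heavy":
        num, den = light_total, heavy_total
    elif orientation == "heavy_over_light":
        num, den = heavy_total, light_total
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not den > 0:
        raise ValidationError("denominator channel has no signal (undetectable)")
    return num / den


def estimate_concentration(ratio: float, entry) -> float:
    """Endogenous concentration from a light:heavy ratio and the heavy spike.

    ``est_conc = ratio * heavy_spike_conc * spike_multiplier`` in the units of
    the experiment's matrix (fmol/mg tissue, fmol/uL plasma).
    """
    if ratio < 0:
        raise ValidationError("ratio must be >= 0")
    spike = getattr(entry, "heavy_spike_conc", None)
    mult = getattr(entry, "spike_multiplier", 1.0)
    if spike is None or (isinstance(spike, float) and math.isnan(spike)):
        raise ConfigurationError(
            f"heavy_spike_conc missing for {getattr(entry, 'peptide_id', entry)}")
    return ratio * float(spike) * float(mult)


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd(n-1) / mean, linear scale."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientReplicatesError("CV needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError("CV undefined for non-positive mean")
    return 100.0 * arr.std(ddof=1) / mean


def qc_transitions(light: pd.DataFrame, heavy: pd.DataFrame,
                   cfg: AnalysisConfig) -> pd.DataFrame:
    """Pair light/heavy transitions of one peptide-sample and flag interference.

    For each transition id present in both channels, computes the RT
    difference and each channel's relative (fractional) transition area over
    the paired set.  A transition is flagged as interfered when its RT delta
    exceeds ``cfg.rt_tolerance`` or the light and heavy fractional areas
    disagree by more than ``cfg.rel_area_tolerance``.  Flagged transitions are
    retained in neither channel; the relative areas renormalized over the
    retained set are reported alongside.
    """
    merged = pd.merge(light, heavy, on="transition_id",
                      suffixes=("_light", "_heavy"))
    if merged.empty:
        return pd.DataFrame(columns=QC_REPORT_COLUMNS[2:])
    li = merged["peak_area_light"] + merged["background_light"]
    hi = merged["peak_area_heavy"] + merged["background_heavy"]
    if li.sum() <= 0 or hi.sum() <= 0:
        return pd.DataFrame(columns=QC_REPORT_COLUMNS[2:])
    rel_l = li / li.sum()
    rel_h = hi / hi.sum()
    rt_delta = (merged["retention_time_light"]
                - merged["retention_time_heavy"]).abs()
    flag = (rt_delta > cfg.rt_tolerance) | ((rel_l - rel_h).abs()
                                            > cfg.rel_area_tolerance)
    out = pd.DataFrame({
        "transition_id": merged["transition_id"],
        "rt_delta": rt_delta,
        "light_rel_area": rel_l,
        "heavy_rel_area": rel_h,
        "interference_flag": flag,
        "retained": ~flag,
    })
    kept = out["retained"]
    if kept.any():
        out["light_rel_area_retained"] = np.where(
            kept, li / li[kept].sum(), np.nan)
        out["heavy_rel_area_retained"] = np.where(
            kept, hi / hi[kept].sum(), np.nan)
    else:
        out["light_rel_area_retained"] = np.nan
        out["heavy_rel_area_retained"] = np.nan
    return out


def quantify(report: pd.DataFrame, panel: pd.DataFrame,
             cfg: AnalysisConfig | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every sample x peptide of a transition report.

    Returns ``(quants, qc_report)``: one quantification row per
    sample x peptide (ratio, log2 ratio, estimated concentration, QC flags)
    and the per-transition QC detail.  Peptide-samples with fewer than
    ``cfg.min_transitions`` retained transitions, or a missing channel, are
    reported unquantified (NaN ratio) with the corresponding flag.
    """
    cfg = cfg or AnalysisConfig()
    spike = panel.set_index("peptide_id")[["heavy_spike_conc",
                                           "spike_multiplier"]]
    unknown = sorted(set(report["peptide_id"]) - set(spike.index))
    if unknown:
        raise ValidationError(
            f"report contains peptide(s) absent from the panel: {unknown[:5]}")

    key = ["sample_id", "peptide_id"]
    light = report[report["label"] == "light"]
    heavy = report[report["label"] == "heavy"]
    pair = pd.merge(light, heavy, on=key + ["transition_id"],
                    suffixes=("_light", "_heavy"))
    pair = pair.sort_values(key + ["transition_id"],
                            kind="mergesort").reset_index(drop=True)
    li = pair["peak_area_light"] + pair["background_light"]
    hi = pair["peak_area_heavy"] + pair["background_heavy"]
    lsum = li.groupby([pair["sample_id"], pair["peptide_id"]]).transform("sum")
    hsum = hi.groupby([pair["sample_id"], pair["peptide_id"]]).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_l = li / lsum
        rel_h = hi / hsum
    rt_delta = (pair["retention_time_light"]
                - pair["retention_time_heavy"]).abs()
    rt_bad = rt_delta > cfg.rt_tolerance
    area_bad = (rel_l - rel_h).abs() > cfg.rel_area_tolerance
    # groups where a channel summed to zero cannot be paired meaningfully
    dead = (lsum <= 0) | (hsum <= 0)
    flagged = (rt_bad | area_bad) & ~dead
    retained = ~flagged & ~dead

    qc_report = pd.DataFrame({
        "sample_id": pair["sample_id"], "peptide_id": pair["peptide_id"],
        "transition_id": pair["transition_id"], "rt_delta": rt_delta,
        "light_rel_area": rel_l, "heavy_rel_area": rel_h,
        "interference_flag": flagged, "retained": retained,
    })
    li_kept = li.where(retained)
    hi_kept = hi.where(retained)
    lsum_kept = li_kept.groupby(
        [pair["sample_id"], pair["peptide_id"]]).transform("sum")
    hsum_kept = hi_kept.groupby(
        [pair["sample_id"], pair["peptide_id"]]).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        qc_report["light_rel_area_retained"] = li_kept / lsum_kept
        qc_report["heavy_rel_area_retained"] = hi_kept / hsum_kept

    agg = pd.DataFrame({
        "light_total": li_kept.groupby(
            [pair["sample_id"], pair["peptide_id"]]).sum(),
        "heavy_total": hi_kept.groupby(
            [pair["sample_id"], pair["peptide_id"]]).sum(),
        "n_transitions_used": retained.groupby(
            [pair["sample_id"], pair["peptide_id"]]).sum(),
        "rt_mismatch": rt_bad.groupby(
            [pair["sample_id"], pair["peptide_id"]]).any(),
        "rel_area_mismatch": area_bad.groupby(
            [pair["sample_id"], pair["peptide_id"]]).any(),
        "dead": dead.groupby(
            [pair["sample_id"], pair["peptide_id"]]).all(),
    })
    # every sample x peptide present in the report gets a row
    all_keys = report[key].drop_duplicates().sort_values(
        key, kind="mergesort").set_index(key)
    agg = agg.reindex(all_keys.index)
    agg["n_transitions_used"] = agg["n_transitions_used"].fillna(0).astype(int)
    unpaired = agg["light_total"].isna() | agg["dead"].eq(True)

    quants = agg.reset_index()
    quants["qc_flags"] = [
        ";".join(sorted(
            ({"rt_mismatch"} if rt is True else set())
            | ({"rel_area_mismatch"} if ra is True else set())
            | ({"missing_channel"} if miss else set())
            | ({"too_few_transitions"}
               if (not miss and n < cfg.min_transitions) else set())))
        for rt, ra, miss, n in zip(quants["rt_mismatch"],
                                   quants["rel_area_mismatch"],
                                   unpaired.to_numpy(),
                                   quants["n_transitions_used"])]
    quantifiable = (~unpaired.to_numpy()
                    & (quants["n_transitions_used"] >= cfg.min_transitions)
                    & (quants["light_total"] > 0)
                    & (quants["heavy_total"] > 0))
    loh = quants["light_total"] / quants["heavy_total"]
    if cfg.ratio_orientation == "light_over_heavy":
        ratio = loh
    else:
        ratio = 1.0 / loh
    sp = panel.set_index("peptide_id").reindex(quants["peptide_id"])
    est = (loh * sp["heavy_spike_conc"].to_numpy()
           * sp["spike_multiplier"].to_numpy())
    quants["ratio"] = ratio.where(quantifiable)
    quants["log2_ratio"] = np.log2(quants["ratio"])
    quants["est_conc"] = est.where(quantifiable)
    quants.loc[~quantifiable, ["light_total", "heavy_total"]] = np.nan
    quants = quants[QUANT_COLUMNS]
    logger.info("quantify: %d peptide-samples, %d flagged [cfg %s]",
                len(quants), int((quants["qc_flags"] != "").sum()),
                cfg.digest())
    return quants, qc_report[QC_REPORT_COLUMNS]


def apply_lloq_filter(quants: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Flag each quantification as detected iff est_conc strictly exceeds the LLOQ.

    ``fits`` must provide ``peptide_id`` and ``lloq`` (same concentration units
    as the quants).  Peptides without a fit raise; peptides whose curve gave
    no LLOQ (NaN) are never detected.  Below-LLOQ rows are retained with
    ``detected == False`` so the matrix keeps below-LLOQ cells distinct from
    missing ones.
    """
    if "lloq" not in fits.columns:
        raise ConfigurationError("fits must carry an 'lloq' column")
    missing = sorted(set(quants["peptide_id"]) - set(fits["peptide_id"]))
    if missing:
        raise ConfigurationError(f"no LLOQ available for peptide(s) {missing[:5]}")
    out = quants.merge(fits[["peptide_id", "lloq"]], on="peptide_id", how="left")
    out["detected"] = (out["est_conc"] > out["lloq"]).fillna(False)
    return out


def rppa_expression_call(values) -> pd.DataFrame:
    """Mean-normalized expression calls for a protein-array measurement.

    Each value is divided by the collection mean; normalized levels below 0.5
    are called ``negative_or_weak``, above 1.5 ``strong_positive``, and
    ``intermediate`` otherwise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one value")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError("mean must be positive for normalization")
    norm = arr / mean
    labels = np.where(norm < 0.5, "negative_or_weak",
                      np.where(norm > 1.5, "strong_positive", "intermediate"))
    return pd.DataFrame({"value": arr, "normalized": norm, "label": labels})
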