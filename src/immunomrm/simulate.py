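"""Synthetic transition-level MRM data with full ground-truth bookkeeping.

The generator emulates the statistical structure the analysis stages assume:

* per-transition intensity = ``response_factor * fraction * conc * exp(eps)
  + background``, where ``eps`` collects lognormal day and replicate effects
  and the background is an additive truncated-normal floor per transition;
* the lognormal effects are applied to the *analyte* channel only (the
  titrated heavy standard in calibration/repeatability experiments, the
  endogenous light peptide in panel experiments), while the reference
  channel carries signal plus background.  The internal-standard ratio thus
  has log-scale replicate sd ``sigma_within`` and day sd
  ``sigma_between_day``, the nested variance-component structure with
  closed-form CVs used throughout the tests;
* the additive background floor inflates the ratio CV as the analyte
  concentration falls, producing an *emergent* lower limit of quantification
  whose analytic location is part of the ground truth.

Every dataset builder returns ``(report, design, truth)`` where the report
and design are the same CSV dialects the readers consume and ``truth`` is a
:class:`GroundTruth` carrying the simulated panel table, true concentrations,
detectability flags, planted condition effects and cluster memberships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError

#: Heavy-standard dilution series used by default for response curves
#: (fmol/mg tissue); the blank (0) is generated separately.
DEFAULT_CURVE_LEVELS = (2000.0, 200.0, 20.0, 8.0, 3.2, 1.28, 0.512, 0.205)

#: Default repeatability spike levels (fmol/mg): low, medium, high.
DEFAULT_REPEATABILITY_LEVELS = {"low": 10.0, "medium": 100.0, "high": 1000.0}

DEFAULT_STABILITY_CONDITIONS = ("4C_8h", "4C_48h", "freeze_thaw_x2",
                                "minus80_5wk")

#: Digestion-timecourse sampling times (h) and the planted saturating
#: recovery profile (fraction of maximum recovery).
DEFAULT_TIMEPOINTS = (2.0, 6.0, 16.0, 24.0)
DEFAULT_TIMECOURSE_PROFILE = {2.0: 0.55, 6.0: 0.85, 16.0: 1.0, 24.0: 1.0}


@dataclass
class SimParams:
    """Parameters of the synthetic MRM data generator.

    Defaults emulate the validated tissue assay: ~5% within-day and ~10%
    between-day ratio CV, a constant 200 fmol/mg light (or heavy-standard)
    spike, three transitions per peptide, and a background floor whose
    variability drives the ratio CV above 20% at the bottom of the default
    dilution series.
    """

    n_peptides: int = 52
    transition_fractions: tuple = (0.5, 0.3, 0.2)
    response_factor: float = 1000.0      # intensity counts per fmol
    sigma_within: float = 0.05           # log-scale replicate (process) sd
    sigma_between_day: float = 0.09975   # log-scale day-effect sd (~10% CV)
    sigma_between_sample: float = 0.6    # log-scale inter-individual sd
    background_mean: float = 500.0       # additive floor per transition
    background_sd: float = 300.0
    heavy_spike_conc: float = 200.0      # fmol/mg (or fmol/uL)
    spike_multiplier: float = 1.0
    light_spike_conc: float = 200.0      # constant light spike in curves
    condition_effects: dict = field(default_factory=dict)
    rt_center: float = 20.0              # minutes
    rt_jitter: float = 0.01              # sd of per-record RT jitter
    seed: int = 0

    def __post_init__(self):
        fr = np.asarray(self.transition_fractions, dtype=float)
        if fr.size < 2 or (fr <= 0).any():
            raise ValidationError("need >= 2 positive transition fractions")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValidationError("transition fractions must sum to 1")
        for name in ("sigma_within", "sigma_between_day",
                     "sigma_between_sample", "background_mean",
                     "background_sd", "rt_jitter"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.response_factor <= 0:
            raise ValidationError("response_factor must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    @property
    def n_transitions(self) -> int:
        return len(self.transition_fractions)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        if "transition_fractions" in data:
            data["transition_fractions"] = tuple(data["transition_fractions"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-dataset bookkeeping of everything the generator planted."""

    panel: pd.DataFrame
    params: SimParams
    analytic_lloq: pd.Series | None = None
    true_conc: pd.DataFrame | None = None        # samples x peptides
    detect_truth: pd.DataFrame | None = None     # samples x peptides, bool
    lloq: pd.Series | None = None                # LLOQ used for detect_truth
    groups: pd.Series | None = None              # sample -> planted group
    signatures: dict | None = None               # group -> signature peptides
    condition_factors: pd.DataFrame | None = None
    profile: dict | None = None                  # timecourse recovery profile


# ---------------------------------------------------------------------------
# building blocks

def _peptide_ids(n: int) -> list[str]:
    return [f"PEP{i + 1:03d}" for i in range(n)]


def make_panel(params: SimParams) -> pd.DataFrame:
    """Synthetic panel table matching the generator's peptides."""
    ids = _peptide_ids(params.n_peptides)
    return pd.DataFrame({
        "gene_symbol": [f"GENE{i + 1:03d}" for i in range(params.n_peptides)],
        "peptide_id": ids,
        "accession": [f"P{i + 1:05d}" for i in range(params.n_peptides)],
        "description": ["synthetic assay"] * params.n_peptides,
        "status": ["active"] * params.n_peptides,
        "spike_multiplier": [params.spike_multiplier] * params.n_peptides,
        "heavy_spike_conc": [params.heavy_spike_conc] * params.n_peptides,
        "is_phospho": [False] * params.n_peptides,
    })


def _truncated_background(rng: np.random.Generator, n: int,
                          mean: float, sd: float) -> np.ndarray:
    """Draw n backgrounds ~ Normal(mean, sd) truncated at 0 (rejection)."""
    if sd == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def background_moments(params: SimParams) -> tuple[float, float]:
    """Mean and variance of one transition's truncated-normal background."""
    if params.background_mean == 0 and params.background_sd == 0:
        return 0.0, 0.0
    if params.background_sd == 0:
        return params.background_mean, 0.0
    a = -params.background_mean / params.background_sd
    m, v = stats.truncnorm.stats(a, np.inf, loc=params.background_mean,
                                 scale=params.background_sd, moments="mv")
    return float(m), float(v)


def simulate_intensity(conc: float, params: SimParams,
                       rng: np.random.Generator, eps: float = 0.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One channel's transition intensities at a given concentration.

    Returns ``(peak_areas, backgrounds)``; total intensity per transition is
    their sum, ``response_factor * f_t * conc * exp(eps) + b_t``.
    """
    if conc < 0:
        raise ValidationError("concentration must be >= 0")
    fr = np.asarray(params.transition_fractions, dtype=float)
    peak = params.response_factor * fr * conc * math.exp(eps)
    bg = _truncated_background(rng, fr.size, params.background_mean,
                               params.background_sd)
    return peak, bg


def _emit(rows: list, sample_id: str, peptide_id: str, label: str,
          peak: np.ndarray, bg: np.ndarray, rt: float,
          rng: np.random.Generator, params: SimParams) -> None:
    for t in range(len(peak)):
        rows.append((sample_id, peptide_id, label, f"2+/y{t + 4}",
                     float(peak[t]), float(bg[t]),
                     rt + float(rng.normal(0.0, params.rt_jitter))))


def _frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["sample_id", "peptide_id", "label",
                                       "transition_id", "peak_area",
                                       "background", "retention_time"])


def _rt_of(params: SimParams, pep_index: int) -> float:
    return params.rt_center + 0.05 * pep_index


# ---------------------------------------------------------------------------
# analytic noise model

def analytic_ratio_cv(conc: float, params: SimParams, sigma: float | None = None,
                      ref_conc: float | None = None,
                      multiplier: float = 1.0) -> float:
    """Delta-method CV (percent) of the analyte:reference intensity ratio.

    The analyte channel carries ``response_factor * conc * multiplier *
    exp(eps)`` plus backgrounds; the reference channel carries the constant
    spike plus backgrounds.  Exact lognormal moments are combined with the
    truncated-normal background moments.
    """
    sigma = params.sigma_within if sigma is None else sigma
    ref_conc = params.light_spike_conc if ref_conc is None else ref_conc
    k = params.n_transitions
    mb, vb = background_moments(params)
    s = params.response_factor * conc * multiplier
    e_a = s * math.exp(sigma ** 2 / 2) + k * mb
    var_a = s ** 2 * math.exp(sigma ** 2) * (math.exp(sigma ** 2) - 1) + k * vb
    s_ref = params.response_factor * ref_conc
    e_r = s_ref + k * mb
    var_r = k * vb
    if e_a <= 0:
        raise ValidationError("analyte channel has zero expected intensity")
    return 100.0 * math.sqrt(var_a / e_a ** 2 + var_r / e_r ** 2)


def analytic_lloq(params: SimParams, levels=DEFAULT_CURVE_LEVELS,
                  cv_threshold: float = 20.0, multiplier: float = 1.0) -> float:
    """Lowest level whose analytic CV (and every higher level's) is below
    the threshold; NaN when none qualifies."""
    lloq = math.nan
    for conc in sorted(levels, reverse=True):
        if analytic_ratio_cv(conc, params, multiplier=multiplier) >= cv_threshold:
            break
        lloq = conc
    return lloq


def analytic_expected_est(conc: float, params: SimParams) -> float:
    """Expected estimated concentration of an endogenous (light) analyte.

    The estimate is (light total / heavy total) * spike; summing
    Peak Area + Background biases it upward by the background floor.
    """
    k = params.n_transitions
    mb, _ = background_moments(params)
    spike = params.heavy_spike_conc * params.spike_multiplier
    s_l = params.response_factor * conc * math.exp(params.sigma_within ** 2 / 2)
    s_h = params.response_factor * spike
    return (s_l + k * mb) / (s_h + k * mb) * spike


def _invert_expected_est(target: float, params: SimParams) -> float:
    """Concentration whose expected estimate equals ``target`` (0 if none)."""
    k = params.n_transitions
    mb, _ = background_moments(params)
    spike = params.heavy_spike_conc * params.spike_multiplier
    s_h = params.response_factor * spike
    s_l = target / spike * (s_h + k * mb) - k * mb
    conc = s_l / (params.response_factor
                  * math.exp(params.sigma_within ** 2 / 2))
    return max(conc, 0.0)


# ---------------------------------------------------------------------------
# dataset builders

def simulate_curve_dataset(params: SimParams, levels=DEFAULT_CURVE_LEVELS,
                           reps: int = 4, include_blank: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Calibration dilution series: heavy titrated, light constant.

    Per level and replicate, every peptide's heavy channel receives the
    level concentration (times its spike multiplier) with replicate noise;
    the light channel receives the constant light spike.  Blanks carry the
    light spike only (no heavy standard).
    """
    if len(levels) < 4:
        raise ValidationError("need at least 4 curve levels")
    rng = np.random.default_rng(params.seed)
    panel = make_panel(params)
    rows, design = [], []
    for li, conc in enumerate(sorted(levels, reverse=True)):
        for r in range(reps):
            sid = f"curve_L{li + 1}_R{r + 1}"
            design.append(dict(sample_id=sid, role="curve_point",
                               nominal_conc=conc, matrix="frozen_tissue",
                               replicate=r + 1))
            for pi, pep in enumerate(panel["peptide_id"]):
                rt = _rt_of(params, pi)
                mult = float(panel["spike_multiplier"].iloc[pi])
                eps = float(rng.normal(0.0, params.sigma_within))
                peak, bg = simulate_intensity(conc * mult, params, rng, eps)
                _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
                peak, bg = simulate_intensity(params.light_spike_conc,
                                              params, rng, 0.0)
                _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
    if include_blank:
        for r in range(reps):
            sid = f"blank_R{r + 1}"
            design.append(dict(sample_id=sid, role="blank", nominal_conc=0.0,
                               matrix="frozen_tissue", replicate=r + 1))
            for pi, pep in enumerate(panel["peptide_id"]):
                rt = _rt_of(params, pi)
                peak, bg = simulate_intensity(params.light_spike_conc,
                                              params, rng, 0.0)
                _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
    lloqs = pd.Series(
        {pep: analytic_lloq(params, levels,
                            multiplier=float(panel["spike_multiplier"].iloc[pi]))
         for pi, pep in enumerate(panel["peptide_id"])})
    truth = GroundTruth(panel=panel, params=params, analytic_lloq=lloqs)
    return _frame(rows), pd.DataFrame(design), truth


def simulate_repeatability_dataset(params: SimParams, days: int = 5,
                                   reps: int = 3,
                                   levels: dict | None = None,
                                   endogenous_conc: float | None = None
                                   ) -> tuple[pd.DataFrame, pd.DataFrame,
                                              GroundTruth]:
    """Multi-day replicate design at low/medium/high heavy spikes.

    Day effects are drawn per peptide x day (sd ``sigma_between_day``) and
    shared by all replicates and spike levels of that day; replicate noise
    (sd ``sigma_within``) is drawn per measurement.  When
    ``endogenous_conc`` is given, an additional ``endogenous`` level carries
    the noise on the light channel with the heavy standard constant.
    """
    levels = dict(DEFAULT_REPEATABILITY_LEVELS) if levels is None else levels
    if days < 2 or reps < 2:
        raise ValidationError("need >= 2 days and >= 2 replicates")
    rng = np.random.default_rng(params.seed)
    panel = make_panel(params)
    day_eff = rng.normal(0.0, params.sigma_between_day,
                         size=(params.n_peptides, days))
    rows, design = [], []
    all_levels = dict(levels)
    if endogenous_conc is not None:
        all_levels["endogenous"] = float(endogenous_conc)
    for level, conc in all_levels.items():
        for d in range(days):
            for r in range(reps):
                sid = f"rep_{level}_D{d + 1}_R{r + 1}"
                design.append(dict(sample_id=sid, role="repeatability",
                                   spike_level=level, day=d + 1,
                                   replicate=r + 1, matrix="frozen_tissue"))
                for pi, pep in enumerate(panel["peptide_id"]):
                    rt = _rt_of(params, pi)
                    eps = float(day_eff[pi, d]
                                + rng.normal(0.0, params.sigma_within))
                    if level == "endogenous":
                        # endogenous light analyte, heavy standard reference
                        peak, bg = simulate_intensity(conc, params, rng, eps)
                        _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
                        peak, bg = simulate_intensity(
                            params.heavy_spike_conc, params, rng, 0.0)
                        _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
                    else:
                        peak, bg = simulate_intensity(conc, params, rng, eps)
                        _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
                        peak, bg = simulate_intensity(
                            params.light_spike_conc, params, rng, 0.0)
                        _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
    truth = GroundTruth(panel=panel, params=params)
    return _frame(rows), pd.DataFrame(design), truth


def simulate_stability_dataset(params: SimParams,
                               conditions=DEFAULT_STABILITY_CONDITIONS,
                               reps: int = 3, analyte_conc: float = 200.0,
                               replicate_sigma: float = 0.01
                               ) -> tuple[pd.DataFrame, pd.DataFrame,
                                          GroundTruth]:
    """Fresh control plus storage/handling arms with planted condition effects.

    Mirrors the validation design: the heavy standard is spiked at
    ``analyte_conc`` into every aliquot and carries the replicate noise and
    any degradation, with a constant light reference.
    ``params.condition_effects`` maps a condition name to either a scalar
    multiplier or a per-peptide mapping ``{peptide_id: factor}``; the factor
    scales the recovered heavy analyte, so a factor f shifts the light:heavy
    ratio by 1/f.  Unlisted conditions and peptides get factor 1.

    Replicates are repeat injections of stored aliquots of one prepared
    capture, so they carry instrument-level noise (``replicate_sigma``,
    default 1%) rather than the full process variability of complete
    process replicates.
    """
    if reps < 2:
        raise ValidationError("need >= 2 replicates per arm")
    rng = np.random.default_rng(params.seed)
    panel = make_panel(params)
    peptides = list(panel["peptide_id"])
    factors = pd.DataFrame(1.0, index=peptides,
                           columns=["fresh", *conditions])
    for cond, eff in (params.condition_effects or {}).items():
        if cond not in factors.columns:
            raise ValidationError(f"unknown condition {cond!r}")
        if isinstance(eff, dict):
            for pep, f in eff.items():
                factors.loc[pep, cond] = float(f)
        else:
            factors[cond] = float(eff)
    rows, design = [], []
    for cond in ["fresh", *conditions]:
        for r in range(reps):
            sid = f"stab_{cond}_R{r + 1}"
            design.append(dict(sample_id=sid, role="stability",
                               condition=cond, replicate=r + 1,
                               matrix="frozen_tissue"))
            for pi, pep in enumerate(peptides):
                rt = _rt_of(params, pi)
                eps = float(rng.normal(0.0, replicate_sigma))
                conc = analyte_conc * float(factors.loc[pep, cond])
                peak, bg = simulate_intensity(conc, params, rng, eps)
                _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
                peak, bg = simulate_intensity(params.light_spike_conc,
                                              params, rng, 0.0)
                _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
    truth = GroundTruth(panel=panel, params=params,
                        condition_factors=factors)
    return _frame(rows), pd.DataFrame(design), truth


def simulate_timecourse_dataset(params: SimParams,
                                timepoints=DEFAULT_TIMEPOINTS, reps: int = 3,
                                profile: dict | None = None,
                                base_conc: float = 100.0
                                ) -> tuple[pd.DataFrame, pd.DataFrame,
                                           GroundTruth]:
    """Digestion timecourse with a planted saturating recovery profile."""
    profile = dict(DEFAULT_TIMECOURSE_PROFILE) if profile is None else profile
    missing = [t for t in timepoints if t not in profile]
    if missing:
        raise ValidationError(f"profile lacks timepoint(s) {missing}")
    rng = np.random.default_rng(params.seed)
    panel = make_panel(params)
    rows, design = [], []
    for t in timepoints:
        for r in range(reps):
            sid = f"tc_{t:g}h_R{r + 1}"
            design.append(dict(sample_id=sid, role="timecourse",
                               timepoint_h=float(t), replicate=r + 1,
                               matrix="frozen_tissue"))
            for pi, pep in enumerate(panel["peptide_id"]):
                rt = _rt_of(params, pi)
                eps = float(rng.normal(0.0, params.sigma_within))
                conc = base_conc * float(profile[t])
                peak, bg = simulate_intensity(conc, params, rng, eps)
                _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
                peak, bg = simulate_intensity(params.heavy_spike_conc,
                                              params, rng, 0.0)
                _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
    truth = GroundTruth(panel=panel, params=params, profile=profile)
    return _frame(rows), pd.DataFrame(design), truth


def simulate_panel_dataset(params: SimParams, n_samples: int = 40,
                           groups: tuple | None = None,
                           group_effect: float = 4.0,
                           signature_size: int | None = None,
                           lloq: float = 12.8,
                           detect_margin: float = 2.0,
                           detect_fraction: float = 0.6,
                           enforce_margin: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Biospecimen-style panel with endogenous concentrations and truth flags.

    A fraction ``detect_fraction`` of peptides is planted detectable: their
    per-sample expected estimated concentration is kept at or above
    ``detect_margin * lloq`` (draws spread upward by a folded lognormal with
    sd ``sigma_between_sample``); the rest are kept at or below
    ``lloq / detect_margin``.  With ``groups`` (sample counts per planted
    group), disjoint signature subsets of the detectable peptides are shifted
    up by ``group_effect * sigma_between_sample`` on the log scale in their
    group's samples.

    With ``enforce_margin=False`` the folded (one-sided) draws become plain
    two-sided lognormal spread around the anchors, so the inter-individual
    log-sd is exactly ``sigma_between_sample``; truth flags then follow each
    cell's expected estimate without a guaranteed margin.
    """
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")
    if detect_margin < 1:
        raise ValidationError("detect_margin must be >= 1")
    rng = np.random.default_rng(params.seed)
    panel = make_panel(params)
    peptides = list(panel["peptide_id"])
    n_det = int(round(detect_fraction * params.n_peptides))
    detectable = np.array([i < n_det for i in range(params.n_peptides)])

    group_of = pd.Series(["all"] * n_samples,
                         index=[f"tumor_{i + 1:03d}" for i in range(n_samples)])
    signatures: dict[str, list[str]] = {}
    if groups is not None:
        if sum(groups) != n_samples:
            raise ValidationError("group sizes must sum to n_samples")
        labels = []
        for gi, size in enumerate(groups):
            labels += [f"group{gi + 1}"] * size
        group_of = pd.Series(labels, index=group_of.index)
        sig = signature_size or max(1, n_det // (2 * len(groups)))
        for gi in range(len(groups)):
            signatures[f"group{gi + 1}"] = peptides[gi * sig:(gi + 1) * sig]

    sites = ["breast", "colon", "lung", "ovary", "kidney"]
    # anchor concentrations: expected estimate exactly at the margin bound
    c_above = _invert_expected_est(detect_margin * lloq, params)
    c_below = _invert_expected_est(lloq / detect_margin, params)
    rows, design = [], []
    conc_mat = pd.DataFrame(0.0, index=group_of.index, columns=peptides)
    for si, sid in enumerate(group_of.index):
        design.append(dict(sample_id=sid, role="panel",
                           matrix="frozen_tissue", input_amount=500.0,
                           tissue_site=sites[si % len(sites)]))
        for pi, pep in enumerate(peptides):
            eta = float(rng.normal(0.0, params.sigma_between_sample))
            if enforce_margin:
                eta = abs(eta)
            if detectable[pi]:
                conc = c_above * math.exp(eta)
                for g, sig in signatures.items():
                    if pep in sig and group_of.iloc[si] == g:
                        conc *= math.exp(group_effect
                                         * params.sigma_between_sample)
            else:
                conc = c_below * math.exp(-eta)
            conc_mat.iloc[si, pi] = conc
            rt = _rt_of(params, pi)
            eps = float(rng.normal(0.0, params.sigma_within))
            peak, bg = simulate_intensity(conc, params, rng, eps)
            _emit(rows, sid, pep, "light", peak, bg, rt, rng, params)
            peak, bg = simulate_intensity(
                params.heavy_spike_conc, params, rng, 0.0)
            _emit(rows, sid, pep, "heavy", peak, bg, rt, rng, params)
    expected = conc_mat.map(lambda c: analytic_expected_est(c, params))
    detect_truth = expected > lloq
    truth = GroundTruth(panel=panel, params=params, true_conc=conc_mat,
                        detect_truth=detect_truth,
                        lloq=pd.Series(lloq, index=peptides),
                        groups=group_of if groups is not None else None,
                        signatures=signatures or None)
    return _frame(rows), pd.DataFrame(design), truth


def inject_interference(report: pd.DataFrame, peptide_id: str,
                        transition_id: str, factor: float = 1.0,
                        rt_shift: float = 0.0, sample_id: str | None = None,
                        label: str = "light") -> pd.DataFrame:
    """Multiply one light transition's intensity and/or shift its RT.

    Provides positive controls for the interference QC: scaling a single
    light transition distorts its relative area, shifting its RT breaks RT
    concordance.  Returns a modified copy; all other records are untouched.
    """
    out = report.copy()
    mask = ((out["peptide_id"] == peptide_id)
            & (out["transition_id"] == transition_id)
            & (out["label"] == label))
    if sample_id is not None:
        mask &= out["sample_id"] == sample_id
    if not mask.any():
        raise ValidationError(
            f"no record matches {peptide_id}/{transition_id}/{label}")
    out.loc[mask, "peak_area"] *= factor
    out.loc[mask, "background"] *= factor
    out.loc[mask, "retention_time"] += rt_shift
    return out
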