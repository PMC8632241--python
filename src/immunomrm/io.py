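"""Data model and file I/O for transition reports, design sheets and the assay panel.

The pipeline consumes three plain-CSV inputs:

* a long-format *transition report* — one row per sample x peptide x label
  channel x transition, carrying the integrated peak area, the background
  estimate and the retention time (the dialect mirrors a Skyline
  transition-results export, frozen to one fixed header);
* a *design sheet* mapping each sample to its experimental role (calibration
  point, repeatability replicate, stability arm, biospecimen panel member...),
  day/replicate indices, spike level and matrix;
* a *panel table* describing the assayed peptides (gene, modified sequence,
  UniProt accession, validation status, heavy-standard spike).

All tabular data are held as :class:`pandas.DataFrame` with the fixed column
sets below; the dataclasses are provided for record-level construction and
for configuration.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, fields, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ReportFormatError, ValidationError

logger = logging.getLogger("immunomrm")

#: Columns of a transition report, in canonical order.
REPORT_COLUMNS = [
    "sample_id",
    "peptide_id",
    "label",
    "transition_id",
    "peak_area",
    "background",
    "retention_time",
]

#: Key identifying one measured transition within a report.
REPORT_KEY = ["sample_id", "peptide_id", "label", "transition_id"]

LABELS = ("light", "heavy")

#: Columns of a study-design sheet. Fields not applicable to a role are empty.
DESIGN_COLUMNS = [
    "sample_id",
    "role",
    "nominal_conc",
    "spike_level",
    "day",
    "replicate",
    "condition",
    "timepoint_h",
    "matrix",
    "input_amount",
    "tissue_site",
]

ROLES = ("curve_point", "blank", "repeatability", "stability", "panel", "timecourse")
CONDITIONS = ("fresh", "4C_8h", "4C_48h", "freeze_thaw_x2", "minus80_5wk", "none")
SPIKE_LEVELS = ("low", "medium", "high", "endogenous", "none")

PANEL_COLUMNS = [
    "gene_symbol",
    "peptide_modified_sequence",
    "accession",
    "description",
    "status",
    "spike_multiplier",
    "heavy_spike_conc",
]

#: Modification tokens that may appear in bracket notation in a sequence.
KNOWN_MODIFICATIONS = ("ph", "cam")


@dataclass(frozen=True)
class TransitionRecord:
    """One measured transition of one peptide in one sample and label channel."""

    sample_id: str
    peptide_id: str
    label: str          # "light" (endogenous) or "heavy" (labeled standard)
    transition_id: str  # e.g. "2+/y7"
    peak_area: float
    background: float
    retention_time: float  # minutes

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValidationError(f"unknown label channel {self.label!r}")
        if self.peak_area < 0:
            raise ValidationError("peak_area must be >= 0")
        if self.background < 0:
            raise ValidationError("background must be >= 0")
        if not self.retention_time > 0:
            raise ValidationError("retention_time must be > 0")


@dataclass(frozen=True)
class PanelEntry:
    """One assayed peptide of the multiplexed panel."""

    gene_symbol: str
    peptide_id: str      # modified sequence, e.g. "NLS[ph]DIDQSFNK"
    accession: str
    status: str          # "active" or "failed_linearity"
    spike_multiplier: float = 1.0
    heavy_spike_conc: float = 200.0  # fmol/mg (tissue) or fmol/uL (plasma)

    @property
    def is_phospho(self) -> bool:
        return "[ph]" in self.peptide_id


@dataclass
class AnalysisConfig:
    """Tunable thresholds and conventions used throughout the pipeline.

    Fractions are on (0, 1); CV thresholds apply to CVs expressed as
    fractions of the mean (0.20 == 20%).
    """

    cv_lloq_threshold: float = 0.20      # replicate-CV bound defining the LLOQ
    linearity_r2_min: float = 0.90       # minimum R^2 of the log-log fit
    ratio_orientation: str = "light_over_heavy"
    rt_tolerance: float = 0.10           # minutes, light-vs-heavy RT concordance
    rel_area_tolerance: float = 0.20     # abs. difference of fractional areas
    detect_min_fraction: float = 0.50    # panel filter for clustering
    alpha: float = 0.05                  # one-sided confidence for min-input
    stability_cv_max: float = 0.20
    stability_diff_max: float = 0.20
    plateau_tolerance: float = 0.05      # timecourse plateau rule
    min_transitions: int = 2             # minimum transitions per quantified peptide
    random_seed: int = 0

    def __post_init__(self):
        for name in ("cv_lloq_threshold", "linearity_r2_min", "rel_area_tolerance",
                     "detect_min_fraction", "alpha", "stability_cv_max",
                     "stability_diff_max", "plateau_tolerance"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.ratio_orientation not in ("light_over_heavy", "heavy_over_light"):
            raise ValidationError(
                f"unknown ratio_orientation {self.ratio_orientation!r}")
        if self.rt_tolerance <= 0:
            raise ValidationError("rt_tolerance must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ReportFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the configuration, for log auditing."""
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


# ---------------------------------------------------------------------------
# transition reports

def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ReportFormatError(f"{what} is missing required column {col!r}")


def read_transition_report(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a long-format transition report CSV.

    Parameters
    ----------
    path : path-like or file-like
    column_map : optional mapping from the file's column names to the
        canonical ``REPORT_COLUMNS`` names, for exports using a different
        header dialect.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "peptide_id": str,
                                  "label": str, "transition_id": str},
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    _require_columns(df, REPORT_COLUMNS, "transition report")
    df = df[REPORT_COLUMNS].copy()
    for col in ("peak_area", "background", "retention_time"):
        df[col] = pd.to_numeric(df[col])
    neg = df.index[(df["peak_area"] < 0)]
    if len(neg):
        raise ValidationError(
            f"negative peak_area at row(s) {list(neg[:5])} of the transition report")
    neg = df.index[(df["background"] < 0)]
    if len(neg):
        raise ValidationError(
            f"negative background at row(s) {list(neg[:5])} of the transition report")
    bad = df.index[~(df["retention_time"] > 0)]
    if len(bad):
        raise ValidationError(
            f"non-positive retention_time at row(s) {list(bad[:5])}")
    bad_label = sorted(set(df["label"]) - set(LABELS))
    if bad_label:
        raise ValidationError(f"unknown label channel(s) {bad_label}")
    dup = df.duplicated(REPORT_KEY)
    if dup.any():
        key = df.loc[dup.idxmax(), REPORT_KEY].tolist()
        raise ValidationError(f"duplicate transition key {key} in report")
    logger.info("read_transition_report: %d records from %s", len(df), path)
    return df


def write_transition_report(df: pd.DataFrame, path) -> None:
    """Write a canonicalized transition report (sorted keys, fixed float format)."""
    _require_columns(df, REPORT_COLUMNS, "transition report")
    out = df[REPORT_COLUMNS].sort_values(REPORT_KEY, kind="mergesort")
    # shortest-repr floats: byte-stable and lossless on re-read
    out.to_csv(path, index=False, lineterminator="\n")


def records_to_frame(records) -> pd.DataFrame:
    """Assemble :class:`TransitionRecord` objects into a report DataFrame."""
    rows = [asdict(r) if isinstance(r, TransitionRecord) else r for r in records]
    return pd.DataFrame(rows)[REPORT_COLUMNS]


# ---------------------------------------------------------------------------
# design sheets

def read_design(path) -> pd.DataFrame:
    """Read a study-design sheet mapping samples to experimental roles."""
    df = pd.read_csv(path, dtype={"sample_id": str, "role": str})
    _require_columns(df, ["sample_id", "role"], "design sheet")
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[DESIGN_COLUMNS].copy()
    for col in ("nominal_conc", "timepoint_h", "input_amount"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("day", "replicate"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    bad_roles = sorted(set(df["role"].dropna()) - set(ROLES))
    if bad_roles:
        raise ValidationError(f"unknown design role(s) {bad_roles}")
    missing = df[(df["role"] == "curve_point") & df["nominal_conc"].isna()]
    if len(missing):
        raise ValidationError(
            "curve_point samples without nominal_conc: "
            f"{missing['sample_id'].tolist()[:5]}")
    dup = df.duplicated("sample_id")
    if dup.any():
        raise ValidationError(
            f"duplicate sample_id {df.loc[dup.idxmax(), 'sample_id']!r} in design")
    return df


def write_design(df: pd.DataFrame, path) -> None:
    out = df.reindex(columns=DESIGN_COLUMNS)
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# panel table

def _validate_sequence(seq: str) -> None:
    """Check bracket-notation modifications against the known token set."""
    i = 0
    while True:
        i = seq.find("[", i)
        if i < 0:
            return
        j = seq.find("]", i)
        if j < 0:
            raise ValidationError(f"unbalanced modification bracket in {seq!r}")
        token = seq[i + 1:j]
        if token not in KNOWN_MODIFICATIONS:
            raise ValidationError(
                f"unknown modification token [{token}] in {seq!r}")
        i = j + 1


def load_panel(path=None) -> pd.DataFrame:
    """Load a panel-definition table; defaults to the packaged panel.

    The packaged table transcribes the published 55-peptide immuno-oncology
    panel: 46 distinct protein accessions, 5 phosphopeptides, and 3 assays
    carrying status ``failed_linearity`` (inadequate response-curve linearity),
    leaving 52 active assays.
    """
    if path is None:
        src = resources.files("immunomrm.data").joinpath("panel.csv")
        df = pd.read_csv(_io.StringIO(src.read_text()))
    else:
        df = pd.read_csv(path)
    _require_columns(df, ["gene_symbol", "peptide_modified_sequence", "accession"],
                     "panel table")
    if "status" not in df.columns:
        df["status"] = "active"
    if "spike_multiplier" not in df.columns:
        df["spike_multiplier"] = 1.0
    if "heavy_spike_conc" not in df.columns:
        df["heavy_spike_conc"] = np.nan
    df = df.rename(columns={"peptide_modified_sequence": "peptide_id"})
    dup = df.duplicated("peptide_id")
    if dup.any():
        raise ValidationError(
            f"duplicate peptide sequence {df.loc[dup.idxmax(), 'peptide_id']!r}")
    for seq in df["peptide_id"]:
        _validate_sequence(seq)
    bad = sorted(set(df["status"]) - {"active", "failed_linearity"})
    if bad:
        raise ValidationError(f"unknown panel status {bad}")
    bad_mult = sorted(set(df["spike_multiplier"]) - {1, 10})
    if bad_mult:
        raise ValidationError(f"spike_multiplier must be 1 or 10, got {bad_mult}")
    df["is_phospho"] = df["peptide_id"].str.contains(r"\[ph\]", regex=True)
    df["spike_multiplier"] = df["spike_multiplier"].astype(float)
    logger.info("load_panel: %d entries (%d active)", len(df),
                int((df["status"] == "active").sum()))
    return df.reset_index(drop=True)


def check_report_against_panel(report: pd.DataFrame, panel: pd.DataFrame) -> None:
    """Reject transition records whose peptide is absent from the panel."""
    unknown = sorted(set(report["peptide_id"]) - set(panel["peptide_id"]))
    if unknown:
        raise ValidationError(
            f"report contains peptide(s) absent from the panel: {unknown[:5]}")


def panel_entries(panel: pd.DataFrame) -> list[PanelEntry]:
    """View a panel DataFrame as a list of :class:`PanelEntry`."""
    return [
        PanelEntry(gene_symbol=r.gene_symbol, peptide_id=r.peptide_id,
                   accession=r.accession, status=r.status,
                   spike_multiplier=float(r.spike_multiplier),
                   heavy_spike_conc=float(r.heavy_spike_conc))
        for r in panel.itertuples()
    ]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
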