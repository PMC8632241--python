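"""Application of validated assays to biospecimen panels.

Builds peptide x sample detection matrices (log2 light:heavy ratios with
above-LLOQ flags), summarizes inter-individual variability, clusters
z-scored expression, correlates paired measurement platforms, and estimates
the minimum sample input that keeps each analyte detectable.

Signal-to-noise is operationalized as estimated concentration divided by the
assay's LLOQ: chromatographic S/N is unavailable downstream of the
transition report, and this ratio is exactly the margin the detection rule
tests.  The minimum-input rule scales each sample's S/N linearly with input
mass and asks, per analyte, whether the one-sided lower 95% confidence bound
of the mean log S/N stays above 0 (S/N 1) at the reduced mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import AnalysisConfig
from .quant import apply_lloq_filter, cv

logger = logging.getLogger("immunomrm")


@dataclass
class DetectionMatrix:
    """Peptides x samples quantification grid with above-LLOQ flags.

    ``log2_ratio`` and ``est_conc`` hold NaN for missing cells (no
    QC-passing quantification), which are distinct from present-but-
    below-LLOQ cells (``detected`` False with a value).
    """

    log2_ratio: pd.DataFrame      # peptides x samples
    est_conc: pd.DataFrame
    detected: pd.DataFrame        # boolean, False where missing
    annotations: pd.DataFrame     # per-sample design annotations
    lloq: pd.Series               # per-peptide LLOQ used for the flags

    def detected_fraction(self) -> pd.Series:
        """Per peptide, the fraction of panel samples detected above LLOQ."""
        return self.detected.mean(axis=1)

    def detected_count_per_sample(self) -> pd.Series:
        """Per sample, the number of peptides detected above LLOQ."""
        return self.detected.sum(axis=0).astype(int)


@dataclass
class ClusterResult:
    z: pd.DataFrame               # retained peptides x samples, z-scored
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list


@dataclass
class MinInputEstimate:
    table: pd.DataFrame           # input_mass, predicted_count, ci_low, ci_high
    m_star: pd.Series             # per-analyte minimum input mass
    m0: float
    n_analytes: int


def detection_matrix(quants: pd.DataFrame, fits: pd.DataFrame,
                     design: pd.DataFrame) -> DetectionMatrix:
    """Assemble panel-sample quantifications into a flagged matrix."""
    panel_design = design[design["role"] == "panel"]
    if panel_design.empty:
        raise ValidationError("design contains no panel samples")
    sub = quants[quants["sample_id"].isin(panel_design["sample_id"])]
    if sub.empty:
        raise ValidationError("no quantifications for panel samples")
    flagged = apply_lloq_filter(sub, fits)
    log2 = flagged.pivot(index="peptide_id", columns="sample_id",
                         values="log2_ratio")
    est = flagged.pivot(index="peptide_id", columns="sample_id",
                        values="est_conc")
    det = flagged.pivot(index="peptide_id", columns="sample_id",
                        values="detected").fillna(False).astype(bool)
    order = [s for s in panel_design["sample_id"] if s in log2.columns]
    log2, est, det = log2[order], est[order], det[order]
    ann = panel_design.set_index("sample_id").loc[
        order, ["tissue_site", "matrix", "input_amount"]]
    lloq = fits.set_index("peptide_id")["lloq"].reindex(log2.index)
    logger.info("detection_matrix: %d peptides x %d samples, %.1f%% detected",
                *log2.shape, 100 * det.to_numpy().mean())
    return DetectionMatrix(log2_ratio=log2, est_conc=est, detected=det,
                           annotations=ann, lloq=lloq)


def inter_individual_cv(matrix: DetectionMatrix) -> tuple[pd.Series, dict]:
    """Per-peptide percent CV of linear-scale ratios across detected samples.

    Peptides with fewer than 2 detected samples are omitted.  Returns the
    per-peptide series plus the panel median and range.
    """
    out = {}
    for pep in matrix.log2_ratio.index:
        vals = matrix.log2_ratio.loc[pep][matrix.detected.loc[pep]].dropna()
        if len(vals) < 2:
            logger.info("inter_individual_cv: %s omitted (<2 detected)", pep)
            continue
        out[pep] = cv(np.exp2(vals.to_numpy()))
    series = pd.Series(out, dtype=float)
    summary = {
        "median_cv": float(series.median()) if len(series) else math.nan,
        "min_cv": float(series.min()) if len(series) else math.nan,
        "max_cv": float(series.max()) if len(series) else math.nan,
        "n_peptides": int(len(series)),
    }
    return series, summary


def _nan_euclidean(mat: np.ndarray) -> np.ndarray:
    """Pairwise euclidean distances over rows, ignoring NaN coordinates.

    Shared-coordinate squared differences are rescaled to the full dimension
    count so sparser overlaps are not rewarded with smaller distances.
    """
    n, d = mat.shape
    dist = np.zeros((n, n))
    finite = np.isfinite(mat)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            k = int(both.sum())
            if k == 0:
                raise ValidationError(
                    "rows share no observed coordinates; cannot cluster")
            diff = mat[i, both] - mat[j, both]
            dist[i, j] = dist[j, i] = math.sqrt((diff ** 2).sum() * d / k)
    return dist


def cluster_matrix(matrix: DetectionMatrix,
                   cfg: AnalysisConfig | None = None) -> ClusterResult:
    """Z-score and hierarchically cluster the detection matrix.

    Peptides detected in more than ``cfg.detect_min_fraction`` of samples are
    retained; below-LLOQ cells are excluded (left NaN), not imputed.  Each
    retained peptide's log2 ratios are standardized over its detected
    samples; zero-variance peptides are dropped with a warning.  Rows and
    columns are clustered with average-linkage euclidean distances (NaNs
    handled pairwise); inputs are sorted lexicographically first so the
    result is invariant to input order.
    """
    cfg = cfg or AnalysisConfig()
    frac = matrix.detected_fraction()
    keep = frac.index[frac > cfg.detect_min_fraction]
    if len(keep) < 2 or matrix.log2_ratio.shape[1] < 2:
        raise ValidationError("need >= 2 retained peptides and >= 2 samples")
    vals = matrix.log2_ratio.loc[keep].where(matrix.detected.loc[keep])
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flat = sd.index[~(sd > 0)]
    if len(flat):
        logger.warning("cluster_matrix: dropping zero-variance peptide(s) %s",
                       list(flat))
        vals = vals.drop(index=flat)
        mean, sd = mean.drop(index=flat), sd.drop(index=flat)
    z = vals.sub(mean, axis=0).div(sd, axis=0)
    z = z.sort_index(axis=0).sort_index(axis=1)

    row_link = hierarchy.linkage(squareform(_nan_euclidean(z.to_numpy()),
                                            checks=False), method="average")
    col_link = hierarchy.linkage(squareform(_nan_euclidean(z.to_numpy().T),
                                            checks=False), method="average")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(z=z, row_linkage=row_link, col_linkage=col_link,
                         row_order=row_order, col_order=col_order)


def top_split(result: ClusterResult, axis: str = "columns") -> pd.Series:
    """Two-cluster cut of the dendrogram on the requested axis."""
    if axis == "columns":
        labels, link = list(result.z.columns), result.col_linkage
    else:
        labels, link = list(result.z.index), result.row_linkage
    assign = hierarchy.fcluster(link, 2, criterion="maxclust")
    return pd.Series(assign, index=labels)


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Serialize a scipy linkage tree as a newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def correlate_paired(a: pd.DataFrame, b: pd.DataFrame,
                     grouping: pd.Series | None = None,
                     min_pairs: int = 3) -> pd.DataFrame:
    """Per-analyte Pearson correlation between two paired log2 matrices.

    ``a`` and ``b`` are analyte x unit matrices sharing unit identifiers
    (columns); rows are aligned on analyte.  Correlations use complete pairs
    only and require at least ``min_pairs``; analytes with a constant vector
    are omitted.  With ``grouping`` (unit -> group), correlations are also
    computed within each group; the ``all`` group always spans every unit.

    Returns a long DataFrame (analyte, group, r, n_pairs).
    """
    units = a.columns.intersection(b.columns)
    analytes = a.index.intersection(b.index)
    if len(units) < min_pairs:
        raise ValidationError("fewer shared units than min_pairs")
    groups = {"all": list(units)}
    if grouping is not None:
        for g, sub in pd.Series(grouping).groupby(grouping):
            groups[str(g)] = [u for u in sub.index if u in units]
    rows = []
    for gname, gunits in groups.items():
        for analyte in analytes:
            x = a.loc[analyte, gunits].astype(float)
            y = b.loc[analyte, gunits].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                logger.info("correlate_paired: %s constant in %s; omitted",
                            analyte, gname)
                continue
            r = stats.pearsonr(xv, yv).statistic
            rows.append(dict(analyte=analyte, group=gname, r=float(r),
                             n_pairs=int(ok.sum())))
    return pd.DataFrame(rows, columns=["analyte", "group", "r", "n_pairs"])


def median_correlation(corr: pd.DataFrame, group: str = "all") -> float:
    vals = corr.loc[corr["group"] == group, "r"]
    return float(vals.median()) if len(vals) else math.nan


DEFAULT_INPUT_GRID = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0)


def minimum_input(matrix: DetectionMatrix,
                  cfg: AnalysisConfig | None = None,
                  input_grid=DEFAULT_INPUT_GRID, m0: float = 500.0,
                  log_scale: bool = True, min_samples: int = 3
                  ) -> MinInputEstimate:
    """Predict how many analytes stay detectable as input mass decreases.

    Per analyte, S/N = est_conc / LLOQ over quantified samples at the
    reference mass ``m0``.  Scaling to mass m multiplies every S/N by m/m0;
    the analyte is predicted detectable at m when the one-sided lower
    ``1 - cfg.alpha`` confidence bound of the mean log S/N (t distribution,
    df = n - 1) remains above 0.  ``predicted_count`` and ``ci_low`` count
    analytes at the lower endpoint; ``ci_high`` at the upper endpoint.
    ``m_star`` is the smallest mass keeping the lower bound at 0.

    With ``log_scale=False`` the same rule is applied to linear-scale S/N
    against the detectability threshold 1 (sensitivity variant).
    """
    cfg = cfg or AnalysisConfig()
    grid = sorted(float(m) for m in input_grid)
    if any(m > m0 for m in grid):
        raise ValidationError("input grid masses must not exceed the "
                              f"reference mass {m0}")
    if any(m <= 0 for m in grid):
        raise ValidationError("input masses must be positive")

    stats_rows = {}
    for pep in matrix.est_conc.index:
        lloq = matrix.lloq.loc[pep]
        if not lloq > 0:
            continue
        sn = (matrix.est_conc.loc[pep].dropna() / lloq)
        sn = sn[sn > 0]
        n = len(sn)
        if n < min_samples:
            logger.info("minimum_input: %s excluded (%d samples)", pep, n)
            continue
        vals = np.log(sn.to_numpy()) if log_scale else sn.to_numpy()
        m = float(vals.mean())
        s = float(vals.std(ddof=1))
        half = stats.t.ppf(1 - cfg.alpha, n - 1) * s / math.sqrt(n)
        stats_rows[pep] = (m, half, n)
    if not stats_rows:
        raise ValidationError("no analyte has enough samples for the t-bound")

    def counts_at(mass: float) -> tuple[int, int]:
        lo = hi = 0
        scale = mass / m0
        for m, half, _ in stats_rows.values():
            if log_scale:
                lo += m - half + math.log(scale) > 0
                hi += m + half + math.log(scale) > 0
            else:
                lo += (m - half) * scale > 1
                hi += (m + half) * scale > 1
        return lo, hi

    rows = []
    for mass in grid:
        lo, hi = counts_at(mass)
        rows.append(dict(input_mass=mass, predicted_count=lo,
                         ci_low=lo, ci_high=hi))
    table = pd.DataFrame(rows)

    m_star = {}
    for pep, (m, half, _) in stats_rows.items():
        if log_scale:
            m_star[pep] = m0 * math.exp(half - m)
        else:
            denom = m - half
            m_star[pep] = m0 / denom if denom > 0 else math.inf
    return MinInputEstimate(table=table, m_star=pd.Series(m_star, dtype=float),
                            m0=float(m0), n_analytes=len(stats_rows))
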