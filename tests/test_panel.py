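"""Detection matrices, clustering, paired correlation, minimum input."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunomrm as im
from immunomrm.errors import ValidationError
from immunomrm.panel import DEFAULT_INPUT_GRID, DetectionMatrix
from immunomrm.simulate import SimParams, simulate_panel_dataset


def simulate_matrix(seed=21, n_peptides=20, n_samples=15, **kw):
    params = SimParams(n_peptides=n_peptides, seed=seed)
    report, design, truth = simulate_panel_dataset(params, n_samples=n_samples,
                                                   **kw)
    quants, _ = im.quantify(report, truth.panel)
    fits = pd.DataFrame({"peptide_id": truth.lloq.index,
                         "lloq": truth.lloq.values})
    return im.detection_matrix(quants, fits, design), truth


class TestDetectionMatrix:
    def test_flags_match_planted_truth_exactly(self):
        matrix, truth = simulate_matrix(seed=21, n_peptides=20, n_samples=15)
        want = truth.detect_truth.T.loc[matrix.detected.index,
                                        matrix.detected.columns]
        assert matrix.detected.equals(want)

    def test_everything_above_lloq_all_detected(self):
        matrix, _ = simulate_matrix(seed=3, detect_fraction=1.0,
                                    detect_margin=10.0)
        assert matrix.detected.to_numpy().all()
        assert (matrix.detected_fraction() == 1.0).all()

    def test_peptide_far_below_lloq_never_detected(self):
        matrix, truth = simulate_matrix(seed=4, detect_fraction=0.5,
                                        detect_margin=10.0)
        below = truth.detect_truth.columns[~truth.detect_truth.iloc[0]]
        assert (matrix.detected_fraction().loc[below] == 0.0).all()

    def test_missing_cell_distinct_from_below_lloq(self):
        quants = pd.DataFrame({
            "sample_id": ["s1", "s2", "s1", "s2"],
            "peptide_id": ["P1", "P1", "P2", "P2"],
            "log2_ratio": [0.0, np.nan, 1.0, 1.0],
            "est_conc": [5.0, np.nan, 100.0, 90.0],
        })
        fits = pd.DataFrame({"peptide_id": ["P1", "P2"], "lloq": [10.0, 10.0]})
        design = pd.DataFrame({"sample_id": ["s1", "s2"], "role": "panel",
                               "tissue_site": "lung",
                               "matrix": "frozen_tissue",
                               "input_amount": 500.0})
        m = im.detection_matrix(quants, fits, design)
        assert math.isnan(m.est_conc.loc["P1", "s2"])      # missing
        assert not m.detected.loc["P1", "s1"]              # below LLOQ
        assert m.detected.loc["P2", "s1"]


class TestInterIndividualCV:
    def test_examples(self):
        log2 = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 1.0],
                             "s3": [0.0, math.log2(3)]},
                            index=["flat", "rising"])
        det = log2.notna()
        m = DetectionMatrix(log2_ratio=log2, est_conc=log2, detected=det,
                            annotations=pd.DataFrame(index=log2.columns),
                            lloq=pd.Series(1.0, index=log2.index))
        series, summary = im.inter_individual_cv(m)
        assert series["flat"] == 0.0
        # linear ratios 1, 2, 3: sd 1, mean 2
        assert series["rising"] == pytest.approx(50.0)
        assert summary["median_cv"] == pytest.approx(25.0)

    def test_lognormal_closed_form(self):
        # pure lognormal spread (no margin folding): CV ~ sqrt(exp(s^2)-1)
        params = SimParams(n_peptides=30, seed=13)
        report, design, truth = simulate_panel_dataset(
            params, n_samples=60, detect_fraction=1.0, enforce_margin=False,
            detect_margin=4.0)
        quants, _ = im.quantify(report, truth.panel)
        fits = pd.DataFrame({"peptide_id": truth.lloq.index,
                             "lloq": truth.lloq.values})
        matrix = im.detection_matrix(quants, fits, design)
        series, summary = im.inter_individual_cv(matrix)
        expected = 100 * math.sqrt(math.exp(0.6 ** 2) - 1)
        assert summary["median_cv"] == pytest.approx(expected, abs=10.0)


class TestClusterMatrix:
    def test_zscore_rows_standardized(self):
        matrix, _ = simulate_matrix(seed=6, detect_fraction=1.0)
        res = im.cluster_matrix(matrix)
        assert np.allclose(res.z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(res.z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_low_detection_peptides_excluded(self, cfg):
        matrix, truth = simulate_matrix(seed=7, detect_fraction=0.4)
        res = im.cluster_matrix(matrix, cfg)
        frac = matrix.detected_fraction()
        assert set(res.z.index) == set(frac.index[frac > 0.5])

    def test_planted_groups_recovered_at_top_split(self):
        matrix, truth = simulate_matrix(seed=8, n_peptides=30, n_samples=24,
                                        groups=(12, 12))
        res = im.cluster_matrix(matrix)
        split = im.top_split(res)
        tab = pd.crosstab(split, truth.groups[split.index])
        # each planted group maps to exactly one dendrogram branch
        assert (tab.max(axis=0) == tab.sum(axis=0)).all()
        assert tab.shape == (2, 2)

    def test_invariant_to_input_order(self, cfg):
        matrix, _ = simulate_matrix(seed=9, detect_fraction=1.0)
        res1 = im.cluster_matrix(matrix, cfg)
        rng = np.random.default_rng(0)
        perm_r = rng.permutation(matrix.log2_ratio.index)
        perm_c = rng.permutation(matrix.log2_ratio.columns)
        shuffled = DetectionMatrix(
            log2_ratio=matrix.log2_ratio.loc[perm_r, perm_c],
            est_conc=matrix.est_conc.loc[perm_r, perm_c],
            detected=matrix.detected.loc[perm_r, perm_c],
            annotations=matrix.annotations.loc[perm_c],
            lloq=matrix.lloq.loc[perm_r])
        res2 = im.cluster_matrix(shuffled, cfg)
        assert res1.row_order == res2.row_order
        assert res1.col_order == res2.col_order

    def test_newick_export_parses(self):
        matrix, _ = simulate_matrix(seed=10, detect_fraction=1.0)
        res = im.cluster_matrix(matrix)
        nwk = im.linkage_to_newick(res.col_linkage, list(res.z.columns))
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")")
        for label in res.z.columns:
            assert label in nwk


class TestCorrelatePaired:
    def make(self, seed=0, n_analytes=20, n_units=30):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame(rng.normal(0, 1, (n_analytes, n_units)),
                         index=[f"A{i}" for i in range(n_analytes)],
                         columns=[f"u{i}" for i in range(n_units)])
        return a

    def test_identity_gives_r_one(self):
        a = self.make()
        corr = im.correlate_paired(a, a.copy())
        assert np.allclose(corr["r"], 1.0)
        assert im.median_correlation(corr) == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = self.make()
        corr = im.correlate_paired(a, -a)
        assert np.allclose(corr["r"], -1.0)

    def test_constant_analyte_omitted(self):
        a = self.make(n_analytes=3)
        b = a.copy()
        a.loc["A0"] = 1.0
        corr = im.correlate_paired(a, b)
        assert "A0" not in set(corr["analyte"])

    def test_noise_tuned_for_r06(self):
        # b = a + noise with var chosen so true r = 0.6
        rng = np.random.default_rng(207)
        a = self.make(seed=31, n_analytes=52, n_units=74)
        lam = math.sqrt(1 / 0.6 ** 2 - 1)
        b = a + pd.DataFrame(rng.normal(0, lam, a.shape), index=a.index,
                             columns=a.columns)
        corr = im.correlate_paired(a, b)
        assert 0.5 <= im.median_correlation(corr) <= 0.7

    def test_grouping_adds_within_group_rows(self):
        a = self.make(n_analytes=5, n_units=20)
        grouping = pd.Series(["x"] * 10 + ["y"] * 10, index=a.columns)
        corr = im.correlate_paired(a, a.copy(), grouping=grouping)
        assert set(corr["group"]) == {"all", "x", "y"}


def matrix_from_sn(sn_rows, lloq=10.0):
    """DetectionMatrix with given per-analyte S/N sample vectors."""
    n = max(len(v) for v in sn_rows.values())
    est = pd.DataFrame(
        {f"s{i}": {a: (v[i] * lloq if i < len(v) else np.nan)
                   for a, v in sn_rows.items()} for i in range(n)})
    det = est.notna()
    return DetectionMatrix(log2_ratio=np.log2(est), est_conc=est,
                           detected=det,
                           annotations=pd.DataFrame(index=est.columns),
                           lloq=pd.Series(lloq, index=est.index))


class TestMinimumInput:
    def test_zero_variance_m_star(self, cfg):
        m = matrix_from_sn({"A": [10.0, 10.0, 10.0]})
        est = im.minimum_input(m, cfg, m0=500.0)
        assert est.m_star["A"] == pytest.approx(50.0, rel=1e-9)

    def test_halving_sn_doubles_m_star(self, cfg):
        rng = np.random.default_rng(1)
        sn = list(np.exp(rng.normal(2.0, 0.3, 8)))
        m1 = im.minimum_input(matrix_from_sn({"A": sn}), cfg)
        m2 = im.minimum_input(matrix_from_sn({"A": [v / 2 for v in sn]}), cfg)
        assert m2.m_star["A"] == pytest.approx(2 * m1.m_star["A"], rel=1e-9)

    def test_against_t_quantile_oracle(self, cfg):
        rng = np.random.default_rng(7)
        sn_rows = {f"A{i}": list(np.exp(rng.normal(rng.uniform(0, 3), 0.5,
                                                   int(rng.integers(3, 12)))))
                   for i in range(52)}
        m = matrix_from_sn(sn_rows)
        est = im.minimum_input(m, cfg, m0=500.0)
        for mass in DEFAULT_INPUT_GRID:
            count = 0
            for sn in sn_rows.values():
                logs = np.log(np.asarray(sn) * mass / 500.0)
                n = len(logs)
                tq = stats.t.ppf(0.95, n - 1)
                lower = logs.mean() - tq * logs.std(ddof=1) / math.sqrt(n)
                count += lower > 0
            got = est.table.loc[est.table["input_mass"] == mass,
                                "predicted_count"].iloc[0]
            assert got == count
        for analyte, sn in sn_rows.items():
            logs = np.log(np.asarray(sn))
            n = len(logs)
            tq = stats.t.ppf(0.95, n - 1)
            m_star = 500.0 * math.exp(tq * logs.std(ddof=1) / math.sqrt(n)
                                      - logs.mean())
            assert est.m_star[analyte] == pytest.approx(m_star, rel=1e-6)

    def test_counts_monotone_and_bounded(self, cfg):
        matrix, _ = simulate_matrix(seed=12, n_peptides=30, n_samples=20)
        est = im.minimum_input(matrix, cfg)
        counts = est.table["predicted_count"]
        assert counts.is_monotonic_increasing  # grid sorted ascending in mass
        assert (est.table["ci_low"] <= counts).all()
        assert (counts <= est.table["ci_high"]).all()

    def test_reference_mass_consistency(self, cfg):
        matrix, _ = simulate_matrix(seed=14, n_peptides=25, n_samples=20)
        est = im.minimum_input(matrix, cfg, m0=500.0)
        at_m0 = est.table.loc[est.table["input_mass"] == 500.0,
                              "predicted_count"].iloc[0]
        # plain confidence criterion at the reference mass
        count = int((est.m_star <= 500.0).sum())
        assert at_m0 == count

    def test_grid_above_reference_rejected(self, cfg):
        matrix, _ = simulate_matrix(seed=15)
        with pytest.raises(ValidationError):
            im.minimum_input(matrix, cfg, input_grid=(100.0, 600.0), m0=500.0)

    def test_linear_scale_variant_zero_variance(self, cfg):
        m = matrix_from_sn({"A": [10.0, 10.0, 10.0]})
        est = im.minimum_input(m, cfg, log_scale=False)
        assert est.m_star["A"] == pytest.approx(50.0, rel=1e-9)
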