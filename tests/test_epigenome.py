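"""Overlap tests, differential methylation, residualized correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svcis.epigenome import (
    differential_methylation_by_type,
    residual_correlation,
    residual_correlation_scan,
    set_overlap_test,
)
from svcis.genomic_model import DataError, OmicsMatrix, logit_clamped


class TestSetOverlap:
    def test_expected_count_is_product_over_universe(self):
        universe = [f"f{i}" for i in range(100)]
        r = set_overlap_test(universe[:20], universe[10:40], universe)
        assert r.expected_overlap == pytest.approx(20 * 30 / 100)
        assert r.n_overlap == 10

    def test_promoter_background_expectation(self):
        """802 significant probes against a 47% promoter background expect
        ~377 promoter probes by chance; 581 observed is 72%."""
        n_universe, promoter_frac = 10_000, 0.47
        universe = [f"cg{i}" for i in range(n_universe)]
        promoters = universe[: int(promoter_frac * n_universe)]
        overlap = 581
        sig = promoters[:overlap] + universe[-(802 - overlap):]
        r = set_overlap_test(sig, promoters, universe)
        assert round(r.expected_overlap) == 377
        assert round(100 * r.n_overlap / r.n_setA) == 72
        assert r.p_value < 1e-40

    def test_identical_sets_match_expectation_with_p_one(self):
        universe = [f"f{i}" for i in range(50)]
        r = set_overlap_test(universe, universe, universe)
        assert r.n_overlap == pytest.approx(r.expected_overlap)
        assert r.p_value == 1.0

    def test_chi2_statistic_matches_hand_oracle(self):
        # universe 100, A 20, B 30, overlap 12
        universe = [f"f{i}" for i in range(100)]
        A = universe[:20]
        B = universe[8:38]
        r = set_overlap_test(A, B, universe, "chi2")
        table = np.array([[12, 8], [18, 62]], float)
        rowsum, colsum = table.sum(1), table.sum(0)
        expected = np.outer(rowsum, colsum) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert r.n_overlap == 12
        assert r.statistic == pytest.approx(chi2_hand)

    def test_fisher_matches_hypergeometric_sum_oracle(self):
        universe = [f"f{i}" for i in range(100)]
        A = universe[:20]
        B = universe[8:38]
        r = set_overlap_test(A, B, universe, "fisher")
        # P(overlap >= 12) summed from the hypergeometric pmf
        p_hand = sum(stats.hypergeom.pmf(k, 100, 20, 30) for k in range(12, 21))
        assert r.p_value == pytest.approx(p_hand, rel=1e-10)

    def test_empty_universe_is_error(self):
        with pytest.raises(DataError, match="empty universe"):
            set_overlap_test([], [], [])

    def test_sets_must_be_subsets_of_universe(self):
        with pytest.raises(DataError, match="subset"):
            set_overlap_test(["x"], [], ["a", "b"])


def _meth_matrix(seed=0, n_probes=30, shift_probes=(), shift=0.0,
                 n_a=15, n_b=25):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_a + n_b)]
    types = ["t1"] * n_a + ["rest"] * n_b
    info = pd.DataFrame({"sample_id": samples, "project": "P",
                         "cancer_type": types, "wgs_pass": "high"}
                        ).set_index("sample_id", drop=False)
    base = rng.uniform(0.2, 0.6, n_probes)
    logit = np.log(base / (1 - base))[:, None] + rng.normal(
        0, 0.4, (n_probes, n_a + n_b))
    for i in shift_probes:
        logit[i, :n_a] += shift
    beta = 1 / (1 + np.exp(-logit))
    M = OmicsMatrix(
        pd.DataFrame(beta, index=[f"p{i}" for i in range(n_probes)],
                     columns=samples),
        "methylation_beta",
    )
    return M, info


class TestDifferentialMethylation:
    def test_identical_groups_give_t0_p1(self):
        vals = np.tile(np.array([0.2, 0.4, 0.6]), (1, 2))
        M = OmicsMatrix(pd.DataFrame(vals, index=["p0"],
                                     columns=[f"S{i}" for i in range(6)]),
                        "methylation_beta")
        info = pd.DataFrame({
            "sample_id": M.sample_ids, "project": "P",
            "cancer_type": ["t1"] * 3 + ["rest"] * 3, "wgs_pass": "high",
        }).set_index("sample_id", drop=False)
        res = differential_methylation_by_type(M, info, "t1")
        assert res.loc[0, "t_stat"] == 0.0
        assert res.loc[0, "p_value"] == 1.0

    def test_welch_formula_oracle_on_toy_vectors(self):
        M, info = _meth_matrix(seed=3, n_probes=1, n_a=3, n_b=3)
        res = differential_methylation_by_type(M, info, "t1")
        y = logit_clamped(M.values.to_numpy())[0]
        a, b = y[:3], y[3:]
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert res.loc[0, "t_stat"] == pytest.approx(t_hand, rel=1e-10)

    def test_swapping_group_labels_negates_t(self):
        M, info = _meth_matrix(seed=4)
        r1 = differential_methylation_by_type(M, info, "t1")
        info2 = info.copy()
        info2["cancer_type"] = np.where(info["cancer_type"] == "t1", "rest", "t1")
        r2 = differential_methylation_by_type(M, info2, "t1")
        assert np.allclose(r1["t_stat"], -r2["t_stat"])

    def test_planted_shift_detected(self):
        """+0.3 beta shift (about +1.3 logit at beta 0.4) in one type is
        recovered at stringent FDR in nearly all seeds."""
        hits = 0
        for seed in range(10):
            M, info = _meth_matrix(seed=seed, n_probes=200,
                                   shift_probes=range(10), shift=1.5,
                                   n_a=40, n_b=200)
            res = differential_methylation_by_type(M, info, "t1")
            found = res.loc[res.index[:10], "q_value"] < 0.001
            positive = res.loc[res.index[:10], "t_stat"] > 0
            hits += int(found.all() and positive.all())
        assert hits >= 9

    def test_singleton_group_is_error(self):
        M, info = _meth_matrix(seed=5)
        info_bad = info.copy()
        info_bad["cancer_type"] = "rest"
        with pytest.raises(DataError):
            differential_methylation_by_type(M, info_bad, "t1")


class TestPerTypeComposition:
    def test_type_specific_hits_intersect_hypermethylated_genes(self):
        """Composition of the two per-type analyses: genes planted with both
        a type-specific SSV-expression effect and type-specific CGI
        hypermethylation are recovered in the intersection of the two hit
        sets (expression FDR < 0.1 within the type, differential
        methylation FDR < 0.001) with recall >= 0.8."""
        from svcis.association import ScanConfig, scan_features
        from svcis.breakpoint_features import BreakpointFeatureMatrix

        rng = np.random.default_rng(0)
        n_a, n_b, n_genes, n_joint = 120, 180, 300, 12
        samples = [f"S{i}" for i in range(n_a + n_b)]
        info = pd.DataFrame({
            "sample_id": samples, "project": "P",
            "cancer_type": ["A"] * n_a + ["rest"] * n_b, "wgs_pass": "high",
        }).set_index("sample_id", drop=False)
        genes = [f"g{i}" for i in range(n_genes)]
        joint = genes[:n_joint]
        # distance predictor: planted genes get close breakpoints in 12
        # type-A carrier samples, background breakpoints land at random
        dist = np.where(rng.random((n_genes, n_a + n_b)) < 0.3,
                        rng.integers(1e4, 1e6, (n_genes, n_a + n_b)),
                        1_000_000)
        log_expr = rng.normal(5, 0.5, (n_genes, n_a + n_b))
        logit_meth = rng.normal(-1.5, 0.5, (n_genes, n_a + n_b))
        for i in range(n_joint):
            carriers = rng.choice(n_a, 12, replace=False)
            dist[i, carriers] = rng.integers(1_000, 30_000, 12)
            log_expr[i, carriers] += 1.2
            logit_meth[i, :n_a] += 1.5  # hypermethylated across type A
        P = BreakpointFeatureMatrix(
            pd.DataFrame(dist, index=genes, columns=samples),
            mode="distance")
        expr = OmicsMatrix(
            pd.DataFrame(np.exp2(log_expr) - 1, index=genes, columns=samples),
            "expression")
        meth = OmicsMatrix(
            pd.DataFrame(1 / (1 + np.exp(-logit_meth)),
                         index=[f"p{i}" for i in range(n_genes)],
                         columns=samples),
            "methylation_beta")
        # within-type expression scan on type-A samples only
        cfg = ScanConfig(predictor="log2_distance",
                         covariates=("cancer_type",),
                         cancer_type_column="project")
        res = scan_features(expr, P, info, cfg, samples=samples[:n_a])
        expr_hits = set(res.loc[(res.q_value < 0.1) & (res.direction == "+"),
                                "feature_id"])
        # type-A differential methylation across the full cohort
        dm = differential_methylation_by_type(meth, info, "A")
        meth_hit_genes = {
            f"g{p[1:]}" for p in dm.loc[(dm.q_value < 0.001) & (dm.t_stat > 0),
                                        "probe_id"]
        }
        both = expr_hits & meth_hit_genes
        recall = len(both & set(joint)) / n_joint
        assert recall >= 0.8
        overlap = set_overlap_test(expr_hits, meth_hit_genes, genes)
        assert overlap.p_value < 0.002


class TestResidualCorrelation:
    def test_identical_vectors_give_r1(self):
        y = np.random.default_rng(0).normal(size=30)
        r, p = residual_correlation(y, y)
        assert r == pytest.approx(1.0)
        assert p < 1e-100

    def test_shared_covariate_removed(self):
        rng = np.random.default_rng(0)
        n = 200
        c = rng.normal(size=n)
        y1 = c + rng.normal(size=n)
        y2 = c + rng.normal(size=n)
        r_raw, _ = residual_correlation(y1, y2)
        r_resid, _ = residual_correlation(y1, y2, c)
        assert abs(r_raw) > 0.3
        assert abs(r_resid) < 0.15

    def test_matches_regress_then_correlate_oracle(self):
        rng = np.random.default_rng(2)
        n = 50
        C = rng.normal(size=(n, 2))
        y1 = C @ [1.0, -0.5] + rng.normal(size=n)
        y2 = C @ [0.3, 0.8] + rng.normal(size=n)
        r, p = residual_correlation(y1, y2, C)
        X = np.hstack([np.ones((n, 1)), C])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        r_hand = stats.pearsonr((np.eye(n) - H) @ y1,
                                (np.eye(n) - H) @ y2).statistic
        assert r == pytest.approx(r_hand, abs=1e-10)

    def test_too_few_pairs_skipped(self):
        assert residual_correlation([1.0, 2, 3], [1.0, 2, 3]) is None

    def test_scan_computes_qvalues_over_tested_pairs(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(40)]
        e = OmicsMatrix(
            pd.DataFrame(rng.uniform(1, 100, (5, 40)),
                         index=[f"g{i}" for i in range(5)], columns=samples),
            "expression")
        m = OmicsMatrix(
            pd.DataFrame(rng.uniform(0.1, 0.9, (5, 40)),
                         index=[f"p{i}" for i in range(5)], columns=samples),
            "methylation_beta")
        pairs = [(f"g{i}", f"p{i}") for i in range(5)] + [("gX", "p0")]
        res = residual_correlation_scan(pairs, e, m)
        assert (res["status"] == "tested").sum() == 5
        assert res.iloc[-1]["status"] == "skipped"
        assert res.loc[res["status"] == "tested", "q_value"].notna().all()
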