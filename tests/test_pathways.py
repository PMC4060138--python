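"""RPKM normalization, principal curves, deregulation scores, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from concordmut import (
    DeregParams,
    PathwayDefinition,
    cluster_samples,
    filter_pathways_by_sd,
    fit_principal_curve,
    geneset_enrichment,
    pathway_deregulation_score,
    rpkm_normalize,
    score_matrix,
)
from tests._oracles import hypergeom_upper_tail_grid


class TestRpkmNormalize:
    def test_direct_formula(self):
        counts = pd.DataFrame({"S1": [1000]}, index=["G1"])
        out = rpkm_normalize(
            counts, pd.Series([1000], index=["G1"]),
            library_sizes=pd.Series([1_000_000], index=["S1"]), offset=0.0,
        )
        assert out.loc["G1", "S1"] == pytest.approx(np.log2(1000), abs=1e-9)

    def test_zero_count_with_offset(self):
        counts = pd.DataFrame({"S1": [0]}, index=["G1"])
        out = rpkm_normalize(
            counts, pd.Series([500], index=["G1"]),
            library_sizes=pd.Series([1_000_000], index=["S1"]), offset=1.0,
        )
        assert out.loc["G1", "S1"] == 0.0

    def test_matches_independent_evaluation(self, rng):
        genes = [f"G{i}" for i in range(40)]
        samples = [f"S{j}" for j in range(6)]
        counts = pd.DataFrame(rng.integers(0, 5000, (40, 6)), index=genes, columns=samples)
        lengths = pd.Series(rng.integers(200, 8000, 40), index=genes)
        libs = pd.Series(rng.integers(10**6, 10**7, 6), index=samples)
        out = rpkm_normalize(counts, lengths, libs, offset=1.0)
        # independent elementwise evaluation of the definition
        for g in genes[:10]:
            for s in samples:
                expected = np.log2(
                    counts.loc[g, s] * 1e9 / (lengths[g] * libs[s]) + 1.0
                )
                assert out.loc[g, s] == pytest.approx(expected, abs=1e-12)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"S1": [5]}, index=["G1"])
        with pytest.raises(ValueError, match="length"):
            rpkm_normalize(counts, pd.Series([0], index=["G1"]))


class TestPrincipalCurve:
    def test_collinear_points_are_fixed_point(self, rng):
        t = np.sort(rng.uniform(-3, 3, 60))
        direction = np.array([2.0, 1.0]) / np.sqrt(5)
        points = t[:, None] * direction[None, :]
        curve = fit_principal_curve(points)
        assert curve.mse < 1e-8
        # projection order equals order along the line
        assert (np.diff(curve.projection) > 0).all()

    def test_quadratic_arc_recovered(self, rng):
        x = np.linspace(-1, 1, 200)
        points = np.column_stack([x, 0.8 * x**2])
        curve = fit_principal_curve(points, DeregParams(curve_span=0.1))
        # distance from every sample to the fitted curve stays small
        from concordmut.pathways import _project_to_polyline

        _, d2 = _project_to_polyline(points - points.mean(axis=0),
                                     curve.points - points.mean(axis=0))
        assert np.sqrt(d2.mean()) < 0.05

    def test_arc_length_nondecreasing(self, rng):
        points = rng.normal(size=(50, 3))
        curve = fit_principal_curve(points)
        assert (np.diff(curve.arc_length) >= 0).all()
        assert curve.projection.shape == (50,)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4 points"):
            fit_principal_curve(np.zeros((3, 2)))

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_principal_curve(np.ones((10, 2)))


def _toy_expression(rng, n_genes=20, n_tumors=10, n_normals=6, shift=0.0, n_shifted=5):
    genes = [f"G{i}" for i in range(n_genes)]
    tumors = [f"T{i}" for i in range(n_tumors)]
    normals = [f"N{i}" for i in range(n_normals)]
    base = rng.normal(5, 1, size=(n_genes, 1))
    X = base + rng.normal(0, 0.3, size=(n_genes, n_tumors + n_normals))
    X[:, :n_shifted] += shift  # first tumors shifted
    return pd.DataFrame(X, index=genes, columns=tumors + normals), tumors, normals


class TestPathwayScore:
    def test_identical_samples_score_zero(self):
        expr = pd.DataFrame(
            np.tile(np.arange(5, dtype=float)[:, None], (1, 8)),
            index=[f"G{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(8)],
        )
        pw = PathwayDefinition("P1", "p", [f"G{i}" for i in range(5)])
        scores = pathway_deregulation_score(expr, pw, ["S6", "S7"])
        assert (scores == 0).all()

    def test_normal_median_exactly_zero(self, rng):
        expr, tumors, normals = _toy_expression(rng, shift=1.5)
        pw = PathwayDefinition("P1", "p", list(expr.index))
        scores = pathway_deregulation_score(expr, pw, normals)
        assert np.median(scores[normals]) == 0.0

    def test_scores_in_unit_interval_with_max_one(self, rng):
        expr, tumors, normals = _toy_expression(rng, shift=2.0)
        pw = PathwayDefinition("P1", "p", list(expr.index))
        scores = pathway_deregulation_score(expr, pw, normals)
        assert scores.min() >= 0.0 and scores.max() == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        expr, tumors, normals = _toy_expression(rng, shift=1.0)
        pw = PathwayDefinition("P1", "p", list(expr.index))
        a = pathway_deregulation_score(expr, pw, normals)
        b = pathway_deregulation_score(expr * 3.7, pw, normals)
        assert np.allclose(a, b, atol=1e-8)

    def test_too_few_genes_skipped(self, rng, caplog):
        expr, tumors, normals = _toy_expression(rng)
        pw = PathwayDefinition("P1", "p", ["G0", "G1", "MISSING"])
        with caplog.at_level("WARNING"):
            out = pathway_deregulation_score(expr, pw, normals)
        assert out is None
        assert "skipped" in caplog.text

    def test_planted_deregulation_separates_groups(self, default_cohort, default_analysis):
        """Planted deregulated pathways score higher in the high-risk tumors."""
        labels = default_cohort.truth.subgroup_labels
        hi = labels[labels == "highrisk"].index
        lo = labels[labels == "lowrisk"].index
        for pw_id in default_cohort.truth.deregulated_pathways:
            s = default_analysis.scores_all.loc[pw_id]
            _, p = mannwhitneyu(s[hi], s[lo], alternative="greater")
            assert p < 0.01, f"{pw_id} fails to separate (p={p:.3g})"


class TestSdFilter:
    def test_constant_pathway_removed(self):
        scores = pd.DataFrame(
            {"T1": [0.5, 0.1], "T2": [0.5, 0.9], "T3": [0.5, 0.2]},
            index=["flat", "var"],
        )
        out = filter_pathways_by_sd(scores, ["T1", "T2", "T3"], 0.2)
        assert list(out.index) == ["var"]

    def test_threshold_is_strict(self):
        # sd across tumors exactly 0.2
        vals = np.array([0.3, 0.5, 0.7])
        assert np.isclose(vals.std(ddof=1), 0.2)
        scores = pd.DataFrame([vals], index=["edge"], columns=["T1", "T2", "T3"])
        assert len(filter_pathways_by_sd(scores, ["T1", "T2", "T3"], 0.2)) == 0

    def test_matches_independent_sd(self, rng):
        scores = pd.DataFrame(
            rng.uniform(0, 1, (30, 10)),
            index=[f"P{i}" for i in range(30)],
            columns=[f"T{j}" for j in range(10)],
        )
        out = filter_pathways_by_sd(scores, list(scores.columns), 0.25)
        expected = {
            p for p in scores.index
            if np.std(scores.loc[p].to_numpy(), ddof=1) > 0.25
        }
        assert set(out.index) == expected


class TestClustering:
    def test_perfectly_correlated_pair_share_cluster(self, rng):
        base = rng.normal(size=20)
        scores = pd.DataFrame(
            {"A": base, "B": 2 * base + 1, "C": -base, "D": -base + rng.normal(0, 0.1, 20)}
        )
        labels = cluster_samples(scores, 2)
        assert labels["A"] == labels["B"]
        assert labels["A"] != labels["C"]

    def test_single_cluster(self, rng):
        scores = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("ABCDE"))
        assert cluster_samples(scores, 1).nunique() == 1

    def test_two_block_structure_fully_recovered(self, rng):
        """Anti-correlated score blocks are recovered with ARI = 1."""
        n_pw = 40
        pattern = rng.normal(size=n_pw)
        cols, truth = {}, []
        for i in range(14):
            block = i < 7
            cols[f"S{i}"] = (pattern if block else -pattern) + rng.normal(0, 0.2, n_pw)
            truth.append(int(block))
        labels = cluster_samples(pd.DataFrame(cols), 2)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_permutation_invariance(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(25, 12)), columns=[f"S{i}" for i in range(12)]
        )
        a = cluster_samples(scores, 3)
        perm = list(rng.permutation(scores.columns))
        b = cluster_samples(scores[perm], 3)
        # same partition up to label renaming
        assert adjusted_rand_score(a[scores.columns], b[scores.columns]) == 1.0

    def test_zero_variance_sample_named(self, rng):
        scores = pd.DataFrame({"A": rng.normal(size=10), "B": np.zeros(10), "C": rng.normal(size=10)})
        with pytest.raises(ValueError, match="B"):
            cluster_samples(scores, 2)


class TestGenesetEnrichment:
    def test_disjoint_query_p_one(self):
        gs = PathwayDefinition("P", "p", [f"G{i}" for i in range(10)])
        assert geneset_enrichment([f"H{i}" for i in range(10)], gs, 100) == 1.0

    def test_complete_overlap_extreme(self):
        genes = [f"G{i}" for i in range(10)]
        gs = PathwayDefinition("P", "p", genes)
        p = geneset_enrichment(genes, gs, 100)
        assert p == pytest.approx(5.776904234533874e-14, rel=1e-9)

    def test_partial_overlap_pinned(self):
        gs = PathwayDefinition("P", "p", [f"G{i}" for i in range(10)])
        query = [f"G{i}" for i in range(5)] + [f"H{i}" for i in range(5)]
        assert geneset_enrichment(query, gs, 100) == pytest.approx(6.7162774826505e-04, rel=1e-9)

    def test_matches_bruteforce_tail(self):
        tail = hypergeom_upper_tail_grid(90, 10)  # universe 100, query 10
        gs = PathwayDefinition("P", "p", [f"G{i}" for i in range(7)])
        query = [f"G{i}" for i in range(3)] + [f"H{i}" for i in range(7)]
        assert geneset_enrichment(query, gs, 100) == pytest.approx(tail[7, 3], abs=1e-12)

    def test_empty_query_rejected(self):
        gs = PathwayDefinition("P", "p", ["G1"])
        with pytest.raises(ValueError, match="empty"):
            geneset_enrichment([], gs, 10)


def test_score_matrix_skips_unresolvable(default_cohort, rng):
    expr = pd.DataFrame(
        rng.normal(5, 1, (6, 8)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )
    pws = [
        PathwayDefinition("ok", "p", [f"G{i}" for i in range(6)]),
        PathwayDefinition("bad", "p", ["X1", "X2", "X3"]),
    ]
    out = score_matrix(expr, pws, ["S6", "S7"])
    assert list(out.index) == ["ok"]
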