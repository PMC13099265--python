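"""Expression normalization, module scores, O2 signature and analyses."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from cellodeg.programs import (
    GeneSetPair,
    ModuleScoreParams,
    ModuleScorer,
    UMIMatrix,
    cluster_filters,
    correlate,
    covariate_check,
    lognorm,
    lpmo_contrast,
    map_symbols_to_features,
    marker_genes,
    module_score,
    o2_score,
    rank_score,
)
from cellodeg.simulate import CellSimSpec, default_cell_sim_spec, gen_umi_matrix


def _tiny_matrix(counts):
    counts = np.asarray(counts)
    return UMIMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        feature_ids=[f"G|g{j}" for j in range(counts.shape[1])],
    )


class TestLognorm:
    def test_zero_count_entry_stays_zero(self):
        m = _tiny_matrix([[0, 5], [3, 2]])
        X = lognorm(m).toarray()
        assert X[0, 0] == 0.0

    def test_single_gene_cell_closed_form(self):
        m = _tiny_matrix([[7, 0], [1, 1]])
        X = lognorm(m, scale=10_000).toarray()
        assert X[0, 0] == pytest.approx(np.log(1 + 10_000))

    def test_per_cell_scale_invariance(self):
        m1 = _tiny_matrix([[2, 4, 6], [1, 2, 3]])
        m2 = _tiny_matrix([[4, 8, 12], [1, 2, 3]])
        assert np.allclose(lognorm(m1).toarray(), lognorm(m2).toarray())

    def test_zero_count_cell_rejected(self):
        m = _tiny_matrix([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero-count"):
            lognorm(m)


class TestModuleScore:
    def test_null_set_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 1, size=(100, 120))
        fids = [f"G|g{j}" for j in range(120)]
        scores = module_score(X, fids, [f"g{j}" for j in range(0, 120, 10)],
                              ModuleScoreParams(nbin=6, ctrl=10))
        assert abs(scores.mean()) < 0.1

    def test_constant_shift_cancels_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 1, size=(50, 80))
        fids = [f"G|g{j}" for j in range(80)]
        gene_set = ["g3", "g17", "g40"]
        params = ModuleScoreParams(nbin=5, ctrl=8)
        s1 = module_score(X, fids, gene_set, params)
        s2 = module_score(X + 2.5, fids, gene_set, params)
        assert np.allclose(s1, s2 - 0.0, atol=1e-12) or np.allclose(s1, s2)

    def test_seeded_scores_bit_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0, 1, size=(40, 60))
        fids = [f"G|g{j}" for j in range(60)]
        s1 = module_score(X, fids, ["g1", "g2", "g3"])
        s2 = module_score(X, fids, ["g1", "g2", "g3"])
        assert (s1 == s2).all()

    def test_planted_program_scores_higher(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        scorer = ModuleScorer(nbin=24, ctrl=100, random_state=1)
        scorer.fit(norm, matrix.feature_ids)
        aero_symbols = [f.split("|")[1] for f in spec.program_genes["aerobic"]]
        s = scorer.score_symbols(aero_symbols)
        y = (truth["program"] == "aerobic").astype(int)
        assert roc_auc_score(y, s) >= 0.9

    def test_unmatched_set_aborts_with_gene_list(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, size=(10, 20))
        fids = [f"G|g{j}" for j in range(20)]
        with pytest.raises(ValueError, match="nope1"):
            module_score(X, fids, ["g1", "nope1", "nope2"], min_matched=3)

    def test_symbol_mapping(self):
        fids = ["A|cyoA", "B|cyoA", "A|sdhB"]
        cols, unmapped = map_symbols_to_features(fids, ["cyoA", "missing"])
        assert cols == [0, 1]
        assert unmapped == ["missing"]
        cols, _ = map_symbols_to_features(
            fids, ["cyoA"], symbol_map={"cyoA": ["A|cyoA"]})
        assert cols == [0]


class TestO2Score:
    def test_set_swap_antisymmetry_exact(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        pair = GeneSetPair()
        st1 = o2_score(norm, matrix.feature_ids, pair)
        st2 = o2_score(norm, matrix.feature_ids,
                       GeneSetPair(o2_plus=pair.o2_minus,
                                   o2_minus=pair.o2_plus))
        assert np.array_equal(st1["o2_score"].to_numpy(),
                              -st2["o2_score"].to_numpy())

    def test_z_column_standardized(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        st = o2_score(norm, matrix.feature_ids)
        assert st["o2_score_z"].mean() == pytest.approx(0.0, abs=1e-6)
        assert st["o2_score_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_planted_programs_separate(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        st = o2_score(norm, matrix.feature_ids)
        y = (truth["program"] == "aerobic").astype(int)
        assert roc_auc_score(y, st["o2_score"]) >= 0.9

    def test_insufficient_matches_abort(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        bad = GeneSetPair(o2_plus=("nonexistentA", "nonexistentB",
                                   "nonexistentC"))
        with pytest.raises(ValueError, match="nonexistent"):
            o2_score(norm, matrix.feature_ids, bad)


class TestRankScore:
    def test_top_ranked_set_scores_one(self):
        X = np.array([[9.0, 8.0, 1.0, 0.5, 0.2],
                      [7.0, 6.0, 0.1, 0.0, 0.0]])
        fids = ["G|a", "G|b", "G|c", "G|d", "G|e"]
        s = rank_score(X, fids, ["a", "b"], r_max=4)
        assert np.allclose(s, 1.0)

    def test_floor_closed_form(self):
        # both set genes at/beyond r_max
        X = np.array([[5.0, 4.0, 3.0, 2.0, 1.0, 0.5]])
        fids = [f"G|g{j}" for j in range(6)]
        n_set, r_max = 2, 4
        s = rank_score(X, fids, ["g4", "g5"], r_max=r_max)
        expected = 1 - (n_set * r_max - n_set * (n_set + 1) / 2) / (n_set * r_max)
        assert s[0] == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.lognormal(0, 1, size=(20, 50))
        fids = [f"G|g{j}" for j in range(50)]
        gene_set = ["g4", "g9", "g33"]
        s1 = rank_score(X, fids, gene_set, r_max=40)
        s2 = rank_score(np.exp(X) + 7.0, fids, gene_set, r_max=40)
        assert np.allclose(s1, s2)

    def test_set_larger_than_rmax_rejected(self):
        X = np.ones((3, 5))
        fids = [f"G|g{j}" for j in range(5)]
        with pytest.raises(ValueError, match="r_max"):
            rank_score(X, fids, ["g0", "g1", "g2"], r_max=2)

    def test_concordant_with_module_score_on_planted_data(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        st = o2_score(norm, matrix.feature_ids)
        pair = GeneSetPair()
        contrast = (rank_score(norm, matrix.feature_ids, pair.o2_plus)
                    - rank_score(norm, matrix.feature_ids, pair.o2_minus))
        rho = spearmanr(contrast, st["o2_score"]).statistic
        assert rho >= 0.8


class TestClusterFilters:
    def test_boundaries(self):
        labels = (["a"] * 100 + ["b"] * 99 + ["c"] * 120)
        samples = (["s1", "s2"] * 50 + ["s1", "s2"] * 49 + ["s1"]
                   + ["s1"] * 120)
        retained, report = cluster_filters(labels, samples)
        rep = report.set_index("cluster")
        assert "a" in retained                      # 100 cells, 2 samples
        assert "b" not in retained                  # 99 cells
        assert "c" not in retained                  # 1 sample only
        assert rep.loc["b", "n_cells"] == 99
        assert rep.loc["c", "n_samples"] == 1


class TestMarkerGenes:
    def test_planted_markers_recovered(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        mk = marker_genes(norm, matrix.feature_ids,
                          truth["program"].to_numpy())
        found = set(mk[(mk.cluster == "aerobic") & mk.is_marker].feature)
        planted = set(spec.program_genes["aerobic"])
        recall = len(found & planted) / len(planted)
        assert recall >= 0.9

    def test_identical_clusters_produce_no_markers(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(0, 1, size=(60, 40))
        fids = [f"G|g{j}" for j in range(40)]
        labels = np.array(["a", "b"] * 30)
        mk = marker_genes(X, fids, labels)
        assert mk.is_marker.sum() == 0

    def test_absent_gene_yields_finite_log2fc(self):
        X = np.ones((10, 3))
        X[:5, 0] = 0.0  # gene absent in cluster a
        fids = ["G|g0", "G|g1", "G|g2"]
        labels = np.array(["a"] * 5 + ["b"] * 5)
        mk = marker_genes(X, fids, labels)
        assert np.isfinite(mk["log2fc"]).all()

    def test_tiny_cluster_skipped_with_warning(self):
        X = np.random.default_rng(0).lognormal(size=(8, 4))
        labels = np.array(["a"] * 6 + ["b"] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            mk = marker_genes(X, [f"G|g{j}" for j in range(4)], labels)
        assert set(mk["cluster"]) == {"a"}


class TestLpmoContrast:
    def test_identical_groups_p_near_one(self):
        # same score values in both groups: rank sums coincide exactly
        rng = np.random.default_rng(8)
        v = rng.normal(size=20)
        score = np.concatenate([v, v])
        lpmo = np.concatenate([np.zeros(20), np.ones(20)])
        res = lpmo_contrast(score, lpmo)
        assert res.p_value > 0.9

    def test_positive_association_detected(self, small_cells_norm):
        spec, matrix, norm, truth = small_cells_norm
        st = o2_score(norm, matrix.feature_ids)
        lp_cols = [i for i, f in enumerate(matrix.feature_ids)
                   if f in spec.program_genes["lpmo"]]
        lp = np.asarray(matrix.counts[:, lp_cols].sum(axis=1)).ravel()
        res = lpmo_contrast(st["o2_score_z"].to_numpy(), lp)
        assert res.direction > 0
        assert res.p_value < 0.05

    def test_small_groups_use_exact_distribution(self):
        score = np.array([1.0, 2, 3, 10, 11, 12, 13, 14])
        lpmo = np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        res = lpmo_contrast(score, lpmo)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 56)  # C(8,3) orderings

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            lpmo_contrast([1.0, 2.0], [0.0, 0.0])


class TestCorrelate:
    def test_self_correlation_and_distances(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.1, 200),
                           "anti": -a})
        res = correlate(df)
        assert res["rho"].loc["a", "a"] == pytest.approx(1.0)
        assert res["distance"].loc["a", "a"] == 0.0
        assert res["rho"].loc["a", "anti"] == pytest.approx(-1.0)
        assert res["distance"].loc["a", "anti"] == pytest.approx(2.0)
        assert res["significant"].loc["a", "b"]

    def test_constant_column_excluded_from_clustering(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"a": rng.normal(size=50),
                           "b": rng.normal(size=50),
                           "flat": np.ones(50)})
        res = correlate(df)
        assert np.isnan(res["rho"].loc["a", "flat"])
        assert "flat" not in res["clustered_columns"]
        assert set(res["clustered_columns"]) == {"a", "b"}

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        res = correlate(df)
        # Spearman of a bivariate Gaussian: (6/pi) * arcsin(rho/2)
        expected = 6 / np.pi * np.arcsin(0.6 / 2)
        assert res["rho"].loc["x", "y"] == pytest.approx(expected, abs=0.1)


class TestCovariateCheck:
    def test_independent_covariate_preserves_ordering(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=300)
        nf = rng.integers(20, 100, 300)
        nc = rng.integers(100, 1000, 300)
        clusters = rng.integers(0, 5, 300)
        out = covariate_check(z, nf, nc, clusters)
        assert abs(out["rho_nfeature"]) < 0.15
        assert out["cluster_ordering_rho"] > 0.9

    def test_score_equal_to_covariate_residual_vanishes(self):
        rng = np.random.default_rng(13)
        nf = rng.integers(20, 100, 200).astype(float)
        nc = np.full(200, 500.0)
        z = np.log(nf)
        out = covariate_check(z, nf, nc)
        assert np.allclose(out["residual"], 0.0, atol=1e-8)

    def test_depth_confounding_removed_by_adjustment(self):
        rng = np.random.default_rng(14)
        nc = rng.lognormal(5, 0.5, size=500)
        nf = rng.lognormal(3, 0.3, size=500)
        z = 2.0 * np.log(nc) + rng.normal(0, 0.1, 500)
        out = covariate_check(z, nf, nc)
        rho_after = spearmanr(out["residual"], nc).statistic
        assert abs(out["rho_ncount"]) > 0.9
        assert abs(rho_after) < 0.05


class TestSimSpecValidation:
    def test_overlapping_program_sets_rejected(self):
        genes = tuple(f"G|g{j}" for j in range(6))
        spec = CellSimSpec(
            gene_universe=genes,
            program_genes={"aerobic": genes[:3], "anaerobic": genes[2:5]},
        )
        with pytest.raises(ValueError, match="disjoint"):
            gen_umi_matrix(spec)
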