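import numpy as np
import pandas as pd
import pytest

from imputebench import (ConfigError, GeneratorConfig, MaskedMatrix, MethodConfig,
                         canonical_method_configs, delete_entries,
                         generate_expression_matrix, impute, impute_bpca, impute_knn,
                         impute_lls, impute_lsa, impute_nipals, impute_row_average,
                         impute_svd)
from conftest import mask_cells


@pytest.fixture()
def small_masked():
    cfg = GeneratorConfig(n_probe_sets=120, seed=21)
    cd = generate_expression_matrix(cfg)
    return delete_entries(cd, 0.05, seed=2)


class TestRowAverage:
    def test_row_mean_fill(self):
        vals = np.array([[2.0, 1.0, 4.0, 1.0, 6.0], [1.0, 2.0, 3.0, 4.0, 5.0]])
        m = mask_cells(vals, [(0, 1), (0, 3)])
        r = impute_row_average(m)
        assert r.values[0, 1] == pytest.approx(4.0)
        assert r.values[0, 3] == pytest.approx(4.0)

    def test_single_observed_value_propagates(self):
        vals = np.array([[7.0, 1.0, 1.0], [5.0, 6.0, 7.0]])
        m = mask_cells(vals, [(0, 1), (0, 2)])
        r = impute_row_average(m)
        np.testing.assert_allclose(r.values[0], [7.0, 7.0, 7.0])

    def test_fully_missing_row_gets_global_mean(self):
        vals = np.array([[5.0, 5.0], [10.0, 10.0], [1.0, 1.0]])
        m = mask_cells(vals, [(2, 0), (2, 1)])
        r = impute_row_average(m)
        np.testing.assert_allclose(r.values[2], [7.5, 7.5])

    def test_matches_independent_oracle(self, small_masked):
        r = impute_row_average(small_masked)
        df = pd.DataFrame(small_masked.values)
        oracle = df.apply(lambda row: row.fillna(row.mean()), axis=1).to_numpy()
        np.testing.assert_allclose(r.values, oracle, rtol=1e-12)


class TestKNN:
    def test_zero_distance_neighbour_wins(self):
        vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [10.0, 10.0, 10.0]])
        m = mask_cells(vals, [(1, 2)])
        r = impute_knn(m, k=1)
        assert r.values[1, 2] == pytest.approx(3.0)

    def test_k2_unweighted_mean_of_neighbours(self):
        # two equidistant nearest neighbours with values 4 and 6 at the column
        vals = np.array([
            [1.0, 2.0, 5.0],
            [1.0 + 0.1, 2.0 + 0.1, 4.0],
            [1.0 - 0.1, 2.0 - 0.1, 6.0],
            [50.0, 60.0, 70.0],
        ])
        m = mask_cells(vals, [(0, 2)])
        r = impute_knn(m, k=2)
        assert r.values[0, 2] == pytest.approx(5.0)

    def test_pearson_distance_selects_correlated_row(self):
        vals = np.array([
            [1.0, 2.0, 3.0, 100.0],
            [10.0, 20.0, 30.0, 40.0],     # perfectly correlated with target
            [3.0, 2.0, 1.0, 999.0],
        ])
        m = mask_cells(vals, [(0, 3)])
        r = impute_knn(m, k=1, distance="pearson")
        assert r.values[0, 3] == pytest.approx(40.0)

    def test_single_row_falls_back_to_row_average(self):
        vals = np.array([[2.0, 4.0, 6.0]])
        m = mask_cells(vals, [(0, 2)])
        r = impute_knn(m, k=3)
        assert r.values[0, 2] == pytest.approx(3.0)


class TestSVD:
    def test_rank1_recovery(self, rank1_matrix):
        m = delete_entries(rank1_matrix, 0.05, seed=1)
        r = impute_svd(m, n_components=1, threshold=1e-10, max_iter=2000)
        rel = np.abs(r.values[m.mask] - m.truth[m.mask]) / m.truth[m.mask]
        assert rel.max() < 1e-6

    def test_no_missing_returns_input_zero_iterations(self, rank1_matrix):
        m = MaskedMatrix(rank1_matrix.to_numpy(), np.zeros((50, 5), dtype=bool))
        r = impute_svd(m, n_components=2)
        assert r.iterations_used == 0
        np.testing.assert_array_equal(r.values, rank1_matrix.to_numpy())

    def test_component_bounds_enforced(self, rank1_matrix):
        m = delete_entries(rank1_matrix, 0.05, seed=1)
        with pytest.raises(ConfigError):
            impute_svd(m, n_components=5)


class TestLLS:
    def test_k_must_stay_below_column_count(self, small_masked):
        with pytest.raises(ConfigError, match="k < number of columns"):
            impute_lls(small_masked, k=5)

    def test_gene_mode_single_neighbour_example(self):
        vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 9.9], [10.0, 10.0, 10.0]])
        m = mask_cells(vals, [(1, 2)])
        r = impute_lls(m, k=1, mode="genes")
        # neighbour g1=(1,2,3); solve (1,2)x = (1,2) -> x=1 -> imputed 3
        assert r.values[1, 2] == pytest.approx(3.0, rel=1e-9)

    def test_gene_mode_anticorrelated_neighbour_recovers_exactly(self):
        """A neighbour with r = -1 is still selected under |r| ranking and a
        second (constant-offset carrier) row makes the recovery exact."""
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        anti = 10.0 - base            # r = -1 with the target
        anti2 = 12.0 - 2.0 * base     # also r = -1; spans the offset
        vals = np.vstack([base, anti, anti2])
        m = mask_cells(vals, [(0, 4)])
        r = impute_lls(m, k=2, mode="genes")
        assert r.values[0, 4] == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("mode", ["genes", "replicates"])
    def test_rank1_recovery_both_modes(self, rank1_matrix, mode):
        m = delete_entries(rank1_matrix, 0.05, seed=1)
        r = impute_lls(m, k=1, mode=mode)
        rel = np.abs(r.values[m.mask] - m.truth[m.mask]) / m.truth[m.mask]
        assert rel.max() < 1e-6

    def test_replicates_mode_linear_combination_recovery(self):
        """A column that is an exact linear combination of two others is
        recovered exactly by k=2 column regression."""
        rng = np.random.default_rng(5)
        a = rng.uniform(50, 500, 40)
        b = rng.uniform(50, 500, 40)
        c = 0.6 * a + 0.4 * b
        vals = np.column_stack([a, b, c])
        m = mask_cells(vals, [(3, 2), (17, 2)])
        r = impute_lls(m, k=2, mode="replicates")
        assert r.values[3, 2] == pytest.approx(c[3], rel=1e-9)
        assert r.values[17, 2] == pytest.approx(c[17], rel=1e-9)


class TestLSA:
    def test_duplicated_rows_give_exact_gene_estimate(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(100, 200, (30, 5))
        vals = np.vstack([base, base[:3]])  # duplicates of the first 3 rows
        m = mask_cells(vals, [(30, 4)])
        r = impute_lsa(m, MethodConfig(method="LSA", seed=0))
        assert r.values[30, 4] == pytest.approx(base[0, 4], rel=1e-6)

    def test_blend_weight_closed_form(self):
        # probe data a=(2,0), b=(0,2), y=(1,1): p* = sum((y-b)(a-b))/sum((a-b)^2)
        a = np.array([2.0, 0.0])
        b = np.array([0.0, 2.0])
        y = np.array([1.0, 1.0])
        d = a - b
        p = ((y - b) * d).sum() / (d**2).sum()
        assert p == pytest.approx(0.5)

    def test_seed_determinism(self, small_masked):
        r1 = impute_lsa(small_masked, MethodConfig(method="LSA", seed=7))
        r2 = impute_lsa(small_masked, MethodConfig(method="LSA", seed=7))
        np.testing.assert_array_equal(r1.values, r2.values)


class TestBPCA:
    def test_rank1_plus_noise_recovery(self):
        rng = np.random.default_rng(4)
        u = np.exp(rng.normal(5, 1, 60))
        v = np.exp(rng.normal(0, 0.2, 5))
        X = np.outer(u, v) * np.exp(rng.normal(0, 1e-4, (60, 5)))
        cd = pd.DataFrame(X)
        m = delete_entries(cd, 0.05, seed=3)
        r = impute_bpca(m, seed=11)
        rel = np.abs(r.values[m.mask] - m.truth[m.mask]) / m.truth[m.mask]
        assert rel.max() < 1e-3

    def test_no_missing_unchanged(self, rank1_matrix):
        m = MaskedMatrix(rank1_matrix.to_numpy(), np.zeros((50, 5), dtype=bool))
        r = impute_bpca(m, seed=0)
        np.testing.assert_array_equal(r.values, rank1_matrix.to_numpy())

    def test_seed_determinism(self, small_masked):
        r1 = impute_bpca(small_masked, seed=5)
        r2 = impute_bpca(small_masked, seed=5)
        np.testing.assert_array_equal(r1.values, r2.values)


class TestNIPALS:
    def test_rank1_recovery(self, rank1_matrix):
        m = delete_entries(rank1_matrix, 0.05, seed=1)
        r = impute_nipals(m, n_components=1, tol=1e-9, max_iter=2000)
        rel = np.abs(r.values[m.mask] - m.truth[m.mask]) / m.truth[m.mask]
        assert rel.max() < 1e-6

    def test_full_rank_reconstruction_without_missing(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(10, 100, (20, 4))
        m = MaskedMatrix(X, np.zeros_like(X, dtype=bool))
        r = impute_nipals(m, n_components=4, tol=1e-12, max_iter=5000)
        np.testing.assert_allclose(r.values, X, rtol=1e-8)

    def test_constant_columns_degenerate_to_mean(self):
        X = np.full((10, 4), 25.0)
        m = mask_cells(X, [(2, 3)])
        r = impute_nipals(m, n_components=2)
        assert r.values[2, 3] == pytest.approx(25.0)


class TestDispatchAndInvariants:
    def test_dispatch_row_equals_direct_call(self, small_masked):
        via_dispatch = impute(small_masked, MethodConfig(method="ROW"))
        direct = impute_row_average(small_masked)
        np.testing.assert_array_equal(via_dispatch.values, direct.values)

    def test_canonical_labels_are_the_table_rows(self):
        labels = [c.name for c in canonical_method_configs()]
        assert labels == ["BPCA", "KNN1", "KNN5", "LLS1", "LLS3", "LLS4",
                          "LSA", "NIPALS", "ROW", "SVD"]

    def test_lls_k_equal_columns_rejected_via_dispatch(self, small_masked):
        with pytest.raises(ConfigError, match="k < number of columns"):
            impute(small_masked, MethodConfig(method="LLS", k=5))

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            MethodConfig(method="MAGIC")

    @pytest.mark.parametrize("cfg", canonical_method_configs(seed=3),
                             ids=lambda c: c.name)
    def test_observed_preserved_and_output_complete(self, small_masked, cfg):
        r = impute(small_masked, cfg)
        assert not np.isnan(r.values).any()
        obs = ~small_masked.mask
        np.testing.assert_array_equal(r.values[obs], small_masked.values[obs])
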