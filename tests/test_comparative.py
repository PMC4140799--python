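import numpy as np
import pytest

from antpolyandry.comparative import (
    PhyloTree,
    SpeciesRecord,
    correspondence_analysis,
    inverse_transform,
    paternity_rank_table,
    pgls,
    slope_null_interval,
    transform_for_regression,
)
from antpolyandry.simulate import DEFAULT_NINE_SPECIES_NEWICK, \
    simulate_species_set

NINE_TIP_TREE = PhyloTree.from_newick(DEFAULT_NINE_SPECIES_NEWICK)


class TestPhyloTree:
    def test_covariance_diagonal_is_tip_depth(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        V = tree.covariance_matrix(order=["a", "b", "c"])
        assert np.allclose(np.diag(V), [2, 2, 2])
        assert V[0, 1] == pytest.approx(1.0)  # a,b share the basal branch
        assert V[0, 2] == pytest.approx(0.0)

    def test_star_tree_covariance_diagonal(self):
        tree = PhyloTree.star(["a", "b", "c", "d"])
        V = tree.covariance_matrix()
        assert np.allclose(V, np.eye(4))

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("((a:1,a:1):1,b:2);")


class TestPgls:
    def test_reduces_to_ols_on_star_tree(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 0.5 - 0.3 * x + rng.normal(scale=0.2, size=12)
        tree = PhyloTree.star([f"s{i}" for i in range(12)])
        fit = pgls(y, x, tree)
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope_ols, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept_ols, abs=1e-8)

    def test_perfect_fit_edge_case(self):
        x = np.arange(5.0)
        tree = PhyloTree.star([f"s{i}" for i in range(5)])
        fit = pgls(2 * x, x, tree)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(0.0)

    def test_lrt_nonnegative_and_full_model_dominates(self):
        rng = np.random.default_rng(2)
        for rep in range(10):
            df = simulate_species_set(NINE_TIP_TREE, slope=0.0, intercept=0.0,
                                      noise_var=1.0, seed=rep)
            fit = pgls(df["y"].to_numpy(), df["x"].to_numpy(), NINE_TIP_TREE,
                       species=list(df["species"]))
            assert fit.lrt_chi2 >= 0.0
            assert fit.loglik_full >= fit.loglik_null - 1e-9
            assert 0.0 <= fit.r_squared <= 1.0

    def test_brownian_slope_recovery(self):
        slopes = []
        for rep in range(200):
            df = simulate_species_set(NINE_TIP_TREE, slope=-0.005,
                                      intercept=0.5, noise_var=0.001,
                                      seed=rep, x_var=25.0)
            fit = pgls(df["y"].to_numpy(), df["x"].to_numpy(), NINE_TIP_TREE,
                       species=list(df["species"]))
            slopes.append(fit.slope)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - (-0.005)) < 2 * se

    def test_singular_covariance_rejected(self):
        tree = PhyloTree.from_newick("((a:0,b:0):1,c:1);")
        with pytest.raises(ValueError, match="singular"):
            pgls([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], tree,
                 species=["a", "b", "c"])


class TestTransforms:
    def test_zero_skew_maps_to_zero(self):
        assert transform_for_regression([0.0], "skew")[0] == 0.0

    def test_colony_size_log10(self):
        assert transform_for_regression([1e6], "colony_size")[0] == \
            pytest.approx(6.0)

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, size=20)
        assert np.allclose(
            inverse_transform(transform_for_regression(s, "skew"), "skew"), s)
        cs = rng.uniform(10, 1e6, size=20)
        assert np.allclose(
            inverse_transform(transform_for_regression(cs, "colony_size"),
                              "colony_size"), cs)

    def test_negative_skew_rejected(self):
        with pytest.raises(ValueError):
            transform_for_regression([-0.1], "skew")


class TestSlopeNullInterval:
    def _records(self):
        return [SpeciesRecord(species_id=f"sp{i}", k_obs=5 + 2 * i, S=0.1)
                for i in range(9)]

    def test_degenerate_all_zero_draws(self):
        records = self._records()
        nulls = {r.species_id: np.zeros(200) for r in records}
        low, high, slopes = slope_null_interval(records, NINE_TIP_TREE, nulls,
                                                n_runs=20, seed=1)
        assert low == high == 0.0
        assert np.allclose(slopes, 0.0)

    def test_fixed_seed_reproducible(self):
        records = self._records()
        rng = np.random.default_rng(4)
        nulls = {r.species_id: rng.uniform(0, 0.3, size=500) for r in records}
        a = slope_null_interval(records, NINE_TIP_TREE, nulls, seed=9)
        b = slope_null_interval(records, NINE_TIP_TREE, nulls, seed=9)
        assert a[:2] == b[:2]

    def test_warns_when_draws_fewer_than_runs(self):
        records = self._records()
        nulls = {r.species_id: np.array([0.0, 0.1]) for r in records}
        with pytest.warns(UserWarning, match="with replacement"):
            slope_null_interval(records, NINE_TIP_TREE, nulls, n_runs=10,
                                seed=2)


class TestCorrespondenceAnalysis:
    def test_homogeneous_table_zero_chi2(self):
        table = np.outer([4, 3, 2], [5, 10])
        res = correspondence_analysis(table)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert all(v == 0.0 for v in res.relative_inertia_columns.values())

    def test_2x2_hand_oracle(self):
        res = correspondence_analysis(np.array([[10, 0], [0, 10]]))
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_df_arithmetic_for_rank_by_species_table(self):
        # 26 patriline ranks x 6 species
        rng = np.random.default_rng(5)
        counts_by_group = {
            f"sp{i}": rng.integers(1, 30, size=k).tolist()
            for i, k in enumerate([26, 22, 18, 12, 11, 7])
        }
        table, rows, cols = paternity_rank_table(counts_by_group)
        assert table.shape == (26, 6)
        res = correspondence_analysis(table, rows, cols)
        assert res.df == 125

    def test_relative_inertias_sum_to_one(self):
        rng = np.random.default_rng(6)
        table = rng.integers(0, 20, size=(8, 4))
        table[0, :] += 1  # avoid zero margins
        table[:, 0] += 1
        res = correspondence_analysis(table)
        assert sum(res.relative_inertia_columns.values()) == pytest.approx(1.0)
        assert sum(res.relative_inertia_rows.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in res.relative_inertia_columns.values())

    def test_rank_table_sorts_descending_within_group(self):
        table, rows, cols = paternity_rank_table({"a": [1, 5, 3], "b": [2, 2]})
        assert list(table[:, 0]) == [5, 3, 1]
        assert list(table[:, 1]) == [2, 2, 0]
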