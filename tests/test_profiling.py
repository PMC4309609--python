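"""Normalization, fold changes, Welch/BH statistics and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy as sch

from cazstarve.corpus import CONDITION_LABELS, ExpressionMatrix
from cazstarve.profiling import (
    bh_fdr,
    differential_table,
    expressed,
    fold_change,
    fold_change_table,
    hierarchical_cluster,
    leaf_order,
    normalize_to_reference,
    round_fold,
    to_newick,
    welch_t_test,
)

from naive_oracles import naive_agglomerate


def _matrix(values: np.ndarray, genes=None) -> ExpressionMatrix:
    genes = genes or [f"An99g{i + 1:05d}" for i in range(len(values))]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=list(CONDITION_LABELS)))


class TestNormalization:
    def test_reference_maps_to_100_and_ratios_preserved(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            rng.uniform(10, 1000, size=(5, 12)),
            index=[f"An99g{i:05d}" for i in range(1, 6)],
            columns=list(CONDITION_LABELS),
        )
        # gene 2 = exactly twice the reference everywhere
        raw.iloc[1] = 2.0 * raw.iloc[0]
        norm = normalize_to_reference(raw, raw.index[0], per_strain=True)
        for strain in ("wt", "flbA", "brlA"):
            assert norm.value(raw.index[0], strain, "exp") == pytest.approx(100.0)
        assert np.allclose(norm.df.iloc[1], 2.0 * norm.df.iloc[0])

    def test_round_trip_recovers_raw(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(
            rng.uniform(1, 50, size=(3, 12)),
            index=["An99g00001", "An99g00002", "An99g00003"],
            columns=list(CONDITION_LABELS),
        )
        norm = normalize_to_reference(raw, "An99g00001")
        back = norm.df.copy()
        for strain in ("wt", "flbA", "brlA"):
            cols = [c for c in CONDITION_LABELS if c.startswith(strain)]
            back[cols] *= raw.at["An99g00001", f"{strain}_exp"] / 100.0
        assert np.allclose(back.values, raw.values)

    def test_zero_reference_fails_naming_strain(self):
        raw = pd.DataFrame(
            np.ones((2, 12)), index=["An99g00001", "An99g00002"],
            columns=list(CONDITION_LABELS),
        )
        raw.at["An99g00001", "flbA_exp"] = 0.0
        with pytest.raises(ValueError, match="flbA"):
            normalize_to_reference(raw, "An99g00001")


class TestFoldChange:
    def test_printed_table_claims(self, expression_matrix):
        assert fold_change(expression_matrix, "An01g03750", "wt", "d3") == pytest.approx(
            8.8 / 0.6
        )
        assert fold_change(expression_matrix, "An02g13580", "wt", "d3") == pytest.approx(48.5)

    def test_baseline_is_one_and_zero_baseline_undefined(self, expression_matrix):
        g = expression_matrix.genes[0]
        assert fold_change(expression_matrix, g, "wt", "exp") == 1.0
        m = _matrix(np.zeros((1, 12)) + [[0, 1, 2, 3, 1, 1, 1, 1, 1, 1, 1, 1]])
        assert np.isnan(fold_change(m, m.genes[0], "wt", "d1"))

    @given(scale=st.floats(0.01, 1000), base=st.floats(0.1, 50), v=st.floats(0.1, 500))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, base, v):
        row = np.full(12, base)
        row[1] = v
        m1 = _matrix(row[None, :])
        m2 = _matrix(scale * row[None, :])
        f1 = fold_change(m1, m1.genes[0], "wt", "d1")
        f2 = fold_change(m2, m2.genes[0], "wt", "d1")
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_round_fold_half_away_from_zero(self):
        assert round_fold(14.67) == 15
        assert round_fold(2.5) == 3
        assert round_fold(-2.5) == -3
        assert round_fold(0.4) == 0

    def test_table_covers_all_strains_and_days(self, expression_matrix):
        t = fold_change_table(expression_matrix)
        assert t.shape == (len(expression_matrix.genes), 9)
        assert t.at["An01g03750", "wt_d3"] == pytest.approx(8.8 / 0.6)


class TestExpressed:
    def test_floor_boundary_inclusive(self):
        assert expressed(0.2)
        assert not expressed(0.19)
        assert expressed(69.6)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_scale_invariance(self):
        t1, _, p1 = welch_t_test([1, 2, 3], [4, 5, 6])
        t2, _, p2 = welch_t_test([10, 20, 30], [40, 50, 60])
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, _, p = welch_t_test([1, 1], [2, 2])
        assert t == -np.inf and 0 < p < 1e-300


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_order_preserving(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_differential_table_monotone_q(self):
        rng = np.random.default_rng(3)
        genes = [f"An99g{i:05d}" for i in range(1, 31)]
        a = pd.DataFrame(rng.normal(0, 1, (30, 4)), index=genes)
        b = pd.DataFrame(rng.normal(0.5, 1, (30, 4)), index=genes)
        table = differential_table(a, b, fdr=0.05)
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert set(table.columns) == {"t", "df", "p", "q", "significant"}


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        d = hierarchical_cluster(x, linkage="wpgma", log_transform=False)
        assert d.merges[0][:3] == (0, 1, 0.0)

    def test_three_point_wpgma_hand_example(self):
        d = hierarchical_cluster(
            np.array([[0.0], [1.0], [5.0]]), linkage="wpgma", log_transform=False
        )
        (a, b, h1, _), (_, _, h2, _) = d.merges
        assert (a, b, h1) == (0, 1, 1.0)
        assert h2 == pytest.approx(4.5)

    @pytest.mark.parametrize("linkage", ["wpgma", "ward"])
    def test_agrees_with_naive_oracle(self, linkage):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = rng.integers(3, 13)
            x = rng.normal(size=(n, 4))
            mine = hierarchical_cluster(x, linkage=linkage, log_transform=False)
            oracle = naive_agglomerate(x, linkage)
            for (a, b, h, s), (oa, ob, oh, os) in zip(mine.merges, oracle):
                assert (a, b, s) == (oa, ob, os)
                assert h == pytest.approx(oh, rel=1e-9, abs=1e-9)
            assert np.all(np.diff(mine.heights) >= -1e-9)  # monotone merges

    @pytest.mark.parametrize("linkage,scipy_method", [("wpgma", "weighted"), ("ward", "ward")])
    def test_agrees_with_scipy(self, linkage, scipy_method):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 5))
        mine = hierarchical_cluster(x, linkage=linkage, log_transform=False)
        Z = sch.linkage(x, method=scipy_method, metric="euclidean")
        assert np.allclose(sorted(m[2] for m in mine.merges), sorted(Z[:, 2]))

    def test_pearson_metric_runs(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.5, 100, size=(8, 12))
        d = hierarchical_cluster(x, metric="one_minus_pearson", linkage="wpgma")
        assert len(d.merges) == 7

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 4))
        d1 = hierarchical_cluster(x, linkage="ward", log_transform=False)
        d2 = hierarchical_cluster(x, linkage="ward", log_transform=False)
        assert leaf_order(d1) == leaf_order(d2)
        assert sorted(leaf_order(d1)) == sorted(d1.labels)

    def test_two_leaves_input_order(self):
        d = hierarchical_cluster(np.array([[0.0], [1.0]]), log_transform=False)
        assert leaf_order(d) == ["0", "1"]

    def test_newick_well_formed(self):
        d = hierarchical_cluster(
            np.array([[0.0], [1.0], [5.0]]), linkage="wpgma", log_transform=False
        )
        nwk = to_newick(d)
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")") == 2
        # root-to-leaf depth equals the final merge height
        assert ":4.5" in nwk or ":3.5" in nwk
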