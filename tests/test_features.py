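"""Hyperedge feature families, assembly, niche representations, clustering."""

import numpy as np
import pytest

from hyperwave import (
    CellLabels,
    assemble_features,
    build_incidence,
    celltype_count_features,
    cluster_niches,
    diffusion_correlation_features,
    diffusion_operator,
    gene_pair_correlation_features,
    make_scales,
    mean_expression_features,
    niche_representations,
    select_variable_genes,
    transform_counts,
)
from hyperwave.pipeline import run_niche_pipeline


class TestTransformCounts:
    def test_row_at_target_sum_is_plain_log1p(self):
        expr = transform_counts(np.array([[10.0, 90.0]]), target_sum=100)
        np.testing.assert_allclose(expr.transformed, [[np.log1p(10), np.log1p(90)]])

    def test_equal_split_scaling(self):
        expr = transform_counts(np.array([[1.0, 1.0]]), target_sum=100)
        np.testing.assert_allclose(expr.transformed, [[np.log1p(50), np.log1p(50)]])

    def test_zero_row_stays_zero(self):
        expr = transform_counts(np.array([[0.0, 0.0], [2.0, 2.0]]), target_sum=10)
        np.testing.assert_array_equal(expr.transformed[0], 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            transform_counts(np.array([[1.0, -1.0]]))


def _expr_from_transformed(T):
    """Wrap a given matrix as if it were already transformed values."""
    T = np.asarray(T, dtype=float)
    expr = transform_counts(np.zeros_like(T))
    expr.transformed = T
    return expr


class TestMeanExpression:
    def test_two_point_mean_and_singleton(self):
        g = build_incidence([{0, 1}, {1}], 2)
        expr = _expr_from_transformed([[1.0], [3.0]])
        feats = mean_expression_features(expr, g, [0])
        np.testing.assert_allclose(feats, [[2.0], [3.0]])

    def test_constant_gene_gives_constant_feature(self):
        g = build_incidence([{0, 1}, {1, 2}, {0, 2}], 3)
        expr = _expr_from_transformed(np.full((3, 2), 7.0))
        feats = mean_expression_features(expr, g, [0, 1])
        np.testing.assert_allclose(feats, 7.0)

    def test_empty_gene_subset_rejected(self):
        g = build_incidence([{0, 1}], 2)
        with pytest.raises(ValueError, match="non-empty"):
            mean_expression_features(_expr_from_transformed([[1.0], [2.0]]), g, [])


class TestGenePairCorrelation:
    def test_perfect_correlation_and_anticorrelation(self):
        g = build_incidence([{0, 1, 2, 3}], 4)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr_from_transformed(np.column_stack([a, a, -a + 10]))
        feats = gene_pair_correlation_features(expr, g, [0, 1, 2])
        # pairs in order (0,1), (0,2), (1,2)
        np.testing.assert_allclose(feats, [[1.0, -1.0, -1.0]], atol=1e-9)

    def test_constant_gene_defaults_to_zero(self):
        g = build_incidence([{0, 1, 2, 3}], 4)
        expr = _expr_from_transformed(
            np.column_stack([np.ones(4), [1.0, 2, 3, 4]])
        )
        feats = gene_pair_correlation_features(expr, g, [0, 1])
        np.testing.assert_array_equal(feats, [[0.0]])

    def test_small_hyperedge_defaults_to_zero(self):
        g = build_incidence([{0, 1}, {0, 1, 2}], 3)
        expr = _expr_from_transformed(np.column_stack([[1.0, 2, 3], [2.0, 4, 5]]))
        feats = gene_pair_correlation_features(expr, g, [0, 1])
        assert feats[0, 0] == 0.0
        assert feats[1, 0] != 0.0

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(0)
        g = build_incidence([set(range(0, 6)), set(range(3, 10))], 10)
        T = rng.normal(size=(10, 4))
        expr = _expr_from_transformed(T)
        feats = gene_pair_correlation_features(expr, g, [0, 1, 2, 3])
        members = [list(range(0, 6)), list(range(3, 10))]
        ia, ib = np.triu_indices(4, k=1)
        for j, mem in enumerate(members):
            C = np.corrcoef(T[mem].T)
            np.testing.assert_allclose(feats[j], C[ia, ib], atol=1e-9)


class TestDiffusionCorrelation:
    def test_fixed_point_signal_gives_one(self):
        # the vertex-degree vector is a fixed point of P, so a synthetic
        # gene equal to d_V correlates perfectly with its diffusion
        g = build_incidence([{0, 1, 2}, {0, 1}, {0, 3}], 4)
        op = diffusion_operator(g)
        dv = g.vertex_degrees.astype(float)
        assert len(set(dv[list(g.hyperedge_members(0))])) > 1
        expr = _expr_from_transformed(dv[:, None])
        feats = diffusion_correlation_features(expr, g, op, [0])
        assert feats[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_degree_two_hyperedge_is_degenerate(self):
        g = build_incidence([{0, 1}, {0, 1, 2}], 3)
        op = diffusion_operator(g)
        expr = _expr_from_transformed(np.array([[1.0], [2.0], [3.0]]))
        feats = diffusion_correlation_features(expr, g, op, [0])
        assert feats[0, 0] == 0.0

    def test_globally_constant_gene_is_degenerate(self):
        g = build_incidence([{0, 1, 2}], 3)
        op = diffusion_operator(g)
        expr = _expr_from_transformed(np.full((3, 1), 4.0))
        feats = diffusion_correlation_features(expr, g, op, [0])
        assert feats[0, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        g = build_incidence([{0, 1, 2}], 3)
        other = build_incidence([{0, 1}], 2)
        expr = _expr_from_transformed(np.ones((3, 1)))
        with pytest.raises(ValueError, match="operator dimension"):
            diffusion_correlation_features(expr, g, diffusion_operator(other), [0])


class TestCelltypeCounts:
    @staticmethod
    def _labels():
        return CellLabels(
            cell_type=np.array(["A", "A", "B"]),
            subclass=np.array(["s1", "s2", "s2"]),
            supertype=np.array(["u", "u", "u"]),
        )

    def test_counting_and_zero_categories(self):
        g = build_incidence([{0, 1, 2}, {2}], 3)
        feats, names = celltype_count_features(self._labels(), g)
        assert names == [
            "cell_type:A", "cell_type:B",
            "subclass:s1", "subclass:s2",
            "supertype:u",
        ]
        np.testing.assert_array_equal(feats[0], [2, 1, 1, 2, 3])
        np.testing.assert_array_equal(feats[1], [0, 1, 0, 1, 1])

    def test_rows_sum_to_degree_per_granularity(self):
        g = build_incidence([{0, 1}, {0, 1, 2}, {2}], 3)
        feats, _ = celltype_count_features(self._labels(), g)
        for lo, hi in [(0, 2), (2, 4), (4, 5)]:
            np.testing.assert_array_equal(feats[:, lo:hi].sum(axis=1), g.edge_degrees)

    def test_unknown_category_rejected(self):
        g = build_incidence([{0, 1, 2}], 3)
        vocab = {
            "cell_type": np.array(["A"]),  # B missing
            "subclass": np.array(["s1", "s2"]),
            "supertype": np.array(["u"]),
        }
        with pytest.raises(ValueError, match="unknown cell_type"):
            celltype_count_features(self._labels(), g, vocabularies=vocab)

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CellLabels(
                cell_type=np.array(["A", None], dtype=object),
                subclass=np.array(["s", "s"]),
                supertype=np.array(["u", "u"]),
            )


class TestAssembleFeatures:
    def test_widths_add_and_schema_recorded(self):
        m = 4
        blocks = [
            ("a", np.ones((m, 5)), [f"a{i}" for i in range(5)]),
            ("b", np.zeros((m, 10)), [f"b{i}" for i in range(10)]),
            ("c", np.full((m, 7), 2.0), [f"c{i}" for i in range(7)]),
        ]
        z = assemble_features(blocks, standardize=False)
        assert z.n_features == 22
        assert z.blocks == {"a": (0, 5), "b": (5, 15), "c": (15, 22)}
        assert z.column_names[5] == "b0"

    def test_standardized_columns(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(50, 3))
        mat[:, 2] = 5.0  # constant column
        z = assemble_features([("x", mat, ["x0", "x1", "x2"])], standardize=True)
        np.testing.assert_allclose(z.values[:, :2].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.values[:, :2].std(axis=0), 1, atol=1e-12)
        np.testing.assert_array_equal(z.values[:, 2], 0)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row count"):
            assemble_features(
                [("a", np.ones((3, 1)), ["a0"]), ("b", np.ones((4, 1)), ["b0"])]
            )

    def test_frame_roundtrip_keeps_schema(self, tmp_path):
        z = assemble_features(
            [("a", np.arange(6.0).reshape(3, 2), ["a0", "a1"])], standardize=False
        )
        path = tmp_path / "z.csv"
        z.to_frame().to_csv(path)
        import pandas as pd

        back = pd.read_csv(path, index_col=0)
        assert list(back.columns) == z.column_names
        np.testing.assert_allclose(back.to_numpy(), z.values)


class TestNicheRepresentations:
    def test_width_and_zero_input(self):
        g = build_incidence([{0, 1}, {1, 2}, {0, 2}], 3)
        z = assemble_features(
            [("a", np.zeros((3, 1)), ["a0"])], standardize=False, edge_ids=[0, 1, 2]
        )
        rep = niche_representations(z, g, make_scales(1))
        assert rep.values.shape == (3, 2)
        np.testing.assert_array_equal(rep.values, 0)

    def test_telescoping_on_dual(self):
        rng = np.random.default_rng(1)
        g = build_incidence([{0, 1}, {1, 2}, {0, 2}, {0, 1, 2}], 3)
        vals = rng.normal(size=(4, 3))
        z = assemble_features([("a", vals, ["a", "b", "c"])], standardize=False)
        rep = niche_representations(z, g, make_scales(2))
        p = 3
        recon = rep.values[:, :p] + rep.values[:, p : 2 * p] + rep.values[:, 2 * p :]
        np.testing.assert_allclose(recon, vals, atol=1e-9)


class TestClusterNiches:
    def test_single_cluster(self):
        assert set(cluster_niches(np.random.default_rng(0).normal(size=(10, 3)), 1)) == {0}

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(size=(40, 4)) * 0.05
        blob2 = rng.normal(size=(40, 4)) * 0.05 + 50.0
        X = np.vstack([blob1, blob2])
        truth = np.r_[np.zeros(40), np.ones(40)]
        labels = cluster_niches(X, 2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        a = cluster_niches(X, 4, seed=9)
        b = cluster_niches(X, 4, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_niches(np.ones((5, 2)), 6)


class TestPipelineEquivariance:
    def test_permuting_cells_permutes_niche_rows(self, small_tissue):
        ds = small_tissue
        perm = np.random.default_rng(0).permutation(ds.n_cells)
        labels_perm = CellLabels(
            cell_type=ds.labels.cell_type[perm],
            subclass=ds.labels.subclass[perm],
            supertype=ds.labels.supertype[perm],
        )
        base = run_niche_pipeline(
            ds.coordinates, ds.counts, ds.labels, k=2, J=2, n_clusters=None
        )
        permuted = run_niche_pipeline(
            ds.coordinates[perm], ds.counts[perm], labels_perm, k=2, J=2, n_clusters=None
        )
        np.testing.assert_allclose(
            permuted.representation.values, base.representation.values[perm],
            atol=1e-8, rtol=1e-6,
        )


def test_select_variable_genes_stable_under_cell_permutation(small_tissue):
    expr = transform_counts(small_tissue.counts)
    perm = np.random.default_rng(1).permutation(small_tissue.n_cells)
    expr_perm = transform_counts(small_tissue.counts[perm])
    np.testing.assert_array_equal(
        select_variable_genes(expr, 10), select_variable_genes(expr_perm, 10)
    )


def test_correlation_features_bounded(small_tissue):
    from hyperwave import build_cell_graph, khop_lift

    ds = small_tissue
    hg = khop_lift(build_cell_graph(ds.coordinates), k=2)
    expr = transform_counts(ds.counts)
    subset = select_variable_genes(expr, 8)
    pair = gene_pair_correlation_features(expr, hg, subset)
    diff = diffusion_correlation_features(expr, hg, diffusion_operator(hg), subset)
    assert np.all(np.abs(pair) <= 1.0)
    assert np.all(np.abs(diff) <= 1.0)
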