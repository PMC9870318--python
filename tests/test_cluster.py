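import numpy as np
import pandas as pd
import pytest

from bnstephys.cluster import (
    PARAMETER_SETS, build_feature_matrix, standardize, unstandardize,
    ward_linkage, cut_tree, agreement, export_dendrogram_newick,
    export_heatmap, scatter3d_export, FeatureMatrix,
)
from oracles import ward_oracle, linkage_to_merges


def toy_table():
    rng = np.random.default_rng(42)
    cols = PARAMETER_SETS["six"]
    df = pd.DataFrame(rng.normal(size=(10, 6)), columns=cols,
                      index=[f"n{i}" for i in range(10)])
    df["evoked_spikes_+60pA"] = rng.integers(0, 20, 10).astype(float)
    return df


class TestMatrixConstruction:
    def test_missing_parameter_drops_row(self):
        df = toy_table()
        df.loc["n3", "first_isi_+40pA"] = np.nan
        fm = build_feature_matrix(df, "six")
        assert "n3" in fm.dropped
        assert "n3" not in fm.values.index

    def test_complete_three_set_preserves_rows(self):
        fm = build_feature_matrix(toy_table(), "three")
        assert len(fm.values) == 10 and fm.dropped == []

    def test_others_removed_from_six_set(self):
        df = toy_table()
        labels = {i: ("Others" if i in ("n1", "n4") else "I")
                  for i in df.index}
        fm = build_feature_matrix(df, "six", labels=labels)
        assert "n1" not in fm.values.index and "n4" not in fm.values.index
        # but Others stays in the three-parameter set
        fm3 = build_feature_matrix(df, "three", labels=labels)
        assert "n1" in fm3.values.index

    def test_others_lacking_low_step_features_self_exclude(self, cohort_run):
        """Simulated Others neurons lack latency/first-ISI at low steps, so
        the six-parameter matrix contains no Others rows even without the
        a-priori removal."""
        table, truth = cohort_run["table"], cohort_run["truth"]
        fm = build_feature_matrix(table, "six", labels=None)
        others = {i for i, t in truth.items() if t == "Others"}
        assert others.isdisjoint(set(fm.values.index))


class TestStandardize:
    def test_constant_column_rejected(self):
        df = toy_table()
        df["sag_-80pA"] = 1.0
        with pytest.raises(ValueError, match="sag_-80pA"):
            standardize(build_feature_matrix(df, "three"))

    def test_zscore_moments_and_inverse(self):
        fm = standardize(build_feature_matrix(toy_table(), "six"))
        assert np.allclose(fm.values.mean(), 0.0, atol=1e-12)
        assert np.allclose(fm.values.std(ddof=1), 1.0, atol=1e-12)
        back = unstandardize(fm)
        orig = build_feature_matrix(toy_table(), "six").values
        assert np.allclose(back.to_numpy(), orig.to_numpy(), atol=1e-10)


class TestWardLinkage:
    def test_1d_points_match_exhaustive_oracle(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        tree = ward_linkage(X)
        got = linkage_to_merges(tree.merges)
        exp = ward_oracle(X)
        assert [s for s, _ in got] == [s for s, _ in exp]
        assert np.allclose([h for _, h in got], [h for _, h in exp])
        # first two merges are the tight pairs
        assert got[0][0] == frozenset({0, 1})
        assert got[1][0] == frozenset({2, 3})

    def test_identical_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        tree = ward_linkage(X)
        assert tree.merges[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_rows_merge_at_euclidean_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_linkage(X)
        assert tree.merges.shape[0] == 1
        assert tree.merges[0, 2] == pytest.approx(5.0)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.zeros((1, 3)))

    def test_random_matrices_match_oracle(self):
        """Merge memberships and heights equal the exhaustive O(n^3)
        agglomeration on random matrices (n <= 12)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            d = int(rng.integers(1, 5))
            X = rng.normal(size=(n, d))
            got = linkage_to_merges(ward_linkage(X).merges)
            exp = ward_oracle(X)
            assert [s for s, _ in got] == [s for s, _ in exp]
            assert np.allclose([h for _, h in got], [h for _, h in exp])

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        h = ward_linkage(X).merges[:, 2]
        assert np.all(np.diff(h) >= -1e-12)

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 3))
        h1 = np.sort(ward_linkage(X).merges[:, 2])
        perm = rng.permutation(15)
        h2 = np.sort(ward_linkage(X[perm]).merges[:, 2])
        assert np.allclose(h1, h2)


class TestCutAndAgreement:
    def test_k_equals_n(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        tree = ward_linkage(X)
        cl = cut_tree(tree, 6)
        assert sorted(cl.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_equals_one(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        cl = cut_tree(ward_linkage(X), 1)
        assert set(cl.values()) == {1}

    def test_purity_bounds_and_partition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        tree = ward_linkage(X)
        cl = cut_tree(tree, 4)
        assert len(cl) == 20
        types = {i: ("A" if i < 10 else "B") for i in range(20)}
        ag = agreement(cl, types)
        assert all(0.0 <= p <= 1.0 for p in ag["purity"].values())
        assert int(ag["table"].to_numpy().sum()) == 20


class TestExports:
    def test_two_leaf_newick(self):
        X = np.array([[0.0], [4.0]])
        tree = ward_linkage(X)
        s = export_dendrogram_newick(tree)
        assert s == "(0:2,1:2);"

    def test_newick_roundtrip_topology(self, tmp_path):
        import io as _io
        from Bio import Phylo

        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        fm = FeatureMatrix(values=pd.DataFrame(
            X, index=[f"n{i}" for i in range(8)]), dropped=[])
        tree = ward_linkage(fm)
        path = tmp_path / "t.nwk"
        export_dendrogram_newick(tree, path)
        parsed = Phylo.read(str(path), "newick")
        leaves = {t.name for t in parsed.get_terminals()}
        assert leaves == {f"n{i}" for i in range(8)}
        # ultrametric: every leaf at the same depth (= root merge height / 2)
        depths = parsed.depths()
        leaf_depths = {d for t, d in depths.items() if t.is_terminal()}
        assert np.allclose(sorted(leaf_depths), tree.merges[-1, 2] / 2.0)

    def test_heatmap_tsv_rows_follow_leaf_order(self, tmp_path):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(9, 3)), columns=list("abc"),
                          index=[f"n{i}" for i in range(9)])
        fm = FeatureMatrix(values=df, dropped=[])
        tree = ward_linkage(fm)
        out = tmp_path / "h.tsv"
        export_heatmap(fm, tree, tsv_path=out)
        written = pd.read_csv(out, sep="\t", index_col=0)
        assert list(written.index) == tree.leaf_order()

    def test_scatter3d_raw_values(self):
        df = toy_table()
        out = scatter3d_export(df)
        assert list(out.columns) == ["evoked_spikes_+60pA", "rebound_-80pA",
                                     "sag_-80pA"]
        assert len(out) == 10
        # raw, not scaled
        assert np.allclose(out["sag_-80pA"], df["sag_-80pA"])

    def test_scatter3d_empty_input(self):
        out = scatter3d_export(pd.DataFrame())
        assert out.empty
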