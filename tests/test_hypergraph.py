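"""Bipartite correlation, incidence binarization, adjacency, central cluster."""

import numpy as np
import pandas as pd
import pytest

import epicoord as ec
from epicoord.datatypes import IncidenceMatrix
from conftest import make_annotation, make_dataset


def incidence_from_array(arr, rows=None, cols=None):
    arr = np.asarray(arr)
    rows = rows or [f"d{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    return IncidenceMatrix(values=pd.DataFrame(arr, index=rows, columns=cols),
                           threshold_used=0.5)


def adjacency_oracle(B):
    """Shared-support counts via set intersection, independent of matmul."""
    supports = [set(np.flatnonzero(row)) for row in B]
    n = len(supports)
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            A[i, j] = len(supports[i] & supports[j])
    return A


class TestBipartiteCorrelation:
    def _ds(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 10))
        vals[3] = vals[0]          # background copy of DMP 0
        vals[4] = -vals[1]         # negated copy of DMP 1
        return make_dataset(vals, ["case"] * 5 + ["control"] * 5)

    def test_copy_and_negated_copy_give_unit_correlation(self):
        ds = self._ds()
        ids = list(ds.probe_ids)
        R = ec.bipartite_correlation(ds, ids[:3])
        assert R.loc[ids[0], ids[3]] == pytest.approx(1.0)
        assert R.loc[ids[1], ids[4]] == pytest.approx(-1.0)

    def test_null_mean_abs_r_matches_closed_form(self):
        # E|r| under independence ~ sqrt(2 / (pi (n-1)))
        rng = np.random.default_rng(1)
        n = 50
        ds = make_dataset(rng.normal(size=(220, n)),
                          ["case"] * 25 + ["control"] * 25,
                          annotation=make_annotation(220))
        R = ec.bipartite_correlation(ds, list(ds.probe_ids[:20]))
        expected = np.sqrt(2 / (np.pi * (n - 1)))
        assert abs(np.abs(R.to_numpy()).mean() - expected) / expected < 0.1

    def test_constant_row_zeroed(self):
        ds = self._ds()
        ds.values.iloc[5] = 7.0
        R = ec.bipartite_correlation(ds, list(ds.probe_ids[:3]))
        assert (R[ds.probe_ids[5]] == 0).all()


class TestBinarize:
    def test_hand_computed_sd_cutoff(self):
        R = pd.DataFrame([[0.9, 0.1], [0.2, 0.8]],
                         index=["d0", "d1"], columns=["c0", "c1"])
        M = ec.binarize_incidence(R)
        assert M.threshold_used == pytest.approx(np.std([0.9, 0.1, 0.2, 0.8], ddof=1))
        assert M.values.to_numpy().tolist() == [[1, 0], [0, 1]]

    def test_strictly_greater_than_threshold(self):
        # entries at c, one at 0: t > 0, only |r| > t retained
        R = pd.DataFrame([[0.5, 0.5], [0.5, 0.0]])
        t = np.std([0.5, 0.5, 0.5, 0.0], ddof=1)
        M = ec.binarize_incidence(R)
        expected = (np.abs(R.to_numpy()) > t).astype(int)
        assert (M.values.to_numpy() == expected).all()

    def test_sign_symmetry(self):
        rng = np.random.default_rng(2)
        R = pd.DataFrame(rng.uniform(-1, 1, size=(5, 20)))
        a = ec.binarize_incidence(R).values.to_numpy()
        b = ec.binarize_incidence(-R).values.to_numpy()
        assert (a == b).all()

    def test_degenerate_all_equal_rejected(self):
        R = pd.DataFrame(np.full((3, 4), 0.5))
        with pytest.raises(ValueError, match="degenerate"):
            ec.binarize_incidence(R)


class TestAdjacency:
    def test_small_example(self):
        M = incidence_from_array([[1, 1, 0], [0, 1, 1]])
        A = ec.adjacency_from_incidence(M)
        assert A.to_numpy().tolist() == [[2, 1], [1, 2]]

    def test_zero_row_gives_zero_vertex(self):
        M = incidence_from_array([[0, 0, 0], [1, 1, 0]])
        A = ec.adjacency_from_incidence(M).to_numpy()
        assert (A[0] == 0).all() and (A[:, 0] == 0).all()

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(3)
        B = (rng.random((20, 200)) < 0.3).astype(int)
        A = ec.adjacency_from_incidence(incidence_from_array(B)).to_numpy()
        assert (A == adjacency_oracle(B)).all()

    def test_psd_and_hyperedge_count_conservation(self):
        rng = np.random.default_rng(4)
        B = (rng.random((15, 120)) < 0.4).astype(int)
        A = ec.adjacency_from_incidence(incidence_from_array(B)).to_numpy()
        assert np.linalg.eigvalsh(A.astype(float)).min() >= -1e-8
        off_sum = A.sum() - np.trace(A)
        col = B.sum(axis=0)
        assert off_sum == (col * (col - 1)).sum()


class TestCentralCluster:
    def test_planted_block_recovered(self, small_sim_zscored):
        _, _, z, truth = small_sim_zscored
        dmp_list = sorted(truth.dmp_ids & set(z.probe_ids))
        R = ec.bipartite_correlation(z, dmp_list, group="control")
        A = ec.adjacency_from_incidence(ec.binarize_incidence(R))
        cluster = ec.extract_central_cluster(A, min_size=5)
        coord = truth.coordinated_cluster_ids & set(z.probe_ids)
        overlap = ec.compare_clusters(cluster.members, coord)
        assert overlap["jaccard"] >= 0.8

    def test_uniform_adjacency_returns_full_set(self):
        n = 6
        A = pd.DataFrame(np.full((n, n), 3), index=list("abcdef"),
                         columns=list("abcdef"))
        np.fill_diagonal(A.values, 10)
        cluster = ec.extract_central_cluster(A, min_size=2)
        assert sorted(cluster.members) == list("abcdef")

    def test_permuting_vertex_order_permutes_membership_only(self):
        rng = np.random.default_rng(5)
        B = np.zeros((12, 60), dtype=int)
        B[:6, :30] = (rng.random((6, 30)) < 0.9).astype(int)
        B[6:, 30:] = (rng.random((6, 30)) < 0.2).astype(int)
        A = ec.adjacency_from_incidence(incidence_from_array(B))
        perm = rng.permutation(12)
        Ap = A.iloc[perm, perm]
        a = set(ec.extract_central_cluster(A, min_size=3).members)
        b = set(ec.extract_central_cluster(Ap, min_size=3).members)
        assert a == b

    def test_unreachable_min_size_errors(self):
        A = pd.DataFrame(np.diag([5, 5, 5]), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="min_size"):
            ec.extract_central_cluster(A, min_size=4)


class TestPeripheral:
    def test_strict_95_percent_boundary(self):
        B = np.ones((20, 2), dtype=int)
        B[0, 1] = 0  # second CpG hits 19/20 = 0.95 exactly
        M = incidence_from_array(B)
        cluster = ec.extract_central_cluster(
            ec.adjacency_from_incidence(M), min_size=2
        )
        # force full membership for the boundary check
        cluster.members = list(M.values.index)
        out = ec.refine_peripheral_cpgs(M, cluster, fraction=0.95)
        assert out == ["c0"]

    def test_planted_hyperedge_cpgs_recovered(self, small_sim_zscored):
        _, _, z, truth = small_sim_zscored
        dmp_list = sorted(truth.dmp_ids & set(z.probe_ids))
        R = ec.bipartite_correlation(z, dmp_list, group="control")
        M = ec.binarize_incidence(R)
        cluster = ec.extract_central_cluster(
            ec.adjacency_from_incidence(M), min_size=5
        )
        peripheral = set(ec.refine_peripheral_cpgs(M, cluster))
        planted = truth.hyperedge_cpg_ids & set(R.columns)
        tp = len(peripheral & planted)
        assert tp / len(planted) >= 0.9          # sensitivity
        assert tp / max(len(peripheral), 1) >= 0.9  # precision


class TestComparisons:
    def test_cluster_overlap_arithmetic(self):
        out = ec.compare_clusters({"a", "b", "c"}, {"b", "c", "d"})
        assert out == {"shared": 2, "unique_a": 1, "unique_b": 1, "jaccard": 0.5}
        assert ec.compare_clusters({"a"}, {"a"})["jaccard"] == 1.0
        assert ec.compare_clusters({"a"}, {"b"})["jaccard"] == 0.0

    def test_self_comparison_is_neutral(self, small_sim_zscored):
        _, _, z, truth = small_sim_zscored
        dmp_list = sorted(truth.dmp_ids & set(z.probe_ids))
        R = ec.bipartite_correlation(z, dmp_list, group="control")
        M = ec.binarize_incidence(R)
        cl = ec.extract_central_cluster(ec.adjacency_from_incidence(M), min_size=5)
        out = ec.peripheral_strength_comparison(R, M, cl, R, M, cl)
        assert out["fold_ratio"] == pytest.approx(1.0)
        assert out["wilcoxon_p"] > 0.05

    def test_wilcoxon_matches_exact_enumeration(self):
        from scipy.stats import mannwhitneyu

        # rank-sum of (1,2,3) vs (4,5,6): most extreme of C(6,3)=20 splits
        p = mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided",
                         method="exact").pvalue
        assert p == pytest.approx(2 * 1 / 20)
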