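import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cut_tree as scipy_cut, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from naive_linkage import linkage_partitions, naive_agglomerate
from toxicoclust import (
    ClusterAssignment,
    agglomerate,
    cut_tree,
    error_rate,
    pairwise_distance,
    suggest_k,
)
from toxicoclust.hclust import LINKAGES


def _frame(arr, prefix="g"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"c{j}" for j in range(arr.shape[1])],
    )


class TestPairwiseDistance:
    def test_three_four_five_triangle(self):
        m = _frame([[0, 0], [3, 4]])
        assert pairwise_distance(m, "gene", "euclidean").condensed[0] == pytest.approx(5.0)
        assert pairwise_distance(m, "gene", "manhattan").condensed[0] == pytest.approx(7.0)

    def test_minkowski_p2_equals_euclidean(self, rng):
        m = _frame(rng.normal(size=(6, 4)))
        e = pairwise_distance(m, "gene", "euclidean").condensed
        mk = pairwise_distance(m, "gene", "minkowski", p=2).condensed
        assert np.allclose(e, mk)

    def test_dc_axis_uses_columns(self, small_matrix):
        d = pairwise_distance(small_matrix, "dc")
        assert d.labels == list(small_matrix.columns)
        assert d.n == 3

    def test_invalid_order_rejected(self, small_matrix):
        with pytest.raises(ValueError, match=">= 1"):
            pairwise_distance(small_matrix, "gene", "minkowski", p=0.5)


class TestAgglomerate:
    def test_ward_d_hand_example(self):
        """1-D points {0,1,10}: merge (0,1) at 1, then (2*10+2*9-1)/3."""
        t = agglomerate(pairwise_distance(_frame([[0.0], [1.0], [10.0]])), "ward.d")
        assert t.heights == pytest.approx([1.0, 37 / 3])

    def test_ward_d2_hand_example(self):
        """Same points under the squared recurrence: sqrt(361/3) final height."""
        t = agglomerate(pairwise_distance(_frame([[0.0], [1.0], [10.0]])), "ward.d2")
        assert t.heights == pytest.approx([1.0, np.sqrt(361 / 3)])

    def test_identical_items_merge_at_zero(self):
        t = agglomerate(pairwise_distance(_frame([[1.0, 2.0], [1.0, 2.0]])), "ward.d2")
        assert t.heights[0] == 0.0

    @pytest.mark.parametrize("method", LINKAGES)
    def test_matches_naive_recomputation(self, method, rng):
        """Incremental Lance-Williams equals from-scratch recursive costs."""
        for _ in range(25):
            n = rng.integers(3, 9)
            m = _frame(rng.normal(size=(n, 3)))
            d = pairwise_distance(m, "gene")
            t = agglomerate(d, method)
            heights, partitions = naive_agglomerate(d.square(), method)
            assert np.allclose(t.heights, heights, atol=1e-9)
            assert linkage_partitions(t) == partitions

    @pytest.mark.parametrize(
        "method,scipy_method",
        [("ward.d2", "ward"), ("single", "single"), ("complete", "complete"), ("average", "average")],
    )
    def test_matches_scipy(self, method, scipy_method, rng):
        X = rng.normal(size=(12, 5))
        t = agglomerate(pairwise_distance(_frame(X), "gene"), method)
        Z = scipy_linkage(pdist(X), method=scipy_method)
        assert np.allclose(np.sort(t.heights), np.sort(Z[:, 2]))
        mine = cut_tree(t, 3).codes
        ref = scipy_cut(Z, n_clusters=3).ravel() + 1
        rep = error_rate(
            ClusterAssignment(list(t.labels), mine, 3),
            ClusterAssignment(list(t.labels), ref, 3),
        )
        assert rep.er == 0.0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    @pytest.mark.parametrize("method,r_method", [("ward.d", "ward.D"), ("ward.d2", "ward.D2")])
    def test_matches_r_hclust(self, method, r_method, rng, tmp_path):
        """Both Ward variants reproduce R's hclust heights and 3-cuts."""
        X = rng.normal(size=(10, 4))
        csv = tmp_path / "m.csv"
        np.savetxt(csv, X, delimiter=",")
        script = (
            f'm <- as.matrix(read.csv("{csv}", header=FALSE));'
            f'h <- hclust(dist(m), method="{r_method}");'
            'cat(paste(sort(h$height), collapse=","), "\\n");'
            'cat(paste(cutree(h, k=3), collapse=","), "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.strip().split("\n")
        r_heights = np.array([float(v) for v in out[0].split(",")])
        r_cut = np.array([int(v) for v in out[1].split(",")])
        t = agglomerate(pairwise_distance(_frame(X), "gene"), method)
        assert np.allclose(np.sort(t.heights), r_heights)
        rep = error_rate(
            ClusterAssignment(list(t.labels), cut_tree(t, 3).codes, 3),
            ClusterAssignment(list(t.labels), r_cut, 3),
        )
        assert rep.er == 0.0

    @pytest.mark.parametrize("method", ["ward.d", "ward.d2", "complete", "average"])
    def test_heights_nondecreasing(self, method, rng):
        m = _frame(rng.normal(size=(15, 4)))
        t = agglomerate(pairwise_distance(m, "gene"), method)
        assert np.all(np.diff(t.heights) >= -1e-12)

    def test_permutation_changes_labels_only(self, rng):
        X = rng.normal(size=(10, 4))
        perm = rng.permutation(10)
        t1 = cut_tree(agglomerate(pairwise_distance(_frame(X), "gene"), "ward.d2"), 3)
        t2 = cut_tree(agglomerate(pairwise_distance(_frame(X[perm]), "gene"), "ward.d2"), 3)
        by_label_1 = dict(zip(t1.labels, t1.codes))
        by_label_2 = {f"g{i}": c for i, c in zip(perm, t2.codes)}
        rep = error_rate(
            ClusterAssignment(t1.labels, [by_label_1[l] for l in t1.labels], 3),
            ClusterAssignment(t1.labels, [by_label_2[l] for l in t1.labels], 3),
        )
        assert rep.er == 0.0

    def test_single_item_rejected(self):
        d = pairwise_distance(_frame([[0.0], [1.0]]), "gene")
        d.condensed = np.array([])
        d.labels = ["only"]
        with pytest.raises(ValueError, match="at least 2"):
            agglomerate(d)


class TestCutTree:
    def test_extreme_k(self, rng):
        t = agglomerate(pairwise_distance(_frame(rng.normal(size=(6, 3))), "gene"))
        assert cut_tree(t, 6).k == 6 and len(set(cut_tree(t, 6).codes)) == 6
        assert set(cut_tree(t, 1).codes) == {1}

    def test_out_of_range_k(self, rng):
        t = agglomerate(pairwise_distance(_frame(rng.normal(size=(4, 2))), "gene"))
        for bad in (0, 5):
            with pytest.raises(ValueError, match="k must be"):
                cut_tree(t, bad)

    def test_cuts_are_nested(self, rng):
        t = agglomerate(pairwise_distance(_frame(rng.normal(size=(12, 4))), "gene"))
        for k in range(2, 12):
            fine = cut_tree(t, k).codes
            coarse = cut_tree(t, k - 1).codes
            # each fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1

    def test_codes_numbered_by_first_appearance(self, rng):
        t = agglomerate(pairwise_distance(_frame(rng.normal(size=(8, 3))), "gene"))
        codes = cut_tree(t, 3).codes
        first_seen = [codes[i] for i in sorted(np.unique(codes, return_index=True)[1])]
        assert first_seen == [1, 2, 3]


class TestSuggestK:
    def test_two_separated_blobs(self):
        m = _frame([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        k, gaps = suggest_k(agglomerate(pairwise_distance(m, "gene")), k_max=5)
        assert k == 2
        assert set(gaps["k"]) == {2, 3, 4, 5}

    def test_noise_free_block_design_suggests_four_gene_clusters(self):
        from toxicoclust import SimulationConfig, generate_fcge, logistic_transform

        cfg = SimulationConfig(noise_variance=0.0)
        f, _ = generate_fcge(cfg, 0)
        x = logistic_transform(f)
        k, _ = suggest_k(agglomerate(pairwise_distance(x, "gene")), k_max=8)
        assert k == 4

    def test_tie_breaks_toward_smaller_k(self):
        m = _frame([[0.0], [1.0], [2.0], [3.0]])  # equally spaced points
        t = agglomerate(pairwise_distance(m, "gene"), "single")
        k, gaps = suggest_k(t, k_max=3)
        assert k == gaps.loc[gaps["gap"].idxmax(), "k"]
        ties = gaps[gaps["gap"] == gaps["gap"].max()]["k"]
        assert k == ties.min()
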