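"""Propagation, SNF, consensus clustering and silhouette model selection."""

import numpy as np
import pandas as pd
import pytest

from driversub import fusion
from driversub.types import GeneNetwork, MutationRecord


def mut(sample, gene, pos=10):
    return MutationRecord(sample, gene, pos, "A", "V", "missense")


class TestBinarize:
    def test_presence_not_count(self):
        muts = [mut("s1", "g1"), mut("s1", "g1", 11), mut("s1", "g1", 12)]
        f0 = fusion.binarize_mutations(muts, ["g1", "g2"], ["s1", "s2"])
        assert f0.loc["s1", "g1"] == 1.0
        assert set(np.unique(f0.to_numpy())) <= {0.0, 1.0}

    def test_all_zero_row_permitted(self):
        f0 = fusion.binarize_mutations([mut("s1", "g1")], ["g1"], ["s1", "s2"])
        assert f0.loc["s2"].sum() == 0

    def test_empty_gene_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fusion.binarize_mutations([], [], ["s1"])

    def test_silent_mutations_ignored(self):
        muts = [MutationRecord("s1", "g1", 5, "A", "A", "silent")]
        f0 = fusion.binarize_mutations(muts, ["g1"], ["s1"])
        assert f0.loc["s1", "g1"] == 0.0


class TestNormalizeNetwork:
    def test_two_gene_unit_edge(self):
        net = GeneNetwork.from_edges([("a", "b", 1.0)])
        a = fusion.normalize_network(net, ["a", "b"])
        np.testing.assert_allclose(a, [[0, 1], [1, 0]])

    def test_isolated_gene_self_retention(self):
        net = GeneNetwork.from_edges([("a", "b", 1.0)])
        a = fusion.normalize_network(net, ["a", "b", "c"])
        np.testing.assert_allclose(a[2], [0, 0, 1])

    def test_rows_sum_to_one(self, rng):
        genes = [f"g{i}" for i in range(15)]
        edges = [
            (genes[i], genes[j], float(rng.uniform(0.1, 2)))
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.random() < 0.3
        ]
        a = fusion.normalize_network(GeneNetwork.from_edges(edges), genes)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)


class TestPropagate:
    def test_alpha_zero_returns_f0(self):
        f0 = pd.DataFrame([[1.0, 0.0]], index=["s1"], columns=["a", "b"])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = fusion.propagate(f0, a, alpha=0.0)
        np.testing.assert_array_equal(out.values, f0.to_numpy())

    def test_two_gene_fixed_point(self):
        """Closed form for A=[[0,1],[1,0]], F0=[1,0], alpha=0.7:
        (1-a) F0 (I - a A)^-1 = [0.3/0.51, 0.21/0.51]."""
        f0 = pd.DataFrame([[1.0, 0.0]], index=["s1"], columns=["a", "b"])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = fusion.propagate(f0, a, alpha=0.7)
        np.testing.assert_allclose(
            out.values[0], [0.3 / 0.51, 0.21 / 0.51], atol=1e-5
        )
        assert out.final_step_norm < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closed_form_on_random_networks(self, seed):
        """Iterated propagation equals (1-a) F0 (I - a A)^-1 on seeded
        20-gene networks, and per-patient mass is conserved."""
        rng = np.random.default_rng(seed)
        n = 20
        genes = [f"g{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.2:
                    edges.append((genes[i], genes[j], float(rng.uniform(0.5, 2.0))))
        a = fusion.normalize_network(GeneNetwork.from_edges(edges), genes)
        f0 = pd.DataFrame(
            (rng.random((5, n)) < 0.2).astype(float),
            index=[f"s{k}" for k in range(5)],
            columns=genes,
        )
        out = fusion.propagate(f0, a, alpha=0.7, tol=1e-10)
        closed = 0.3 * f0.to_numpy() @ np.linalg.inv(np.eye(n) - 0.7 * a)
        assert np.abs(out.values - closed).max() <= 1e-8
        np.testing.assert_allclose(
            out.values.sum(axis=1), f0.to_numpy().sum(axis=1), atol=1e-9
        )

    def test_alpha_one_rejected(self):
        f0 = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(ValueError, match="alpha"):
            fusion.propagate(f0, np.eye(1), alpha=1.0)

    def test_nonconvergence_is_error(self):
        f0 = pd.DataFrame([[1.0, 0.0]], columns=["a", "b"])
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(RuntimeError, match="converge"):
            fusion.propagate(f0, a, alpha=0.99, tol=1e-14, max_iter=3)


class TestZscore:
    def test_hand_example_population_sd(self):
        # gene values with log2(x+1) = (2, 4, 6)
        expr = pd.DataFrame([[3.0, 15.0, 63.0]], index=["g"], columns=list("abc"))
        z = fusion.zscore_expression(expr)
        np.testing.assert_allclose(
            z.to_numpy()[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_degenerate_gene_all_zero(self):
        expr = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"], columns=list("abc"))
        z = fusion.zscore_expression(expr)
        np.testing.assert_array_equal(z.to_numpy()[0], 0.0)

    def test_rows_standardized(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 100, size=(10, 30)))
        z = fusion.zscore_expression(expr).to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)


def _two_block_layer(rng, n=60, shift=4.0, n_feat=20):
    x = rng.normal(0, 1, size=(n, n_feat))
    x[n // 2 :, :] += shift
    return pd.DataFrame(x, index=[f"s{i}" for i in range(n)])


class TestSnf:
    def test_identical_samples_maximal_affinity(self, rng):
        x = rng.normal(0, 1, size=(10, 5))
        x[1] = x[0]
        w = fusion._affinity_kernel(x, k=3, mu=0.5)
        off = w - np.diag(np.diag(w))
        assert off[0, 1] == pytest.approx(off.max())

    def test_symmetry_and_positive_diagonal(self, rng):
        layers = [
            pd.DataFrame(rng.normal(size=(25, 8))),
            pd.DataFrame(rng.normal(size=(25, 4))),
        ]
        fused = fusion.snf_fuse(layers, k=5)
        assert np.abs(fused.w - fused.w.T).max() <= 1e-12
        assert (np.diag(fused.w) > 0).all()
        assert np.isfinite(fused.w).all()

    def test_k_reduced_when_too_large(self, rng):
        layers = [pd.DataFrame(rng.normal(size=(8, 3)))]
        fused = fusion.snf_fuse(layers, k=20)
        assert fused.k == 7

    def test_mismatched_samples_rejected(self, rng):
        l1 = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcde"))
        l2 = pd.DataFrame(rng.normal(size=(5, 2)), index=list("fghij"))
        with pytest.raises(ValueError, match="sample universe"):
            fusion.snf_fuse([l1, l2])

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_blocks_recovered_through_fusion(self, seed):
        rng = np.random.default_rng(seed)
        layers = [_two_block_layer(rng), _two_block_layer(rng)]
        fused = fusion.snf_fuse(layers, k=10)
        per_k = fusion.consensus_cluster(fused, max_k=3, reps=100, seed=seed)
        labels = per_k[2].labels
        truth = np.array([0] * 30 + [1] * 30)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0


class TestConsensus:
    def test_two_far_blocks_consensus_saturated(self):
        rng = np.random.default_rng(3)
        layer = _two_block_layer(rng, n=20, shift=8.0)
        fused = fusion.snf_fuse([layer], k=5)
        per_k = fusion.consensus_cluster(fused, max_k=3, reps=200, seed=0)
        m = per_k[2].m
        within = np.concatenate([m[:10, :10].ravel(), m[10:, 10:].ravel()])
        between = m[:10, 10:].ravel()
        assert within.min() == pytest.approx(1.0)
        assert between.max() <= 0.05

    def test_matrix_bounds_and_diagonal(self, rng):
        layer = pd.DataFrame(rng.normal(size=(15, 6)))
        fused = fusion.snf_fuse([layer], k=5)
        per_k = fusion.consensus_cluster(fused, max_k=4, reps=50, seed=1)
        for cm in per_k.values():
            assert (cm.m >= 0).all() and (cm.m <= 1).all()
            np.testing.assert_array_equal(np.diag(cm.m), 1.0)

    def test_seeded_determinism(self, rng):
        layer = pd.DataFrame(rng.normal(size=(15, 6)))
        fused = fusion.snf_fuse([layer], k=5)
        a = fusion.consensus_cluster(fused, max_k=3, reps=50, seed=9)
        b = fusion.consensus_cluster(fused, max_k=3, reps=50, seed=9)
        np.testing.assert_array_equal(a[2].m, b[2].m)
        np.testing.assert_array_equal(a[2].labels, b[2].labels)


class TestSilhouette:
    def test_hand_example_on_a_line(self):
        """Points {0, 0.1} and {10, 10.1}: sil(0) = (10.05 - 0.1)/10.05."""
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        d = np.abs(pts[:, None] - pts[None, :])
        labels = np.array([0, 0, 1, 1])
        sil = fusion.silhouette_samples_from_distance(d, labels)
        assert sil[0] == pytest.approx((10.05 - 0.1) / 10.05)
        assert sil.mean() > 0.98

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import silhouette_samples

        x = rng.normal(size=(40, 3))
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        labels = rng.integers(0, 3, size=40)
        ours = fusion.silhouette_samples_from_distance(d, labels)
        ref = silhouette_samples(d, labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_label_permutation_invariance(self, rng):
        x = rng.normal(size=(20, 2))
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        labels = rng.integers(0, 2, size=20)
        s1 = fusion.silhouette_samples_from_distance(d, labels)
        s2 = fusion.silhouette_samples_from_distance(d, 1 - labels)
        np.testing.assert_allclose(s1, s2)

    def test_singleton_cluster_silhouette_zero(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        sil = fusion.silhouette_samples_from_distance(d, np.array([0, 1, 1]))
        assert sil[0] == 0.0

    def test_choose_k_picks_two_for_two_blocks(self):
        rng = np.random.default_rng(0)
        layer = _two_block_layer(rng, n=30, shift=6.0)
        fused = fusion.snf_fuse([layer], k=5)
        per_k = fusion.consensus_cluster(fused, max_k=5, reps=100, seed=0)
        assignment = fusion.silhouette_and_choose_k(per_k, fused)
        assert assignment.chosen_k == 2
        labels = assignment.labels
        assert set(labels.unique()) == {"CLASS A", "CLASS B"}
        # CLASS A is the larger (or equal-size, first-seen) cluster
        assert (labels == "CLASS A").sum() >= (labels == "CLASS B").sum()
        assert assignment.silhouette.between(-1, 1).all()
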