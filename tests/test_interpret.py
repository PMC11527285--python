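"""Interpretability: gene weights, occlusion attribution, enrichment."""

import itertools
import math

import numpy as np
import pytest

import genecaps as gc
from genecaps.autodiff import Tensor
from genecaps.capsule import CapsuleEncoderParams
from genecaps.expression_io import ValidationError
from genecaps.interpret import hypergeometric_pvalue
from genecaps.training import TrainConfig, initialize_model


def exact_upper_tail(k, N, K, n):
    """Direct combinatorial enumeration of P[X >= k]."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


class TestGeneWeights:
    def _params(self, W):
        P, d_p, n = W.shape
        return CapsuleEncoderParams(
            Tensor(W, requires_grad=True),
            Tensor(np.zeros((P, 2, 2, d_p)), requires_grad=True))

    def test_zero_weights_zero_importance(self):
        t = gc.primary_capsule_gene_weights(self._params(np.zeros((2, 3, 4))))
        np.testing.assert_array_equal(t.importance, 0.0)

    def test_single_row_l2_is_absolute_value(self):
        W = np.array([[[-2.0, 3.0, 0.5]]])  # P=1, d_p=1, n=3
        t = gc.primary_capsule_gene_weights(self._params(W))
        np.testing.assert_allclose(t.importance[:, 0], [2.0, 3.0, 0.5])

    def test_matches_per_column_norm_oracle(self, rng):
        W = rng.normal(size=(4, 3, 5))
        t = gc.primary_capsule_gene_weights(self._params(W))
        for i in range(4):
            for g in range(5):
                assert t.importance[g, i] == pytest.approx(
                    np.sqrt(sum(W[i, d, g] ** 2 for d in range(3))),
                    abs=1e-12)

    def test_unknown_aggregation_rejected(self, rng):
        with pytest.raises(ValidationError):
            gc.primary_capsule_gene_weights(
                self._params(np.zeros((1, 1, 1))), aggregation="max")


class TestImportantGenes:
    def _table(self, imp):
        return gc.GeneImportanceTable(
            [f"g{i}" for i in range(imp.shape[0])], imp, "l2_norm")

    def test_threshold_above_max_gives_empty_sets(self, rng):
        sets, counts = gc.important_genes(self._table(rng.random((5, 2))),
                                          threshold=2.0)
        assert all(not v for v in sets.values())
        assert counts.empty

    def test_boundary_is_strict_inequality(self):
        sets, _ = gc.important_genes(
            self._table(np.array([[0.05], [0.07], [0.06]])), threshold=0.06)
        assert sets[0] == ["g1"]

    def test_matches_brute_force_scan(self, rng):
        imp = rng.normal(size=(20, 4)) * 0.1
        sets, counts = gc.important_genes(self._table(imp), threshold=0.06)
        for i in range(4):
            expected = [f"g{g}" for g in range(20)
                        if abs(imp[g, i]) > 0.06]
            assert sets[i] == expected
        assert counts.sum() == (np.abs(imp) > 0.06).any(axis=1).sum()


class TestCapsuleActivation:
    def test_dead_gene_has_exactly_zero_attribution(self, rng):
        cfg = TrainConfig(epochs=1, seed=2, n_primary=2, n_capsules=3,
                          d_primary=3, d_capsule=3, n_heads=1, n_hidden=4)
        ckpt = initialize_model([f"g{i}" for i in range(6)], cfg)
        ckpt.encoder.primary_weights.data[:, :, 4] = 0.0  # kill gene 4
        ref = gc.ExpressionMatrix([f"g{i}" for i in range(6)],
                                  [f"s{j}" for j in range(5)],
                                  rng.random((6, 5)) + 1.0)
        attr = gc.attribution_matrix(ckpt, ref)
        np.testing.assert_array_equal(attr[4], 0.0)
        assert np.abs(attr[[0, 1, 2, 3, 5]]).max() > 0

    def test_block_diagonal_routing_isolates_capsule(self, rng):
        """A gene feeding one primary capsule that routes to one output
        capsule only perturbs that capsule's norm."""
        n, P, J, d = 4, 2, 2, 2
        W = np.zeros((P, d, n))
        W[0, :, 0] = 1.0        # gene 0 -> primary capsule 0 only
        W[1, :, 1:] = rng.normal(size=(d, 3))
        w = np.zeros((P, J, d, d))
        w[0, 0] = np.eye(d)     # primary 0 -> output capsule 0 only
        w[1, 1] = np.eye(d)
        cfg = TrainConfig(epochs=1, seed=0, n_primary=P, n_capsules=J,
                          d_primary=d, d_capsule=d, n_heads=1, n_hidden=4)
        ckpt = initialize_model([f"g{i}" for i in range(n)], cfg)
        ckpt.encoder.primary_weights.data[:] = W
        ckpt.encoder.routing_weights.data[:] = w
        ref = gc.ExpressionMatrix([f"g{i}" for i in range(n)], ["s0", "s1"],
                                  rng.random((n, 2)) + 1.0)
        attr = gc.attribution_matrix(ckpt, ref)
        assert abs(attr[0, 0]) > 1e-6
        assert attr[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_capsule_view_matches_matrix_column(self, tiny_checkpoint,
                                                       tiny_dataset):
        ref = tiny_dataset.matrix.subset_samples(range(6))
        attr = gc.attribution_matrix(tiny_checkpoint, ref)
        one = gc.capsule_activation_test(tiny_checkpoint, ref,
                                         capsule_index=2)
        np.testing.assert_allclose(one.scores, attr[:, 2], atol=1e-12)

    def test_out_of_range_capsule_rejected(self, tiny_checkpoint,
                                           tiny_dataset):
        with pytest.raises(ValidationError):
            gc.capsule_activation_test(tiny_checkpoint, tiny_dataset.matrix,
                                       capsule_index=99)

    def test_activate_mode_scores_informative_genes(self, tiny_checkpoint,
                                                    tiny_dataset):
        ref = tiny_dataset.matrix.subset_samples(range(6))
        attr = gc.attribution_matrix(tiny_checkpoint, ref,
                                     mode="activate_single")
        assert np.isfinite(attr).all() and np.abs(attr).max() > 0


class TestHypergeometricEnrichment:
    def test_pvalues_match_exact_enumeration_small_universes(self):
        """Full sweep of every instance with universe size <= 12."""
        for N in range(1, 13):
            for K in range(1, N + 1):
                for n in range(0, N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert hypergeometric_pvalue(k, N, K, n) \
                            == pytest.approx(exact_upper_tail(k, N, K, n),
                                             abs=1e-12)

    def test_worked_combinatorial_case(self):
        # N=10, K=5, n=3, k=3: C(5,3)/C(10,3) = 10/120
        universe = [f"g{i}" for i in range(10)]
        coll = gc.GeneSetCollection({"s": universe[:5]})
        df = gc.hypergeometric_enrichment(universe[:3], coll, universe)
        assert df.loc[0, "p_value"] == pytest.approx(10 / 120, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        coll = gc.GeneSetCollection({"s": universe[:3]})
        df = gc.hypergeometric_enrichment(universe[5:7], coll, universe)
        assert df.loc[0, "overlap"] == 0
        assert df.loc[0, "p_value"] == 1.0

    def test_full_universe_query_is_certain(self):
        universe = [f"g{i}" for i in range(6)]
        coll = gc.GeneSetCollection({"all": universe})
        df = gc.hypergeometric_enrichment(universe, coll, universe)
        assert df.loc[0, "p_value"] == 1.0

    def test_bh_adjustment_is_monotone(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = {f"s{j}": list(rng.choice(universe, size=8, replace=False))
                for j in range(12)}
        df = gc.hypergeometric_enrichment(
            list(rng.choice(universe, size=10, replace=False)),
            gc.GeneSetCollection(sets), universe)
        assert (df["adjusted_p"] >= df["p_value"] - 1e-15).all()
        assert list(df["adjusted_p"]) == sorted(df["adjusted_p"])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            gc.hypergeometric_enrichment(
                ["zz"], gc.GeneSetCollection({"s": ["g0"]}), ["g0", "g1"])


class TestCapsulePathwayNetwork:
    def test_exact_match_produces_edge(self):
        universe = [f"g{i}" for i in range(30)]
        coll = gc.GeneSetCollection({"pathway_a": universe[:5],
                                     "pathway_b": universe[10:20]})
        nodes, edges = gc.capsule_pathway_network(
            {0: universe[:5]}, coll, universe, alpha=0.05)
        assert ("pathway_a" in set(edges["pathway"]))
        assert set(nodes[nodes["type"] == "capsule"]["node"]) \
            == {"capsule_0"}

    def test_no_significant_sets_gives_empty_edges(self):
        universe = [f"g{i}" for i in range(30)]
        coll = gc.GeneSetCollection({"p": universe[:10]})
        nodes, edges = gc.capsule_pathway_network(
            {0: universe[25:28]}, coll, universe, alpha=1e-6)
        assert edges.empty
        assert not nodes.empty

    def test_edges_unique_per_pair(self):
        universe = [f"g{i}" for i in range(30)]
        coll = gc.GeneSetCollection({"p": universe[:6]})
        _, edges = gc.capsule_pathway_network(
            {0: universe[:6], 1: universe[:6]}, coll, universe, alpha=0.05)
        assert not edges.duplicated(["capsule", "pathway"]).any()
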