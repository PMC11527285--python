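"""Expression I/O: parsing, filtering, normalization, splits, GMT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genecaps as gc
from genecaps.expression_io import ParseError, ValidationError


@pytest.fixture()
def small_matrix():
    return gc.ExpressionMatrix(["gA", "gB", "gC"], ["s1", "s2"],
                               [[1.0, 2.0], [0.0, 3.0], [4.0, 5.0]])


class TestReadWrite:
    def test_tsv_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        gc.write_expression(small_matrix, path)
        back = gc.read_expression(path, format="tsv")
        assert back.gene_ids == small_matrix.gene_ids
        assert back.sample_ids == small_matrix.sample_ids
        np.testing.assert_allclose(back.values, small_matrix.values,
                                   atol=1e-9)

    def test_transposed_orientation_recovers_same_matrix(self, small_matrix,
                                                         tmp_path):
        path = tmp_path / "t.csv"
        small_matrix.to_frame().T.to_csv(path)
        back = gc.read_expression(path, format="csv",
                                  orientation="samples_by_genes")
        assert back.gene_ids == small_matrix.gene_ids
        np.testing.assert_allclose(back.values, small_matrix.values)

    def test_mtx_triplets_densify(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "3 2 2\n1 1 5.0\n3 2 2.0\n")
        (tmp_path / "genes.tsv").write_text("gA\ngB\ngC\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        m = gc.read_expression(tmp_path / "m.mtx", format="mtx")
        np.testing.assert_array_equal(
            m.values, [[5.0, 0.0], [0.0, 0.0], [0.0, 2.0]])
        assert m.gene_ids == ["gA", "gB", "gC"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("\ts1\ngA\t1\ngA\t2\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            gc.read_expression(tmp_path / "d.tsv")

    def test_nan_cell_rejected(self, tmp_path):
        (tmp_path / "n.tsv").write_text("\ts1\ngA\t1\ngB\tnan\n")
        with pytest.raises(ValidationError, match="NaN"):
            gc.read_expression(tmp_path / "n.tsv")

    def test_round_trip_precision_12_digits(self, tmp_path, rng):
        m = gc.ExpressionMatrix([f"g{i}" for i in range(20)], ["a", "b"],
                                rng.random((20, 2)) * 100)
        gc.write_expression(m, tmp_path / "p.tsv")
        back = gc.read_expression(tmp_path / "p.tsv")
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)


class TestFilterMatrix:
    def test_all_zero_sample_dropped(self):
        vals = np.ones((5, 5))
        vals[:, 2] = 0.0
        m = gc.ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"s{j}" for j in range(5)], vals)
        out = gc.filter_matrix(m)
        assert out.sample_ids == ["s0", "s1", "s3", "s4"]
        assert out.gene_ids == m.gene_ids

    def test_dense_matrix_unchanged(self, rng):
        m = gc.ExpressionMatrix([f"g{i}" for i in range(4)],
                                [f"s{j}" for j in range(4)],
                                rng.random((4, 4)) + 0.1)
        out = gc.filter_matrix(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_matches_brute_force_recount(self, rng):
        vals = (rng.random((10, 10)) < 0.35) * rng.random((10, 10))
        m = gc.ExpressionMatrix([f"g{i}" for i in range(10)],
                                [f"s{j}" for j in range(10)], vals)
        try:
            out = gc.filter_matrix(m, 0.2, 0.2)
        except ValidationError:
            pytest.skip("degenerate draw emptied the matrix")
        keep_s = [j for j in range(10) if (vals[:, j] > 0).mean() >= 0.2]
        keep_g = [i for i in range(10)
                  if (vals[np.ix_([i], keep_s)] > 0).mean() >= 0.2]
        assert out.sample_ids == [f"s{j}" for j in keep_s]
        assert out.gene_ids == [f"g{i}" for i in keep_g]

    def test_idempotent(self, rng):
        vals = (rng.random((8, 8)) < 0.5) * 1.0
        m = gc.ExpressionMatrix([f"g{i}" for i in range(8)],
                                [f"s{j}" for j in range(8)], vals)
        once = gc.filter_matrix(m)
        twice = gc.filter_matrix(once)
        assert once.gene_ids == twice.gene_ids
        assert once.sample_ids == twice.sample_ids
        np.testing.assert_array_equal(once.values, twice.values)

    def test_empty_result_raises(self):
        m = gc.ExpressionMatrix(["g0"], ["s0"], [[0.0]])
        with pytest.raises(ValidationError):
            gc.filter_matrix(m)


class TestLogNormalize:
    def test_tpm_hand_computation(self):
        m = gc.ExpressionMatrix(["gA", "gB"], ["s1"], [[10.0], [10.0]])
        out = gc.log_normalize(m, gene_lengths={"gA": 1000, "gB": 1000},
                               mode="log2_tpm")
        np.testing.assert_allclose(out.values, np.log2(5e5 + 1),
                                   atol=1e-12)

    def test_all_zero_sample_stays_zero(self):
        m = gc.ExpressionMatrix(["gA"], ["s1"], [[0.0]])
        out = gc.log_normalize(m, mode="log2_cpm")
        np.testing.assert_array_equal(out.values, 0.0)

    def test_passthrough_rejects_negative(self):
        m = gc.ExpressionMatrix(["gA"], ["s1"], [[-1.0]])
        with pytest.raises(ValidationError):
            gc.log_normalize(m, mode="passthrough")

    def test_missing_gene_length_names_gene(self):
        m = gc.ExpressionMatrix(["gA", "gB"], ["s1"], [[1.0], [1.0]])
        with pytest.raises(ValidationError, match="gB"):
            gc.log_normalize(m, gene_lengths={"gA": 500}, mode="log2_tpm")


class TestIntersectGenes:
    def _make(self, genes, rng):
        return gc.ExpressionMatrix(genes, ["s1", "s2"],
                                   rng.random((len(genes), 2)))

    def test_pairwise_intersection(self, rng):
        a = self._make(["A", "B", "C"], rng)
        b = self._make(["B", "C", "D"], rng)
        out_a, out_b = gc.intersect_genes([a, b])
        assert out_a.gene_ids == out_b.gene_ids == ["B", "C"]

    def test_identical_matrices_canonical_order(self, rng):
        a = self._make(["C", "A", "B"], rng)
        out1, out2 = gc.intersect_genes([a, a])
        assert out1.gene_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(out1.values, out2.values)

    def test_triple_matches_set_algebra(self, rng):
        ms = [self._make(list(g), rng)
              for g in ("ABCDE", "BCDEF", "CDEFG")]
        outs = gc.intersect_genes(ms)
        expected = sorted(set("ABCDE") & set("BCDEF") & set("CDEFG"))
        for out in outs:
            assert out.gene_ids == expected

    def test_empty_intersection_raises(self, rng):
        with pytest.raises(ValidationError):
            gc.intersect_genes([self._make(["A"], rng),
                                self._make(["B"], rng)])


class TestSplitCells:
    def _dataset(self, n, rng):
        m = gc.ExpressionMatrix([f"g{i}" for i in range(3)],
                                [f"s{j}" for j in range(n)],
                                rng.random((3, n)))
        return gc.LabelledDataset(m, rng.integers(0, 2, n))

    def test_floor_rounding_sizes(self, rng):
        tr, va, te = gc.split_cells(self._dataset(10, rng), seed=0)
        assert (tr.n_samples, va.n_samples, te.n_samples) == (8, 1, 1)

    def test_same_seed_same_membership(self, rng):
        d = self._dataset(50, rng)
        a = gc.split_cells(d, seed=3)
        b = gc.split_cells(d, seed=3)
        for x, y in zip(a, b):
            assert x.matrix.sample_ids == y.matrix.sample_ids

    def test_different_seeds_differ_but_same_sizes(self, rng):
        d = self._dataset(1000, rng)
        a = gc.split_cells(d, seed=1)
        b = gc.split_cells(d, seed=2)
        assert [x.n_samples for x in a] == [x.n_samples for x in b]
        assert a[0].matrix.sample_ids != b[0].matrix.sample_ids

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_partition_disjoint_and_exhaustive(self, seed):
        rng = np.random.default_rng(0)
        d = self._dataset(37, rng)
        parts = gc.split_cells(d, seed=seed)
        ids = [s for p in parts for s in p.matrix.sample_ids]
        assert sorted(ids) == sorted(d.matrix.sample_ids)
        assert len(set(ids)) == len(ids)

    def test_empty_partition_raises(self, rng):
        with pytest.raises(ValidationError):
            gc.split_cells(self._dataset(5, rng), (0.8, 0.1, 0.1), seed=0)


class TestGmt:
    def test_two_line_file(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        coll = gc.read_gmt(p)
        assert set(coll.sets) == {"setA", "setB"}
        assert coll.sets["setA"] == ["g1", "g2"]

    def test_duplicate_set_name_rejected(self, tmp_path):
        p = tmp_path / "d.gmt"
        p.write_text("setA\tx\tg1\nsetA\tx\tg2\n")
        with pytest.raises(ParseError, match="line 2"):
            gc.read_gmt(p)

    def test_duplicate_gene_counted_once(self, tmp_path):
        p = tmp_path / "g.gmt"
        p.write_text("setA\tx\tg1\tg1\tg2\n")
        assert gc.read_gmt(p).sets["setA"] == ["g1", "g2"]

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("setA\tx\tg1\nsetB\tonlydesc\n")
        with pytest.raises(ParseError, match="line 2"):
            gc.read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = gc.GeneSetCollection({"m1": ["a", "b"], "m2": ["c"]})
        gc.write_gmt(coll, tmp_path / "w.gmt")
        assert gc.read_gmt(tmp_path / "w.gmt").sets == coll.sets
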