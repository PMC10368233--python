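"""Format readers/writers: triplet and dense Hi-C, bedGraph, BEDPE."""
import gzip

import numpy as np
import pytest

from chromaloop.data_io import (
    AnchorPair,
    ContactMatrix,
    GenomeGrid,
    clean_matrix,
    read_bedgraph_binned,
    read_bedpe,
    read_contact_matrix,
    write_scored_bedpe,
)


@pytest.fixture
def g3():
    return GenomeGrid("chr1", 10_000, 3)


class TestReadContactMatrix:
    def test_triplet_entry_is_mirrored(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t10000\t5\n")
        m = read_contact_matrix(p, g3, "triplet")
        assert m.counts[0, 1] == m.counts[1, 0] == 5
        assert m.counts.sum() == 10

    def test_empty_file_gives_zero_matrix(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("")
        m = read_contact_matrix(p, g3, "triplet")
        assert m.counts.shape == (3, 3) and not m.counts.any()

    def test_diagonal_and_offdiagonal_fill(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("10000\t10000\t2\n0\t20000\t7\n")
        m = read_contact_matrix(p, g3, "triplet")
        expected = np.zeros((3, 3))
        expected[1, 1] = 2
        expected[0, 2] = expected[2, 0] = 7
        np.testing.assert_array_equal(m.counts, expected)

    def test_negative_count_row_rejected(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t10000\t-4\n0\t20000\t3\n")
        m = read_contact_matrix(p, g3, "triplet")
        assert m.counts[0, 1] == 0 and m.counts[0, 2] == 3

    def test_out_of_grid_bin_raises_with_row(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t50000\t3\n")
        with pytest.raises(ValueError, match="line 1"):
            read_contact_matrix(p, g3, "triplet")

    def test_gzip_input(self, g3, tmp_path):
        p = tmp_path / "m.txt.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("0\t10000\t5\n")
        assert read_contact_matrix(p, g3, "triplet").counts[1, 0] == 5

    def test_dense_dialect(self, g3, tmp_path):
        p = tmp_path / "m.txt"
        mat = np.arange(9).reshape(3, 3)
        mat = mat + mat.T
        np.savetxt(p, mat)
        np.testing.assert_allclose(
            read_contact_matrix(p, g3, "dense").counts, mat
        )

    def test_triplet_roundtrip_preserves_nonzeros(self, tmp_path):
        """write (upper triangle) -> read reproduces the matrix exactly."""
        rng = np.random.default_rng(0)
        n, r = 20, 10_000
        grid = GenomeGrid("chr1", r, n)
        m = np.triu(rng.poisson(3.0, size=(n, n)))
        m = m + np.triu(m, 1).T
        p = tmp_path / "m.txt"
        with open(p, "wt") as fh:
            for i in range(n):
                for j in range(i, n):
                    if m[i, j]:
                        fh.write(f"{i * r}\t{j * r}\t{m[i, j]}\n")
        back = read_contact_matrix(p, grid, "triplet")
        np.testing.assert_array_equal(back.counts, m)


class TestCleanMatrix:
    def test_nan_row_zeroed_and_flagged(self):
        g = GenomeGrid("chr1", 10_000, 6)
        c = np.ones((6, 6))
        c[4, :] = np.nan
        cleaned, unmappable = clean_matrix(ContactMatrix(g, c))
        assert unmappable == {4}
        assert not cleaned.counts[4].any() and not cleaned.counts[:, 4].any()

    def test_finite_matrix_unchanged(self):
        g = GenomeGrid("chr1", 10_000, 4)
        c = np.full((4, 4), 2.0)
        cleaned, unmappable = clean_matrix(ContactMatrix(g, c))
        np.testing.assert_array_equal(cleaned.counts, c)
        assert unmappable == set()

    def test_single_nan_zeroes_mirror_entry(self):
        g = GenomeGrid("chr1", 10_000, 5)
        c = np.ones((5, 5))
        c[2, 3] = np.nan
        cleaned, unmappable = clean_matrix(ContactMatrix(g, c))
        assert cleaned.counts[2, 3] == cleaned.counts[3, 2] == 0
        assert unmappable == set()
        np.testing.assert_array_equal(cleaned.counts, cleaned.counts.T)

    def test_idempotent(self):
        g = GenomeGrid("chr1", 10_000, 5)
        c = np.random.default_rng(1).random((5, 5))
        c[0, :] = np.nan
        once, u1 = clean_matrix(ContactMatrix(g, c))
        twice, u2 = clean_matrix(once)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert u1 == u2


class TestReadBedgraphBinned:
    def test_full_bin_interval(self, g3, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t0\t10000\t4.0\n")
        t = read_bedgraph_binned(p, g3)
        assert t.values[0] == 4.0

    def test_weighted_mean_of_split_intervals(self, g3, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t0\t5000\t2.0\nchr1\t5000\t10000\t6.0\n")
        t = read_bedgraph_binned(p, g3)
        assert t.values[0] == pytest.approx(4.0)

    def test_uncovered_bin_is_zero(self, tmp_path):
        g = GenomeGrid("chr1", 10_000, 10)
        p = tmp_path / "c.bg"
        p.write_text("chr1\t0\t10000\t1.0\n")
        assert read_bedgraph_binned(p, g).values[7] == 0.0

    def test_interval_spanning_bins_splits_proportionally(self, g3, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t5000\t25000\t2.0\n")
        t = read_bedgraph_binned(p, g3)
        np.testing.assert_allclose(t.values, [1.0, 2.0, 1.0])

    def test_other_chromosome_rows_skipped(self, g3, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr2\t0\t10000\t9.0\nchr1\t0\t10000\t1.0\n")
        t = read_bedgraph_binned(p, g3)
        assert t.values[0] == 1.0

    def test_signal_conservation_on_tiling_intervals(self, tmp_path):
        """sum(values) * r == sum(value * length) when intervals tile the grid."""
        rng = np.random.default_rng(3)
        g = GenomeGrid("chr1", 10_000, 30)
        edges = np.sort(
            rng.choice(np.arange(1, 300) * 1000, size=25, replace=False)
        )
        edges = np.concatenate([[0], edges, [300_000]])
        total = 0.0
        p = tmp_path / "c.bg"
        with open(p, "wt") as fh:
            for s, e in zip(edges[:-1], edges[1:]):
                v = float(rng.random())
                fh.write(f"chr1\t{s}\t{e}\t{v}\n")
                total += v * (e - s)
        t = read_bedgraph_binned(p, g)
        assert t.values.sum() * 10_000 == pytest.approx(total)


class TestReadBedpe:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t10050\t19900\tchr1\t1000000\t1009000\n")
        pairs = read_bedpe(p)
        assert pairs == [AnchorPair("chr1", 10050, 19900, 1000000, 1009000)]

    def test_interchromosomal_dropped(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t100\tchr2\t0\t100\n")
        assert read_bedpe(p) == []

    def test_reversed_anchors_swapped(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t1000000\t1009000\tchr1\t10050\t19900\n")
        (pair,) = read_bedpe(p)
        assert pair.start1 == 10050 and pair.start2 == 1000000

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t200\t300\nchr1\tx\ty\tchr1\t1\t2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bedpe(p)

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "a.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t200\t300\tloop1\t0.9\t+\t-\n")
        assert len(read_bedpe(p)) == 1


class TestWriteScoredBedpe:
    def test_bin_to_bp_arithmetic(self, tmp_path):
        g = GenomeGrid("chr", 10_000, 120)
        probs = np.zeros((120, 120))
        probs[1, 100] = probs[100, 1] = 0.9
        out = tmp_path / "o.bedpe"
        n = write_scored_bedpe(probs, g, out, min_score=0.5)
        assert n == 1
        assert out.read_text().strip() == "chr\t10000\t20000\tchr\t1000000\t1010000\t0.9"

    def test_min_score_above_one_writes_nothing(self, tmp_path):
        g = GenomeGrid("chr", 10_000, 5)
        n = write_scored_bedpe(np.ones((5, 5)), g, tmp_path / "o.bedpe", 1.1)
        assert n == 0

    def test_rows_sorted_by_descending_score(self, tmp_path):
        g = GenomeGrid("chr", 10_000, 10)
        probs = np.zeros((10, 10))
        probs[0, 3] = probs[3, 0] = 0.3
        probs[1, 5] = probs[5, 1] = 0.8
        out = tmp_path / "o.bedpe"
        assert write_scored_bedpe(probs, g, out, min_score=0.0) == 45
        first = out.read_text().splitlines()[0]
        assert first.endswith("0.8")
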