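import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from multiomecnv.bin_aggregation import (
    CellFeatureCounts,
    build_reference,
    combine_references,
    concat_modalities,
    fragments_to_bins,
    genes_to_bins,
    peaks_to_bins,
)


def make_features(rows):
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])


class TestGenesToBins:
    def test_genes_in_same_bin_are_summed(self, toy_bins):
        feats = make_features(
            [("g1", "chr1", 10_000, 20_000), ("g2", "chr1", 30_000, 40_000)]
        )
        m = CellFeatureCounts(["c1"], feats, sp.csr_matrix([[3, 4]]), "RNA")
        out = genes_to_bins(m, toy_bins)
        assert out.counts[0, 0] == 7
        assert out.counts.sum() == 7

    def test_gene_outside_bins_dropped_and_ledgered(self, toy_bins):
        feats = make_features(
            [("g1", "chr1", 10_000, 20_000), ("g2", "chr9", 0, 10_000)]
        )
        m = CellFeatureCounts(["c1", "c2"], feats, sp.csr_matrix([[3, 5], [1, 2]]), "RNA")
        out = genes_to_bins(m, toy_bins)
        assert out.counts.sum() == 4  # column sums minus dropped gene counts
        assert list(out.dropped["feature_id"]) == ["g2"]
        assert out.dropped["total_count"].iloc[0] == 7

    def test_boundary_spanning_gene_goes_to_maximal_overlap_bin(self, toy_bins):
        # gene spans b1 (60%) and b2 (40%): all counts to b1
        feats = make_features([("g1", "chr1", 140_000, 240_000)])
        m = CellFeatureCounts(["c1"], feats, sp.csr_matrix([[10]]), "RNA")
        out = genes_to_bins(m, toy_bins)
        assert out.counts[0, 0] == 10
        assert out.counts[0, 1] == 0

    def test_wrong_modality_rejected(self, toy_bins):
        feats = make_features([("p1", "chr1", 0, 100)])
        m = CellFeatureCounts(["c1"], feats, sp.csr_matrix([[1]]), "ATAC")
        with pytest.raises(ValueError, match="RNA"):
            genes_to_bins(m, toy_bins)


class TestPeaksToBins:
    def test_peaks_summed_and_dropped(self, toy_bins):
        feats = make_features(
            [("p1", "chr1", 10_000, 10_500), ("p2", "chr1", 20_000, 20_500),
             ("p3", "chr9", 0, 500)]
        )
        m = CellFeatureCounts(["c1"], feats, sp.csr_matrix([[1, 5, 9]]), "ATAC")
        out = peaks_to_bins(m, toy_bins)
        assert out.counts[0, 0] == 6
        assert out.counts.sum() == 6

    def test_consistent_with_fragments_of_same_peaks(self, toy_bins):
        """Aggregating a peak matrix vs the raw fragments behind it must agree."""
        rng = np.random.default_rng(11)
        peak_rows = [("p1", "chr1", 50_000, 50_400), ("p2", "chr1", 350_000, 350_400)]
        counts = rng.integers(0, 6, size=(3, 2))
        cells = ["c1", "c2", "c3"]
        m = CellFeatureCounts(cells, make_features(peak_rows), sp.csr_matrix(counts), "ATAC")
        via_peaks = peaks_to_bins(m, toy_bins)
        frag_rows = []
        for ci, cell in enumerate(cells):
            for pi, (_, chrom, s, e) in enumerate(peak_rows):
                for _ in range(counts[ci, pi]):
                    frag_rows.append((chrom, s, e, cell, 1))
        frags = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "barcode", "count"])
        via_frags = fragments_to_bins(frags, toy_bins, barcodes=cells)
        assert np.array_equal(
            np.asarray(via_peaks.counts.todense()), np.asarray(via_frags.counts.todense())
        )


class TestFragmentsToBins:
    def test_midpoint_assignment_and_count_column(self, toy_bins):
        frags = pd.DataFrame(
            [("chr1", 390_000, 410_010, "c1", 2)],
            columns=["chrom", "start", "end", "barcode", "count"],
        )
        out = fragments_to_bins(frags, toy_bins)
        # midpoint 400005 falls in bin 2 ([400k, 600k))
        assert out.counts[0, 2] == 2

    def test_midpoint_on_boundary_goes_to_right_bin(self, toy_bins):
        frags = pd.DataFrame(
            [("chr1", 190_000, 210_000, "c1", 1)],
            columns=["chrom", "start", "end", "barcode", "count"],
        )
        out = fragments_to_bins(frags, toy_bins)
        assert out.counts[0, 1] == 1  # midpoint 200000 -> second bin (half-open)

    def test_negative_coordinates_rejected(self, toy_bins):
        frags = pd.DataFrame(
            [("chr1", -5, 10, "c1", 1)],
            columns=["chrom", "start", "end", "barcode", "count"],
        )
        with pytest.raises(ValueError, match="negative"):
            fragments_to_bins(frags, toy_bins)

    def test_disallowed_barcodes_skipped(self, toy_bins):
        frags = pd.DataFrame(
            [("chr1", 0, 100, "good", 1), ("chr1", 0, 100, "bad", 5)],
            columns=["chrom", "start", "end", "barcode", "count"],
        )
        out = fragments_to_bins(frags, toy_bins, barcodes=["good"])
        assert out.counts.sum() == 1

    def test_uniform_fragments_split_evenly(self, toy_bins):
        rng = np.random.default_rng(5)
        pos = rng.integers(0, 400_000, size=1000)
        frags = pd.DataFrame(
            {"chrom": "chr1", "start": pos, "end": pos + 1, "barcode": "c1", "count": 1}
        )
        out = fragments_to_bins(frags, toy_bins)
        # binomial(1000, .5) 99% interval ~ [459, 541]
        assert 459 <= out.counts[0, 0] <= 541
        assert out.counts[0, 0] + out.counts[0, 1] == 1000


class TestConcatModalities:
    def test_rows_stack_and_barcodes_get_modality_suffix(self, toy_bins):
        rna = fragments_to_bins(
            pd.DataFrame([("chr1", 0, 100, "AAAC", 1)],
                         columns=["chrom", "start", "end", "barcode", "count"]),
            toy_bins, modality="RNA",
        )
        atac = fragments_to_bins(
            pd.DataFrame([("chr1", 0, 100, "AAAC", 2)],
                         columns=["chrom", "start", "end", "barcode", "count"]),
            toy_bins, modality="ATAC",
        )
        both = concat_modalities(rna, atac)
        assert list(both.cells["cell"]) == ["AAAC#RNA", "AAAC#ATAC"]
        assert both.counts.shape == (2, len(toy_bins))
        assert both.counts.sum() == 3

    def test_mismatched_bins_rejected(self, toy_bins):
        import multiomecnv.genome_bins as gb

        other = gb.BinSet(
            pd.DataFrame([("chr1", 0, 100_000)], columns=["chrom", "start", "end"])
        )
        rna = fragments_to_bins(
            pd.DataFrame([("chr1", 0, 100, "a", 1)],
                         columns=["chrom", "start", "end", "barcode", "count"]),
            toy_bins, modality="RNA",
        )
        atac = fragments_to_bins(
            pd.DataFrame([("chr1", 0, 100, "a", 1)],
                         columns=["chrom", "start", "end", "barcode", "count"]),
            other, modality="ATAC",
        )
        with pytest.raises(ValueError, match="differ"):
            concat_modalities(rna, atac)


class TestReference:
    def _counts(self, toy_bins, mat, cells, modality="RNA"):
        from multiomecnv.bin_aggregation import CellBinCounts

        return CellBinCounts(
            pd.DataFrame({"cell": cells, "modality": modality}),
            toy_bins,
            sp.csr_matrix(mat),
        )

    def test_single_cell_normalization(self, toy_bins):
        mat = np.zeros((1, len(toy_bins)))
        mat[0, :2] = [2, 8]
        ref = build_reference(self._counts(toy_bins, mat, ["c1"]), {"c1": "t"})
        assert np.allclose(ref.column("t")[:2], [0.2, 0.8])
        assert np.isclose(ref.column("t").sum(), 1.0)

    def test_subsampling_cap_and_determinism(self, toy_bins):
        rng = np.random.default_rng(0)
        n = 40
        mat = rng.integers(0, 5, size=(n, len(toy_bins)))
        cells = [f"c{i}" for i in range(n)]
        labels = {c: "t" for c in cells}
        counts = self._counts(toy_bins, mat, cells)
        r1 = build_reference(counts, labels, max_per_type=10, seed=123)
        r2 = build_reference(counts, labels, max_per_type=10, seed=123)
        r3 = build_reference(counts, labels, max_per_type=10, seed=124)
        assert r1.rates.equals(r2.rates)
        assert not r1.rates.equals(r3.rates)  # different subsample, same data

    def test_two_labels_two_columns(self, toy_bins):
        mat = np.ones((4, len(toy_bins)))
        cells = ["a", "b", "c", "d"]
        ref = build_reference(
            self._counts(toy_bins, mat, cells), {"a": "x", "b": "x", "c": "y", "d": "y"}
        )
        assert sorted(ref.labels) == ["x", "y"]
        assert np.allclose(ref.rates.sum(axis=0), 1.0)

    def test_unknown_cell_rejected(self, toy_bins):
        mat = np.ones((1, len(toy_bins)))
        with pytest.raises(ValueError, match="without a type"):
            build_reference(self._counts(toy_bins, mat, ["c1"]), {"other": "t"})

    def test_combine_references_suffixes_and_preserves_sums(self, toy_bins):
        mat = np.ones((1, len(toy_bins)))
        rna = build_reference(self._counts(toy_bins, mat, ["c1"]), {"c1": "t"})
        atac = build_reference(self._counts(toy_bins, mat * 3, ["c1"], "ATAC"), {"c1": "t"})
        both = combine_references(rna, atac)
        assert list(both.labels) == ["t#RNA", "t#ATAC"]
        assert np.allclose(both.rates.sum(axis=0), 1.0)
        assert np.allclose(both.rates["t#RNA"].values, rna.rates["t"].values)


def test_count_conservation_property(toy_bins):
    """Total output counts equal input counts minus the dropped ledger."""
    rng = np.random.default_rng(3)
    feats = make_features(
        [("g1", "chr1", 10_000, 20_000), ("g2", "chr1", 950_000, 1_100_000),
         ("g3", "chr5", 0, 1000)]
    )
    mat = rng.integers(0, 10, size=(6, 3))
    m = CellFeatureCounts([f"c{i}" for i in range(6)], feats, sp.csr_matrix(mat), "RNA")
    out = genes_to_bins(m, toy_bins)
    assert out.counts.sum() + out.dropped["total_count"].sum() == mat.sum()
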