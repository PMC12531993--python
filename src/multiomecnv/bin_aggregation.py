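"""Projection of per-modality count data onto the shared bin space.

Genes, ATAC peaks and ATAC fragments are mapped onto the common BinSet:
features (genes/peaks) go to the single bin with maximal overlap (ties to the
lower-coordinate bin) so no molecule is double counted; fragments go to the
bin containing their midpoint.  RNA and ATAC cell-by-bin matrices share the
bin columns and are concatenated vertically, and normalized per-cell-type
reference profiles are built from annotated normal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_bins import BinSet, GenomicInterval

__all__ = [
    "CellFeatureCounts",
    "CellBinCounts",
    "ReferenceProfile",
    "genes_to_bins",
    "peaks_to_bins",
    "fragments_to_bins",
    "concat_modalities",
    "build_reference",
    "combine_references",
    "MODALITY_SEP",
]

MODALITY_SEP = "#"
DEFAULT_MAX_CELLS_PER_TYPE = 1500
DEFAULT_REFERENCE_SEED = 123


def _as_csr(m) -> sp.csr_matrix:
    m = sp.csr_matrix(m)
    if (m.data < 0).any():
        raise ValueError("counts must be non-negative")
    return m


@dataclass
class CellFeatureCounts:
    """Sparse cells x features counts with optional feature coordinates."""

    cells: list[str]
    features: pd.DataFrame  # columns: feature_id [, chrom, start, end]
    counts: sp.csr_matrix
    modality: str  # "RNA" | "ATAC"

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.cells)}, {len(self.features)})"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")


@dataclass
class CellBinCounts:
    """Sparse cells x bins counts tagged with per-cell modality (and sample)."""

    cells: pd.DataFrame  # columns: cell, modality [, sample]
    binset: BinSet
    counts: sp.csr_matrix
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature_id", "reason", "total_count"]
        )
    )

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        if self.counts.shape != (len(self.cells), len(self.binset)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.cells)}, {len(self.binset)})"
            )
        if self.cells["cell"].duplicated().any():
            raise ValueError("duplicate cell barcodes")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell"].values

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_ids) -> "CellBinCounts":
        if isinstance(mask_or_ids, (list, set, pd.Index, np.ndarray)) and not (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool
        ):
            mask = self.cells["cell"].isin(list(mask_or_ids)).values
        else:
            mask = np.asarray(mask_or_ids)
        return CellBinCounts(
            self.cells.loc[mask].reset_index(drop=True),
            self.binset,
            self.counts[mask],
            self.dropped,
        )


@dataclass
class ReferenceProfile:
    """Normalized expected rates per bin (rows) and cell type (columns).

    Each column sums to one: it is the expected fraction of a diploid cell's
    molecules falling in each bin for that cell type (and modality).
    """

    rates: pd.DataFrame  # index: bin_id, columns: cell-type labels

    def __post_init__(self):
        if (self.rates.values < 0).any():
            raise ValueError("reference rates must be non-negative")
        sums = self.rates.sum(axis=0)
        if not np.allclose(sums.values, 1.0, atol=1e-9):
            raise ValueError(f"reference columns must sum to 1, got {sums.to_dict()}")

    @property
    def labels(self) -> list[str]:
        return list(self.rates.columns)

    def column(self, label: str) -> np.ndarray:
        return self.rates[label].values


def _features_to_bin_index(
    features: pd.DataFrame, binset: BinSet
) -> tuple[np.ndarray, pd.DataFrame]:
    """Maximal-overlap bin index per feature (-1 = unassigned) + drop report."""
    needed = {"chrom", "start", "end"}
    if not needed.issubset(features.columns):
        raise ValueError("features need chrom/start/end coordinates for binning")
    assign = np.full(len(features), -1, dtype=np.int64)
    reasons = np.full(len(features), "", dtype=object)
    starts = binset.df["start"].values
    ends = binset.df["end"].values
    for i, f in enumerate(features.itertuples(index=False)):
        if pd.isna(f.chrom) or pd.isna(f.start) or pd.isna(f.end):
            reasons[i] = "missing_coordinates"
            continue
        iv = GenomicInterval(str(f.chrom), int(f.start), int(f.end))
        cand = binset.overlapping_bins(iv)
        if len(cand) == 0:
            reasons[i] = "no_overlapping_bin"
            continue
        ov = np.minimum(ends[cand], iv.end) - np.maximum(starts[cand], iv.start)
        # ties break to the lower-coordinate bin via argmax's first-hit rule
        assign[i] = cand[int(np.argmax(ov))]
    report = pd.DataFrame(
        {"feature_id": features["feature_id"].values, "reason": reasons}
    )
    return assign, report[report["reason"] != ""].reset_index(drop=True)


def _aggregate_features(m: CellFeatureCounts, binset: BinSet) -> CellBinCounts:
    assign, report = _features_to_bin_index(m.features, binset)
    keep = assign >= 0
    if not keep.any():
        raise ValueError("no feature overlaps any bin")
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    report = report.merge(
        pd.DataFrame({"feature_id": m.features["feature_id"], "total_count": totals}),
        on="feature_id",
        how="left",
    )
    # features -> bins is a sparse projection matrix multiply
    proj = sp.csr_matrix(
        (
            np.ones(int(keep.sum())),
            (np.nonzero(keep)[0], assign[keep]),
        ),
        shape=(len(m.features), len(binset)),
    )
    out = sp.csr_matrix(m.counts @ proj)
    cells = pd.DataFrame({"cell": m.cells, "modality": m.modality})
    return CellBinCounts(cells, binset, out, dropped=report)


def genes_to_bins(m: CellFeatureCounts, binset: BinSet) -> CellBinCounts:
    """Aggregate a cell-by-gene matrix into cell-by-bin counts.

    Each gene's counts go entirely to the single bin with which the gene body
    has maximal overlap; genes overlapping no bin are dropped and reported in
    the ``dropped`` ledger of the result.
    """
    if m.modality != "RNA":
        raise ValueError(f"genes_to_bins expects RNA counts, got {m.modality}")
    return _aggregate_features(m, binset)


def peaks_to_bins(m: CellFeatureCounts, binset: BinSet) -> CellBinCounts:
    """Aggregate a cell-by-peak matrix into cell-by-bin counts (same rule as genes)."""
    if m.modality != "ATAC":
        raise ValueError(f"peaks_to_bins expects ATAC counts, got {m.modality}")
    return _aggregate_features(m, binset)


def fragments_to_bins(
    fragments, binset: BinSet, barcodes=None, modality: str = "ATAC"
) -> CellBinCounts:
    """Accumulate an ATAC fragment table into cell-by-bin counts.

    ``fragments`` is a DataFrame or TSV path with columns
    (chrom, start, end, barcode[, count]), the 10x fragments dialect.  Each
    fragment is assigned to the bin containing its midpoint, which avoids
    double counting fragments that straddle a bin edge.  ``barcodes``
    restricts to an allowed set (rows outside it are skipped).
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = pd.read_csv(
            fragments,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "barcode", "count"],
        )
    frags = fragments.copy()
    if "count" not in frags.columns or frags["count"].isna().all():
        frags["count"] = 1
    frags["count"] = frags["count"].fillna(1).astype(np.int64)
    if (frags["start"] < 0).any() or (frags["end"] < 0).any():
        raise ValueError("negative fragment coordinates")
    if barcodes is not None:
        frags = frags[frags["barcode"].isin(set(barcodes))]
        cell_list = list(barcodes)
    else:
        cell_list = sorted(frags["barcode"].unique())
    cell_index = {c: i for i, c in enumerate(cell_list)}
    mid = ((frags["start"].values + frags["end"].values) // 2).astype(np.int64)
    bin_idx = np.full(len(frags), -1, dtype=np.int64)
    for chrom in frags["chrom"].unique():
        sel = frags["chrom"].values == chrom
        bin_idx[sel] = binset.find_bin(chrom, mid[sel])
    keep = bin_idx >= 0
    rows = frags["barcode"].map(cell_index).values[keep]
    mat = sp.coo_matrix(
        (frags["count"].values[keep], (rows, bin_idx[keep])),
        shape=(len(cell_list), len(binset)),
    ).tocsr()
    n_dropped = int(frags["count"].values[~keep].sum())
    dropped = pd.DataFrame(
        {"feature_id": ["<fragments_outside_bins>"], "reason": ["no_overlapping_bin"],
         "total_count": [n_dropped]}
    ) if n_dropped else pd.DataFrame(columns=["feature_id", "reason", "total_count"])
    cells = pd.DataFrame({"cell": cell_list, "modality": modality})
    return CellBinCounts(cells, binset, mat, dropped=dropped)


def _check_same_bins(a: BinSet, b: BinSet) -> None:
    if len(a) != len(b) or not (
        (a.df["chrom"].values == b.df["chrom"].values).all()
        and (a.df["start"].values == b.df["start"].values).all()
        and (a.df["end"].values == b.df["end"].values).all()
    ):
        n = min(len(a), len(b))
        for i in range(n):
            ra, rb = a.df.iloc[i], b.df.iloc[i]
            if tuple(ra[["chrom", "start", "end"]]) != tuple(rb[["chrom", "start", "end"]]):
                raise ValueError(
                    f"bin sets differ at index {i}: "
                    f"{ra['chrom']}:{ra['start']}-{ra['end']} vs "
                    f"{rb['chrom']}:{rb['start']}-{rb['end']}"
                )
        raise ValueError(f"bin sets differ in length: {len(a)} vs {len(b)}")


def tag_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Suffix barcodes with their modality (``AAAC`` -> ``AAAC#RNA``)."""
    cells = cells.copy()
    untagged = ~cells["cell"].str.contains(MODALITY_SEP, regex=False)
    cells.loc[untagged, "cell"] = (
        cells.loc[untagged, "cell"] + MODALITY_SEP + cells.loc[untagged, "modality"]
    )
    return cells


def concat_modalities(rna: CellBinCounts, atac: CellBinCounts) -> CellBinCounts:
    """Vertically concatenate RNA and ATAC cell-by-bin matrices.

    Both inputs must share the identical bin set; barcodes are suffixed with
    the modality tag so a cell profiled in both assays keeps two distinct rows.
    """
    _check_same_bins(rna.binset, atac.binset)
    cells = pd.concat([tag_cells(rna.cells), tag_cells(atac.cells)], ignore_index=True)
    counts = sp.vstack([rna.counts, atac.counts]).tocsr()
    dropped = pd.concat([rna.dropped, atac.dropped], ignore_index=True)
    return CellBinCounts(cells, rna.binset, counts, dropped=dropped)


def build_reference(
    m: CellBinCounts,
    cell_types: dict | pd.Series,
    max_per_type: int = DEFAULT_MAX_CELLS_PER_TYPE,
    seed: int = DEFAULT_REFERENCE_SEED,
) -> ReferenceProfile:
    """Build a normalized bin-by-cell-type reference from annotated cells.

    Per cell type: subsample without replacement to ``max_per_type`` when the
    type has more cells (seeded, hence deterministic), sum raw counts over the
    sampled cells, and divide by the total so every column sums to one.
    """
    cell_types = pd.Series(cell_types)
    ids = pd.Series(m.cell_ids)
    unknown = ~ids.isin(cell_types.index)
    if unknown.any():
        raise ValueError(f"cells without a type label: {ids[unknown].tolist()[:5]}")
    rng = np.random.default_rng(seed)
    cols = {}
    labels = cell_types.loc[ids].values
    for label in pd.unique(labels):
        idx = np.nonzero(labels == label)[0]
        if len(idx) > max_per_type:
            idx = np.sort(rng.choice(idx, size=max_per_type, replace=False))
        summed = np.asarray(m.counts[idx].sum(axis=0)).ravel().astype(float)
        total = summed.sum()
        if total <= 0:
            raise ValueError(f"cell type {label!r} has zero total counts")
        cols[str(label)] = summed / total
    rates = pd.DataFrame(cols, index=m.binset.bin_ids)
    return ReferenceProfile(rates)


def combine_references(
    rna_ref: ReferenceProfile, atac_ref: ReferenceProfile
) -> ReferenceProfile:
    """Horizontally combine per-modality references for the combined-bin mode."""
    if not rna_ref.rates.index.equals(atac_ref.rates.index):
        raise ValueError("references built on different bin sets")
    left = rna_ref.rates.add_suffix(f"{MODALITY_SEP}RNA")
    right = atac_ref.rates.add_suffix(f"{MODALITY_SEP}ATAC")
    return ReferenceProfile(pd.concat([left, right], axis=1))
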