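"""Per-SNP allele counts: modality merging, phasing, pseudobulk tracks.

Allele counts at heterozygous SNPs are merged across RNA and ATAC, attached
to a population-phased VCF (one haplotype arbitrarily labelled "paternal"),
and aggregated into pseudobulk haplotype tracks (a_j paternal reads out of
d_j total at SNP j, genome-ordered).  Population phasing carries
distance-dependent switch errors; the probability that the phase flips
between adjacent SNPs grows exponentially toward 1/2 with their separation,
which the HMM consumes via :func:`phase_switch_prob`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bin_aggregation import MODALITY_SEP
from .genome_bins import chrom_sort_key

__all__ = [
    "CellSnpAlleleCounts",
    "PseudobulkAlleleTrack",
    "merge_modality_allele_counts",
    "read_phased_vcf",
    "attach_phase",
    "pseudobulk_haplotype_counts",
    "phase_switch_prob",
    "DEFAULT_NU_BP",
]

DEFAULT_NU_BP = 1e7  # phase-switch length scale; switch prob 0.5*(1-exp(-d/nu))

COUNT_COLUMNS = [
    "cell", "modality", "snp_id", "chrom", "pos", "ref", "alt",
    "ref_count", "alt_count",
]


@dataclass
class CellSnpAlleleCounts:
    """Long-format per-cell per-SNP ref/alt counts (one modality per row)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(COUNT_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"allele counts missing columns {sorted(missing)}")
        df = self.df
        if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
            raise ValueError("allele counts must be non-negative")
        if df.duplicated(subset=["cell", "modality", "snp_id"]).any():
            raise ValueError("duplicate (cell, modality, snp) records")
        # one (ref, alt) definition per SNP id
        defs = df[["snp_id", "ref", "alt"]].drop_duplicates()
        if defs["snp_id"].duplicated().any():
            bad = defs.loc[defs["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"conflicting ref/alt definitions for SNP {bad!r}")

    @classmethod
    def from_tsv(cls, path) -> "CellSnpAlleleCounts":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def merge_modality_allele_counts(
    rna: CellSnpAlleleCounts, atac: CellSnpAlleleCounts
) -> CellSnpAlleleCounts:
    """Union RNA- and ATAC-derived allele counts under modality-tagged barcodes.

    A cell profiled in both assays keeps two rows per SNP, suffixed
    ``AAAC#RNA`` / ``AAAC#ATAC`` to stay consistent with the vertical
    concatenation of the bin-count matrices.
    """
    parts = []
    for part in (rna, atac):
        df = part.df.copy()
        untagged = ~df["cell"].str.contains(MODALITY_SEP, regex=False)
        df.loc[untagged, "cell"] = (
            df.loc[untagged, "cell"] + MODALITY_SEP + df.loc[untagged, "modality"]
        )
        parts.append(df)
    return CellSnpAlleleCounts(pd.concat(parts, ignore_index=True))


def read_phased_vcf(path) -> pd.DataFrame:
    """Read phased heterozygous genotypes from a VCF.

    Returns a DataFrame (chrom, pos, ref, alt, paternal_is_ref) with ``pos``
    converted to 0-based.  Haplotype 1 of the GT field is taken as the
    arbitrarily-labelled paternal haplotype.  Homozygous and unphased sites
    are skipped.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = var.genotypes[0]  # [hap1, hap2, phased]
        if len(g) < 3 or not g[2]:
            continue
        if g[0] == g[1]:
            continue
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alt": var.ALT[0],
                "paternal_is_ref": g[0] == 0,
            }
        )
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "paternal_is_ref"])


def attach_phase(
    counts: CellSnpAlleleCounts, phased: pd.DataFrame | str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach population phase: per record, the paternal-haplotype read count.

    ``phased`` is a phased VCF path or the DataFrame from
    :func:`read_phased_vcf`.  Returns ``(phased_records, dropped)`` where
    ``phased_records`` adds columns ``pat_count`` (reads on the paternal
    haplotype) and ``total_count``, and ``dropped`` lists records at SNPs
    absent from the VCF (or unphased/homozygous there).
    """
    if not isinstance(phased, pd.DataFrame):
        phased = read_phased_vcf(phased)
    df = counts.df.merge(
        phased[["chrom", "pos", "ref", "alt", "paternal_is_ref"]],
        on=["chrom", "pos", "ref", "alt"],
        how="left",
    )
    dropped = df[df["paternal_is_ref"].isna()].drop(columns="paternal_is_ref")
    kept = df[df["paternal_is_ref"].notna()].copy()
    kept["pat_count"] = np.where(
        kept["paternal_is_ref"].astype(bool), kept["ref_count"], kept["alt_count"]
    )
    kept["total_count"] = kept["ref_count"] + kept["alt_count"]
    kept = kept.drop(columns="paternal_is_ref")
    return kept.reset_index(drop=True), dropped.reset_index(drop=True)


@dataclass
class PseudobulkAlleleTrack:
    """Genome-ordered pseudobulk SNP track: (chrom, pos, a, d, dist).

    ``a`` is the paternal count, ``d`` the total depth and ``dist`` the bp
    distance to the previous SNP on the same chromosome (0 for the first).
    """

    df: pd.DataFrame

    def __post_init__(self):
        need = {"chrom", "pos", "a", "d", "dist"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"allele track missing columns {sorted(missing)}")
        if (self.df["a"] > self.df["d"]).any():
            raise ValueError("paternal count exceeds depth")
        if (self.df["dist"] < 0).any():
            raise ValueError("negative inter-SNP distance")

    def __len__(self) -> int:
        return len(self.df)


def _add_snp_distances(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["_key"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_key", "pos"], kind="stable").drop(columns="_key")
    df = df.reset_index(drop=True)
    dist = df["pos"].diff()
    first = df["chrom"] != df["chrom"].shift()
    dist[first] = 0
    df["dist"] = dist.astype(np.int64)
    return df


def pseudobulk_haplotype_counts(
    phased_records: pd.DataFrame, cells=None, min_depth: int = 1
) -> PseudobulkAlleleTrack:
    """Sum phased per-cell allele counts over a cell subset into a track.

    ``phased_records`` comes from :func:`attach_phase`; ``cells`` selects the
    pseudobulk (None = all cells).  SNPs with pooled depth below ``min_depth``
    are omitted.
    """
    df = phased_records
    if cells is not None:
        cells = list(cells)
        if len(cells) == 0:
            raise ValueError("empty pseudobulk cell subset")
        df = df[df["cell"].isin(set(cells))]
    pooled = (
        df.groupby(["chrom", "pos"], sort=False)
        .agg(a=("pat_count", "sum"), d=("total_count", "sum"))
        .reset_index()
    )
    pooled = pooled[pooled["d"] >= min_depth]
    return PseudobulkAlleleTrack(_add_snp_distances(pooled))


def phase_switch_prob(distance, nu: float = DEFAULT_NU_BP):
    """Probability the population phase flips across a gap of ``distance`` bp.

    p(d) = 0.5 * (1 - exp(-d / nu)): zero at d=0, saturating at 1/2 (random
    phase) for distant SNPs, the exponential decay of population-phasing
    accuracy with inter-SNP distance.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    d = np.asarray(distance, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    p = 0.5 * (1.0 - np.exp(-d / nu))
    return float(p) if np.isscalar(distance) or d.ndim == 0 else p
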