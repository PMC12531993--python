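"""Genomic coordinate system: bins, chromosome arms and cytobands.

Every modality (RNA genes, ATAC fragments/peaks, SNP allele counts) is
projected onto one shared, non-overlapping, genome-ordered bin set, so the
whole pipeline speaks a single coordinate language.  All coordinates are
0-based half-open, matching BED; VCF positions are converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "BinSet",
    "ChromArmTable",
    "CytobandTable",
    "overlap_length",
    "load_bin_set",
    "assign_arm",
    "cytoband_label",
    "make_uniform_bins",
    "hg38_arm_table",
    "default_bin_set",
    "chrom_sort_key",
]

DEFAULT_TELOMERE_TRIM_BP = 10_000
DEFAULT_BIN_SIZE_BP = 220_000

_CHROM_RE = re.compile(r"^(?:chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: chr1..chr22, chrX, chrY, then lexicographic."""
    m = _CHROM_RE.match(chrom)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), "")
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
        return (0, order[tok], "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap between two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class BinSet:
    """Ordered, non-overlapping genomic bins: the shared feature space.

    Backed by a DataFrame with columns (chrom, start, end, bin_id), sorted by
    (chrom, start) under natural chromosome order.
    """

    def __init__(self, df: pd.DataFrame, genome_build: str = "custom"):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"bin table needs columns {sorted(required)}")
        df = df.copy()
        if "bin_id" not in df.columns:
            df["bin_id"] = [f"b{i + 1}" for i in range(len(df))]
        if df["bin_id"].duplicated().any():
            dup = df.loc[df["bin_id"].duplicated(), "bin_id"].iloc[0]
            raise ValueError(f"duplicate bin id {dup!r}")
        df["_key"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values(["_key", "start"], kind="stable").drop(columns="_key")
        df = df.reset_index(drop=True)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValueError("bins must satisfy 0 <= start < end")
        same = df["chrom"].values[1:] == df["chrom"].values[:-1]
        if np.any(same & (df["start"].values[1:] < df["end"].values[:-1])):
            i = int(np.nonzero(same & (df["start"].values[1:] < df["end"].values[:-1]))[0][0])
            raise ValueError(
                f"overlapping bins on {df['chrom'].iloc[i]}: "
                f"[{df['start'].iloc[i]},{df['end'].iloc[i]}) and "
                f"[{df['start'].iloc[i + 1]},{df['end'].iloc[i + 1]})"
            )
        self.df = df[["chrom", "start", "end", "bin_id"]]
        self.genome_build = genome_build
        # per-chromosome index for O(log n) point/interval lookups
        self._chrom_slices: dict[str, tuple[int, int]] = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            self._chrom_slices[chrom] = (int(grp.index[0]), int(grp.index[-1]) + 1)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinSet)
            and self.genome_build == other.genome_build
            and self.df.equals(other.df)
        )

    @property
    def bin_ids(self) -> np.ndarray:
        return self.df["bin_id"].values

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).values

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].values + self.df["end"].values) // 2).astype(np.int64)

    def find_bin(self, chrom: str, pos) -> np.ndarray:
        """Global bin index containing each position, -1 when uncovered."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        out = np.full(pos.shape, -1, dtype=np.int64)
        if chrom not in self._chrom_slices:
            return out
        lo, hi = self._chrom_slices[chrom]
        starts = self.df["start"].values[lo:hi]
        ends = self.df["end"].values[lo:hi]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = idx[ok] + lo
        return out

    def overlapping_bins(self, iv: GenomicInterval) -> np.ndarray:
        """Global indices of all bins overlapping the interval."""
        if iv.chrom not in self._chrom_slices:
            return np.empty(0, dtype=np.int64)
        lo, hi = self._chrom_slices[iv.chrom]
        starts = self.df["start"].values[lo:hi]
        ends = self.df["end"].values[lo:hi]
        first = np.searchsorted(ends, iv.start, side="right")
        last = np.searchsorted(starts, iv.end, side="left")
        return np.arange(lo + first, lo + last, dtype=np.int64)

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end", "bin_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def load_bin_set(path, genome_build: str = "custom") -> BinSet:
    """Read a bin set from a BED file (3+ columns, 4th column used as bin id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4 and parts[3]:
                row["bin_id"] = parts[3]
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no bins found")
    df = pd.DataFrame(rows)
    if "bin_id" in df.columns and df["bin_id"].isna().any():
        df = df.drop(columns="bin_id")
    return BinSet(df, genome_build=genome_build)


class ChromArmTable:
    """Per-chromosome p-arm, q-arm and centromere intervals.

    The centromere is the gap [p_end, q_start); arm tables already exclude it,
    mirroring the acen-region convention of cytogenetic annotation files.
    """

    COLUMNS = ["chrom", "p_start", "p_end", "q_start", "q_end", "length"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"arm table missing columns {sorted(missing)}")
        df = df.copy()
        df["_key"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values("_key").drop(columns="_key").reset_index(drop=True)
        bad = ~(
            (df["p_start"] >= 0)
            & (df["p_start"] <= df["p_end"])
            & (df["p_end"] <= df["q_start"])
            & (df["q_start"] <= df["q_end"])
            & (df["q_end"] <= df["length"])
        )
        if bad.any():
            raise ValueError(f"inconsistent arm rows for {df.loc[bad, 'chrom'].tolist()}")
        self.df = df[self.COLUMNS]
        self._by_chrom = {r.chrom: r for r in df.itertuples()}

    @classmethod
    def from_tsv(cls, path) -> "ChromArmTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def chroms(self) -> list[str]:
        return self.df["chrom"].tolist()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_chrom

    def chrom_length(self, chrom: str) -> int:
        return int(self._by_chrom[chrom].length)

    def centromere(self, chrom: str) -> GenomicInterval | None:
        r = self._by_chrom[chrom]
        if r.p_end < r.q_start:
            return GenomicInterval(chrom, int(r.p_end), int(r.q_start))
        return None

    def arm_interval(
        self, chrom: str, arm: str, telomere_trim_bp: int = 0
    ) -> GenomicInterval | None:
        """Arm interval, optionally with the terminal telomere-side trim applied."""
        if chrom not in self._by_chrom:
            raise KeyError(f"chromosome {chrom!r} not in arm table")
        r = self._by_chrom[chrom]
        if arm == "p":
            start, end = int(r.p_start) + telomere_trim_bp, int(r.p_end)
        elif arm == "q":
            start, end = int(r.q_start), int(r.q_end) - telomere_trim_bp
        else:
            raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")
        if start >= end:
            return None
        return GenomicInterval(chrom, start, end)


def assign_arm(
    iv: GenomicInterval,
    arms: ChromArmTable,
    telomere_trim_bp: int = DEFAULT_TELOMERE_TRIM_BP,
) -> tuple[str, int]:
    """Assign an interval to a chromosome arm by majority overlap.

    The last ``telomere_trim_bp`` of each arm (telomere side) is excluded both
    from the overlap computation and from the returned effective arm length,
    so telomeric scraps never drive arm-fraction statistics.  Returns
    ``(arm, effective_arm_length)``; arm is ``"p"``, ``"q"`` or
    ``"unassigned"`` (centromere/trimmed-telomere only).  Ties break to "p".
    """
    if iv.chrom not in arms:
        raise KeyError(f"chromosome {iv.chrom!r} not in arm table")
    best = ("unassigned", 0, -1)
    for arm in ("p", "q"):
        trimmed = arms.arm_interval(iv.chrom, arm, telomere_trim_bp=telomere_trim_bp)
        if trimmed is None:
            continue
        ov = overlap_length(iv, trimmed)
        if ov > best[2]:
            best = (arm, trimmed.length, ov)
    if best[2] <= 0:
        return "unassigned", 0
    return best[0], best[1]


class CytobandTable:
    """Cytogenetic bands tiling each chromosome (chrom, start, end, band, arm)."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end", "band"}
        if not required.issubset(df.columns):
            raise ValueError(f"cytoband table needs columns {sorted(required)}")
        df = df.copy()
        if "arm" not in df.columns:
            df["arm"] = df["band"].str[0]
        df["_key"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values(["_key", "start"]).drop(columns="_key").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if grp["band"].duplicated().any():
                raise ValueError(f"duplicate band label on {chrom}")
            if np.any(grp["start"].values[1:] < grp["end"].values[:-1]):
                raise ValueError(f"overlapping bands on {chrom}")
        self.df = df[["chrom", "start", "end", "band", "arm"]]

    @classmethod
    def from_bed(cls, path) -> "CytobandTable":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "band", "stain"],
            usecols=[0, 1, 2, 3],
        )
        return cls(df)

    @classmethod
    def uniform(cls, arms: ChromArmTable, n_bands_per_arm: int = 4) -> "CytobandTable":
        """Synthetic uniform band tiling derived from an arm table.

        Splits each arm into equal-width bands labelled p1..pN (telomere to
        centromere) and q1..qN (centromere to telomere), the orientation used
        by real karyotype tables.  A stand-in for build-specific cytoband
        files when only arm boundaries are known.
        """
        rows = []
        for chrom in arms.chroms:
            for arm in ("p", "q"):
                aiv = arms.arm_interval(chrom, arm)
                if aiv is None:
                    continue
                edges = np.linspace(aiv.start, aiv.end, n_bands_per_arm + 1).astype(int)
                for i in range(n_bands_per_arm):
                    # p-arm band numbering runs away from the centromere
                    num = n_bands_per_arm - i if arm == "p" else i + 1
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(edges[i]),
                            "end": int(edges[i + 1]),
                            "band": f"{arm}{num}",
                            "arm": arm,
                        }
                    )
        return cls(pd.DataFrame(rows))


def cytoband_label(iv: GenomicInterval, bands: CytobandTable) -> str:
    """Band-range label for an interval, e.g. ``"q21.1-q22"`` or ``"p11"``."""
    sub = bands.df[bands.df["chrom"] == iv.chrom]
    hit = sub[(sub["start"] < iv.end) & (sub["end"] > iv.start)]
    if hit.empty:
        raise KeyError(f"no cytoband overlaps {iv.chrom}:{iv.start}-{iv.end}")
    first, last = hit["band"].iloc[0], hit["band"].iloc[-1]
    return first if first == last else f"{first}-{last}"


def make_uniform_bins(
    arms: ChromArmTable,
    bin_size_bp: int = DEFAULT_BIN_SIZE_BP,
    genome_build: str = "custom",
    chroms: list[str] | None = None,
) -> BinSet:
    """Tile chromosome arms with fixed-size windows, truncating at arm ends.

    Windows never cross the centromere; the final window of each arm is
    truncated to the arm boundary, so the mean width sits slightly below
    ``bin_size_bp``.
    """
    rows = []
    for chrom in chroms if chroms is not None else arms.chroms:
        for arm in ("p", "q"):
            aiv = arms.arm_interval(chrom, arm)
            if aiv is None:
                continue
            pos = aiv.start
            while pos < aiv.end:
                end = min(pos + bin_size_bp, aiv.end)
                rows.append({"chrom": chrom, "start": pos, "end": end})
                pos = end
    df = pd.DataFrame(rows)
    df["bin_id"] = [f"b{i + 1}" for i in range(len(df))]
    return BinSet(df, genome_build=genome_build)


def hg38_arm_table() -> ChromArmTable:
    """The packaged hg38 chromosome-arm table (UCSC-style sizes/acen bounds)."""
    with resources.as_file(
        resources.files("multiomecnv.data") / "arm_table_hg38.tsv"
    ) as p:
        return ChromArmTable.from_tsv(p)


def default_bin_set(bin_size_bp: int = DEFAULT_BIN_SIZE_BP) -> BinSet:
    """Default genome-wide bin set: ~220-kb arm-truncated windows on hg38.

    Approximates the variable ~200-kb expression-unit bin sets used for
    single-cell CNV work; any user BED overrides it via :func:`load_bin_set`.
    Sex chromosomes are excluded by default (haploid coverage in males breaks
    the diploid-neutral baseline).
    """
    arms = hg38_arm_table()
    autosomes = [c for c in arms.chroms if c not in ("chrX", "chrY")]
    return make_uniform_bins(
        arms, bin_size_bp=bin_size_bp, genome_build="hg38", chroms=autosomes
    )
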