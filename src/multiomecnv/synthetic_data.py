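"""Seeded generator of paired RNA/ATAC multiome data with planted clonal CNVs.

Emulates the generative model the inference assumes: per-cell bin counts are
Poisson-log-normal around library size x baseline rate x clone dosage, and
per-SNP allele counts are beta-binomial around the clone's paternal
haplotype fraction, observed through a population-phased VCF whose phase
carries distance-dependent switch errors.  Every draw flows from one seed,
so identical configs give byte-identical data.  The default genome is a
desk-scale stand-in (six 60-Mb chromosomes) rather than hg38, keeping full
pipeline runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .allele_counts import CellSnpAlleleCounts
from .bin_aggregation import CellBinCounts, ReferenceProfile, build_reference
from .genome_bins import BinSet, ChromArmTable, make_uniform_bins

__all__ = [
    "EventSpec",
    "CloneSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedSample",
    "sim_genome",
    "simulate_baseline",
    "simulate_cells",
    "simulate_alleles",
    "simulate_sample",
    "default_cohort_config",
    "subclone_scenario_config",
    "chromothripsis_config",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

MODALITIES = ("RNA", "ATAC")


def sim_genome(
    n_chroms: int = 6,
    chrom_length: int = 60_000_000,
    p_end: int = 27_000_000,
    q_start: int = 30_000_000,
) -> ChromArmTable:
    """Small synthetic genome: n metacentric chromosomes with a 3-Mb centromere."""
    rows = [
        {
            "chrom": f"chr{i + 1}",
            "p_start": 0,
            "p_end": p_end,
            "q_start": q_start,
            "q_end": chrom_length,
            "length": chrom_length,
        }
        for i in range(n_chroms)
    ]
    return ChromArmTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class EventSpec:
    """One planted CNV: interval plus total (c) and paternal (m) copies."""

    chrom: str
    start: int
    end: int
    c: int
    m: int

    @property
    def status(self) -> str:
        minor = min(self.m, self.c - self.m)
        if self.c == 0:
            return "bdel"
        if self.c < 2:
            return "del"
        if self.c == 2:
            return "cnloh" if minor == 0 else "neutral"
        return "bamp" if self.m * 2 == self.c else "amp"


@dataclass(frozen=True)
class CloneSpec:
    name: str
    proportion: float
    events: tuple = ()


@dataclass
class SimConfig:
    """Full description of one simulated multiome sample."""

    arms: ChromArmTable = field(default_factory=sim_genome)
    bin_size: int = 500_000
    clones: tuple = (CloneSpec("normal", 1.0),)
    n_cells: dict = field(default_factory=lambda: {"RNA": 250, "ATAC": 250})
    n_ref_cells: dict = field(default_factory=lambda: {"RNA": 300, "ATAC": 300})
    lib_size_mean: dict = field(default_factory=lambda: {"RNA": 6000.0, "ATAC": 12000.0})
    lib_size_sigma: float = 0.3
    baseline_sigma: dict = field(default_factory=lambda: {"RNA": 1.0, "ATAC": 1.0})
    zero_bin_fraction: dict = field(default_factory=lambda: {"RNA": 0.02, "ATAC": 0.10})
    snp_spacing: int = 40_000
    allele_capture: dict = field(default_factory=lambda: {"RNA": 0.05, "ATAC": 0.12})
    sigma_truth: float = 0.3
    gamma_truth: float = 20.0
    nu_switch: float = 1e7  # phase-switch error length scale of the emitted VCF
    allele_seq_error: float = 0.005
    seed: int = 0

    def __post_init__(self):
        total = sum(c.proportion for c in self.clones)
        if not np.isclose(total, 1.0):
            raise ValueError(f"clone proportions must sum to 1, got {total}")
        for clone in self.clones:
            for ev in clone.events:
                if ev.chrom not in self.arms:
                    raise ValueError(f"event chrom {ev.chrom} outside genome")
                if ev.end > self.arms.chrom_length(ev.chrom):
                    raise ValueError(f"event {ev} beyond chromosome end")

    @property
    def binset(self) -> BinSet:
        return make_uniform_bins(self.arms, self.bin_size, genome_build="sim")


@dataclass
class SimTruth:
    """Planted truth: per-cell clone labels, event table and WGS-style seg table."""

    clone_of_cell: pd.Series  # index: tagged cell id -> clone name
    events: pd.DataFrame  # chrom, start, end, c, m, status, clones
    seg: pd.DataFrame  # chrom, start, end, total_cn, minor_cn (cancer-rescaled)
    snps: pd.DataFrame  # chrom, pos, ref, alt, pat_is_ref(true), phase table


@dataclass
class SimulatedSample:
    config: SimConfig
    binset: BinSet
    counts: dict  # modality -> CellBinCounts (tumor sample cells)
    reference: ReferenceProfile  # combined (modality-suffixed) reference
    allele_counts: dict  # modality -> CellSnpAlleleCounts
    phased_vcf: pd.DataFrame  # chrom,pos,ref,alt,paternal_is_ref (with switch errors)
    truth: SimTruth


def _clone_phi_theta(config: SimConfig, binset: BinSet, snps: pd.DataFrame):
    """Per clone: per-bin dosage phi and per-SNP paternal fraction theta."""
    phi = {}
    theta = {}
    mid = binset.midpoints()
    for clone in config.clones:
        p = np.ones(len(binset))
        th = np.full(len(snps), 0.5)
        for ev in clone.events:
            sel = (binset.df["chrom"].values == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
            p[sel] = ev.c / 2.0
            ssel = (snps["chrom"].values == ev.chrom) & (snps["pos"].values >= ev.start) & (
                snps["pos"].values < ev.end
            )
            th[ssel] = ev.m / ev.c if ev.c > 0 else 0.5
        phi[clone.name] = p
        theta[clone.name] = th
    return phi, theta


def simulate_baseline(
    binset: BinSet, modality: str, rng: np.random.Generator,
    sigma: float = 1.0, zero_fraction: float = 0.02,
) -> np.ndarray:
    """Heavy-tailed normalized baseline rates lambda_b for one modality.

    Log-normal bin propensities with a zero-inflated fraction of dead bins;
    the ATAC default zero fraction exceeds the RNA one, mirroring the
    sparser accessible-chromatin coverage.
    """
    lam = rng.lognormal(mean=0.0, sigma=sigma, size=len(binset))
    dead = rng.random(len(binset)) < zero_fraction
    lam[dead] = 0.0
    return lam / lam.sum()


def _place_snps(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    bases = np.array(list("ACGT"))
    for chrom in config.arms.chroms:
        for arm in ("p", "q"):
            aiv = config.arms.arm_interval(chrom, arm)
            if aiv is None:
                continue
            pos = np.arange(aiv.start + config.snp_spacing // 2, aiv.end, config.snp_spacing)
            pos = pos + rng.integers(-config.snp_spacing // 4, config.snp_spacing // 4, len(pos))
            for p in pos:
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append({"chrom": chrom, "pos": int(p), "ref": bases[ref], "alt": bases[alt]})
    snps = pd.DataFrame(rows)
    snps["pat_is_ref"] = rng.random(len(snps)) < 0.5  # true haplotype assignment
    snps["snp_id"] = [f"s{i + 1}" for i in range(len(snps))]
    return snps


def _emit_phased_vcf(
    snps: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Observed phasing: true haplotypes with Markov switch errors along each chrom."""
    out = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        dist = np.diff(grp["pos"].values, prepend=grp["pos"].values[0])
        p_switch = 0.5 * (1 - np.exp(-dist / config.nu_switch))
        flips = rng.random(len(grp)) < p_switch
        orientation = np.where(np.cumsum(flips) % 2 == 0, 1, -1)
        obs_pat_is_ref = np.where(
            orientation > 0, grp["pat_is_ref"].values, ~grp["pat_is_ref"].values
        )
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].values,
                    "ref": grp["ref"].values,
                    "alt": grp["alt"].values,
                    "paternal_is_ref": obs_pat_is_ref,
                    "orientation": orientation,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def simulate_cells(
    config: SimConfig,
    binset: BinSet,
    baselines: dict,
    modality: str,
    clone_names: np.ndarray,
    phi: dict,
    rng: np.random.Generator,
    prefix: str,
) -> CellBinCounts:
    """Draw one modality's cell-by-bin counts under the PLN coverage model.

    counts ~ Poisson(N_c * lambda_b * phi_clone,b * e^z) with
    z ~ N(-sigma^2/2, sigma^2) per cell and bin.
    """
    n = len(clone_names)
    lam = baselines[modality]
    mean_lib = config.lib_size_mean[modality]
    libs = rng.lognormal(np.log(mean_lib), config.lib_size_sigma, n)
    sig = config.sigma_truth
    rows = np.empty((n, len(binset)), dtype=np.int64)
    for i in range(n):
        mu = libs[i] * lam * phi[clone_names[i]]
        z = rng.normal(-0.5 * sig**2, sig, len(binset)) if sig > 0 else 0.0
        rows[i] = rng.poisson(mu * np.exp(z))
    cells = pd.DataFrame(
        {"cell": [f"{prefix}{i + 1:04d}" for i in range(n)], "modality": modality}
    )
    return CellBinCounts(cells, binset, sp.csr_matrix(rows))


def simulate_alleles(
    config: SimConfig,
    binset: BinSet,
    counts: CellBinCounts,
    snps: pd.DataFrame,
    theta: dict,
    clone_names: np.ndarray,
    modality: str,
    rng: np.random.Generator,
) -> CellSnpAlleleCounts:
    """Draw per-cell per-SNP allele counts thinned from the bin coverage.

    Expected SNP depth is the cell's count in the SNP's bin times the
    modality capture rate, split evenly across the bin's SNPs; the paternal
    read count is beta-binomial around the clone's haplotype fraction, with
    a small symmetric read-level error rate.
    """
    snp_bin = np.full(len(snps), -1, dtype=np.int64)
    for chrom in snps["chrom"].unique():
        selc = snps["chrom"].values == chrom
        snp_bin[selc] = binset.find_bin(chrom, snps["pos"].values[selc])
    in_bin = snp_bin >= 0
    n_snps_per_bin = np.bincount(snp_bin[in_bin], minlength=len(binset)).astype(float)
    cap = config.allele_capture[modality]
    x = counts.counts.toarray().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_snp_rate = np.where(n_snps_per_bin > 0, cap / n_snps_per_bin, 0.0)
    expected = x[:, snp_bin[in_bin]] * per_snp_rate[snp_bin[in_bin]]
    depth = rng.poisson(expected)
    ci, sj = np.nonzero(depth)
    d = depth[ci, sj]
    snp_idx = np.nonzero(in_bin)[0][sj]
    th_cells = np.array([theta[c] for c in clone_names])  # (n_cells, n_snps)
    th = th_cells[ci, snp_idx]
    g = config.gamma_truth
    p = np.where(
        (th <= 0) | (th >= 1), th, rng.beta(np.maximum(th * g, 1e-9), np.maximum((1 - th) * g, 1e-9))
    )
    pat = rng.binomial(d, np.clip(p, 0, 1))
    eps = config.allele_seq_error
    if eps > 0:
        pat = rng.binomial(pat, 1 - eps) + rng.binomial(d - pat, eps)
    pat_is_ref = snps["pat_is_ref"].values[snp_idx]
    ref_count = np.where(pat_is_ref, pat, d - pat)
    alt_count = d - ref_count
    df = pd.DataFrame(
        {
            "cell": counts.cells["cell"].values[ci],
            "modality": modality,
            "snp_id": snps["snp_id"].values[snp_idx],
            "chrom": snps["chrom"].values[snp_idx],
            "pos": snps["pos"].values[snp_idx],
            "ref": snps["ref"].values[snp_idx],
            "alt": snps["alt"].values[snp_idx],
            "ref_count": ref_count,
            "alt_count": alt_count,
        }
    )
    return CellSnpAlleleCounts(df)


def _truth_tables(config: SimConfig, snps: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cancer = [c for c in config.clones if c.events]
    w = np.array([c.proportion for c in cancer], dtype=float)
    w = w / w.sum() if w.sum() > 0 else w
    ev_rows = []
    for clone, wk in zip(cancer, w):
        for ev in clone.events:
            ev_rows.append(
                {
                    "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                    "c": ev.c, "m": ev.m, "status": ev.status, "clone": clone.name,
                    "weight": wk,
                }
            )
    events = pd.DataFrame(ev_rows)
    seg_rows = []
    for chrom in config.arms.chroms:
        length = config.arms.chrom_length(chrom)
        cuts = {0, length}
        if not events.empty:
            for r in events[events["chrom"] == chrom].itertuples():
                cuts.update((r.start, r.end))
        cuts = sorted(cuts)
        for s, e in zip(cuts[:-1], cuts[1:]):
            total, minor = 2.0, 1.0
            if not events.empty:
                hit = events[
                    (events["chrom"] == chrom) & (events["start"] <= s) & (events["end"] >= e)
                ]
                if len(hit):
                    # cancer-cell-rescaled copy number, weighted over cancer clones
                    covered = hit["weight"].sum()
                    total = (hit["weight"] * hit["c"]).sum() + (1 - covered) * 2
                    minor = (
                        hit["weight"] * np.minimum(hit["m"], hit["c"] - hit["m"])
                    ).sum() + (1 - covered) * 1
            seg_rows.append(
                {"chrom": chrom, "start": s, "end": e, "total_cn": total, "minor_cn": minor}
            )
    if not events.empty:
        events = events.drop(columns="weight")
        events = (
            events.groupby(["chrom", "start", "end", "c", "m", "status"])["clone"]
            .apply(lambda s: ",".join(sorted(set(s))))
            .reset_index()
            .rename(columns={"clone": "clones"})
        )
    return events, pd.DataFrame(seg_rows)


def simulate_sample(config: SimConfig) -> SimulatedSample:
    """Generate one full multiome sample plus matched reference and truth."""
    rng = np.random.default_rng(config.seed)
    binset = config.binset
    snps = _place_snps(config, rng)
    phi, theta = _clone_phi_theta(config, binset, snps)
    baselines = {
        m: simulate_baseline(
            binset, m, rng, config.baseline_sigma[m], config.zero_bin_fraction[m]
        )
        for m in MODALITIES
    }
    phased_vcf = _emit_phased_vcf(snps, config, rng)
    props = np.array([c.proportion for c in config.clones])
    names = np.array([c.name for c in config.clones])
    counts, alleles, clone_labels = {}, {}, {}
    for modality, prefix in (("RNA", "R"), ("ATAC", "A")):
        n = config.n_cells[modality]
        clone_names = names[rng.choice(len(names), size=n, p=props)]
        clone_labels[modality] = clone_names
        counts[modality] = simulate_cells(
            config, binset, baselines, modality, clone_names, phi, rng, prefix
        )
        alleles[modality] = simulate_alleles(
            config, binset, counts[modality], snps, theta, clone_names, modality, rng
        )
    # held-out normal cells -> normalized reference, combined across modalities
    refs = {}
    for modality, prefix in (("RNA", "N"), ("ATAC", "M")):
        n = config.n_ref_cells[modality]
        ref_counts = simulate_cells(
            config, binset, baselines, modality,
            np.array(["normal"] * n), {"normal": np.ones(len(binset))}, rng, prefix,
        )
        refs[modality] = build_reference(
            ref_counts, {c: "normal" for c in ref_counts.cell_ids}
        )
    from .bin_aggregation import combine_references

    reference = combine_references(refs["RNA"], refs["ATAC"])
    clone_of_cell = pd.concat(
        [
            pd.Series(
                clone_labels[m],
                index=[
                    f"{c}#{m}" for c in counts[m].cells["cell"].values
                ],
            )
            for m in MODALITIES
        ]
    )
    events, seg = _truth_tables(config, snps)
    truth = SimTruth(
        clone_of_cell=clone_of_cell,
        events=events,
        seg=seg,
        snps=snps.merge(
            phased_vcf[["chrom", "pos", "orientation"]], on=["chrom", "pos"]
        ),
    )
    return SimulatedSample(
        config=config,
        binset=binset,
        counts=counts,
        reference=reference,
        allele_counts=alleles,
        phased_vcf=phased_vcf.drop(columns="orientation"),
        truth=truth,
    )


def fragments_from_bin_counts(
    counts: CellBinCounts, rng: np.random.Generator, fragment_length: int = 200
) -> pd.DataFrame:
    """Expand bin counts into a synthetic fragment table (10x dialect columns).

    Each count becomes one fragment whose midpoint is uniform within its
    bin, so re-binning the fragments at any resolution is consistent with
    the original counts in expectation.
    """
    binset = counts.binset
    coo = counts.counts.tocoo()
    reps = coo.data.astype(np.int64)
    cell_idx = np.repeat(coo.row, reps)
    bin_idx = np.repeat(coo.col, reps)
    starts = binset.df["start"].values[bin_idx]
    ends = binset.df["end"].values[bin_idx]
    mid = rng.integers(starts, ends)
    half = fragment_length // 2
    return pd.DataFrame(
        {
            "chrom": binset.df["chrom"].values[bin_idx],
            "start": np.maximum(mid - half, 0),
            "end": mid + half,
            "barcode": counts.cells["cell"].values[cell_idx],
            "count": 1,
        }
    )


# ---------------------------------------------------------------------------
# scenario presets


def _arm_bounds(arms: ChromArmTable, chrom: str, arm: str) -> tuple[int, int]:
    iv = arms.arm_interval(chrom, arm)
    return iv.start, iv.end


def default_cohort_config(sample_index: int, seed: int) -> SimConfig:
    """One sample of the default benchmark cohort.

    Six 60-Mb chromosomes; eight clonal events per sample spanning
    amp/bamp/del/cnloh at arm and focal scale, placed on distinct arms by a
    sample-specific seeded draw; one tumor clone at 70% with 30% normal
    contamination, ~250 cells per modality.
    """
    arms = sim_genome(6)
    rng = np.random.default_rng(seed * 1000 + sample_index)
    arm_list = [(c, a) for c in arms.chroms for a in ("p", "q")]
    picks = rng.permutation(len(arm_list))[:8]
    kinds = [
        ("arm", 1, 1), ("arm", 3, 2), ("arm", 2, 2), ("arm", 4, 2),
        ("focal", 1, 1), ("focal", 3, 2), ("focal", 2, 2), ("arm", 1, 0),
    ]
    events = []
    for (kind, c, m), pick in zip(kinds, picks):
        chrom, arm = arm_list[pick]
        lo, hi = _arm_bounds(arms, chrom, arm)
        if kind == "arm":
            events.append(EventSpec(chrom, lo, hi, c, m))
        else:
            start = int(lo + rng.integers(2, 8) * 1_000_000)
            width = int(rng.integers(8, 13) * 1_000_000)
            events.append(EventSpec(chrom, start, min(start + width, hi), c, m))
    clones = (
        CloneSpec("normal", 0.30),
        CloneSpec("tumor", 0.70, tuple(events)),
    )
    return SimConfig(arms=arms, clones=clones, seed=seed * 1000 + sample_index + 1)


def subclone_scenario_config(seed: int) -> SimConfig:
    """Minor-subclone scenario: a 15%-of-tumor CNLoH subclone.

    RNA allele capture is set an order of magnitude below ATAC (scATAC reads
    cover heterozygous SNPs genome-wide while scRNA reads concentrate in
    expressed exons), so the subclone's allelic signal is carried almost
    entirely by the ATAC modality.
    """
    arms = sim_genome(4)
    a = {c: _arm_bounds(arms, c, "q") for c in arms.chroms}
    p1 = _arm_bounds(arms, "chr3", "p")
    shared = (
        EventSpec("chr1", *a["chr1"], 1, 1),
        EventSpec("chr2", *a["chr2"], 3, 2),
        EventSpec("chr3", p1[0], p1[1], 1, 1),
    )
    private = EventSpec("chr4", *a["chr4"], 2, 2)  # CNLoH, subclone-private
    clones = (
        CloneSpec("normal", 0.30),
        CloneSpec("tumor", 0.595, shared),
        CloneSpec("subclone", 0.105, shared + (private,)),
    )
    return SimConfig(
        arms=arms,
        clones=clones,
        n_cells={"RNA": 220, "ATAC": 220},
        allele_capture={"RNA": 0.004, "ATAC": 0.08},
        seed=seed,
    )


def chromothripsis_config(seed: int, n_events: int = 10) -> SimConfig:
    """Chromothripsis-like preset: alternating focal events tiling one q arm."""
    arms = sim_genome(2)
    lo, hi = _arm_bounds(arms, "chr1", "q")
    width = (hi - lo) // n_events
    events = []
    for i in range(n_events):
        if i % 2 == 0:
            events.append(EventSpec("chr1", lo + i * width, lo + (i + 1) * width, 1, 1))
    clones = (CloneSpec("normal", 0.2), CloneSpec("tumor", 0.8, tuple(events)))
    return SimConfig(arms=arms, clones=clones, seed=seed)


# ---------------------------------------------------------------------------
# on-disk bundle


def _write_mtx(dir_path, name: str, m: CellBinCounts) -> None:
    from scipy.io import mmwrite

    mmwrite(str(dir_path / f"{name}_counts.mtx"), m.counts.tocoo())
    m.cells.to_csv(dir_path / f"{name}_cells.tsv", sep="\t", index=False)
    m.binset.df.to_csv(dir_path / f"{name}_bins.tsv", sep="\t", index=False)


def write_phased_vcf_file(phased: pd.DataFrame, path) -> None:
    """Write the emitted phasing as a minimal single-sample GT-only VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(phased["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in phased.itertuples():
            gt = "0|1" if r.paternal_is_ref else "1|0"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_fixture_bundle(sample: SimulatedSample, out_dir, force: bool = False) -> None:
    """Write a self-describing, re-loadable file bundle of a simulated sample."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    for modality in MODALITIES:
        _write_mtx(out, modality.lower(), sample.counts[modality])
        sample.allele_counts[modality].to_tsv(out / f"{modality.lower()}_alleles.tsv")
    sample.reference.rates.to_csv(out / "reference.tsv", sep="\t")
    write_phased_vcf_file(sample.phased_vcf, out / "phased.vcf")
    sample.truth.seg.to_csv(out / "truth.seg.tsv", sep="\t", index=False)
    sample.truth.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
    sample.truth.clone_of_cell.rename("clone").rename_axis("cell").reset_index().to_csv(
        out / "truth_clones.tsv", sep="\t", index=False
    )
    cfg = sample.config
    meta = {
        "bin_size": cfg.bin_size,
        "seed": cfg.seed,
        "n_cells": cfg.n_cells,
        "clones": [
            {
                "name": c.name,
                "proportion": c.proportion,
                "events": [
                    {"chrom": e.chrom, "start": e.start, "end": e.end, "c": e.c, "m": e.m}
                    for e in c.events
                ],
            }
            for c in cfg.clones
        ],
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    cfg.arms.to_tsv(out / "arms.tsv")


def load_fixture_bundle(in_dir) -> dict:
    """Load a bundle written by :func:`write_fixture_bundle` (matrices exact)."""
    from pathlib import Path

    from scipy.io import mmread

    d = Path(in_dir)
    out = {"counts": {}, "allele_counts": {}}
    for modality in MODALITIES:
        cells = pd.read_csv(d / f"{modality.lower()}_cells.tsv", sep="\t")
        bins = pd.read_csv(d / f"{modality.lower()}_bins.tsv", sep="\t")
        mat = sp.csr_matrix(mmread(str(d / f"{modality.lower()}_counts.mtx")))
        out["counts"][modality] = CellBinCounts(cells, BinSet(bins, "sim"), mat)
        out["allele_counts"][modality] = CellSnpAlleleCounts.from_tsv(
            d / f"{modality.lower()}_alleles.tsv"
        )
    rates = pd.read_csv(d / "reference.tsv", sep="\t", index_col=0)
    out["reference"] = ReferenceProfile(rates)
    out["truth_seg"] = pd.read_csv(d / "truth.seg.tsv", sep="\t")
    out["truth_events"] = pd.read_csv(d / "truth_events.tsv", sep="\t")
    out["truth_clones"] = pd.read_csv(d / "truth_clones.tsv", sep="\t")
    out["arms"] = ChromArmTable.from_tsv(d / "arms.tsv")
    out["vcf_path"] = d / "phased.vcf"
    with open(d / "config.yaml") as fh:
        out["config"] = yaml.safe_load(fh)
    return out
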