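"""End-to-end orchestration of the four running modes.

Modes: ``rna_gene`` (gene-level features, no binning), ``rna_bin``,
``atac_bin`` and ``combined_bin`` (vertical concatenation of both
modalities).  A run aggregates counts, matches references, attaches
population phase, segments the whole-sample pseudobulk with the joint HMM,
scores events per cell, assigns clones (with optional refinement) and
annotates arm-level/focal events.  The benchmark harness scores any set of
runs against a ground-truth segmentation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_counts import CellSnpAlleleCounts, attach_phase, merge_modality_allele_counts
from .bin_aggregation import (
    CellBinCounts,
    ReferenceProfile,
    concat_modalities,
    tag_cells,
)
from .clone_inference import (
    CloneModel,
    assign_clones,
    events_from_segmentation,
    iterate_refinement,
    per_cell_event_llr,
)
from .cnv_hmm import (
    HmmParams,
    SegmentationResult,
    build_observation_track,
    make_pseudobulk_profile,
    viterbi_segment,
)
from .event_annotation import annotate_events
from .evaluation import (
    detection_matrix,
    event_recalls,
    precision_recall_f1,
    stratified_metrics,
    truth_from_wgs_segments,
)
from .genome_bins import ChromArmTable, CytobandTable

__all__ = ["RunConfig", "RunResult", "run_inference", "run_benchmark", "run_binsize_sweep", "MODES"]

MODES = ("rna_gene", "rna_bin", "atac_bin", "combined_bin")


@dataclass
class RunConfig:
    """Everything a run needs besides the data itself."""

    mode: str = "combined_bin"
    params: HmmParams = field(default_factory=HmmParams)
    seed: int = 0
    refine: bool = True
    scan_subclones: bool = True
    max_clones: int = 6
    min_cells: int = 20
    use_alleles: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "params"},
             "params": asdict(self.params)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    segments: pd.DataFrame  # whole-sample pseudobulk segmentation
    events: pd.DataFrame  # non-neutral segments (chrom,start,end,status,...)
    annotated: pd.DataFrame  # arm/focal annotated events
    clones: CloneModel
    clone_segments: dict
    reference_columns: dict
    dropped_allele_records: int = 0

    def report(self) -> dict:
        return {
            "mode": self.config.mode,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "n_segments": len(self.segments),
            "n_events": len(self.events),
            "n_clones": self.clones.n_clones,
        }


def _select_inputs(
    counts: dict, alleles: dict | None, mode: str, use_alleles: bool
) -> tuple[CellBinCounts, CellSnpAlleleCounts | None]:
    if mode in ("rna_gene", "rna_bin"):
        binned = counts["RNA"]
        binned = CellBinCounts(
            tag_cells(binned.cells), binned.binset, binned.counts, binned.dropped
        )
        al = alleles.get("RNA") if alleles else None
        if al is not None:
            al = merge_modality_allele_counts(al, CellSnpAlleleCounts(al.df.iloc[0:0]))
    elif mode == "atac_bin":
        binned = counts["ATAC"]
        binned = CellBinCounts(
            tag_cells(binned.cells), binned.binset, binned.counts, binned.dropped
        )
        al = alleles.get("ATAC") if alleles else None
        if al is not None:
            al = merge_modality_allele_counts(CellSnpAlleleCounts(al.df.iloc[0:0]), al)
    else:
        binned = concat_modalities(counts["RNA"], counts["ATAC"])
        al = None
        if alleles and "RNA" in alleles and "ATAC" in alleles:
            al = merge_modality_allele_counts(alleles["RNA"], alleles["ATAC"])
    if not use_alleles:
        al = None
    return binned, al


def run_inference(
    counts: dict,
    reference: ReferenceProfile,
    config: RunConfig,
    alleles: dict | None = None,
    phased_vcf=None,
    arms: ChromArmTable | None = None,
    bands: CytobandTable | None = None,
) -> RunResult:
    """Run one full inference in the configured mode.

    ``counts`` maps modality to :class:`CellBinCounts` (for ``rna_gene`` the
    "bins" are the gene intervals themselves); ``alleles`` maps modality to
    per-cell SNP counts and ``phased_vcf`` is a phased VCF path or phase
    table.  Without allele data the run degrades to coverage-only inference,
    in which copy-neutral LOH is undetectable by construction.
    """
    binned, allele_counts = _select_inputs(counts, alleles, config.mode, config.use_alleles)
    phased_records = None
    n_dropped = 0
    if allele_counts is not None and phased_vcf is not None and len(allele_counts.df):
        phased_records, dropped = attach_phase(allele_counts, phased_vcf)
        n_dropped = len(dropped)
    params = config.params
    prof = make_pseudobulk_profile(binned, reference, phased_records, params=params)
    track = build_observation_track(prof)
    segres = viterbi_segment(track, params)
    segments = segres.segments
    event_models = events_from_segmentation(segres)
    llr = per_cell_event_llr(
        binned, reference, phased_records, event_models, params,
        reference_columns=prof.reference_columns,
    )
    clones = assign_clones(
        llr, max_clones=config.max_clones, seed=config.seed, events=event_models
    )
    clone_segments: dict = {}
    if config.refine and event_models:
        clone_segments, clones = iterate_refinement(
            binned, reference, phased_records, clones,
            arms=arms if config.scan_subclones else None,
            params=params, seed=config.seed, min_cells=config.min_cells,
            max_clones=config.max_clones, scan_subclones=config.scan_subclones,
        )
    events = segments[segments["category"] != "neutral"].copy()
    events = events.rename(columns={"category": "status"})
    annotated = pd.DataFrame()
    if arms is not None and not events.empty:
        annotated = annotate_events(
            events.rename(columns={"status": "category"}), arms, bands
        )
    return RunResult(
        config=config,
        segments=segments,
        events=events,
        annotated=annotated,
        clones=clones,
        clone_segments=clone_segments,
        reference_columns=prof.reference_columns,
        dropped_allele_records=n_dropped,
    )


def prediction_intervals(result: RunResult) -> pd.DataFrame:
    """(chrom, start, end, status) CNV intervals of a run, for evaluation."""
    if result.events.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "status"])
    return result.events[["chrom", "start", "end", "status"]].reset_index(drop=True)


def run_benchmark(
    results: dict,
    truth_seg: pd.DataFrame,
    arms: ChromArmTable | None = None,
    bands: CytobandTable | None = None,
    use_minor_cn: bool = True,
) -> dict:
    """Score a set of runs (keyed by mode/sample label) against WGS-style truth.

    Returns per-run stratified metric tables, a tidy summary (one
    precision/recall/F1 row per run) and the cross-mode detection matrix
    (an event counts as detected at recall >= 0.8).
    """
    truth = truth_from_wgs_segments(truth_seg, use_minor_cn=use_minor_cn)
    metrics, summary_rows, preds = {}, [], {}
    for label, result in results.items():
        pred = prediction_intervals(result)
        preds[label] = pred
        metrics[label] = stratified_metrics(pred, truth, strata=("status",))
        overall = precision_recall_f1(pred, truth, match_status=True)
        summary_rows.append({"run": label, **overall.drop(labels=["stratum"]).to_dict()})
    recalls = event_recalls(preds, truth)
    detect, combo_counts = detection_matrix(recalls)
    return {
        "truth": truth,
        "metrics": metrics,
        "summary": pd.DataFrame(summary_rows),
        "event_recalls": recalls,
        "detection": detect,
        "detection_counts": combo_counts,
    }


def benchmark_cohort(
    seed: int,
    n_samples: int = 6,
    mode: str = "combined_bin",
    refine: bool = False,
) -> pd.DataFrame:
    """Simulate the default benchmark cohort and score every sample.

    Each sample gets its own planted-event layout (derived from ``seed`` and
    the sample index), is run end to end in ``mode``, and is scored with the
    length-weighted overlap metrics against its thresholded truth segments.
    Returns one precision/recall/F1 row per sample.
    """
    from .synthetic_data import default_cohort_config, simulate_sample

    rows = []
    for i in range(1, n_samples + 1):
        sample = simulate_sample(default_cohort_config(i, seed))
        config = RunConfig(mode=mode, seed=seed, refine=refine, scan_subclones=refine)
        result = run_inference(
            sample.counts, sample.reference, config,
            alleles=sample.allele_counts, phased_vcf=sample.phased_vcf,
            arms=sample.config.arms,
        )
        truth = truth_from_wgs_segments(sample.truth.seg)
        m = precision_recall_f1(prediction_intervals(result), truth, match_status=True)
        rows.append(
            {
                "sample": i,
                "precision": m["precision"],
                "recall": m["recall"],
                "f1": m["f1"],
                "n_events_true": int((truth["status"] != "neutral").sum()),
                "n_events_called": len(result.events),
            }
        )
    return pd.DataFrame(rows)


def subclone_recovered(result: RunResult, truth_clones: pd.Series,
                       min_size: int = 10) -> bool:
    """Whether a run isolated the planted minor subclone as its own clone.

    True when some clone's genotype carries a CNLoH event and the majority
    of its assigned cells are true subclone cells (at least ``min_size``).
    """
    model = result.clones
    assign = model.hard_assignments()
    for clone in model.genotypes.index:
        geno = model.genotypes.loc[clone]
        if not any("cnloh" in name for name in geno.index[geno]):
            continue
        members = assign.index[assign == clone]
        if len(members) < min_size:
            continue
        if (truth_clones.reindex(members) == "subclone").mean() > 0.5:
            return True
    return False


def subclone_mode_comparison(seed: int, modes=("combined_bin", "rna_bin")) -> dict:
    """Run the minor-subclone scenario in several modes; report recovery."""
    from .synthetic_data import simulate_sample, subclone_scenario_config

    sample = simulate_sample(subclone_scenario_config(seed))
    out = {}
    for mode in modes:
        result = run_inference(
            sample.counts, sample.reference, RunConfig(mode=mode, seed=seed),
            alleles=sample.allele_counts, phased_vcf=sample.phased_vcf,
            arms=sample.config.arms,
        )
        out[mode] = subclone_recovered(result, sample.truth.clone_of_cell)
    return out


def run_binsize_sweep(
    fragments: pd.DataFrame,
    reference_counts: pd.DataFrame,
    arms: ChromArmTable,
    sizes=(500_000, 200_000, 100_000, 50_000),
    alleles: dict | None = None,
    phased_vcf=None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Re-bin an ATAC fragment table at several bin sizes and re-run inference.

    ``fragments``/``reference_counts`` are fragment tables (chrom, start,
    end, barcode[, count]) for the sample and for reference normal cells.
    Returns one row per bin size with the segment/event counts and wall
    time (informational only).
    """
    import time

    from .bin_aggregation import build_reference, fragments_to_bins
    from .genome_bins import make_uniform_bins

    config = config or RunConfig(mode="atac_bin", refine=False, scan_subclones=False)
    rows = []
    for size in sizes:
        t0 = time.perf_counter()
        binset = make_uniform_bins(arms, size, genome_build="sweep")
        binned = fragments_to_bins(fragments, binset)
        ref_binned = fragments_to_bins(reference_counts, binset)
        ref = build_reference(
            ref_binned, {c: "normal#ATAC" for c in ref_binned.cell_ids}
        )
        result = run_inference(
            {"ATAC": binned}, ref, config, alleles=alleles,
            phased_vcf=phased_vcf, arms=arms,
        )
        elapsed = time.perf_counter() - t0
        ev = result.events
        rows.append(
            {
                "bin_size": size,
                "n_bins": len(binset),
                "n_segments": len(result.segments),
                "n_events": len(ev),
                "n_breakpoints": int(
                    sum(len(g) - 1 for _, g in result.segments.groupby("chrom"))
                ),
                "runtime_s": elapsed,
            }
        )
    return pd.DataFrame(rows)
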