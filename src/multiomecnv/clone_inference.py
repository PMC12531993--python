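"""Clone assignment from per-cell CNV-event likelihoods, with refinement.

Each pseudobulk-level CNV event is scored in every single cell as a
log-likelihood ratio (event copy-number configuration vs diploid) combining
the cell's own bin coverage and phased allele counts.  Cells are then
assigned to clones with an EM over a flat mixture of binary event genotypes
(clone 1 is always the all-neutral normal clone), with the number of clones
chosen by BIC.  Refinement re-segments per-clone pseudobulks and scans for
subclonal allelic-imbalance events that are invisible in the whole-sample
pseudobulk — the mechanism by which added ATAC allele coverage exposes
minor CNLoH subclones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit, logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .bin_aggregation import CellBinCounts, ReferenceProfile
from .cnv_hmm import (
    HmmParams,
    HmmStateSpace,
    PHI_FLOOR,
    SegmentationResult,
    bb_loglik,
    build_observation_track,
    build_state_space,
    make_pseudobulk_profile,
    pln_loglik,
    viterbi_segment,
)
from .genome_bins import ChromArmTable, GenomicInterval, overlap_length

__all__ = [
    "CnvEventModel",
    "CloneModel",
    "events_from_segmentation",
    "per_cell_event_llr",
    "assign_clones",
    "scan_subclonal_events",
    "iterate_refinement",
]

DEFAULT_MIN_CELLS = 20
DEFAULT_MAX_CLONES = 6


@dataclass
class CnvEventModel:
    """One CNV event as a single-cell scoring model.

    ``snp_flips`` maps the event's SNPs to the haplotype orientation chosen
    by the pseudobulk Viterbi path (True = the major haplotype is the
    flipped one), so per-cell allele counts can be oriented consistently.
    """

    chrom: str
    start: int
    end: int
    category: str
    phi: float
    theta: float
    snp_flips: pd.DataFrame  # columns: chrom, pos, flip

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start // 1000000}-{self.end // 1000000}Mb:{self.category}"

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def events_from_segmentation(
    segres: SegmentationResult, min_bins: int = 2
) -> list[CnvEventModel]:
    """Turn non-neutral Viterbi segments into scorable event models."""
    events = []
    for seg in segres.segments.itertuples():
        if seg.category == "neutral" or seg.n_bins < min_bins:
            continue
        sub = segres.segment_track(seg.segment)
        snps = sub[sub["kind"] == "snp"]
        flips = pd.DataFrame(
            {
                "chrom": snps["chrom"].values,
                "pos": snps["pos"].values,
                "flip": segres.states.theta[snps["state"].values] < 0.5,
            }
        )
        events.append(
            CnvEventModel(
                chrom=seg.chrom,
                start=int(seg.start),
                end=int(seg.end),
                category=seg.category,
                phi=float(seg.phi_hat),
                theta=float(seg.theta_hat),
                snp_flips=flips,
            )
        )
    return events


def per_cell_event_llr(
    binned: CellBinCounts,
    ref: ReferenceProfile,
    phased_records: pd.DataFrame | None,
    events: list[CnvEventModel],
    params: HmmParams | None = None,
    reference_columns: dict | None = None,
) -> pd.DataFrame:
    """Cells x events log-likelihood-ratio matrix (event vs diploid).

    Coverage part: PLN log-likelihood of the cell's counts in the event's
    bins at dosage phi versus 1, with the cell's own library size setting
    the expected counts.  Allele part: beta-binomial log-likelihood of the
    cell's phased SNP counts (oriented by the event's Viterbi phase) at the
    event theta versus 0.5.  A cell with no reads in the event region
    scores exactly 0.
    """
    params = params or HmmParams()
    binset = binned.binset
    cells = binned.cells["cell"].values
    cell_pos = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    llr = np.zeros((n, len(events)))
    # per-modality reference rates and per-cell scale
    for modality in binned.cells["modality"].unique():
        mask = (binned.cells["modality"] == modality).values
        if reference_columns and modality in reference_columns:
            label = reference_columns[modality]
        else:
            label = ref.labels[0]
        lam = ref.column(label)
        keep = lam > 0
        sigma = params.sigma.get(modality, 0.3)
        sub = binned.counts[mask]
        lib = np.asarray(sub[:, keep].sum(axis=1)).ravel() / lam[keep].sum()
        rows = np.nonzero(mask)[0]
        for e_idx, ev in enumerate(events):
            phi = max(ev.phi, PHI_FLOOR)
            if abs(phi - 1.0) < 1e-6:
                continue
            bins = binset.overlapping_bins(ev.interval())
            bins = bins[keep[bins]]
            if len(bins) == 0:
                continue
            x = np.asarray(sub[:, bins].todense())
            expect = lib[:, None] * lam[bins][None, :]
            ok = expect > 0
            alt = np.where(ok, pln_loglik(x, np.maximum(expect, 1e-12) * phi, sigma, params.gh_order), 0.0)
            null = np.where(ok, pln_loglik(x, np.maximum(expect, 1e-12), sigma, params.gh_order), 0.0)
            llr[rows, e_idx] += (alt - null).sum(axis=1)
    if phased_records is not None and len(phased_records):
        for e_idx, ev in enumerate(events):
            if ev.snp_flips.empty or abs(ev.theta - 0.5) < 1e-6:
                continue
            rec = phased_records.merge(ev.snp_flips, on=["chrom", "pos"], how="inner")
            if rec.empty:
                continue
            a = rec["pat_count"].values.astype(np.int64)
            d = rec["total_count"].values.astype(np.int64)
            a_major = np.where(rec["flip"].values, d - a, a)
            part = bb_loglik(a_major, d, ev.theta, params.gamma) - bb_loglik(
                a_major, d, 0.5, params.gamma
            )
            contrib = pd.Series(part).groupby(rec["cell"].values).sum()
            for cell, v in contrib.items():
                if cell in cell_pos:
                    llr[cell_pos[cell], e_idx] += v
    return pd.DataFrame(llr, index=cells, columns=[ev.name for ev in events])


@dataclass
class CloneModel:
    """Mixture of binary event genotypes; clone 0 is the normal clone."""

    genotypes: pd.DataFrame  # clones x events (bool)
    posterior: pd.DataFrame  # cells x clones
    mixing: np.ndarray
    loglik: float
    bic: float
    events: list = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.genotypes)

    def hard_assignments(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)

    def clone_sizes(self, modalities: pd.Series | None = None) -> pd.DataFrame:
        assign = self.hard_assignments()
        if modalities is None:
            return assign.value_counts().rename("cells").to_frame()
        df = pd.DataFrame({"clone": assign, "modality": modalities.reindex(assign.index)})
        return df.value_counts().unstack(fill_value=0)


def _em_fit(
    llr: np.ndarray, K: int, seed: int, temperature: float, n_iter: int = 100
):
    n, E = llr.shape
    scaled = llr / temperature
    if K == 1:
        g = np.zeros((1, E), dtype=bool)
        ll_cell = np.where(g[0], log_expit(scaled), log_expit(-scaled)).sum(axis=1)
        return g, np.ones((n, 1)), np.array([1.0]), float(ll_cell.sum())
    feats = np.tanh(llr / 4.0)
    km = KMeans(n_clusters=K, n_init=4, random_state=seed).fit(feats)
    resp = np.full((n, K), 1e-3)
    resp[np.arange(n), km.labels_] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)
    pos, neg = log_expit(scaled), log_expit(-scaled)
    prev_ll = -np.inf
    for _ in range(n_iter):
        # M-step: genotype per clone maximizes sum_c r_ck * llr_ce
        score = resp.T @ llr  # (K, E)
        g = score > 0
        g[0, :] = False  # clone 0 is reserved all-neutral
        pi = np.clip(resp.mean(axis=0), 1e-6, None)
        pi /= pi.sum()
        # E-step
        ll_ck = np.where(g[None, :, :], pos[:, None, :], neg[:, None, :]).sum(axis=2)
        joint = np.log(pi)[None, :] + ll_ck
        norm = logsumexp(joint, axis=1)
        resp = np.exp(joint - norm[:, None])
        ll = float(norm.sum())
        if abs(ll - prev_ll) < 1e-8:
            break
        prev_ll = ll
    return g, resp, pi, prev_ll


def assign_clones(
    llr: pd.DataFrame,
    max_clones: int = DEFAULT_MAX_CLONES,
    seed: int = 0,
    temperature: float = 1.0,
    events: list | None = None,
) -> CloneModel:
    """EM over clone-genotype mixtures; K chosen by BIC up to ``max_clones``.

    Each clone is a binary vector over events; a cell's log-likelihood under
    a clone sums logistic-transformed event LLRs (sigma(LLR) for carried
    events, sigma(-LLR) otherwise).  Clone 1 keeps the all-neutral genotype.
    A degenerate all-zero LLR matrix returns the single normal clone.
    """
    mat = llr.values.astype(float)
    n, E = mat.shape
    if E == 0 or np.allclose(mat, 0.0) or n < 2:
        genotypes = pd.DataFrame(
            np.zeros((1, E), dtype=bool), index=["clone0"], columns=llr.columns
        )
        posterior = pd.DataFrame(np.ones((n, 1)), index=llr.index, columns=["clone0"])
        return CloneModel(genotypes, posterior, np.array([1.0]), 0.0, 0.0, events or [])
    best = None
    for K in range(1, max_clones + 1):
        if K > n:
            break
        g, resp, pi, ll = _em_fit(mat, K, seed, temperature)
        n_params = K * E + (K - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, K, g, resp, pi, ll)
    bic, K, g, resp, pi, ll = best
    clone_names = [f"clone{k}" for k in range(K)]
    genotypes = pd.DataFrame(g, index=clone_names, columns=llr.columns)
    posterior = pd.DataFrame(resp, index=llr.index, columns=clone_names)
    return CloneModel(genotypes, posterior, pi, ll, bic, events or [])


def scan_subclonal_events(
    binned: CellBinCounts,
    ref: ReferenceProfile,
    phased_records: pd.DataFrame,
    cells: list,
    arms: ChromArmTable,
    existing_events: list[CnvEventModel],
    params: HmmParams | None = None,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
    min_scan_cells: int = 10,
    block_snps: int = 50,
    min_arm_depth_per_cell: float = 5.0,
    delta_bic: float = 10.0,
) -> list[CnvEventModel]:
    """Scan one clone's cells for subclonal allelic-imbalance events.

    For each chromosome arm free of known events: pool the cells' phased SNP
    residuals (paternal - depth/2) into phase blocks of ``block_snps``
    consecutive SNPs, take the first principal component of the cells x
    blocks residual matrix (its loadings learn the per-block haplotype
    orientation, so population phase switches do not cancel the signal), and
    test the PC scores for bimodality with a 2- vs 1-component Gaussian
    mixture (BIC margin ``delta_bic``).  A candidate minority cell subset
    (at least ``min_scan_cells``; the floor is below the clone-size minimum
    because a subclone may be carried by a single modality) is confirmed by
    re-segmenting its own pseudobulk on that arm; a confirmed non-neutral
    segment becomes a new event.  Only cells with arm depth of at least
    ``min_arm_depth_per_cell`` reads enter the scan — underpowered cells
    would only dilute the principal component — and arms with fewer than
    ``2 * min_scan_cells`` informative cells are skipped entirely.  This
    depth gate is where sparse allele coverage (RNA-only runs) loses
    subclones.
    """
    params = params or HmmParams()
    rec = phased_records[phased_records["cell"].isin(set(cells))]
    if rec.empty:
        return []
    found = []
    for chrom in arms.chroms:
        for arm in ("p", "q"):
            aiv = arms.arm_interval(chrom, arm)
            if aiv is None:
                continue
            # only well-determined events exclude an arm; a weak blip
            # (near-diploid phi, near-balanced theta) is often the diluted
            # shadow of the very subclonal event the scan should resolve
            covered = any(
                overlap_length(ev.interval(), aiv) > 0.1 * aiv.length
                and (abs(ev.phi - 1.0) > 0.15 or abs(ev.theta - 0.5) > 0.15)
                for ev in existing_events
            )
            if covered:
                continue
            sub = rec[
                (rec["chrom"] == chrom)
                & (rec["pos"] >= aiv.start)
                & (rec["pos"] < aiv.end)
            ]
            if sub.empty:
                continue
            per_cell_depth = sub.groupby("cell")["total_count"].sum()
            per_cell_depth = per_cell_depth.reindex(cells, fill_value=0)
            informative = per_cell_depth.index[
                per_cell_depth >= min_arm_depth_per_cell
            ]
            if len(informative) < 2 * min_scan_cells:
                continue
            sub = sub[sub["cell"].isin(set(informative))]
            snp_order = (
                sub[["pos"]].drop_duplicates().sort_values("pos").reset_index(drop=True)
            )
            snp_rank = {p: i for i, p in enumerate(snp_order["pos"].values)}
            block = sub["pos"].map(snp_rank).values // block_snps
            resid = sub["pat_count"].values - sub["total_count"].values / 2.0
            mat = (
                pd.DataFrame({"cell": sub["cell"].values, "block": block, "r": resid})
                .pivot_table(index="cell", columns="block", values="r", aggfunc="sum")
                .reindex(informative, fill_value=0.0)
                .fillna(0.0)
            )
            if mat.shape[1] < 2:
                continue
            centered = mat.values - mat.values.mean(axis=0, keepdims=True)
            u, s, _ = np.linalg.svd(centered, full_matrices=False)
            scores = (u[:, 0] * s[0]).reshape(-1, 1)
            gm1 = GaussianMixture(1, random_state=seed).fit(scores)
            gm2 = GaussianMixture(2, random_state=seed, n_init=3).fit(scores)
            bic1 = gm1.bic(scores)
            bic2 = gm2.bic(scores)
            if bic1 - bic2 < delta_bic:
                continue
            labels = gm2.predict(scores)
            sizes = np.bincount(labels, minlength=2)
            minority = int(np.argmin(sizes))
            if sizes[minority] < min_scan_cells:
                continue
            cand_cells = list(np.asarray(mat.index)[labels == minority])
            # confirm: segment the candidate subset's pseudobulk on this arm
            try:
                prof = make_pseudobulk_profile(
                    binned, ref, phased_records, cells=cand_cells, params=params
                )
            except ValueError:
                continue
            track = build_observation_track(prof)
            track = track[
                (track["chrom"] == chrom)
                & (track["pos"] >= aiv.start)
                & (track["pos"] < aiv.end)
            ]
            if track.empty:
                continue
            segres = viterbi_segment(track, params)
            for ev in events_from_segmentation(segres, min_bins=2):
                if ev.end - ev.start >= 0.3 * aiv.length and len(ev.snp_flips) >= 10:
                    found.append(ev)
    return found


def _dedupe_events(events: list[CnvEventModel]) -> list[CnvEventModel]:
    """Collapse reciprocally-overlapping (>50%) events to one representative.

    The same genomic event recurs across per-clone pseudobulks, sometimes
    with discordant typing (a subclonal CNLoH diluted into its parent
    clone's pseudobulk looks like a weak amplification).  Within an overlap
    group the event with the strongest allelic imbalance wins (imbalance is
    the more identifiable signal); ties go to the larger span.
    """
    ranked = sorted(
        events,
        key=lambda e: (abs(e.theta - 0.5), e.end - e.start),
        reverse=True,
    )
    kept: list[CnvEventModel] = []
    for ev in ranked:
        dup = any(
            overlap_length(ev.interval(), other.interval())
            > 0.5 * min(ev.interval().length, other.interval().length)
            for other in kept
        )
        if not dup:
            kept.append(ev)
    return sorted(kept, key=lambda e: (e.chrom, e.start, e.end))


def iterate_refinement(
    binned: CellBinCounts,
    ref: ReferenceProfile,
    phased_records: pd.DataFrame | None,
    clones: CloneModel,
    arms: ChromArmTable | None = None,
    params: HmmParams | None = None,
    max_iter: int = 2,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
    max_clones: int = DEFAULT_MAX_CLONES,
    scan_subclones: bool = True,
) -> tuple[dict, CloneModel]:
    """Iteratively re-segment per-clone pseudobulks and re-assign cells.

    Per iteration: hard-assign cells, rebuild each sizeable clone's
    pseudobulk, re-segment it, pool the deduplicated events (plus, when
    ``scan_subclones``, arm-scale allelic candidates from
    :func:`scan_subclonal_events`), recompute per-cell LLRs and re-run the
    clone EM.  Stops when assignments are unchanged, the total data
    log-likelihood would decrease (the previous model is kept), or
    ``max_iter`` is reached.  Returns (per-clone segment tables, clone model).
    """
    params = params or HmmParams()
    model = clones
    clone_segments: dict = {}
    prev_assign = model.hard_assignments()
    prev_event_names = {ev.name for ev in model.events}
    for _ in range(max_iter):
        assign = model.hard_assignments()
        # events the current model already knows; the subclone scan excludes
        # only these, not this iteration's own re-segmentation output
        base_events = list(model.events)
        events: list[CnvEventModel] = []
        clone_segments = {}
        for clone in model.genotypes.index:
            members = assign.index[assign == clone]
            if len(members) < min_cells:
                continue
            prof = make_pseudobulk_profile(
                binned, ref, phased_records, cells=list(members), params=params
            )
            segres = viterbi_segment(build_observation_track(prof), params)
            clone_segments[clone] = segres.segments
            if clone != "clone0":
                events.extend(events_from_segmentation(segres))
            if scan_subclones and arms is not None and phased_records is not None:
                events.extend(
                    scan_subclonal_events(
                        binned, ref, phased_records, list(members), arms,
                        base_events, params=params, seed=seed, min_cells=min_cells,
                    )
                )
        events = _dedupe_events(events)
        if not events:
            break
        llr = per_cell_event_llr(binned, ref, phased_records, events, params)
        new_model = assign_clones(llr, max_clones=max_clones, seed=seed, events=events)
        same_events = {ev.name for ev in events} == prev_event_names
        if same_events and new_model.loglik < model.loglik:
            break  # likelihood comparable only on an identical event set
        model = new_model
        new_assign = model.hard_assignments()
        if same_events and new_assign.equals(prev_assign):
            break
        prev_assign = new_assign
        prev_event_names = {ev.name for ev in events}
    return clone_segments, model
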