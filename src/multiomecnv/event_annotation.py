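"""Merge same-status segments within arms and annotate arm-level/focal events.

Coverage dropout over-segments single-cell copy-number profiles, so adjacent
segments with the same status are first merged within each chromosome arm.
A merged candidate spanning more than 80% of its (telomere-trimmed) arm is
an arm-level event; between 10% and 80% it is focal and gets a cytoband
range label; candidates at or below 10% of the arm, or shorter than 200 kb,
are dropped from event-level reporting.
"""

from __future__ import annotations

import pandas as pd

from .genome_bins import (
    ChromArmTable,
    CytobandTable,
    DEFAULT_TELOMERE_TRIM_BP,
    GenomicInterval,
    assign_arm,
    cytoband_label,
)

__all__ = ["merge_adjacent_segments", "annotate_arm_focal", "annotate_events"]

ARM_FRACTION_MIN = 0.10  # strict: fraction == 0.10 is dropped
ARM_FRACTION_ARM_LEVEL = 0.80  # strict: fraction == 0.80 is focal
MIN_EVENT_LENGTH_BP = 200_000

EVENT_COLUMNS = [
    "chrom", "start", "end", "status", "arm", "arm_fraction", "scope", "label",
]

CNV_STATUSES = ("amp", "bamp", "del", "bdel", "cnloh")


def merge_adjacent_segments(
    segments: pd.DataFrame,
    arms: ChromArmTable,
    telomere_trim_bp: int = DEFAULT_TELOMERE_TRIM_BP,
) -> pd.DataFrame:
    """Merge consecutive same-status CNV segments within one chromosome arm.

    ``segments`` needs columns (chrom, start, end, category); neutral rows
    are ignored.  Returns candidate events with their arm and the fraction
    of the trimmed arm they span (columns of ``EVENT_COLUMNS`` minus
    scope/label).  Merging never crosses an arm boundary.
    """
    segs = segments[segments["category"].isin(CNV_STATUSES)].copy()
    if segs.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS[:6])
    arm_labels, arm_lengths = [], []
    for r in segs.itertuples():
        arm, eff_len = assign_arm(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            arms,
            telomere_trim_bp=telomere_trim_bp,
        )
        arm_labels.append(arm)
        arm_lengths.append(eff_len)
    segs["arm"] = arm_labels
    segs["arm_length"] = arm_lengths
    segs = segs[segs["arm"] != "unassigned"]
    segs = segs.sort_values(["chrom", "start"], kind="stable")
    rows = []
    prev = None
    for r in segs.itertuples():
        if (
            prev is not None
            and r.chrom == prev["chrom"]
            and r.arm == prev["arm"]
            and r.category == prev["status"]
        ):
            prev["end"] = max(prev["end"], int(r.end))
            prev["span"] += int(r.end) - int(r.start)
        else:
            if prev is not None:
                rows.append(prev)
            prev = {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end),
                "status": r.category,
                "arm": r.arm,
                "arm_length": int(r.arm_length),
                "span": int(r.end) - int(r.start),
            }
    if prev is not None:
        rows.append(prev)
    out = pd.DataFrame(rows)
    # covered span (sum of member segment lengths) against the trimmed arm
    out["arm_fraction"] = out["span"] / out["arm_length"]
    return out[["chrom", "start", "end", "status", "arm", "arm_fraction"]]


def annotate_arm_focal(
    candidates: pd.DataFrame, arms: ChromArmTable, bands: CytobandTable | None = None
) -> pd.DataFrame:
    """Label merged candidates as arm-level, focal (with cytobands) or dropped.

    arm_fraction > 0.8 -> arm-level ("chr5p-arm-amp" style label);
    0.1 < fraction <= 0.8 -> focal with a cytoband range label;
    fraction <= 0.1 or span < 200 kb -> dropped.
    """
    if candidates.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    out = candidates.copy()
    scopes, labels = [], []
    for r in out.itertuples():
        length = int(r.end) - int(r.start)
        if r.arm_fraction <= ARM_FRACTION_MIN or length < MIN_EVENT_LENGTH_BP:
            scopes.append("dropped")
            labels.append("")
        elif r.arm_fraction > ARM_FRACTION_ARM_LEVEL:
            scopes.append("arm")
            labels.append(f"{r.chrom}{r.arm}-arm-{r.status}")
        else:
            scopes.append("focal")
            band = ""
            if bands is not None:
                try:
                    band = cytoband_label(
                        GenomicInterval(r.chrom, int(r.start), int(r.end)), bands
                    )
                except KeyError:
                    band = ""
            labels.append(f"{r.chrom}{band}-focal-{r.status}" if band else
                          f"{r.chrom}{r.arm}-focal-{r.status}")
    out["scope"] = scopes
    out["label"] = labels
    return out[EVENT_COLUMNS]


def annotate_events(
    segments: pd.DataFrame,
    arms: ChromArmTable,
    bands: CytobandTable | None = None,
    telomere_trim_bp: int = DEFAULT_TELOMERE_TRIM_BP,
    keep_dropped: bool = False,
) -> pd.DataFrame:
    """Full annotation: merge within arms, then scope + label each event."""
    candidates = merge_adjacent_segments(segments, arms, telomere_trim_bp)
    events = annotate_arm_focal(candidates, arms, bands)
    if not keep_dropped and not events.empty:
        events = events[events["scope"] != "dropped"].reset_index(drop=True)
    return events
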