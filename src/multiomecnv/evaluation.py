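"""Length-weighted precision/recall/F1 of CNV calls against truth segments.

Ground truth comes from WGS segmentations rescaled to the cancer-cell
fraction: total copy number below 1.3 is a deletion, above 2.5 an
amplification, anything between is neutral (optionally copy-neutral LOH when
a minor-allele copy number is supplied).  Precision is the overlapped CNV
length divided by the total predicted CNV length, recall divides by the
total truth CNV length, and F1 is their harmonic mean.  Metrics can be
stratified by status or by arm-level/focal scope, and a detection matrix
marks an event as detected in a mode when its recall is at least 0.8.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "truth_from_wgs_segments",
    "precision_recall_f1",
    "stratified_metrics",
    "detection_matrix",
    "DEL_CN_THRESHOLD",
    "AMP_CN_THRESHOLD",
]

DEL_CN_THRESHOLD = 1.3  # total CN < 1.3 -> del
AMP_CN_THRESHOLD = 2.5  # total CN > 2.5 -> amp
CNLOH_MINOR_CN_THRESHOLD = 0.3  # minor CN < 0.3 within neutral total -> cnloh
DETECTION_RECALL_THRESHOLD = 0.8

# predicted statuses that count as overlapping each truth status when
# truth comes from total-CN thresholds (which cannot separate bamp from amp)
STATUS_EQUIV = {
    "amp": {"amp", "bamp"},
    "del": {"del", "bdel"},
    "cnloh": {"cnloh"},
    "bamp": {"bamp", "amp"},
    "bdel": {"bdel", "del"},
}


def truth_from_wgs_segments(
    segs: pd.DataFrame | str, use_minor_cn: bool = True
) -> pd.DataFrame:
    """Threshold a WGS seg table into del/amp/cnloh/neutral truth statuses.

    ``segs`` is a DataFrame or TSV path with columns (chrom, start, end,
    total_cn[, minor_cn]); copy numbers must already be rescaled to the
    cancer cells.  When ``use_minor_cn`` and a minor_cn column is present,
    copy-neutral totals with minor CN < 0.3 become cnloh.
    """
    if not isinstance(segs, pd.DataFrame):
        segs = pd.read_csv(segs, sep="\t")
    if "total_cn" not in segs.columns:
        raise ValueError("seg table needs a total_cn column")
    bad = segs["total_cn"].isna()
    if bad.any():
        raise ValueError(f"missing total_cn at rows {list(segs.index[bad])[:5]}")
    out = segs.copy()
    cn = out["total_cn"].values.astype(float)
    status = np.where(cn < DEL_CN_THRESHOLD, "del",
                      np.where(cn > AMP_CN_THRESHOLD, "amp", "neutral"))
    if use_minor_cn and "minor_cn" in out.columns:
        minor = out["minor_cn"].values.astype(float)
        cnloh = (
            (status == "neutral")
            & ~np.isnan(minor)
            & (minor < CNLOH_MINOR_CN_THRESHOLD)
            & (cn >= DEL_CN_THRESHOLD)
            & (cn <= AMP_CN_THRESHOLD)
        )
        status = np.where(cnloh, "cnloh", status)
    out["status"] = status
    return out


def _overlap_by_chrom(pred: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Total overlapped bp between two sets of (within-side disjoint) intervals."""
    total = 0
    for chrom, p in pred.groupby("chrom"):
        t = truth[truth["chrom"] == chrom]
        if t.empty:
            continue
        ps, pe = p["start"].values, p["end"].values
        ts, te = t["start"].values, t["end"].values
        ov = np.maximum(
            0, np.minimum(pe[:, None], te[None, :]) - np.maximum(ps[:, None], ts[None, :])
        )
        total += int(ov.sum())
    return total


def _cnv_rows(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["status"] != "neutral"]


def precision_recall_f1(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    match_status: bool = True,
    stratum: str = "overall",
) -> pd.Series:
    """Length-weighted precision/recall/F1 of predicted vs truth CNV intervals.

    Both tables need (chrom, start, end, status) with non-overlapping rows
    within each side; neutral rows are excluded from both numerator and
    denominators.  With ``match_status`` the overlap only counts between
    compatible statuses (bamp predictions count toward amp truth, since
    total-CN truth cannot separate them).  Conventions for empty sides:
    empty predictions give precision NaN, recall 0; empty truth gives recall
    NaN; F1 is 0 whenever either defined component is 0 and NaN when both
    components are NaN.
    """
    p = _cnv_rows(pred)
    t = _cnv_rows(truth)
    pred_len = int((p["end"] - p["start"]).sum()) if len(p) else 0
    truth_len = int((t["end"] - t["start"]).sum()) if len(t) else 0
    if match_status:
        overlap = 0
        for status in t["status"].unique():
            equiv = STATUS_EQUIV.get(status, {status})
            overlap += _overlap_by_chrom(
                p[p["status"].isin(equiv)], t[t["status"] == status]
            )
    else:
        overlap = _overlap_by_chrom(p, t)
    precision = overlap / pred_len if pred_len else np.nan
    recall = overlap / truth_len if truth_len else np.nan
    if np.isnan(precision) and np.isnan(recall):
        f1 = np.nan
    else:
        pr = 0.0 if np.isnan(precision) else precision
        rc = 0.0 if np.isnan(recall) else recall
        f1 = 0.0 if pr + rc == 0 else 2 * pr * rc / (pr + rc)
    return pd.Series(
        {
            "stratum": stratum,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "overlap_bp": overlap,
            "pred_bp": pred_len,
            "truth_bp": truth_len,
        }
    )


def stratified_metrics(
    pred: pd.DataFrame, truth: pd.DataFrame, strata: tuple = ("status", "scope")
) -> pd.DataFrame:
    """Overall metrics plus one row per status and/or arm-vs-focal stratum.

    Status strata are taken from the truth side; scope strata require a
    ``scope`` column on both sides (from event annotation).  Strata with
    empty truth report NaN recall rather than a vacuous 1.
    """
    rows = [precision_recall_f1(pred, truth, match_status=True, stratum="overall")]
    if "status" in strata:
        for status in sorted(_cnv_rows(truth)["status"].unique()):
            equiv = STATUS_EQUIV.get(status, {status})
            rows.append(
                precision_recall_f1(
                    pred[pred["status"].isin(equiv)],
                    truth[truth["status"] == status],
                    match_status=True,
                    stratum=f"status:{status}",
                )
            )
    if "scope" in strata and "scope" in truth.columns and "scope" in pred.columns:
        for scope in sorted(truth.loc[truth["scope"].notna(), "scope"].unique()):
            rows.append(
                precision_recall_f1(
                    pred[pred["scope"] == scope],
                    truth[truth["scope"] == scope],
                    match_status=True,
                    stratum=f"scope:{scope}",
                )
            )
    return pd.DataFrame(rows)


def event_recalls(
    pred_by_mode: dict, truth: pd.DataFrame, match_status: bool = True
) -> pd.DataFrame:
    """Per-truth-event recall under each mode's predictions.

    Returns one row per truth CNV event with a recall column per mode.
    """
    t = _cnv_rows(truth).reset_index(drop=True)
    out = t[["chrom", "start", "end", "status"]].copy()
    for mode, pred in pred_by_mode.items():
        recalls = []
        for r in t.itertuples():
            one = t.iloc[[r.Index]]
            m = precision_recall_f1(pred, one, match_status=match_status)
            recalls.append(m["recall"])
        out[mode] = recalls
    return out


def detection_matrix(
    recalls: pd.DataFrame,
    modes: list[str] | None = None,
    threshold: float = DETECTION_RECALL_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean detection table (recall >= threshold) + per-mode-subset counts.

    ``recalls`` is the output of :func:`event_recalls`; the returned counts
    are UpSet-style: each event contributes to exactly the subset of modes
    that detected it (the empty subset when none did).
    """
    if modes is None:
        modes = [
            c for c in recalls.columns if c not in ("chrom", "start", "end", "status")
        ]
    detected = recalls[modes].fillna(0.0) >= threshold
    detected.columns = modes
    combos = []
    for _, row in detected.iterrows():
        combo = "+".join([m for m in modes if row[m]]) or "(none)"
        combos.append(combo)
    counts = pd.Series(combos).value_counts().sort_index()
    out = recalls[["chrom", "start", "end", "status"]].copy()
    for m in modes:
        out[m] = detected[m].values
    out["modes"] = combos
    return out, counts
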