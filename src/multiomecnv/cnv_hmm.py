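"""Joint 15-state HMM over bin coverage and phased SNP allele fractions.

Hidden states describe the copy-number configuration of a genomic segment in
the aberrant cell fraction: total dosage phi (expected coverage fold change
vs diploid) and paternal haplotype fraction theta (expected fraction of
phased reads from the arbitrarily-labelled paternal haplotype).  Coverage
counts are Poisson-log-normal around N * lambda_b * phi; phased allele
counts are beta-binomial around theta.  States with allelic imbalance come
in mirrored (up/down) pairs; transitions between mirrors model population
phase-switch errors, with probability growing with inter-SNP distance.
Viterbi decoding per chromosome yields segments, each with MLE (phi, theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import betabinom, poisson

from .allele_counts import DEFAULT_NU_BP, PseudobulkAlleleTrack, phase_switch_prob
from .bin_aggregation import CellBinCounts, ReferenceProfile
from .genome_bins import chrom_sort_key

__all__ = [
    "CATEGORIES",
    "HmmState",
    "HmmStateSpace",
    "HmmParams",
    "PseudobulkProfile",
    "expected_state_params",
    "build_state_space",
    "pln_loglik",
    "bb_loglik",
    "estimate_sigma",
    "select_reference_column",
    "make_pseudobulk_profile",
    "build_observation_track",
    "viterbi_segment",
    "estimate_segment_params",
    "classify_segment",
    "SegmentationResult",
]

CATEGORIES = ("neutral", "del", "cnloh", "amp", "bamp", "bdel")
# deterministic tie-break preference (first wins)
CATEGORY_TIEBREAK = ("neutral", "del", "amp", "cnloh", "bamp", "bdel")

THETA_EPS = 1e-6
PHI_FLOOR = 0.05  # residual coverage floor for homozygous-deletion states


def expected_state_params(c_s: float, m_s: float, f: float) -> tuple[float, float]:
    """Expected (phi, theta) for a state with c_s total / m_s paternal copies.

    ``f`` is the effective fraction of aberrant cells in the pseudobulk; the
    remaining 1-f is diploid (2 copies, 1 paternal).  A fully deleted state
    (zero expected coverage) gets theta = 0.5 by convention.
    """
    if not (0 <= m_s <= c_s):
        raise ValueError(f"need 0 <= m_s <= c_s, got c={c_s}, m={m_s}")
    if not (0 <= f <= 1):
        raise ValueError(f"need 0 <= f <= 1, got {f}")
    total = (1 - f) * 2 + f * c_s
    phi = total / 2.0
    if total == 0:
        return 0.0, 0.5
    theta = ((1 - f) * 1 + f * m_s) / total
    return phi, theta


@dataclass(frozen=True)
class HmmState:
    name: str
    category: str
    phase: str  # "up" | "down" | "balanced"
    strength: str  # "strong" | "weak" | "na"
    c: float
    m: float
    f: float
    phi: float
    theta: float


class HmmStateSpace:
    """The 15-state table plus mirror (haplotype-flip) pairing."""

    def __init__(self, states: list[HmmState]):
        self.states = states
        self.names = [s.name for s in states]
        self.index = {s.name: i for i, s in enumerate(states)}
        self.phi = np.array([s.phi for s in states])
        self.theta = np.array([s.theta for s in states])
        self.categories = [s.category for s in states]
        # mirror: same category/strength, opposite phase; balanced maps to itself
        mirror = np.arange(len(states))
        for i, s in enumerate(states):
            if s.phase in ("up", "down"):
                want = "down" if s.phase == "up" else "up"
                for j, o in enumerate(states):
                    if (
                        o.category == s.category
                        and o.strength == s.strength
                        and o.phase == want
                    ):
                        mirror[i] = j
        self.mirror = mirror
        self.neutral_index = self.index["neutral"]

    def __len__(self) -> int:
        return len(self.states)

    def category_indices(self, category: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.categories) if c == category])


def build_state_space(weak_fraction: float = 0.5) -> HmmStateSpace:
    """Enumerate the 15 states.

    neutral(1) + {del, cnloh, amp} x {up, down} x {strong f=1, weak f=weak_fraction}
    (12) + balanced amplification(1) + balanced deletion(1).  Weak states model
    subclonal or contamination-diluted events; (c, m) per category: del (1,1)/
    (1,0), cnloh (2,2)/(2,0), amp (3,2)/(3,1), bamp (4,2), bdel (0,0).
    """
    spec = []
    cm = {"del": (1, 1, 1, 0), "cnloh": (2, 2, 2, 0), "amp": (3, 2, 3, 1)}
    for cat, (c_up, m_up, c_dn, m_dn) in cm.items():
        for strength, f in (("strong", 1.0), ("weak", weak_fraction)):
            spec.append((f"{cat}_up_{strength}", cat, "up", strength, c_up, m_up, f))
            spec.append((f"{cat}_down_{strength}", cat, "down", strength, c_dn, m_dn, f))
    states = [HmmState("neutral", "neutral", "balanced", "na", 2, 1, 1.0, 1.0, 0.5)]
    for name, cat, phase, strength, c, m, f in spec:
        phi, theta = expected_state_params(c, m, f)
        states.append(HmmState(name, cat, phase, strength, c, m, f, phi, theta))
    phi, theta = expected_state_params(4, 2, 1.0)
    states.append(HmmState("bamp", "bamp", "balanced", "na", 4, 2, 1.0, phi, theta))
    phi, theta = expected_state_params(0, 0, 1.0)
    states.append(HmmState("bdel", "bdel", "balanced", "na", 0, 0, 1.0, phi, theta))
    return HmmStateSpace(states)


@dataclass
class HmmParams:
    """Tuning constants of the joint HMM (none are data-fit by default).

    t: probability of switching copy-number state between adjacent
    observations; gamma: beta-binomial concentration (larger = closer to
    binomial); sigma: per-modality log-normal over-dispersion of coverage;
    nu: phase-switch length scale in bp.
    """

    t: float = 1e-5
    gamma: float = 20.0
    sigma: dict = field(default_factory=lambda: {"RNA": 0.3, "ATAC": 0.3})
    nu: float = DEFAULT_NU_BP
    gh_order: int = 32

    def __post_init__(self):
        if not 0 < self.t < 1:
            raise ValueError("t must be in (0, 1)")
        if self.gamma <= 0 or self.nu <= 0:
            raise ValueError("gamma and nu must be positive")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# emissions


def pln_loglik(x, rate, sigma: float, gh_order: int = 32):
    """Poisson-log-normal log pmf: x ~ Poisson(rate * e^z), z ~ N(-sigma^2/2, sigma^2).

    The -sigma^2/2 offset keeps E[rate * e^z] = rate, so sigma inflates the
    variance without shifting the mean.  Evaluated by fixed-order
    Gauss-Hermite quadrature; sigma = 0 degenerates to the exact Poisson.
    Broadcasts over ``x`` and ``rate``.
    """
    x = np.asarray(x)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("rate must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        out = poisson.logpmf(x, rate)
        return float(out) if out.ndim == 0 else out
    # adaptive (mode-centered) Gauss-Hermite: the integrand in z is sharply
    # peaked for large counts, so nodes are placed at the Laplace mode/scale
    mu = -0.5 * sigma**2
    xb, rateb = np.broadcast_arrays(x, rate)
    xb = xb.astype(float)
    # Newton iterations for the mode of x*z - rate*e^z - (z-mu)^2/(2 sigma^2)
    z = np.where(xb > 0, np.log((xb + 0.5) / rateb), mu)
    for _ in range(30):
        ez = rateb * np.exp(z)
        grad = xb - ez - (z - mu) / sigma**2
        hess = ez + 1.0 / sigma**2
        step = grad / hess
        z = z + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    scale = 1.0 / np.sqrt(rateb * np.exp(z) + 1.0 / sigma**2)
    nodes, weights = np.polynomial.hermite.hermgauss(gh_order)
    zk = z[..., None] + np.sqrt(2.0) * scale[..., None] * nodes  # (..., K)
    g = (
        poisson.logpmf(xb[..., None], rateb[..., None] * np.exp(zk))
        - 0.5 * np.log(2 * np.pi * sigma**2)
        - (zk - mu) ** 2 / (2 * sigma**2)
    )
    ll = g + nodes**2 + np.log(weights)
    out = logsumexp(ll, axis=-1) + np.log(np.sqrt(2.0) * scale)
    return float(out) if out.ndim == 0 else out


def bb_loglik(a, d, theta, gamma: float):
    """Beta-binomial log pmf of a paternal reads out of d at mean fraction theta.

    alpha = theta * gamma, beta = (1 - theta) * gamma; boundary theta is
    clamped to [1e-6, 1 - 1e-6].  Broadcasts over all arguments.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    theta = np.clip(np.asarray(theta, dtype=float), THETA_EPS, 1 - THETA_EPS)
    out = betabinom.logpmf(a, d, theta * gamma, (1 - theta) * gamma)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def estimate_sigma(
    x, expect, fallback: float = 0.3, min_expect: float = 20.0
) -> float:
    """Method-of-moments estimate of the PLN overdispersion ``sigma``.

    From counts with known expectations (e.g. held-out normal cells against
    the reference), the variance of the ratio x/expect decomposes into the
    Poisson part (mean of 1/expect) plus the log-normal inflation
    ``e^{sigma^2} - 1``.  Returns ``fallback`` when the residual variance is
    not above the Poisson floor (clean data or too little of it).
    """
    x = np.asarray(x, dtype=float)
    expect = np.asarray(expect, dtype=float)
    keep = expect >= min_expect
    if keep.sum() < 10:
        return fallback
    r = x[keep] / expect[keep]
    excess = r.var() - np.mean(1.0 / expect[keep])
    if excess <= 0:
        return fallback
    return float(np.sqrt(np.log1p(excess)))


# ---------------------------------------------------------------------------
# pseudobulk profile and observation track

TRACK_COLUMNS = [
    "kind", "chrom", "pos", "start", "end", "bin_id", "modality",
    "x", "expect", "a", "d",
]


@dataclass
class PseudobulkProfile:
    """Everything the HMM observes for one pseudobulk.

    ``cov`` has one row per (bin, modality): raw count ``x`` and expected
    count ``expect`` = N_modality * lambda_bin under the matched reference
    column.  ``allele`` is the pooled phased SNP track.
    """

    cov: pd.DataFrame
    allele: PseudobulkAlleleTrack | None
    reference_columns: dict
    excluded_bins: pd.DataFrame


def select_reference_column(
    x: np.ndarray, ref: ReferenceProfile, sigma: float, labels=None,
    gh_order: int = 32,
) -> str:
    """Pick the reference column maximizing PLN likelihood of ``x`` at phi = 1."""
    best, best_ll = None, -np.inf
    for label in labels if labels is not None else ref.labels:
        lam = ref.column(label)
        keep = lam > 0
        if not keep.any():
            continue
        n_tot = x[keep].sum() / lam[keep].sum()
        if n_tot <= 0:
            continue
        ll = pln_loglik(x[keep], n_tot * lam[keep], sigma, gh_order).sum()
        if ll > best_ll:
            best, best_ll = label, ll
    if best is None:
        raise ValueError("no usable reference column")
    return best


def make_pseudobulk_profile(
    binned: CellBinCounts,
    ref: ReferenceProfile,
    phased_records: pd.DataFrame | None = None,
    cells=None,
    params: HmmParams | None = None,
) -> PseudobulkProfile:
    """Aggregate a cell subset into the HMM's pseudobulk observations.

    Sums bin counts per modality, matches each modality to its best reference
    column (modality-suffixed columns are restricted to that modality), and
    pools the phased allele records over the same cells.  Bins with zero
    reference rate are excluded and reported.
    """
    from .allele_counts import pseudobulk_haplotype_counts
    from .bin_aggregation import MODALITY_SEP

    params = params or HmmParams()
    sub = binned if cells is None else binned.subset_cells(cells)
    if len(sub.cells) == 0:
        raise ValueError("empty pseudobulk cell subset")
    binset = sub.binset
    mid = binset.midpoints()
    cov_parts, excluded, ref_cols = [], [], {}
    for modality in sub.cells["modality"].unique():
        mask = (sub.cells["modality"] == modality).values
        x = np.asarray(sub.counts[mask].sum(axis=0)).ravel().astype(np.int64)
        suffixed = [c for c in ref.labels if c.endswith(f"{MODALITY_SEP}{modality}")]
        label = select_reference_column(
            x, ref, params.sigma.get(modality, 0.3), labels=suffixed or None,
        )
        ref_cols[modality] = label
        lam = ref.column(label)
        keep = lam > 0
        excluded.append(
            pd.DataFrame(
                {
                    "bin_id": binset.bin_ids[~keep],
                    "modality": modality,
                    "reason": "zero_reference_rate",
                }
            )
        )
        n_tot = x[keep].sum() / lam[keep].sum()
        part = binset.df.loc[keep, ["chrom", "start", "end", "bin_id"]].copy()
        part["pos"] = mid[keep]
        part["modality"] = modality
        part["x"] = x[keep]
        part["expect"] = n_tot * lam[keep]
        cov_parts.append(part)
    cov = pd.concat(cov_parts, ignore_index=True)
    allele = None
    if phased_records is not None and len(phased_records):
        track_cells = None
        if cells is not None:
            track_cells = list(sub.cells["cell"].values)
        allele = pseudobulk_haplotype_counts(phased_records, cells=track_cells)
    return PseudobulkProfile(
        cov=cov,
        allele=allele,
        reference_columns=ref_cols,
        excluded_bins=pd.concat(excluded, ignore_index=True),
    )


def build_observation_track(p: PseudobulkProfile) -> pd.DataFrame:
    """Interleave coverage and allele observations in genome order.

    One row per observation: coverage rows carry (x, expect, modality) at the
    bin midpoint, allele rows carry (a, d) at the SNP position.  In combined
    mode the RNA and ATAC counts of one bin are two adjacent rows emitted
    from the same hidden state.
    """
    rows = [
        p.cov.assign(kind="cov", a=np.nan, d=np.nan)[
            ["kind", "chrom", "pos", "start", "end", "bin_id", "modality", "x",
             "expect", "a", "d"]
        ]
    ]
    if p.allele is not None and len(p.allele):
        al = p.allele.df
        rows.append(
            pd.DataFrame(
                {
                    "kind": "snp",
                    "chrom": al["chrom"],
                    "pos": al["pos"],
                    "start": al["pos"],
                    "end": al["pos"] + 1,
                    "bin_id": None,
                    "modality": None,
                    "x": np.nan,
                    "expect": np.nan,
                    "a": al["a"],
                    "d": al["d"],
                }
            )
        )
    track = pd.concat(rows, ignore_index=True)
    if track.empty:
        raise ValueError("empty observation track")
    track["_key"] = track["chrom"].map(chrom_sort_key)
    # coverage before SNP at identical position, RNA before ATAC, for determinism
    track["_kind"] = (track["kind"] == "snp").astype(int)
    track = (
        track.sort_values(["_key", "pos", "_kind", "modality"], kind="stable")
        .drop(columns=["_key", "_kind"])
        .reset_index(drop=True)
    )
    return track


def emission_matrix(
    track: pd.DataFrame, params: HmmParams, states: HmmStateSpace
) -> np.ndarray:
    """(n_obs, n_states) log-likelihood matrix."""
    n, K = len(track), len(states)
    em = np.zeros((n, K))
    is_cov = (track["kind"] == "cov").values
    phi = np.maximum(states.phi, PHI_FLOOR)
    if is_cov.any():
        for modality in track.loc[is_cov, "modality"].unique():
            sel = is_cov & (track["modality"] == modality).values
            x = track.loc[sel, "x"].values.astype(np.int64)
            expect = track.loc[sel, "expect"].values
            sigma = params.sigma.get(modality, 0.3)
            em[sel] = pln_loglik(
                x[:, None], expect[:, None] * phi[None, :], sigma, params.gh_order
            )
    is_snp = ~is_cov
    if is_snp.any():
        a = track.loc[is_snp, "a"].values.astype(np.int64)
        d = track.loc[is_snp, "d"].values.astype(np.int64)
        em[is_snp] = bb_loglik(
            a[:, None], d[:, None], states.theta[None, :], params.gamma
        )
    return em


def transition_matrix(
    dist: float, params: HmmParams, states: HmmStateSpace
) -> np.ndarray:
    """(K, K) transition matrix for one inter-observation gap of ``dist`` bp.

    Copy-number state switches cost ``t`` spread uniformly over the other
    K-1 states; within the retained 1-t mass, mirrored (up/down) states
    exchange probability ``phase_switch_prob(dist)``, the distance-dependent
    haplotype-flip channel.  Rows sum to one.
    """
    K = len(states)
    t = params.t
    p_flip = phase_switch_prob(dist, params.nu)
    T = np.full((K, K), t / (K - 1))
    idx = np.arange(K)
    T[idx, idx] = 1.0 - t
    has_m = states.mirror != idx
    T[idx[has_m], idx[has_m]] = (1.0 - t) * (1.0 - p_flip)
    T[idx[has_m], states.mirror[has_m]] = (1.0 - t) * p_flip + t / (K - 1)
    return T


def _initial(params: HmmParams, states: HmmStateSpace) -> np.ndarray:
    K = len(states)
    init = np.full(K, params.t / (K - 1))
    init[states.neutral_index] = 1.0 - params.t
    return init


def _viterbi_chrom(
    em: np.ndarray, dists: np.ndarray, params: HmmParams, states: HmmStateSpace
) -> np.ndarray:
    n, K = em.shape
    delta = np.log(_initial(params, states)) + em[0]
    back = np.zeros((n, K), dtype=np.int64)
    cols = np.arange(K)
    for i in range(1, n):
        logT = np.log(transition_matrix(dists[i], params, states))
        scores = delta[:, None] + logT
        back[i] = np.argmax(scores, axis=0)
        delta = scores[back[i], cols] + em[i]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _posteriors_chrom(
    em: np.ndarray, dists: np.ndarray, params: HmmParams, states: HmmStateSpace
) -> np.ndarray:
    """Forward-backward per-observation state posteriors (n_obs, K).

    Scaled (probability-space) recursions: emissions are exponentiated after
    per-row max subtraction and alpha/beta renormalized each step, which is
    the standard underflow-safe scaling.
    """
    n, K = em.shape
    b = np.exp(em - em.max(axis=1, keepdims=True))
    alpha = np.zeros((n, K))
    beta = np.zeros((n, K))
    a = _initial(params, states) * b[0]
    alpha[0] = a / a.sum()
    Ts = [None] * n
    for i in range(1, n):
        Ts[i] = transition_matrix(dists[i], params, states)
        a = (alpha[i - 1] @ Ts[i]) * b[i]
        alpha[i] = a / a.sum()
    beta[-1] = 1.0 / K
    for i in range(n - 2, -1, -1):
        v = Ts[i + 1] @ (b[i + 1] * beta[i + 1])
        beta[i] = v / v.sum()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


@dataclass
class SegmentationResult:
    """Viterbi decoding output: annotated track plus collapsed segments."""

    track: pd.DataFrame  # adds columns: state, state_name, category, segment
    segments: pd.DataFrame
    states: HmmStateSpace
    params: HmmParams

    def segment_track(self, segment_id: int) -> pd.DataFrame:
        return self.track[self.track["segment"] == segment_id]


SEGMENT_COLUMNS = [
    "segment", "chrom", "start", "end", "category", "phi_hat", "theta_hat",
    "n_bins", "n_snps", "log_fc", "p_hf", "theta_low_conf",
]


def viterbi_segment(
    track: pd.DataFrame,
    params: HmmParams | None = None,
    states: HmmStateSpace | None = None,
    compute_posteriors: bool = True,
) -> SegmentationResult:
    """Maximum a posteriori segmentation of an observation track.

    Chromosomes are decoded independently; the state path is collapsed into
    maximal runs of constant category, each reported as one segment with MLE
    dosage phi_hat and major-haplotype fraction theta_hat (in [0.5, 1]).
    When ``compute_posteriors`` is set, segments are (re)classified by the
    category with the largest aggregated forward-backward posterior mass.
    """
    params = params or HmmParams()
    states = states or build_state_space()
    if track.empty:
        raise ValueError("empty observation track")
    track = track.reset_index(drop=True).copy()
    state_idx = np.zeros(len(track), dtype=np.int64)
    post = np.zeros((len(track), len(states))) if compute_posteriors else None
    for chrom, grp in track.groupby("chrom", sort=False):
        em = emission_matrix(grp, params, states)
        dists = np.diff(grp["pos"].values, prepend=grp["pos"].values[0])
        loc = grp.index.values
        state_idx[loc] = _viterbi_chrom(em, dists, params, states)
        if compute_posteriors:
            post[loc] = _posteriors_chrom(em, dists, params, states)
    track["state"] = state_idx
    track["state_name"] = [states.names[i] for i in state_idx]
    track["category"] = [states.categories[i] for i in state_idx]
    # collapse into runs of constant category per chromosome
    new_seg = (track["category"] != track["category"].shift()) | (
        track["chrom"] != track["chrom"].shift()
    )
    track["segment"] = new_seg.cumsum() - 1
    rows = []
    for seg_id, seg in track.groupby("segment", sort=True):
        cat = seg["category"].iloc[0]
        est = estimate_segment_params(seg, params, states)
        if cat != "neutral":
            # re-type by continuous-fraction profile matching of (phi, theta);
            # the discrete strong/weak state grid can mislabel events whose
            # aberrant-cell fraction falls between its f values
            cat = classify_segment(
                est["phi_hat"],
                est["theta_hat"] if not est["theta_low_conf"] else None,
            )
        cov = seg[seg["kind"] == "cov"]
        rows.append(
            {
                "segment": seg_id,
                "chrom": seg["chrom"].iloc[0],
                "start": int(seg["start"].min()),
                "end": int(seg["end"].max()),
                "category": cat,
                "phi_hat": est["phi_hat"],
                "theta_hat": est["theta_hat"],
                "n_bins": int(cov["bin_id"].nunique()),
                "n_snps": int((seg["kind"] == "snp").sum()),
                "log_fc": est["log_fc"],
                "p_hf": est["p_hf"],
                "theta_low_conf": est["theta_low_conf"],
            }
        )
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentationResult(track, segments, states, params)


def _oriented_counts(seg: pd.DataFrame, states: HmmStateSpace):
    """Per-SNP counts flipped onto the major haplotype using the Viterbi phase."""
    snps = seg[seg["kind"] == "snp"]
    if snps.empty:
        return snps, None, None
    a = snps["a"].values.astype(np.int64)
    d = snps["d"].values.astype(np.int64)
    theta_path = states.theta[snps["state"].values]
    a_major = np.where(theta_path < 0.5, d - a, a)
    balanced = np.isclose(theta_path, 0.5)
    return snps, np.where(balanced, a, a_major), d


def estimate_segment_params(
    seg: pd.DataFrame, params: HmmParams, states: HmmStateSpace | None = None
) -> dict:
    """MLE of (phi, theta) for one segment of an annotated track.

    phi_hat maximizes the PLN likelihood of the segment's coverage counts;
    theta_hat maximizes the beta-binomial likelihood of its phased allele
    counts oriented onto the major haplotype by the Viterbi phase, reported
    in [0.5, 1].  Segments decoded as allelically balanced use a symmetric
    two-component mixture so the estimate is phase-free.  With zero SNPs,
    theta_hat = 0.5 flagged low-confidence.
    """
    states = states or build_state_space()
    cov = seg[seg["kind"] == "cov"]
    if len(cov):
        x = cov["x"].values.astype(np.int64)
        expect = cov["expect"].values
        sigmas = np.array(
            [params.sigma.get(m, 0.3) for m in cov["modality"].values]
        )

        def neg_cov(phi):
            return -np.sum(pln_loglik(x, expect * phi, float(sigmas.mean()), params.gh_order))

        # per-modality sigma: evaluate separately when mixed
        if cov["modality"].nunique() > 1:
            groups = [
                (
                    g["x"].values.astype(np.int64),
                    g["expect"].values,
                    params.sigma.get(m, 0.3),
                )
                for m, g in cov.groupby("modality")
            ]

            def neg_cov(phi):  # noqa: F811
                return -sum(
                    np.sum(pln_loglik(xg, eg * phi, sg, params.gh_order))
                    for xg, eg, sg in groups
                )

        res = minimize_scalar(neg_cov, bounds=(PHI_FLOOR, 4.0), method="bounded")
        phi_hat = float(res.x)
        with np.errstate(divide="ignore"):
            log_fc = float(np.log2(max(phi_hat, 1e-12)))
    else:
        phi_hat, log_fc = 1.0, 0.0
    snps, a_major, d = _oriented_counts(seg, states)
    if a_major is None or d.sum() == 0:
        return {
            "phi_hat": phi_hat, "theta_hat": 0.5, "log_fc": log_fc,
            "p_hf": np.nan, "theta_low_conf": True,
        }
    balanced_mode = bool(
        np.isclose(states.theta[snps["state"].values], 0.5).all()
    )
    a_arr = a_major
    if balanced_mode:

        def neg_allele(theta):
            both = np.logaddexp(
                bb_loglik(a_arr, d, theta, params.gamma),
                bb_loglik(a_arr, d, 1 - theta, params.gamma),
            ) - np.log(2)
            return -np.sum(both)

    else:

        def neg_allele(theta):
            return -np.sum(bb_loglik(a_arr, d, theta, params.gamma))

    res = minimize_scalar(neg_allele, bounds=(0.5, 1 - THETA_EPS), method="bounded")
    theta_hat = float(res.x)
    return {
        "phi_hat": phi_hat,
        "theta_hat": theta_hat,
        "log_fc": log_fc,
        "p_hf": float(a_arr.sum() / d.sum()),
        "theta_low_conf": False,
    }


# canonical (total, paternal) copies per category, at aberrant fraction f = 1
CATEGORY_CM = {
    "neutral": (2, 1),
    "del": (1, 1),
    "cnloh": (2, 2),
    "amp": (3, 2),
    "bamp": (4, 2),
    "bdel": (0, 0),
}
# scales making dosage and haplotype-fraction deviations commensurate
_PHI_SCALE = 0.10
_THETA_SCALE = 0.05
_MIN_EVENT_FRACTION = 0.1


def classify_segment(
    phi_hat, theta_hat=None, category_posteriors: dict | None = None
) -> str:
    """Assign a segment to a CNV category from its (phi, theta) estimates.

    Each category defines a one-parameter family of expected (phi, theta)
    profiles indexed by the aberrant-cell fraction f (non-neutral categories
    require f >= 0.1); the category whose family passes closest to the
    observed estimates wins, with theta compared on the major haplotype.
    This continuous-f matching types events correctly at any purity, where
    a discrete state grid can mislabel diluted events.  ``theta_hat=None``
    (no allele information) drops the theta term.  If aggregated per-category
    posterior mass is supplied instead, returns its argmax.  Ties break
    deterministically (neutral > del > amp > cnloh > bamp > bdel).
    """
    if category_posteriors is not None:
        return max(
            CATEGORY_TIEBREAK,
            key=lambda c: (category_posteriors.get(c, 0.0), -CATEGORY_TIEBREAK.index(c)),
        )
    theta_major = None if theta_hat is None else max(theta_hat, 1 - theta_hat)
    order = {c: i for i, c in enumerate(CATEGORY_TIEBREAK)}
    best = None
    for cat, (c, m) in CATEGORY_CM.items():
        fs = (
            np.array([0.0])
            if cat == "neutral"
            else np.linspace(_MIN_EVENT_FRACTION, 1.0, 91)
        )
        d = np.empty(len(fs))
        for i, f in enumerate(fs):
            phi_f, theta_f = expected_state_params(c, m, f)
            d[i] = ((max(phi_f, PHI_FLOOR) - phi_hat) / _PHI_SCALE) ** 2
            if theta_major is not None:
                theta_f_major = max(theta_f, 1 - theta_f)
                d[i] += ((theta_f_major - theta_major) / _THETA_SCALE) ** 2
        score = (round(float(d.min()), 10), order[cat])
        if best is None or score < best[0]:
            best = (score, cat)
    return best[1]
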