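import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, poisson

from multiomecnv.cnv_hmm import (
    HmmParams,
    bb_loglik,
    build_observation_track,
    build_state_space,
    classify_segment,
    emission_matrix,
    estimate_segment_params,
    expected_state_params,
    pln_loglik,
    transition_matrix,
    viterbi_segment,
)
from multiomecnv.cnv_hmm import _initial


def make_track(chrom, cov=None, snps=None):
    """Assemble an observation track from (pos, x, expect) and (pos, a, d) lists."""
    rows = []
    for pos, x, expect in cov or []:
        rows.append(
            dict(kind="cov", chrom=chrom, pos=pos, start=pos - 1000, end=pos + 1000,
                 bin_id=f"b{pos}", modality="RNA", x=x, expect=expect, a=np.nan, d=np.nan)
        )
    for pos, a, d in snps or []:
        rows.append(
            dict(kind="snp", chrom=chrom, pos=pos, start=pos, end=pos + 1,
                 bin_id=None, modality=None, x=np.nan, expect=np.nan, a=a, d=d)
        )
    return pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)


class TestStateSpace:
    def test_fifteen_states_with_all_categories(self):
        ss = build_state_space()
        assert len(ss) == 15
        assert set(ss.categories) == {"neutral", "del", "cnloh", "amp", "bamp", "bdel"}

    def test_neutral_is_diploid_balanced(self):
        ss = build_state_space()
        s = ss.states[ss.neutral_index]
        assert (s.c, s.m, s.phi, s.theta) == (2, 1, 1.0, 0.5)

    def test_mirror_pairs_swap_haplotypes(self):
        ss = build_state_space()
        for i, s in enumerate(ss.states):
            j = ss.mirror[i]
            assert ss.mirror[j] == i
            if s.phase == "balanced":
                assert j == i
            else:
                assert ss.states[j].theta == pytest.approx(1 - s.theta)
                assert ss.states[j].phi == pytest.approx(s.phi)

    @pytest.mark.parametrize(
        "c, m, f, phi, theta",
        [
            (1, 1, 1.0, 0.5, 1.0),
            (3, 2, 1.0, 1.5, 2 / 3),
            (2, 2, 0.5, 1.0, 0.75),
            (0, 0, 1.0, 0.0, 0.5),  # full deletion: theta by convention
        ],
    )
    def test_expected_state_params(self, c, m, f, phi, theta):
        got_phi, got_theta = expected_state_params(c, m, f)
        assert got_phi == pytest.approx(phi)
        assert got_theta == pytest.approx(theta)


class TestPlnLoglik:
    def test_sigma_zero_is_exact_poisson(self):
        x = np.arange(0, 20)
        assert np.allclose(pln_loglik(x, np.full_like(x, 3.0, dtype=float), 0.0),
                           poisson.logpmf(x, 3.0))

    @pytest.mark.parametrize(
        "x,rate,sigma",
        [(3, 2.0, 0.5), (0, 1.0, 0.3), (2, 4.0, 0.4), (8, 8.0, 0.3), (1, 0.5, 0.6)],
    )
    def test_matches_monte_carlo(self, x, rate, sigma):
        """Quadrature agrees with a seeded 1e6-draw Monte-Carlo estimate.

        Grid points keep the pmf large enough that the Monte-Carlo standard
        error sits well below the 1e-3 comparison tolerance.
        """
        rng = np.random.default_rng(123)
        z = rng.normal(-0.5 * sigma**2, sigma, 1_000_000)
        mc = np.log(np.mean(poisson.pmf(x, rate * np.exp(z))))
        assert pln_loglik(x, rate, sigma) == pytest.approx(mc, abs=1e-3)

    @pytest.mark.parametrize("rate", [0.5, 5.0, 2000.0])
    def test_normalizes_over_support(self, rate):
        xs = np.arange(0, int(rate * 6 + 300))
        total = np.exp(pln_loglik(xs, np.full_like(xs, rate, dtype=float), 0.4)).sum()
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            pln_loglik(1, 0.0, 0.3)


class TestBbLoglik:
    def test_binomial_limit_at_huge_concentration(self):
        a, d = np.arange(0, 8), 7
        got = bb_loglik(a, d, 0.3, 1e8)
        want = binom.logpmf(a, d, 0.3)
        assert np.allclose(got, want, rtol=1e-4)

    def test_imbalanced_theta_preferred_for_skewed_counts(self):
        assert bb_loglik(5, 5, 0.9, 20.0) > bb_loglik(5, 5, 0.5, 20.0)

    def test_matches_polya_urn_enumeration(self):
        """Direct check of the pmf against exhaustive Polya-urn path sums."""
        from itertools import permutations

        a, d, theta, gamma = 2, 7, 0.5, 20.0
        alpha, beta = theta * gamma, (1 - theta) * gamma
        total = 0.0
        for seq in set(permutations([1] * a + [0] * (d - a))):
            p, na, nb = 1.0, alpha, beta
            for s in seq:
                p *= (na if s else nb) / (na + nb)
                if s:
                    na += 1
                else:
                    nb += 1
            total += p
        assert bb_loglik(a, d, theta, gamma) == pytest.approx(np.log(total))

    def test_sums_to_one_over_support(self):
        ll = bb_loglik(np.arange(0, 12), 11, 0.7, 15.0)
        assert np.exp(ll).sum() == pytest.approx(1.0)

    def test_boundary_theta_clamped_not_nan(self):
        assert np.isfinite(bb_loglik(3, 5, 0.0, 10.0))
        assert np.isfinite(bb_loglik(3, 5, 1.0, 10.0))


class TestObservationTrack:
    def test_positional_interleaving(self, small_sample):
        from multiomecnv.bin_aggregation import concat_modalities
        from multiomecnv.cnv_hmm import make_pseudobulk_profile
        from multiomecnv.allele_counts import attach_phase, merge_modality_allele_counts

        binned = concat_modalities(small_sample.counts["RNA"], small_sample.counts["ATAC"])
        merged = merge_modality_allele_counts(
            small_sample.allele_counts["RNA"], small_sample.allele_counts["ATAC"]
        )
        rec, _ = attach_phase(merged, small_sample.phased_vcf)
        prof = make_pseudobulk_profile(binned, small_sample.reference, rec)
        track = build_observation_track(prof)
        for _, grp in track.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
        # combined mode: each bin kept by both modalities appears twice
        cov = track[track["kind"] == "cov"]
        per_bin = cov.groupby("bin_id")["modality"].nunique()
        assert (per_bin <= 2).all() and (per_bin == 2).any()
        # bins with zero reference rate in a modality were excluded, logged
        assert set(prof.excluded_bins["reason"]) <= {"zero_reference_rate"}

    def test_empty_profile_rejected(self):
        from multiomecnv.cnv_hmm import PseudobulkProfile

        prof = PseudobulkProfile(
            cov=pd.DataFrame(columns=["chrom", "pos", "start", "end", "bin_id",
                                      "modality", "x", "expect"]),
            allele=None, reference_columns={}, excluded_bins=pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="empty"):
            build_observation_track(prof)


def brute_force_viterbi(track, params, states):
    """Exhaustive best-path search over all K^n state sequences."""
    em = emission_matrix(track, params, states)
    dists = np.diff(track["pos"].values, prepend=track["pos"].values[0])
    n, K = em.shape
    paths = np.array(np.unravel_index(np.arange(K**n), (K,) * n)).T
    scores = np.log(_initial(params, states))[paths[:, 0]] + em[0, paths[:, 0]]
    for i in range(1, n):
        logT = np.log(transition_matrix(dists[i], params, states))
        scores = scores + logT[paths[:, i - 1], paths[:, i]] + em[i, paths[:, i]]
    return paths[int(np.argmax(scores))], float(scores.max())


class TestViterbi:
    def test_all_neutral_track_yields_single_neutral_segment(self):
        rng = np.random.default_rng(0)
        cov = [(int(p), int(rng.poisson(50)), 50.0) for p in np.arange(40) * 1_000_000]
        snps = [(int(p) + 500_000, int(rng.binomial(8, 0.5)), 8) for p in np.arange(40) * 1_000_000]
        res = viterbi_segment(make_track("chr1", cov, snps))
        assert len(res.segments) == 1
        assert res.segments["category"].iloc[0] == "neutral"

    def test_planted_deletion_boundaries_within_two_bins(self):
        rng = np.random.default_rng(1)
        nb, width = 120, 500_000
        phi = np.ones(nb)
        phi[50:81] = 0.5
        cov = [
            (i * width + width // 2,
             int(rng.poisson(60 * phi[i] * np.exp(rng.normal(-0.045, 0.3)))), 60.0)
            for i in range(nb)
        ]
        snps = []
        for i in range(nb):
            for off in (100_000, 300_000):
                d = int(rng.poisson(5))
                theta = 0.99 if 50 <= i <= 80 else 0.5
                if d:
                    snps.append((i * width + off, int(rng.binomial(d, theta)), d))
        res = viterbi_segment(make_track("chr1", cov, snps))
        dels = res.segments[res.segments["category"] == "del"]
        assert len(dels) == 1
        assert abs(dels["start"].iloc[0] - 50 * width) <= 2 * width
        assert abs(dels["end"].iloc[0] - 81 * width) <= 2 * width

    def test_matches_brute_force_on_short_tracks(self):
        """MAP path equals exhaustive enumeration over all 15^5 paths."""
        params = HmmParams(t=1e-3)
        states = build_state_space()
        rng = np.random.default_rng(42)
        for _ in range(12):
            cov = [(int(p), int(rng.integers(0, 40)), float(rng.uniform(5, 30)))
                   for p in np.sort(rng.choice(10**7, 3, replace=False))]
            snps = [(int(p), 0, 0) for p in []]
            d = rng.integers(1, 12, 2)
            a = [int(rng.integers(0, di + 1)) for di in d]
            snp_pos = np.sort(rng.choice(10**7, 2, replace=False))
            snps = [(int(p), ai, int(di)) for p, ai, di in zip(snp_pos, a, d)]
            track = make_track("chr1", cov, snps)
            res = viterbi_segment(track, params, states, compute_posteriors=False)
            bf_path, _ = brute_force_viterbi(track, params, states)
            assert np.array_equal(res.track["state"].values, bf_path)

    def test_phase_mirror_symmetry(self):
        """Flipping all paternal counts mirrors the path, same likelihood."""
        params = HmmParams(t=1e-3)
        states = build_state_space()
        rng = np.random.default_rng(7)
        d = rng.integers(2, 15, 30)
        a = rng.binomial(d, 0.9)
        pos = np.sort(rng.choice(10**8, 30, replace=False))
        fwd = make_track("chr1", snps=[(int(p), int(ai), int(di)) for p, ai, di in zip(pos, a, d)])
        rev = make_track("chr1", snps=[(int(p), int(di - ai), int(di)) for p, ai, di in zip(pos, a, d)])
        res_f = viterbi_segment(fwd, params, states)
        res_r = viterbi_segment(rev, params, states)
        assert np.array_equal(
            states.mirror[res_f.track["state"].values], res_r.track["state"].values
        )
        assert res_f.segments["category"].tolist() == res_r.segments["category"].tolist()


def test_sigma_estimated_from_reference_residuals():
    """Method-of-moments sigma recovers the truth; clean data falls back."""
    from multiomecnv.cnv_hmm import estimate_sigma

    rng = np.random.default_rng(12)
    expect = rng.uniform(100, 2000, 3000)
    for sigma_true in (0.2, 0.4):
        x = rng.poisson(expect * np.exp(rng.normal(-sigma_true**2 / 2, sigma_true, 3000)))
        assert estimate_sigma(x, expect) == pytest.approx(sigma_true, rel=0.15)
    x_clean = rng.poisson(expect)
    assert estimate_sigma(x_clean, expect, fallback=0.3) == 0.3


def test_atac_stream_never_weakens_event_evidence():
    """Adding ATAC observations cannot shrink the true-vs-null likelihood gap.

    For a planted deletion, the joint log-likelihood margin of the true
    configuration over the all-neutral one is computed on the RNA-only
    track and on the RNA+ATAC track; in expectation over 20 seeds the
    combined margin is at least the RNA-only one (each well-modelled
    observation contributes a non-negative expected margin).
    """
    params = HmmParams()
    gaps_rna, gaps_both = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        margins = {}
        for modality, depth in (("RNA", 30.0), ("ATAC", 60.0)):
            x = rng.poisson(depth * 0.5 * np.exp(rng.normal(-0.045, 0.3, 40)))
            margins[modality] = float(
                np.sum(pln_loglik(x, depth * 0.5, 0.3) - pln_loglik(x, depth, 0.3))
            )
        gaps_rna.append(margins["RNA"])
        gaps_both.append(margins["RNA"] + margins["ATAC"])
    assert np.mean(gaps_both) >= np.mean(gaps_rna)
    assert np.mean(gaps_both) > 0


class TestEstimates:
    def test_phi_recovery_on_simulated_deletion(self):
        rng = np.random.default_rng(3)
        cov = [
            (i * 10**6, int(rng.poisson(50 * 0.5 * np.exp(rng.normal(-0.045, 0.3)))), 50.0)
            for i in range(100)
        ]
        res = viterbi_segment(make_track("chr1", cov=cov))
        est = res.segments.loc[res.segments["n_bins"].idxmax()]
        assert est["category"] == "del"
        assert 0.45 <= est["phi_hat"] <= 0.55

    def test_theta_recovery_on_simulated_cnloh(self):
        rng = np.random.default_rng(4)
        snps = []
        for i in range(60):
            d = int(rng.poisson(4)) + 1
            snps.append((i * 10**5, int(rng.binomial(d, 0.995)), d))
        res = viterbi_segment(make_track("chr1", snps=snps))
        assert res.segments["theta_hat"].iloc[0] >= 0.95

    def test_neutral_recovery(self):
        rng = np.random.default_rng(5)
        cov = [
            (i * 10**6, int(rng.poisson(80 * np.exp(rng.normal(-0.045, 0.3)))), 80.0)
            for i in range(120)
        ]
        snps = [(i * 10**6 + 5000, int(rng.binomial(10, 0.5)), 10) for i in range(120)]
        res = viterbi_segment(make_track("chr1", cov, snps))
        seg = res.segments.iloc[0]
        assert seg["category"] == "neutral"
        assert abs(seg["phi_hat"] - 1.0) < 0.05
        assert abs(seg["theta_hat"] - 0.5) < 0.05

    def test_no_snps_flagged_low_confidence(self):
        cov = [(i * 10**6, 40, 40.0) for i in range(10)]
        res = viterbi_segment(make_track("chr1", cov=cov))
        seg = res.segments.iloc[0]
        assert seg["theta_hat"] == 0.5 and bool(seg["theta_low_conf"])


class TestClassification:
    @pytest.mark.parametrize(
        "phi, theta, want",
        [
            (1.0, 0.5, "neutral"),
            (1.0, 0.99, "cnloh"),
            (2.0, 0.5, "bamp"),
            (0.5, 0.99, "del"),
            (1.5, 0.66, "amp"),
            (0.65, 0.77, "del"),  # 70%-pure deletion: dosage+imbalance consistent
            (1.0, 0.75, "cnloh"),  # 50%-diluted CNLoH
        ],
    )
    def test_profile_classification(self, phi, theta, want):
        assert classify_segment(phi, theta) == want

    def test_without_theta_uses_dosage_only(self):
        assert classify_segment(0.55, None) == "del"
        assert classify_segment(1.0, None) == "neutral"

    def test_posterior_argmax_with_tiebreak(self):
        post = {"neutral": 0.2, "del": 0.4, "amp": 0.4}
        assert classify_segment(None, None, post) == "del"
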