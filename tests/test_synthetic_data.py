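import numpy as np
import pandas as pd
import pytest

from multiomecnv.evaluation import truth_from_wgs_segments
from multiomecnv.synthetic_data import (
    CloneSpec,
    EventSpec,
    SimConfig,
    default_cohort_config,
    load_fixture_bundle,
    sim_genome,
    simulate_baseline,
    simulate_sample,
    subclone_scenario_config,
    write_fixture_bundle,
)


class TestEventSpec:
    @pytest.mark.parametrize(
        "c, m, want",
        [(1, 1, "del"), (0, 0, "bdel"), (2, 2, "cnloh"), (3, 2, "amp"), (4, 2, "bamp")],
    )
    def test_status_derivation(self, c, m, want):
        assert EventSpec("chr1", 0, 10, c, m).status == want


class TestBaseline:
    def test_normalized_and_deterministic(self, toy_bins):
        lam1 = simulate_baseline(toy_bins, "RNA", np.random.default_rng(5))
        lam2 = simulate_baseline(toy_bins, "RNA", np.random.default_rng(5))
        assert np.isclose(lam1.sum(), 1.0)
        assert np.array_equal(lam1, lam2)

    def test_atac_is_sparser_than_rna(self):
        """Averaged over seeds, the ATAC zero-bin fraction exceeds RNA's."""
        from multiomecnv.genome_bins import make_uniform_bins

        bins = make_uniform_bins(sim_genome(4), 200_000)
        zr_rna, zr_atac = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            zr_rna.append((simulate_baseline(bins, "RNA", rng, 1.0, 0.02) == 0).mean())
            zr_atac.append((simulate_baseline(bins, "ATAC", rng, 1.0, 0.10) == 0).mean())
        assert np.mean(zr_atac) > np.mean(zr_rna)


class TestSimulateSample:
    def test_deterministic_under_seed(self, small_sample):
        again = simulate_sample(small_sample.config)
        assert (again.counts["RNA"].counts != small_sample.counts["RNA"].counts).nnz == 0
        assert again.allele_counts["ATAC"].df.equals(small_sample.allele_counts["ATAC"].df)
        assert again.phased_vcf.equals(small_sample.phased_vcf)

    def test_distinct_seeds_differ(self, small_sample):
        from dataclasses import replace

        other = simulate_sample(replace(small_sample.config, seed=8))
        assert (other.counts["RNA"].counts != small_sample.counts["RNA"].counts).nnz > 0

    def test_deletion_halves_coverage_in_tumor_cells(self, small_sample):
        """Mean count ratio tumor/normal on deleted bins approaches 0.5."""
        counts = small_sample.counts["RNA"]
        clones = small_sample.truth.clone_of_cell
        labels = clones.reindex([f"{c}#RNA" for c in counts.cell_ids]).values
        binset = counts.binset
        mid = binset.midpoints()
        in_del = (binset.df["chrom"].values == "chr1") & (mid >= 30_000_000)
        neutral = binset.df["chrom"].values == "chr3"
        neutral &= mid < 27_000_000
        mat = np.asarray(counts.counts.todense(), dtype=float)
        lib = mat.sum(axis=1, keepdims=True)
        rate = mat / lib
        tumor, normal = rate[labels == "tumor"], rate[labels == "normal"]
        ratio = tumor[:, in_del].mean() / normal[:, in_del].mean()
        ratio_neutral = tumor[:, neutral].mean() / normal[:, neutral].mean()
        # library normalization shifts both; the deleted/neutral contrast is ~0.5
        assert abs(ratio / ratio_neutral - 0.5) < 0.05

    def test_sigma_zero_gives_poisson_dispersion(self):
        from dataclasses import replace

        cfg = SimConfig(arms=sim_genome(2), sigma_truth=0.0, seed=3,
                        n_cells={"RNA": 400, "ATAC": 10},
                        n_ref_cells={"RNA": 10, "ATAC": 10},
                        lib_size_sigma=0.0)
        sample = simulate_sample(cfg)
        mat = np.asarray(sample.counts["RNA"].counts.todense(), dtype=float)
        # index of dispersion ~ 1 for Poisson; average over well-covered bins
        mean = mat.mean(axis=0)
        var = mat.var(axis=0)
        good = mean > 5
        assert abs((var[good] / mean[good]).mean() - 1.0) < 0.1

    def test_pln_moment_calibration(self):
        """Empirical variance matches the PLN inflation factor e^{sigma^2}-1."""
        rng_cfg = SimConfig(
            arms=sim_genome(2), sigma_truth=0.4, seed=11,
            n_cells={"RNA": 2000, "ATAC": 10}, n_ref_cells={"RNA": 10, "ATAC": 10},
            lib_size_sigma=0.0,
        )
        sample = simulate_sample(rng_cfg)
        mat = np.asarray(sample.counts["RNA"].counts.todense(), dtype=float)
        mean = mat.mean(axis=0)
        var = mat.var(axis=0)
        good = mean > 20
        # Var = mu + mu^2 (e^{s^2}-1)
        inflation = ((var[good] - mean[good]) / mean[good] ** 2).mean()
        want = np.exp(0.4**2) - 1
        assert inflation == pytest.approx(want, rel=0.15)


class TestSimulatedAlleles:
    def test_neutral_pooled_fraction_balanced(self, small_sample):
        from multiomecnv.allele_counts import attach_phase, pseudobulk_haplotype_counts

        rec, _ = attach_phase(small_sample.allele_counts["ATAC"], small_sample.phased_vcf)
        # chr3 p arm is neutral in every clone
        neutral = rec[(rec["chrom"] == "chr3") & (rec["pos"] < 27_000_000)]
        track = pseudobulk_haplotype_counts(neutral)
        a, d = track.df["a"].sum(), track.df["d"].sum()
        assert abs(a / d - 0.5) < 2.58 * 0.5 / np.sqrt(d) + 0.01

    def test_cnloh_region_skewed_in_tumor_cells(self, small_sample):
        from multiomecnv.allele_counts import attach_phase, pseudobulk_haplotype_counts

        clones = small_sample.truth.clone_of_cell
        rec, _ = attach_phase(small_sample.allele_counts["ATAC"], small_sample.phased_vcf)
        # truth labels are modality-tagged; raw allele counts are not
        tumor_cells = {c.split("#")[0] for c in clones.index[clones == "tumor"]}
        region = rec[(rec["chrom"] == "chr2") & (rec["pos"] < 27_000_000)]
        region = region[region["cell"].isin(set(tumor_cells))]
        track = pseudobulk_haplotype_counts(region)
        assert track.df["d"].sum() >= 200
        # population phase-switch errors flip the sign of the skew along the
        # arm, so the imbalance must be read per local SNP block
        df = track.df.assign(blk=np.arange(len(track.df)) // 50)
        frac = df.groupby("blk").apply(
            lambda g: g["a"].sum() / g["d"].sum(), include_groups=False
        )
        skew = np.maximum(frac, 1 - frac)
        assert np.median(skew) >= 0.9

    def test_zero_switch_error_reproduces_true_haplotypes(self):
        from dataclasses import replace

        cfg = SimConfig(arms=sim_genome(2), nu_switch=np.inf, seed=5,
                        n_cells={"RNA": 20, "ATAC": 20},
                        n_ref_cells={"RNA": 10, "ATAC": 10})
        cfg = replace(cfg, nu_switch=1e18)  # effectively no switches
        sample = simulate_sample(cfg)
        merged = sample.truth.snps.merge(
            sample.phased_vcf, on=["chrom", "pos"], suffixes=("_true", "_vcf")
        )
        assert (merged["pat_is_ref"] == merged["paternal_is_ref"]).all()


class TestBundle:
    def test_roundtrip_and_truth_consistency(self, small_sample, tmp_path):
        out = tmp_path / "bundle"
        write_fixture_bundle(small_sample, out)
        with pytest.raises(FileExistsError):
            write_fixture_bundle(small_sample, out)
        data = load_fixture_bundle(out)
        assert (
            data["counts"]["RNA"].counts != small_sample.counts["RNA"].counts
        ).nnz == 0
        assert np.allclose(
            data["reference"].rates.values, small_sample.reference.rates.values
        )
        # thresholding the written seg table reproduces the planted statuses
        truth = truth_from_wgs_segments(data["truth_seg"])
        planted = small_sample.truth.events
        got = truth[truth["status"] != "neutral"]
        for ev in planted.itertuples():
            hit = got[(got["chrom"] == ev.chrom) & (got["start"] == ev.start)]
            want = {"bamp": "amp", "bdel": "del"}.get(ev.status, ev.status)
            assert len(hit) == 1 and hit["status"].iloc[0] == want

    def test_bundle_vcf_loads_through_real_parser(self, small_sample, tmp_path):
        from multiomecnv.allele_counts import read_phased_vcf

        out = tmp_path / "bundle"
        write_fixture_bundle(small_sample, out)
        table = read_phased_vcf(out / "phased.vcf")
        assert len(table) == len(small_sample.phased_vcf)
        assert (
            table["paternal_is_ref"].values
            == small_sample.phased_vcf["paternal_is_ref"].values
        ).all()


class TestPresets:
    def test_cohort_preset_covers_all_categories(self):
        cfg = default_cohort_config(0, 1)
        statuses = {e.status for c in cfg.clones for e in c.events}
        assert {"amp", "bamp", "del", "cnloh"} <= statuses
        tumor = [c for c in cfg.clones if c.events][0]
        assert len(tumor.events) == 8
        assert sum(c.proportion for c in cfg.clones) == pytest.approx(1.0)

    def test_subclone_preset_structure(self):
        cfg = subclone_scenario_config(1)
        names = {c.name: c for c in cfg.clones}
        sub_frac = names["subclone"].proportion / (
            names["subclone"].proportion + names["tumor"].proportion
        )
        assert sub_frac == pytest.approx(0.15)
        private = set(names["subclone"].events) - set(names["tumor"].events)
        assert len(private) == 1 and next(iter(private)).status == "cnloh"
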