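"""The synthetic cohort generator: reproducibility, population genetics,
generator-classifier consistency and parameter recovery hooks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from junctionqtl.association import ld_r2, scan
from junctionqtl.io_core import read_genotypes
from junctionqtl.junction_phenotypes import classify_read
from junctionqtl.synthetic_data import (
    SimulationConfig,
    covariate_design,
    phenotypes_from_counts,
    simulate_covariates,
    simulate_genotypes,
    simulate_junction_counts,
    simulate_qpcr_plate,
    simulate_reads,
    simulate_truth,
    toy_gene_model,
    write_vcf,
)


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_animals=50, n_markers=20, seed=3)
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.markers == b.markers

    def test_zero_flip_probability_gives_perfect_ld(self):
        cfg = SimulationConfig(n_animals=200, n_markers=11, ld_decay=0.0, seed=4)
        gm = simulate_genotypes(cfg)
        causal = gm.dosages_of("K232A")
        for mid in gm.marker_ids:
            assert ld_r2(causal, gm.dosages_of(mid)) == pytest.approx(1.0)

    def test_allele_frequency_recovered_across_seeds(self):
        freqs = [
            simulate_genotypes(SimulationConfig(n_markers=3, seed=s))
            .dosages_of("K232A")
            .mean()
            / 2.0
            for s in range(100)
        ]
        assert abs(np.mean(freqs) - 0.51) < 0.03

    def test_hardy_weinberg_across_seeds(self):
        passed = 0
        for s in range(100):
            gm = simulate_genotypes(SimulationConfig(n_markers=3, seed=s))
            d = gm.dosages_of("K232A")
            n = d.size
            p = d.mean() / 2.0
            obs = np.array([(d == k).sum() for k in (0, 1, 2)])
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            passed += stats.chi2.sf(chi2, df=1) > 0.01
        assert passed >= 95

    def test_vcf_round_trip(self, tmp_path, small_config):
        gm = simulate_genotypes(small_config)
        path = tmp_path / "m.vcf"
        write_vcf(gm, path)
        back = read_genotypes(str(path))
        assert back.sample_ids == gm.sample_ids
        order = [back.marker_ids.index(m) for m in gm.marker_ids]
        np.testing.assert_array_equal(back.dosage[:, order], gm.dosage)


class TestCovariates:
    def test_ancestry_proportions_sum_to_one(self, small_config):
        cov = simulate_covariates(small_config)
        sums = cov[["anc_nz_hf", "anc_us_hf", "anc_jersey"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)
        assert cov["heterosis"].between(0, 1).all()

    def test_same_seed_identical(self, small_config):
        pd.testing.assert_frame_equal(
            simulate_covariates(small_config), simulate_covariates(small_config)
        )

    def test_omitting_confounded_cohort_inflates_null_scan(self):
        """With cohort membership assorted by genotype and a cohort effect on
        expression (no genotype effect), the unadjusted scan is inflated
        relative to uniform; adjusting for cohort restores calibration."""
        cfg = SimulationConfig(
            n_animals=300,
            n_markers=120,
            seed=9,
            cohort_assortment=0.3,
            cohort_effects=(0.0, 0.6, -0.6),
            expression_by_genotype=(9.4, 9.4, 9.4),  # null genotype effect
        )
        gm = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, gm)
        truth = simulate_truth(cfg, gm, cov)
        y = pd.Series(truth["expression"].to_numpy(), index=gm.sample_ids)
        raw = scan(y, gm)
        adj = scan(y, gm, covariates=covariate_design(cov))
        ks_raw = stats.kstest(raw["p"].to_numpy(), "uniform")
        assert ks_raw.pvalue < 1e-4  # raw scan strongly inflated
        # calibration after adjustment is asserted on the unlinked markers
        # (haplotype flip probability 0.5): the LD cluster around the causal
        # site is a single dependent block and its joint excursions are not
        # an inflation signal
        causal_idx = cfg.n_markers // 2
        unlinked = np.abs(np.arange(cfg.n_markers) - causal_idx) >= np.ceil(
            0.5 / cfg.ld_decay
        )
        assert (raw["p"] < 0.05).mean() > 0.20
        assert (adj.loc[unlinked, "p"] < 0.05).mean() <= 0.12


class TestTruthAndCounts:
    def test_class_means_recover_anchored_intron_pct(self):
        cfg = SimulationConfig(seed=2)
        gm = simulate_genotypes(cfg)
        truth = simulate_truth(cfg, gm)
        ph = phenotypes_from_counts(simulate_junction_counts(cfg, truth))
        anchored = cfg.intron_pct_by_genotype[8]
        for dosage, target in enumerate(anchored):
            vals = ph.loc[truth["dosage"] == dosage, "intronpct_8"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 2 * se + 0.05

    def test_psi_medians_recover_anchored_values(self):
        cfg = SimulationConfig(seed=12, read_depth=20000)
        gm = simulate_genotypes(cfg)
        truth = simulate_truth(cfg, gm)
        ph = phenotypes_from_counts(simulate_junction_counts(cfg, truth))
        for dosage, target in enumerate(cfg.psi_by_genotype):
            med = ph.loc[truth["dosage"] == dosage, "psi"].median()
            assert med == pytest.approx(target, abs=0.6)

    def test_zero_retention_gives_zero_intron_pct(self):
        cfg = SimulationConfig(
            n_animals=20, seed=1,
            intron_pct_by_genotype={}, default_intron_pct=0.0,
        )
        gm = simulate_genotypes(cfg)
        truth = simulate_truth(cfg, gm)
        ph = phenotypes_from_counts(simulate_junction_counts(cfg, truth))
        assert (ph.filter(like="intronpct_") == 0.0).all().all()

    def test_full_retention_floors_efficiency(self):
        cfg = SimulationConfig(
            n_animals=10, seed=1,
            intron_pct_by_genotype={}, default_intron_pct=100.0,
            boundary_share=1.0, spliced_read_fraction=0.0,
        )
        gm = simulate_genotypes(cfg)
        truth = simulate_truth(cfg, gm)
        ph = phenotypes_from_counts(simulate_junction_counts(cfg, truth))
        assert np.allclose(ph.filter(like="intronpct_").to_numpy(), 100.0)
        eff = ph.filter(like="eff_")
        assert (eff < 0.01).all().all()  # pseudocount / (depth + pseudocount)

    def test_retention_converges_to_truth_at_high_depth(self):
        cfg = SimulationConfig(
            n_animals=60, seed=8, read_depth=100_000, retention_sd_logit=0.0,
        )
        gm = simulate_genotypes(cfg)
        truth = simulate_truth(cfg, gm)
        ph = phenotypes_from_counts(simulate_junction_counts(cfg, truth))
        for dosage, target in enumerate(cfg.intron_pct_by_genotype[8]):
            sel = truth["dosage"] == dosage
            if sel.sum() == 0:
                continue
            mean = ph.loc[sel, "intronpct_8"].mean()
            assert abs(mean - target) / target < 0.05


class TestReadLevelSimulation:
    def test_truth_table_matches_classifier(self, small_config):
        model = toy_gene_model()
        gm = simulate_genotypes(small_config)
        truth = simulate_truth(small_config, gm)
        samples = list(truth.index)[:5]
        reads, table = simulate_reads(small_config, model, truth, samples=samples)
        junctions = {j.index: j for j in model.junctions()}
        mismatches = sum(
            classify_read(reads[row.read], junctions[row.junction]) != row.true_class
            for row in table.itertuples()
        )
        assert mismatches == 0

    def test_same_seed_identical_reads(self, small_config):
        model = toy_gene_model()
        gm = simulate_genotypes(small_config)
        truth = simulate_truth(small_config, gm)
        samples = list(truth.index)[:3]
        a, _ = simulate_reads(small_config, model, truth, samples=samples)
        b, _ = simulate_reads(small_config, model, truth, samples=samples)
        assert [r.blocks for r in a] == [r.blocks for r in b]

    def test_alternative_donor_reads_present(self, small_config):
        model = toy_gene_model()
        gm = simulate_genotypes(small_config)
        truth = simulate_truth(small_config, gm)
        _, table = simulate_reads(small_config, model, truth, samples=list(truth.index)[:5])
        assert (table["donor"] == "alt").any() and (table["donor"] == "ref").any()


class TestQPCRPlate:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=13)
        pd.testing.assert_frame_equal(simulate_qpcr_plate(cfg), simulate_qpcr_plate(cfg))

    def test_plate_layout(self):
        cfg = SimulationConfig(seed=13)
        plate = simulate_qpcr_plate(cfg)
        qp = cfg.qpcr
        n_assays = 2 * len(qp.junctions) + len(qp.reference_assays)
        n_curve = n_assays * qp.n_curve_dilutions
        n_exp = 2 * qp.n_samples_per_allele * n_assays * qp.n_wells
        assert len(plate) == n_curve + n_exp
        assert set(plate["assay_role"]) == {"spliced", "unspliced", "reference"}
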