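"""Tests for the synthetic-data generators: determinism, class
bookkeeping, truth consistency, model limits, and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parallex import synthetic_data as syn
from parallex.io import (
    read_counts,
    read_gff3,
    read_pleiotropy_table,
    read_population_file,
    read_sample_table,
    read_vcf,
    write_counts,
    write_gff3,
    write_pleiotropy_table,
    write_population_file,
    write_sample_table,
    write_vcf,
)


class TestLargestRemainder:
    def test_exact_partition(self):
        counts = syn.largest_remainder_counts([0.5, 0.3, 0.2], 10)
        assert counts.tolist() == [5, 3, 2]

    def test_remainder_distribution(self):
        counts = syn.largest_remainder_counts([1 / 3, 1 / 3, 1 / 3], 10)
        assert counts.sum() == 10
        assert sorted(counts.tolist()) == [3, 3, 4]

    def test_always_sums_to_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(2, 8))
            f = rng.dirichlet(np.ones(k))
            total = int(rng.integers(1, 500))
            assert syn.largest_remainder_counts(f, total).sum() == total

    def test_invalid_fractions_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.largest_remainder_counts([0.5, 0.6], 10)


class TestExpressionSim:
    def test_all_null_config_has_zero_lfcs(self):
        cfg = syn.ExpressionSimConfig(
            n_genes=50, samples_per_group=2, class_fractions={"null": 1.0},
            stages=("8-10dpf",), seed=0
        )
        _, _, truth = syn.simulate_expression_study(cfg)
        assert (truth.lfc_snail == 0).all()
        assert (truth.lfc_scale == 0).all()

    def test_same_seed_bit_identical(self):
        cfg = syn.ExpressionSimConfig(n_genes=100, samples_per_group=3, seed=5)
        c1, s1, t1 = syn.simulate_expression_study(cfg)
        c2, s2, t2 = syn.simulate_expression_study(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_class_bookkeeping_matches_largest_remainder(self):
        fracs = {
            "null": 0.7, "parallel_up": 0.1, "parallel_down": 0.1,
            "snail_only": 0.04, "scale_only": 0.04, "opposite": 0.02,
        }
        cfg = syn.ExpressionSimConfig(
            n_genes=333, samples_per_group=2, class_fractions=fracs,
            stages=("8-10dpf",), seed=1
        )
        _, _, truth = syn.simulate_expression_study(cfg)
        expected = syn.largest_remainder_counts(
            [fracs[c] for c in syn.GENE_CLASSES], 333
        )
        observed = truth.class_label.value_counts()
        for cls, n in zip(syn.GENE_CLASSES, expected):
            assert observed.get(cls, 0) == n

    def test_truth_labels_consistent_with_lfc_signs(self):
        cfg = syn.ExpressionSimConfig(n_genes=600, samples_per_group=2, seed=3)
        _, _, truth = syn.simulate_expression_study(cfg)
        by = truth.groupby("class_label")
        for label, grp in by:
            if label == "parallel_up":
                assert ((grp.lfc_snail > 0) & (grp.lfc_scale > 0)).all()
            elif label == "parallel_down":
                assert ((grp.lfc_snail < 0) & (grp.lfc_scale < 0)).all()
            elif label == "opposite":
                assert (np.sign(grp.lfc_snail) == -np.sign(grp.lfc_scale)).all()
            elif label == "snail_only":
                assert (grp.lfc_scale == 0).all() and (grp.lfc_snail != 0).all()
            elif label == "scale_only":
                assert (grp.lfc_snail == 0).all() and (grp.lfc_scale != 0).all()
            else:
                assert (grp.lfc_snail == 0).all() and (grp.lfc_scale == 0).all()

    def test_paper_design_defaults(self):
        cfg = syn.ExpressionSimConfig(n_genes=10, seed=0)
        _, samples, _ = syn.simulate_expression_study(cfg)
        sizes = samples.groupby(["species", "stage"]).size()
        assert sizes[("scale_eater", "8-10dpf")] == 3
        assert sizes[("scale_eater", "17-20dpf")] == 2
        assert sizes[("generalist", "8-10dpf")] == 6

    def test_invalid_fractions_rejected(self):
        cfg = syn.ExpressionSimConfig(class_fractions={"null": 0.9})
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_expression_study(cfg)


class TestGenotypeSim:
    def test_determinism(self):
        cfg = syn.GenotypeSimConfig(n_snps=200, samples_per_pop=5, seed=4)
        v1, p1, t1 = syn.simulate_genotype_study(cfg)
        v2, p2, t2 = syn.simulate_genotype_study(cfg)
        np.testing.assert_array_equal(v1.genotypes, v2.genotypes)
        np.testing.assert_array_equal(v1.pos, v2.pos)
        assert t1 == t2

    def test_forced_fixed_frequencies(self):
        cfg = syn.GenotypeSimConfig(
            n_snps=300, samples_per_pop=6, n_fixed=30, missing_rate=0.0, seed=5
        )
        vt, _, truth = syn.simulate_genotype_study(cfg)
        fixed = np.isin(vt.pos, truth["fixed_positions"])
        assert fixed.sum() == 30
        assert (vt.genotypes[fixed][:, :6] == 2).all()
        assert (vt.genotypes[fixed][:, 6:] == 0).all()

    def test_missing_rate_applied(self):
        cfg = syn.GenotypeSimConfig(
            n_snps=500, samples_per_pop=10, missing_rate=0.2, seed=6
        )
        vt, _, _ = syn.simulate_genotype_study(cfg)
        frac = (vt.genotypes == -1).mean()
        assert 0.17 <= frac <= 0.23

    def test_invalid_config_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_genotype_study(syn.GenotypeSimConfig(F_model=1.0))
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_genotype_study(syn.GenotypeSimConfig(n_snps=5, n_fixed=6))


class TestSweepSim:
    def test_determinism_and_truth(self):
        cfg = syn.SweepSimConfig(
            scaffold_length=50_000, n_sites=400, n_alleles=10,
            sweep_center=25_000, sweep_alpha_true=1e-4, seed=7
        )
        v1, t1 = syn.simulate_sweep_scaffold(cfg)
        v2, t2 = syn.simulate_sweep_scaffold(cfg)
        np.testing.assert_array_equal(v1.genotypes, v2.genotypes)
        assert t1["sweep_center"] == 25_000

    def test_neutral_spectrum_matches_harmonic_weights(self):
        cfg = syn.SweepSimConfig(
            scaffold_length=400_000, n_sites=40_000, n_alleles=10,
            sweep_center=None, seed=8
        )
        vt, _ = syn.simulate_sweep_scaffold(cfg)
        alt = vt.genotypes.sum(axis=1)
        cls = np.minimum(alt, 10 - alt)
        observed = np.bincount(cls, minlength=6)[1:]
        expected = syn.neutral_folded_spectrum(10) * len(cls)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=4) > 1e-4

    def test_all_escape_limit_indistinguishable_from_neutral(self):
        """With huge alpha every lineage escapes: class draws stay neutral."""
        phi = syn.neutral_folded_spectrum(8)
        pvals = []
        for seed in range(30):
            cfg = syn.SweepSimConfig(
                scaffold_length=100_000, n_sites=3_000, n_alleles=8,
                sweep_center=50_000, sweep_alpha_true=50.0, seed=seed
            )
            vt, _ = syn.simulate_sweep_scaffold(cfg)
            alt = vt.genotypes.sum(axis=1)
            cls = np.minimum(alt, 8 - alt)
            observed = np.bincount(cls, minlength=5)[1:]
            expected = phi * observed.sum()
            chi2 = ((observed - expected) ** 2 / expected).sum()
            pvals.append(stats.chi2.sf(chi2, df=len(phi) - 1))
        # p-values should look uniform, not skewed to 0
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_sites_dropped(self):
        cfg = syn.SweepSimConfig(
            scaffold_length=60_000, n_sites=2_000, n_alleles=10,
            sweep_center=30_000, sweep_alpha_true=1e-5, seed=9
        )
        vt, _ = syn.simulate_sweep_scaffold(cfg)
        alt = vt.genotypes.sum(axis=1)
        assert ((alt > 0) & (alt < 10)).all()
        assert vt.n_snps < 2_000  # strong sweep collapses many sites

    def test_odd_allele_count_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_sweep_scaffold(syn.SweepSimConfig(n_alleles=9))


class TestPleiotropySim:
    def test_rate_ratio_applied(self):
        table, truth = syn.simulate_pleiotropy_table(
            2_000, rate_ratio=2.0, dispersion=0.3, seed=10
        )
        means = table.groupby("group").n_ppi.mean()
        assert means["divergent"] / means["parallel"] == pytest.approx(2.0, rel=0.15)
        assert truth["log_rate_ratio"] == pytest.approx(np.log(2.0))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.simulate_pleiotropy_table(1)


class TestRoundTrips:
    def test_counts_and_samples(self, tmp_path):
        cfg = syn.ExpressionSimConfig(n_genes=30, samples_per_group=2, seed=1)
        counts, samples, _ = syn.simulate_expression_study(cfg)
        write_counts(counts, tmp_path / "c.tsv")
        write_sample_table(samples, tmp_path / "s.csv")
        back = read_counts(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back, counts, check_names=False)
        back_s = read_sample_table(tmp_path / "s.csv")
        assert back_s.sample_id.tolist() == samples.sample_id.tolist()

    def test_vcf_with_missing_genotypes(self, tmp_path):
        cfg = syn.GenotypeSimConfig(
            n_snps=80, samples_per_pop=4, missing_rate=0.1, n_fixed=5, seed=2
        )
        vt, pops, _ = syn.simulate_genotype_study(cfg)
        write_vcf(vt, tmp_path / "v.vcf")
        back = read_vcf(tmp_path / "v.vcf")
        np.testing.assert_array_equal(back.genotypes, vt.genotypes)
        np.testing.assert_array_equal(back.pos, vt.pos)
        assert back.samples == vt.samples
        write_population_file(pops, tmp_path / "p.tsv")
        back_p = read_population_file(tmp_path / "p.tsv")
        assert back_p.population.tolist() == pops.population.tolist()

    def test_gff3(self, tmp_path):
        genes = syn.simulate_gene_models(8, 100_000, seed=3)
        write_gff3(genes, tmp_path / "g.gff3")
        back = read_gff3(tmp_path / "g.gff3")
        assert [g.gene_id for g in back] == [g.gene_id for g in genes]
        assert [g.exons for g in back] == [g.exons for g in genes]

    def test_pleiotropy_table(self, tmp_path):
        table, _ = syn.simulate_pleiotropy_table(20, seed=4)
        write_pleiotropy_table(table, tmp_path / "pl.tsv")
        back = read_pleiotropy_table(tmp_path / "pl.tsv")
        pd.testing.assert_frame_equal(back, table)


class TestGeneModels:
    def test_anchored_genes_contain_anchor_positions(self):
        anchors = [5_000, 20_000, 44_000]
        genes = syn.simulate_gene_models(
            10, 100_000, anchor_positions=anchors, seed=5
        )
        by_id = {g.gene_id: g for g in genes}
        for i, a in enumerate(anchors):
            g = by_id[f"gene_{i + 1:05d}"]
            assert g.start <= a <= g.end

    def test_models_do_not_overlap(self):
        genes = syn.simulate_gene_models(15, 200_000, seed=6)
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
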