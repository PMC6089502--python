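"""Tests for variant filtering, Weir-Cockerham Fst, fixed-SNP calls, and
gene-region assignment."""

from fractions import Fraction

import numpy as np
import pytest

from parallex import popgen
from parallex.io import MISSING, GeneModel, VariantTable
from parallex.popgen import (
    VariantFilterConfig,
    assign_snp_regions,
    filter_variants,
    fst_permutation_threshold,
    identify_fixed,
    weir_cockerham_fst,
)
from parallex.synthetic_data import GenotypeSimConfig, simulate_genotype_study


def make_variants(genotype_rows, samples=None, start_pos=100):
    g = np.array(genotype_rows, dtype=np.int8)
    n_snps, n_samples = g.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    return VariantTable(
        scaffold=np.array(["scaf1"] * n_snps, dtype=object),
        pos=np.arange(start_pos, start_pos + n_snps),
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["T"] * n_snps, dtype=object),
        genotypes=g,
        samples=samples,
    )


def wc_oracle_exact(genos_a, genos_b):
    """Symbolic (exact-rational) evaluation of the two-population
    Weir-Cockerham components for complete data."""
    r = Fraction(2)
    na, nb = Fraction(len(genos_a)), Fraction(len(genos_b))
    pa = Fraction(sum(genos_a), 2 * len(genos_a))
    pb = Fraction(sum(genos_b), 2 * len(genos_b))
    ha = Fraction(sum(1 for g in genos_a if g == 1), len(genos_a))
    hb = Fraction(sum(1 for g in genos_b if g == 1), len(genos_b))
    nbar = (na + nb) / r
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (na * ha + nb * hb) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFilterVariants:
    def test_low_maf_snp_removed(self):
        # alt frequency 1/24 < 0.05 -> dropped; second SNP freq 0.5 kept
        rows = [[0] * 11 + [1], [1] * 12]
        vt = make_variants(rows)
        out, report = filter_variants(vt)
        assert out.n_snps == 1
        assert report["n_snps_removed_maf"] == 1

    def test_low_call_rate_individual_removed_first(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        g[:34, 0] = MISSING  # 85% missing < 90% rate
        vt = make_variants(g)
        out, report = filter_variants(vt)
        assert report["n_individuals_removed"] == 1
        assert "s0" not in out.samples

    def test_matches_two_pass_reference_on_fuzz(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_snps = int(rng.integers(5, 40))
            n_ind = int(rng.integers(4, 12))
            g = rng.integers(0, 3, size=(n_snps, n_ind)).astype(np.int8)
            g[rng.random(g.shape) < 0.1] = MISSING
            vt = make_variants(g)
            cfg = VariantFilterConfig()
            # independent two-pass reference
            rate = (g != MISSING).mean(axis=0)
            keep_ind = np.flatnonzero(rate >= cfg.min_genotyping_rate)
            if len(keep_ind) == 0:
                with pytest.raises(ValueError, match="genotyping-rate"):
                    filter_variants(vt, cfg)
                continue
            out, _ = filter_variants(vt, cfg)
            survivors = []
            for i in range(n_snps):
                row = g[i, keep_ind]
                called = row[row != MISSING]
                if len(called) == 0:
                    continue
                f = called.sum() / (2 * len(called))
                if min(f, 1 - f) > cfg.min_maf:
                    survivors.append(vt.pos[i])
            assert out.pos.tolist() == survivors

    def test_all_individuals_dropped_raises(self):
        g = np.full((20, 3), MISSING, dtype=np.int8)
        g[0] = 1
        with pytest.raises(ValueError, match="genotyping-rate"):
            filter_variants(make_variants(g))


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        vt = make_variants([[0, 0, 0, 2, 2, 2]])
        r = weir_cockerham_fst(vt, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert r.fst[0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        vt = make_variants([[0, 1, 2, 0, 1, 2]])
        r = weir_cockerham_fst(vt, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert r.fst[0] <= 0

    def test_toy_matches_symbolic_oracle(self):
        genos_a, genos_b = [0, 0, 1], [2, 2, 1]
        vt = make_variants([genos_a + genos_b])
        r = weir_cockerham_fst(vt, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        a, b, c = wc_oracle_exact(genos_a, genos_b)
        assert r.table.a[0] == pytest.approx(float(a), rel=1e-12)
        assert r.table.b[0] == pytest.approx(float(b), rel=1e-12)
        assert r.table.c[0] == pytest.approx(float(c), rel=1e-12)
        assert r.fst[0] == pytest.approx(float(a / (a + b + c)), rel=1e-12)

    def test_random_sites_match_symbolic_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            ga = rng.integers(0, 3, size=4).tolist()
            gb = rng.integers(0, 3, size=5).tolist()
            vt = make_variants([ga + gb])
            names = vt.samples
            r = weir_cockerham_fst(vt, names[:4], names[4:])
            a, b, c = wc_oracle_exact(ga, gb)
            denom = a + b + c
            if denom == 0:
                assert bool(r.table.undefined[0])
            else:
                assert r.fst[0] == pytest.approx(float(a / denom), rel=1e-10)

    def test_population_swap_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        vt = make_variants(g)
        names = vt.samples
        f1 = weir_cockerham_fst(vt, names[:5], names[5:]).fst
        f2 = weir_cockerham_fst(vt, names[5:], names[:5]).fst
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        vt1 = make_variants(g)
        vt2 = make_variants(2 - g)  # swap ref/alt
        names = vt1.samples
        f1 = weir_cockerham_fst(vt1, names[:5], names[5:]).fst
        f2 = weir_cockerham_fst(vt2, names[:5], names[5:]).fst
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_empty_population_flagged_not_dropped(self):
        g = np.array([[0, 0, MISSING, MISSING]], dtype=np.int8)
        vt = make_variants(g)
        r = weir_cockerham_fst(vt, ["s0", "s1"], ["s2", "s3"])
        assert r.table.undefined[0]
        assert np.isnan(r.fst[0])
        assert len(r.table) == 1


class TestIdentifyFixed:
    def test_definition(self):
        vt = make_variants([[0, 0, 2, 2], [0, 0, 2, 1]])
        r = weir_cockerham_fst(vt, ["s0", "s1"], ["s2", "s3"])
        fixed = identify_fixed(r)
        assert fixed.tolist() == [True, False]

    def test_simulation_truth_recovered_exactly(self):
        cfg = GenotypeSimConfig(
            n_snps=2_000, samples_per_pop=10, F_model=0.1, n_fixed=50, seed=8
        )
        vt, pops, truth = simulate_genotype_study(cfg)
        pop1 = pops.sample_id[pops.population == "pop1"].tolist()
        pop2 = pops.sample_id[pops.population == "pop2"].tolist()
        r = weir_cockerham_fst(vt, pop1, pop2)
        fixed_pos = set(vt.pos[identify_fixed(r)].tolist())
        assert fixed_pos == set(truth["fixed_positions"])

    def test_fixed_implies_theta_one_under_complete_data(self):
        cfg = GenotypeSimConfig(
            n_snps=500, samples_per_pop=8, F_model=0.2, n_fixed=20, seed=9
        )
        vt, pops, _ = simulate_genotype_study(cfg)
        pop1 = pops.sample_id[pops.population == "pop1"].tolist()
        pop2 = pops.sample_id[pops.population == "pop2"].tolist()
        r = weir_cockerham_fst(vt, pop1, pop2)
        fixed = identify_fixed(r)
        np.testing.assert_allclose(r.fst[fixed], 1.0)


class TestPermutationThreshold:
    def test_degenerate_identical_samples_threshold_zero(self):
        g = np.tile(np.array([[1]], dtype=np.int8), (30, 8))
        vt = make_variants(g)
        with pytest.warns(RuntimeWarning, match="threshold set to 0"):
            null = fst_permutation_threshold(vt, (4, 4), n_permutations=20, seed=0)
        assert null.threshold == 0.0

    def test_sizes_exceeding_samples_rejected(self):
        vt = make_variants(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            fst_permutation_threshold(vt, (3, 3))

    def test_pooled_mode_runs(self):
        rng = np.random.default_rng(3)
        vt = make_variants(rng.integers(0, 3, (100, 10)).astype(np.int8))
        null = fst_permutation_threshold(vt, (5, 5), 20, seed=1, mode="pooled")
        assert 0 <= null.threshold <= 1


class TestRegions:
    gene = GeneModel("geneA", "scaf1", [(1001, 1200), (1501, 1800)])

    def _assign(self, positions):
        vt = VariantTable(
            scaffold=np.array(["scaf1"] * len(positions), dtype=object),
            pos=np.array(sorted(positions)),
            ref=np.array(["A"] * len(positions), dtype=object),
            alt=np.array(["T"] * len(positions), dtype=object),
            genotypes=np.zeros((len(positions), 2), dtype=np.int8),
        )
        return assign_snp_regions(vt, [self.gene])

    def test_containment_is_exonic(self):
        assert self._assign([1100]).per_snp.category[0] == "exonic"

    def test_span_minus_exon_is_intronic(self):
        assert self._assign([1300]).per_snp.category[0] == "intronic"

    def test_inclusive_10kb_boundary(self):
        r = self._assign([11_800])  # distance from last exon end 1800 is 10,000
        assert r.per_snp.category[0] == "within_10kb"
        r = self._assign([11_801])
        assert r.per_snp.category[0] == "distal"

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            GeneModel("bad", "scaf1", [(200, 100)])

    def test_matches_interval_scan_oracle_on_fuzz(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n_genes = int(rng.integers(1, 5))
            genes = []
            for gi in range(n_genes):
                start = int(rng.integers(1, 50_000))
                exons = []
                cur = start
                for _ in range(int(rng.integers(1, 4))):
                    e = cur + int(rng.integers(50, 500))
                    exons.append((cur, e))
                    cur = e + int(rng.integers(100, 2_000))
                genes.append(GeneModel(f"g{gi}", "scaf1", exons))
            positions = np.sort(
                rng.choice(80_000, size=int(rng.integers(5, 40)), replace=False) + 1
            )
            vt = VariantTable(
                scaffold=np.array(["scaf1"] * len(positions), dtype=object),
                pos=positions,
                ref=np.array(["A"] * len(positions), dtype=object),
                alt=np.array(["T"] * len(positions), dtype=object),
                genotypes=np.zeros((len(positions), 2), dtype=np.int8),
            )
            result = assign_snp_regions(vt, genes, window=10_000)
            for i, p in enumerate(positions):
                cats = []
                for g in genes:
                    if any(s <= p <= e for s, e in g.exons):
                        cats.append("exonic")
                    elif g.start <= p <= g.end:
                        cats.append("intronic")
                    elif g.start - 10_000 <= p < g.start or g.end < p <= g.end + 10_000:
                        cats.append("within_10kb")
                expected = "distal"
                for c in ("exonic", "intronic", "within_10kb"):
                    if c in cats:
                        expected = c
                        break
                assert result.per_snp.category[i] == expected
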