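"""Population-genetic analyses: variant filtering, per-SNP Weir-Cockerham
Fst, permutation outlier thresholds, fixed-SNP calls, and gene-region
assignment of SNPs.

The differentiation estimator is the Weir & Cockerham (1984) two-population
diploid theta-hat built from the among-population (a), among-individual-
within-population (b), and within-individual (c) variance components:
theta = a / (a + b + c).  Negative estimates are reported as computed, and
sites where the components are undefined (fewer than two called genotypes
in a population, or a zero denominator) are flagged rather than dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GeneModel, VariantTable

logger = logging.getLogger(__name__)

REGION_CATEGORIES = ("exonic", "intronic", "within_10kb", "distal")
_PRECEDENCE = {c: i for i, c in enumerate(REGION_CATEGORIES)}


@dataclass
class VariantFilterConfig:
    """Minor-allele-frequency and per-individual genotyping-rate filters."""

    min_maf: float = 0.05
    min_genotyping_rate: float = 0.90

    def validate(self) -> None:
        if not (0 <= self.min_maf <= 1 and 0 <= self.min_genotyping_rate <= 1):
            raise ValueError("filter thresholds must lie in [0, 1]")


def filter_variants(
    variants: VariantTable, config: VariantFilterConfig | None = None
) -> tuple[VariantTable, dict]:
    """Drop low-call-rate individuals, then low-MAF SNPs.

    Individuals with a genotyping rate below the threshold are removed
    first; the pooled minor-allele frequency is then computed on the
    remaining individuals' called genotypes, and SNPs with MAF <= min_maf
    are dropped.  Returns the filtered table and a step-by-step report.
    """
    config = config or VariantFilterConfig()
    config.validate()
    g = variants.genotypes
    called = g != MISSING
    rate = called.mean(axis=0) if variants.n_snps else np.ones(variants.n_samples)
    keep_ind = rate >= config.min_genotyping_rate
    if not keep_ind.any():
        raise ValueError("all individuals fall below the genotyping-rate threshold")
    kept_samples = [s for s, k in zip(variants.samples, keep_ind) if k]
    vt = variants.take_samples(kept_samples)

    g = vt.genotypes
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(called, g, 0).sum(axis=1) / n_alleles
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep_snp = np.where(n_alleles > 0, maf > config.min_maf, False)
    out = vt.take_sites(keep_snp)
    report = {
        "n_individuals_in": variants.n_samples,
        "n_individuals_removed": int((~keep_ind).sum()),
        "n_snps_in": variants.n_snps,
        "n_snps_removed_maf": int((~keep_snp).sum()),
        "n_snps_out": out.n_snps,
    }
    return out, report


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


@dataclass
class FstResult:
    """Per-SNP Weir-Cockerham components and per-population frequencies."""

    table: pd.DataFrame  # scaffold pos a b c fst freq_a freq_b n_a n_b undefined
    pop_a: str
    pop_b: str
    size_a: int
    size_b: int

    @property
    def fst(self) -> np.ndarray:
        return self.table.fst.to_numpy()


def _pop_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n called diploids, alt frequency, observed het frequency) per SNP."""
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / (2.0 * n)
        h = (g == 1).sum(axis=1) / n
    return n, p, h


def weir_cockerham_fst(
    variants: VariantTable,
    pop_a_samples: list[str],
    pop_b_samples: list[str],
    pop_a: str = "pop_a",
    pop_b: str = "pop_b",
) -> FstResult:
    """Per-SNP Weir & Cockerham (1984) theta-hat for two populations.

    Sites with fewer than two called genotypes in either population, or a
    zero total variance (a + b + c = 0), are flagged ``undefined`` with a
    NaN Fst instead of being dropped.
    """
    ga = variants.take_samples(pop_a_samples).genotypes
    gb = variants.take_samples(pop_b_samples).genotypes
    na, pa, ha = _pop_stats(ga)
    nb, pb, hb = _pop_stats(gb)

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (na + nb) / r
        nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1.0)
        p_bar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1.0) * nbar)
        h_bar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * h_bar
        )
        c = h_bar / 2.0
        denom = a + b + c
        fst = a / denom

    undefined = (na < 2) | (nb < 2) | ~np.isfinite(fst) | (denom == 0)
    fst = np.where(undefined, np.nan, fst)
    table = pd.DataFrame(
        {
            "scaffold": variants.scaffold,
            "pos": variants.pos,
            "a": a,
            "b": b,
            "c": c,
            "fst": fst,
            "freq_a": pa,
            "freq_b": pb,
            "n_a": na.astype(int),
            "n_b": nb.astype(int),
            "undefined": undefined,
        }
    )
    return FstResult(
        table=table,
        pop_a=pop_a,
        pop_b=pop_b,
        size_a=len(pop_a_samples),
        size_b=len(pop_b_samples),
    )


def genome_wide_fst(fst: FstResult) -> float:
    """Genome-wide Weir-Cockerham estimate: sum(a) / sum(a + b + c).

    The ratio-of-sums combines variance components across SNPs before
    dividing (the estimator's recommended multi-locus form, and the one
    genome-wide Fst reports are built from); averaging per-SNP ratios
    instead is downward biased.
    """
    t = fst.table[~fst.table.undefined]
    denom = (t.a + t.b + t.c).sum()
    if denom == 0:
        return float("nan")
    return float(t.a.sum() / denom)


def identify_fixed(fst: FstResult, min_call_rate: float = 0.9) -> np.ndarray:
    """Boolean mask of SNPs fixed for opposite alleles between populations.

    Fixed means the called alt-allele frequency is exactly 0 in one
    population and exactly 1 in the other, with the per-population call
    rate at or above ``min_call_rate``.
    """
    t = fst.table
    rate_a = t.n_a.to_numpy() / fst.size_a
    rate_b = t.n_b.to_numpy() / fst.size_b
    pa = t.freq_a.to_numpy()
    pb = t.freq_b.to_numpy()
    opposite = ((pa == 0.0) & (pb == 1.0)) | ((pa == 1.0) & (pb == 0.0))
    return opposite & (rate_a >= min_call_rate) & (rate_b >= min_call_rate)


# ---------------------------------------------------------------------------
# permutation outlier threshold


@dataclass
class FstNull:
    """Permutation null for the genome-wide Fst outlier threshold."""

    per_permutation: np.ndarray
    threshold: float
    n_permutations: int
    percentile: float
    mode: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "percentile": self.percentile,
            "mode": self.mode,
            "seed": self.seed,
        }


def fst_permutation_threshold(
    variants: VariantTable,
    sizes: tuple[int, int],
    n_permutations: int = 1_000,
    percentile: float = 99.0,
    seed: int = 0,
    mode: str = "per_permutation",
) -> FstNull:
    """Outlier threshold from randomly permuted population labels.

    Each permutation assigns samples uniformly at random (without
    replacement) to two groups of the given sizes and computes per-SNP
    theta-hat.  In ``per_permutation`` mode (default) the threshold is the
    ``percentile`` of the per-permutation ``percentile``-across-SNPs values;
    in ``pooled`` mode it is the ``percentile`` of the pooled permuted Fst
    distribution.
    """
    n_a, n_b = sizes
    if n_a + n_b > variants.n_samples:
        raise ValueError("group sizes exceed available samples")
    if mode not in ("per_permutation", "pooled"):
        raise ValueError("mode must be 'per_permutation' or 'pooled'")
    rng = np.random.default_rng(seed)
    samples = np.array(variants.samples, dtype=object)
    per_perm = np.full(n_permutations, np.nan)
    pooled: list[np.ndarray] = []
    for i in range(n_permutations):
        perm = rng.permutation(len(samples))
        grp_a = samples[perm[:n_a]].tolist()
        grp_b = samples[perm[n_a : n_a + n_b]].tolist()
        fst = weir_cockerham_fst(variants, grp_a, grp_b).fst
        valid = fst[np.isfinite(fst)]
        if len(valid):
            per_perm[i] = np.percentile(valid, percentile)
            if mode == "pooled":
                pooled.append(valid)
    finite = per_perm[np.isfinite(per_perm)]
    if len(finite) == 0:
        threshold = float("-inf")
    elif mode == "pooled":
        threshold = float(np.percentile(np.concatenate(pooled), percentile))
    else:
        threshold = float(np.percentile(finite, percentile))
    if threshold <= 0.0:
        warnings.warn(
            "permuted Fst distribution degenerate (undefined or non-positive); "
            "threshold set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        threshold = 0.0
    return FstNull(
        per_permutation=per_perm,
        threshold=threshold,
        n_permutations=n_permutations,
        percentile=percentile,
        mode=mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# region assignment


@dataclass
class RegionAssignment:
    """SNP-to-gene-region assignment with per-SNP global category."""

    pairs: pd.DataFrame  # scaffold pos gene_id category
    per_snp: pd.DataFrame  # scaffold pos category gene_ids
    window: int

    def category_counts(self) -> dict:
        counts = {c: 0 for c in REGION_CATEGORIES}
        counts.update(self.per_snp.category.value_counts().to_dict())
        return counts


def assign_snp_regions(
    variants: VariantTable | pd.DataFrame,
    genes: list[GeneModel],
    window: int = 10_000,
) -> RegionAssignment:
    """Assign each SNP to gene-region categories.

    Per SNP-gene pair: ``exonic`` if inside any exon; ``intronic`` if
    inside the gene span but not an exon; ``within_10kb`` if within
    ``window`` bp (inclusive) upstream of the first exon's start or
    downstream of the last exon's end.  A SNP may associate with several
    genes; its global category is the highest-precedence one (exonic >
    intronic > within_10kb), or ``distal`` if it matches no gene.
    """
    if isinstance(variants, VariantTable):
        scaffold = variants.scaffold
        pos = variants.pos
    else:
        scaffold = variants["scaffold"].to_numpy()
        pos = variants["pos"].to_numpy()

    pair_rows = []
    best = np.full(len(pos), len(REGION_CATEGORIES) - 1)  # distal
    gene_lists: list[list[str]] = [[] for _ in pos]
    for gene in genes:
        on_scaf = np.flatnonzero(scaffold == gene.scaffold)
        if len(on_scaf) == 0:
            continue
        p = pos[on_scaf]
        near = (p >= gene.start - window) & (p <= gene.end + window)
        for idx, snp_pos in zip(on_scaf[near], p[near]):
            if any(s <= snp_pos <= e for s, e in gene.exons):
                cat = "exonic"
            elif gene.start <= snp_pos <= gene.end:
                cat = "intronic"
            else:
                cat = "within_10kb"
            pair_rows.append(
                {
                    "scaffold": gene.scaffold,
                    "pos": int(snp_pos),
                    "gene_id": gene.gene_id,
                    "category": cat,
                }
            )
            rank = _PRECEDENCE[cat]
            if rank < best[idx]:
                best[idx] = rank
            gene_lists[idx].append(gene.gene_id)

    per_snp = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": pos,
            "category": [REGION_CATEGORIES[b] for b in best],
            "gene_ids": [",".join(g) for g in gene_lists],
        }
    )
    pairs = pd.DataFrame(pair_rows, columns=["scaffold", "pos", "gene_id", "category"])
    return RegionAssignment(pairs=pairs, per_snp=per_snp, window=window)
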