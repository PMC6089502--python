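# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package, and what the synthetic generators do and do not
emulate.

## Differential expression

Counts are modeled as K_gj ~ NB(mean = s_j·q_gj, dispersion = α_g), with
log q_gj linear in a single two-level species indicator. The pieces:

**Size factors.** s_j is the median across genes (restricted to genes with
a positive count in every sample) of K_gj divided by the gene's geometric
mean across samples. Only factor ratios are identified: multiplying one
library by c also shifts every gene's geometric mean by c^(1/n), so all
factors pick up a common c^(−1/n); no renormalization is applied.

**Dispersions.** Per-gene raw estimates are method-of-moments on
normalized counts, using the pooled within-group variance:
α_raw = (v̂ − μ̂·mean(1/s))/μ̂², floored at 1e-8. A parametric trend
α(μ) = a0/μ + a1 is fit by non-negative least squares with iterative
trimming of points more than 100× off the trend. The final estimate
combines log raw and log trend with precision weights (sampling variance of
the log raw estimate taken as 2/df, prior variance 0.25), except that raw
estimates more than 2 prior SDs above the trend are kept as-is (dispersion
outliers). This is a deliberately light-weight stand-in for Cox–Reid
adjusted profile likelihood: it is calibrated by tests (Poisson data yield
median final dispersion ≤ 0.01 at 20 samples; true α = 0.5 is recovered
within ±50%) rather than matched to any particular implementation.

**Wald test.** The per-gene NB GLM (intercept + group indicator, log size
factors as offset, fixed dispersion) is fit by IRLS vectorized across
genes; the 2×2 weighted normal equations are solved in closed form, linear
predictors are clipped to ±30 to survive all-zero groups, and a 1e-12 ridge
stabilizes degenerate weights. The reported log2 fold change is the
maximum-likelihood estimate — no shrinkage prior, although the framework
this emulates reports posterior estimates; importing an unstated prior
seemed worse than documenting the divergence. Wald z = LFC/SE against a
standard normal, two-sided.

**Filtering and FDR.** Genes with total count < 2 across the contrast's
samples are discarded up front (`filtered_low_total`). Independent
filtering scans mean-normalized-count thresholds over the 0–95% quantile
grid in 5% steps and keeps the threshold maximizing BH discoveries at the
target FDR; sub-threshold genes are `filtered_independent` and receive no
adjusted p. BH is the standard step-up with monotonicity enforcement. The
exact filtering rule used upstream of the original counts is not
recoverable, so results at the filtering margin can differ; the scan-based
rule is deterministic and documented here instead.

## Concordance

Overlap enrichment is the one-sided hypergeometric upper tail
P(X ≥ n_both) over a background defaulting to genes tested in both
contrasts (overridable to a fixed N for printed-count reproductions). The
direction null treats each shared-DE gene as a fair coin: draws from
Binomial(n_overlap, ½), empirical p = (1 + #{X ≥ n_same})/(1 + n_perm) —
the +1 correction keeps Monte-Carlo p-values off zero — with the exact
binomial tail reported alongside. Genes with an LFC of exactly 0 cannot be
assigned a direction and are excluded from the tallies with a warning.

Down-sampling subsamples generalists and the first specialist uniformly
without replacement (no lake stratification — none is implied by the
design) to the second specialist's sample size, re-runs both contrasts per
permutation, and reports the distribution of overlap sizes and
same-direction proportions.

## Weir–Cockerham Fst

Per SNP, the two-population diploid estimator computes a (among
populations), b (among individuals within populations), and c (within
individuals) from per-population called sample sizes, allele frequencies,
and observed heterozygosities; θ̂ = a/(a+b+c). Negative values are
reported as computed (not clamped); sites with fewer than two called
genotypes in a population or a zero denominator are flagged undefined
rather than dropped. The multi-locus summary `genome_wide_fst` is the
ratio of sums Σa/Σ(a+b+c), which tracks the Balding–Nichols differentiation
parameter to within ±0.01 in the calibration tests; the naive mean of
per-SNP ratios is downward biased (≈0.14 at F = 0.2 with 20+20 samples)
and is not used as a summary.

Filters run in the stated order: individuals below the 90% genotyping rate
first, then SNPs with pooled minor-allele frequency ≤ 5%. A SNP is *fixed*
when the called alt frequency is exactly 0 in one population and exactly 1
in the other, guarded by a ≥ 90% per-population call rate — an Fst = 1
criterion would be equivalent under complete data but fragile under
missingness.

The outlier threshold permutes population labels: each of (by default)
1,000 permutations draws two groups of the original sizes uniformly without
replacement, computes per-SNP θ̂, and records the 99th percentile across
SNPs; the threshold is the 99th percentile of those per-permutation values.
This follows the two-sentence description of the procedure literally; the
alternative reading (99th percentile of the pooled permuted distribution)
is available behind `mode="pooled"`. Degenerate inputs (all θ̂ undefined
or non-positive) yield a threshold of 0 with a warning.

## Gene-region assignment

Per SNP–gene pair: exonic if inside any exon (1-based inclusive), intronic
if inside the gene span but not an exon, within-10-kb if within 10,000 bp
*inclusive* of the first exon's start or the last exon's end (the boundary
is not specified upstream; inclusive was chosen and pinned by a test), else
distal. A SNP near several genes keeps one category per gene; its global
category is the highest-precedence one (exonic > intronic > within-10-kb).
Strand is ignored for the proximity window.

## Sweep scan

Each scaffold longer than 10 kb is cut into equal windows (1,000 by
default; scans in the test-suite use 20–40 windows on 100-kb scaffolds so
that windows keep ≥ 5 SNPs). The null composite likelihood of a window
sums log Φ(class) over its complete-call polymorphic sites, where Φ is the
scaffold-wide folded SFS (hypergeometric projection handles missingness
when estimating Φ; an externally supplied background spectrum — e.g. one
corrected for a demographic bottleneck — can replace it).

The sweep alternative evaluates, at the window midpoint, a star-genealogy
hitchhiking transform: a site at distance d lets each of the n_p sampled
lineages escape the sweep independently with probability
p_e = 1 − exp(−α·d). Escaped lineages **retain their original alleles** —
the escaped derived count is a without-replacement (hypergeometric) draw
from the pre-sweep configuration of b derived copies — while the
non-escaped lineages coalesce onto the sweeping haplotype and inherit its
allele in a single Bernoulli(b/n_p) draw. The resulting count is folded
and conditioned on polymorphism. Retention (rather than binomial
resampling of the pre-sweep frequency) is what makes the all-escape limit
exact: at p_e = 1 the transformed spectrum *is* Φ, so the large-α end of
the grid recovers the null and CLR → 0 on null data. The transform is
pinned by an exhaustive enumeration oracle in the tests (every allele
arrangement × escape pattern × collapse outcome at n_p = 4 and 6, agreement
to 1e-10).

CLR = max(0, 2·max_α[ℓ(α) − ℓ0]) over a 25-point log-spaced α grid
(1e-7–1e-1 per bp); evaluation is at window midpoints only — a coarser
positional grid than a full per-position scan, chosen for desk-scale
runtimes. Windows with fewer than 5 usable SNPs are ineligible (CLR on
near-empty windows is noise). Outliers are eligible windows strictly above
the per-scaffold 95th percentile of eligible-window CLRs; scaffolds with
fewer than 20 eligible windows are reported unscannable. By construction
≈5% of eligible windows are flagged on neutral scaffolds; the detection
property (the argmax window contains the true sweep center in ≥ 80% of
simulated replicates at α_true = 1e-4, 20 windows of 5 kb, 2,000 sites,
n_p = 20) is part of the acceptance suite.

## Pleiotropy

One NB2 regression per metric: count ~ 1 + I(group = divergent), log link,
maximum likelihood via statsmodels. The reported effect is the log rate
ratio of the divergent group with a two-sided Wald p. When the dispersion
estimate collapses to the Poisson boundary (α < 1e-4) or the NB fit fails
to converge, a Poisson GLM supplies the coefficients and the result is
flagged `poisson_fallback`; in the Poisson limit the two agree to < 1e-4 by
construction (tested). One model per metric, not a joint fit.

## Synthetic generators

All generators are pure functions of (config, seed) via a dedicated
`numpy` Generator; identical configs are bit-identical.

**Expression.** Gene classes are partitioned by deterministic
largest-remainder rounding of the configured fractions. Default fractions
put 88% of genes at null, make shared-DE genes overwhelmingly concordant
(2% up-both, 3% down-both vs 0.5% opposite), and give the scale-eater
contrast more private DE (5.5%) than the snail-eater contrast (1%) —
echoing the observed asymmetry of the motivating study. The default design
is 6 generalists, 6 snail-eaters, and 3 (early) / 2 (late stage)
scale-eaters. Baselines are log-normal(meanlog 4, sdlog 1.5) (median ≈ 55
counts); per-sample depth factors are log-normal with σ = 0.3 so size-factor
estimation is non-trivial; the dispersion trend is α(μ) = 2/μ + 0.05.
The within-species variance of the real system is unreported, so the trend
constants are generic bulk-RNA-seq values chosen once, not calibrated to
pupfish data. Not emulated: lake-of-origin batch effects, isoform
structure, gene–gene correlation, outlier samples — so passing recovery
tests demonstrates correctness of the machinery under a well-specified NB
world, not robustness to those real-data features.

**Genotypes.** Ancestral frequencies Uniform(0.05, 0.95); population
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) per the Balding–Nichols model
(degenerating to identical frequencies at F = 0); diploid genotypes
Binomial(2, p_pop); a chosen number of loci overwritten as fixed
differences (alt frequency 1 vs 0); uniform genotype masking for
missingness. Linkage is absent — every SNP is independent.

**Sweep scaffolds.** Neutral folded classes are drawn from the standard
spectrum (weight 1/i + 1/(n−i), halved at i = n/2). Sweep distortion uses
the same star-genealogy mechanism as the scan's likelihood (escape,
retention, collapse), applied per site by simulation; monomorphic outcomes
are dropped, mirroring the scan's conditioning on polymorphism. Because
simulator and scan share the model family, the localization test is a
well-specified-power check, not a robustness check against, e.g.,
recombination-structured genealogies or soft sweeps.

**Pleiotropy tables.** Three NB2 metrics with parallel-group means
(8, 12, 5) and a configurable divergent/parallel rate ratio applied to all
three; dispersion 0.5 by default.

## Problem sizes and determinism

The acceptance suite runs the sizes its properties state: 20 seeds of the
2,000-gene/6v6 DE design, 100 down-sampling permutations, 10,000 SNPs at
20+20 for Fst calibration, 50 sweep replicates, 200 pleiotropy null tables.
The full pipeline fixture in the tests uses a few hundred genes and SNPs
and completes in seconds; all randomness flows from named per-stage seeds
recorded in the report, and a rerun with the same config reproduces the
report byte-for-byte.

## Known limitations

- Single two-level design factor; no batch/lake covariates or multi-factor
  designs.
- LFCs are unshrunk MLEs; rankings of low-count genes are noisier than
  with a shrinkage prior.
- The sweep scan evaluates one position per window and uses the folded
  spectrum only; it is not a replacement for a full positional-grid scan
  with polarized spectra, and provides no genome-wide FDR for sweep calls.
- The Fst permutation threshold follows the literal two-step percentile
  reading; the pooled alternative can give materially different thresholds
  on small panels.
- Pleiotropy annotations are consumed as a pre-built table; ortholog
  mapping and database extraction are upstream manual steps.
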